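# Methods

## The screen

The package implements a recessive-model collapsing analysis. The unit of
evidence is the *homozygous carrier*: a subject homozygous for the alternate
allele of at least one qualifying variant in a gene set. Carrier counts in
cases and controls form a 2×2 table; the test is the one-tailed Fisher exact
test with the alternative fixed as enrichment in cases. Collapsing is at the
subject level (carrier yes/no), never allele- or variant-level, so a subject
homozygous at several qualifying sites counts once.

Qualifying variants are defined by nested rarity/impact categories applied
after QC, all with strict inequalities:

| category | definition |
|---|---|
| A | dataset MAF < 0.001 |
| B | A ∧ population MAF < 0.01 |
| C | A ∧ population MAF < 0.001 |
| D | C ∧ likely disruptive |

*Dataset MAF* is the folded minor-allele frequency over all non-missing
calls, cases and controls pooled (the category table reports one pooled
individual count per variant, so pooling is the consistent reading).
*Population MAF* is the maximum across external panels (ExAC, ESP, 1000
Genomes) and is consumed as a single precomputed annotation. *Likely
disruptive* means missense with CADD phred > 20, nonsense, or a
splice-junction variant (within 3 bp of an exon/intron boundary per the
upstream annotation). Whether splice-junction variants were additionally
required to pass CADD > 20 in the original screen is ambiguous — the stated
rule admits a CADD 0.66 splice variant that the printed likely-disruptive
count appears to exclude — so both rule variants are implemented
(`splice_needs_cadd`) and neither is treated as uniquely correct.

Strictness of the thresholds is not cosmetic: a hit with population MAF of
exactly 1.00e-3 is classified B-but-not-C, which is the only reading
consistent with the published category counts.

### QC

Order: GQ → homozygous-call contamination → missingness → indels.

1. calls with GQ < 20 (strict) become missing;
2. homozygous-alt calls whose reference reads exceed 5% of the total bases
   at the position (strict) are invalidated — per *call*, not per variant,
   since the stated purpose is removing possible false homozygous calls and
   dropping the site would also discard valid heterozygotes; zero-depth
   homozygous calls are unverifiable and likewise invalidated;
3. variants missing in more than 10% (strict) of cases *or* of controls are
   dropped — missingness is computed on filtered genotypes, which is why
   the call-level filters run first;
4. indels are removed outright.

The stack is idempotent, never un-masks a call, and never rewrites an
alt-allele count except to missing.

### Simulation null

To test set-specificity rather than genome-wide homozygosity excess, the
carrier-frequency difference (case proportion − control proportion) is
recomputed over random gene sets of the same size (default 120 genes,
5,000 replicates), drawn uniformly without replacement within a replicate
and independently across replicates, with no matching on gene length or
variant count. The gene universe is every gene present in the matrix;
genes contributing no qualifying variant stay in the universe (they dilute
random sets exactly as they dilute the genome). The empirical p is the
fraction of replicates with a difference ≥ the observed one — inclusive,
denominator n_sims — with the add-one corrected (count+1)/(n_sims+1) value
reported alongside since the raw fraction can be exactly zero.

### Power

For hypothesized carrier frequencies (p_case, p_control), carrier counts are
binomial and the power at level α is

  Σ_b P(B = b) · P(A ≥ a_min(b)),

where a_min(b) is the smallest case count whose one-tailed Fisher p against
b control carriers falls below α (found by binary search on the
monotonicity of the tail p). With p_control = 0 this collapses to a single
binomial upper tail: for the weakest published category (3/4225 vs 0,
α = 0.05) rejection needs ≥ 4 case carriers and the power is
P(Binom(4225, 3/4225) ≥ 4) = 0.3528 — reported as ≈ 35%, consistent with
the published "33%" given that the original computation method is not
stated. A seeded Monte-Carlo variant handles arbitrary scenarios and agrees
with the exact sum within simulation error.

### Assay ANOVA / LSD

One-way ANOVA is a pure function of per-group (n, mean, SD):
SS_between from group means and sizes, SS_within = Σ(nᵢ−1)sᵢ², so
`anova_from_summary` is algebraically identical to `anova_raw` whenever the
raw data match the summaries (verified to machine precision in the tests).
SDs are read as sample standard deviations (n−1), the convention for "(SD)"
in biology tables; `ddof=0` switches to population SDs. Fisher LSD p-values
are two-sided t-tests pooling MS_within on df_within degrees of freedom and
are deliberately unadjusted for multiplicity. Degenerate inputs (zero
within-group variance with unequal means) yield F = ∞, p = 0 and a
`degenerate` flag rather than an exception. Reproduction of printed results
from printed summaries is rounding-limited: the published F of 24.094
recomputes to 23.92 from the rounded means/SDs (0.7% off), and the LSD
0.681 to 0.685.

## The synthetic cohort generator

`generate_cohort` emulates the structure the screen assumes, not any real
dataset:

* **Genotypes** — independent per variant under Hardy-Weinberg at a
  per-variant true frequency drawn from the configured spectrum. Default
  spectrum: log-uniform on [2.5e-5, 0.5], a crude neutral site-frequency
  spectrum placing ~37% of variants below 10⁻³. No linkage disequilibrium,
  relatedness or population structure.
* **Exome scaffold** — genes `G000001…` with Poisson variant counts
  (default mean 8/gene); annotations (consequence class, CADD, population
  frequency correlated with true frequency on the log scale) exist to
  exercise the classifier, not to model biology.
* **Genotype quality** — a `missing_rate` fraction of calls (default 2%)
  draws GQ uniformly on [0, 19] (destined to be masked by QC), the rest on
  [20, 99]; realised by an inverse-CDF split of a single uniform draw.
* **Depth** — per-subject mean coverage ~ Gamma(dispersion, mean/dispersion)
  (defaults 8, 40/8) with per-call Poisson depth, i.e. marginally
  negative-binomial with within-subject coverage correlation. Hom-ref calls
  carry pure reference support; heterozygous calls draw ref reads
  Binomial(depth, 0.5); clean homozygous-alt calls draw rare reference
  error reads capped below the 5% contamination boundary, so "clean" homs
  are clean by construction and the observable contamination rate equals
  the configured one.
* **Contamination** — a `contamination_rate` fraction (default 2%) of
  hom-alt calls gets a ref-read fraction drawn from [8%, 30%], always
  strictly above the 5% filter boundary.
* **Planting** — `planted_case_hom_excess` randomly chosen cases are made
  homozygous (clean, high-GQ, full-alt depth) at distinct ultra-rare
  (true frequency < `plant_max_freq`, default 10⁻³) non-indel variants in
  distinct genes of the target set: the alternative hypothesis the test
  targets, recorded in a `TruthRecord` for parameter-recovery tests.

What passing tests on these cohorts does **not** show: robustness to
population stratification, relatedness, batch effects in coverage or
annotation error — none of which the generator models (the original
analysis handled ancestry by a precomputed subject exclusion list, which
the pipeline consumes but does not compute).

## Scale and threshold choices in the repeated-cohort experiments

The published simulation p-values (0.0408–0.0482) were computed on an
access-controlled cohort of 10,059 exomes and cannot be recomputed here;
the resampling machinery is validated distributionally instead
(`homburden.experiments`):

* **Uniformity** — over 200 independently seeded null cohorts, the
  target-set empirical p must be approximately Uniform(0, 1); measured as a
  KS distance (< 0.1 passes; observed 0.063 at the committed seed, noise
  floor for 200 draws is ≈ 0.06).
* **Detection** — over 50 cohorts with 8 planted case carriers (one-tailed
  Fisher p ≈ 0.004 against a zero-control background, the regime of the
  published screen's strongest category), the empirical p must fall below
  0.05 in ≥ 90% of cohorts (observed: 100%).

Experiment cohorts use 500 cases / 500 controls, 2,000 genes, 4 variants
per gene and 1,000 replicates per cohort — sizes chosen so a full
generation → QC → classification → resampling cycle stays around a second,
making hundreds of independent cohorts practical.

The qualifying rarity bound in these experiments is scale-matched rather
than the headline 0.001: with n subjects, one homozygote already implies a
dataset MAF of at least 1/n, so at desk scale (10³ subjects) **no** variant
carrying a homozygote can pass MAF < 10⁻³, and the full-cohort threshold
would make every carrier count identically zero. The uniformity experiment
uses MAF < 0.1, giving the carrier-frequency difference a finely resolved
support (the KS comparison is meaningless on a nearly-degenerate discrete
statistic); the planted-detection experiment uses MAF < 0.002, the
ultra-rare regime of the real screen, where a planted homozygote (dataset
MAF 10⁻³) qualifies and background carriers are rare.

## Numerical and interface notes

* Fisher p via the exact hypergeometric tail (scipy); the test suite checks
  it against independent brute-force enumeration over the full support for
  tables with N ≤ 200, the zero-control closed form, and margin-fixed
  monotonicity.
* Ties in the empirical p are exact: observed and replicate differences are
  computed by the same integer-count expression, so the inclusive ≥ needs
  no epsilon.
* Dataset MAF for a variant with zero non-missing calls is undefined (NaN)
  and the variant qualifies for nothing.
* Unknown consequence classes are non-disruptive, with a warning.
* VCF dialect: v4.2, `GT:GQ:AD`, INFO `GENE`, `CSQ_CLASS`, `CADD`,
  `POPMAX_AF`, `INDEL`; 1-based coordinates; case/control labels travel in
  a `<vcf>.groups.tsv` sidecar (VCF has no standard slot for them). Reading
  uses cyvcf2; missing GQ/AD fields degrade gracefully (the contamination
  filter skips calls it cannot assess). Multi-allelic handling: one ALT per
  record (upstream decomposition assumed).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixed seed ⇒ bit-identical cohorts, null
  distributions and report bundles.
* The packaged hit-table fixture transcribes the published six variants
  verbatim, including a printed dataset MAF (9.94e-4 over 10,055
  individuals) that no integral allele count reproduces exactly — the
  expansion uses the nearest count (20 alleles, 9.945e-4) — and a missense
  annotation with CADD 0.03 left uncorrected.
* The placeholder 120-gene set mixes 45 well-known GABAergic genes with
  clearly labelled synthetic symbols; the real curated list is a
  user-supplied input.

## Known limitations

* The screen tests carrier counts only; no covariates, no
  relatedness/ancestry adjustment, no multiple-testing correction across
  categories (deliberately, to mirror the original analysis).
* The random-set null matches set size only — not gene length, variant
  count or coverage.
* Exact power enumeration assumes independent binomial carrier counts; at
  extreme n with non-trivial p_control the control-side support is
  truncated at mass 10⁻¹².
* The generator's annotations are decorative; no real gene models or CADD
  distributions are emulated.
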