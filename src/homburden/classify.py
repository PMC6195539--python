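"""Dataset minor-allele frequency and the four nested rarity categories.

Every QC-passing variant is assigned to a subset of four nested
categories:

* **A** — ultra-rare in the study cohort (dataset MAF < 0.001);
* **B** — A, and rare in external human populations (population MAF < 0.01);
* **C** — A, and ultra-rare in external populations (population MAF < 0.001);
* **D** — C, and likely disruptive.

"Dataset MAF" is the minor-allele frequency over the non-missing calls of
cases and controls combined, computed after QC.  "Population MAF" is the
maximum frequency across external reference panels (ExAC, ESP, 1000
Genomes), consumed as a single precomputed annotation.  All thresholds
are strict inequalities, so a variant at exactly a threshold does not
qualify — e.g. a population MAF of exactly 1e-3 is excluded from C.

A *likely disruptive* variant is a missense variant with CADD phred > 20
(strict), a nonsense substitution, or a splice-junction variant (within
3 bp of an exon/intron boundary, per the upstream annotation).  A second
rule variant additionally requires CADD > 20 for splice-junction variants
(``splice_needs_cadd=True``); which of the two the original screen used
is ambiguous, so both are exposed and nothing is guessed.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .matrix import CSQ_CLASSES, MISSING, CohortMatrix

__all__ = [
    "CATEGORIES",
    "dataset_maf",
    "is_likely_disruptive",
    "classify_variants",
    "load_table3_fixture",
    "table3_cohort",
]

CATEGORIES = ("A", "B", "C", "D")


def dataset_maf(matrix: CohortMatrix) -> np.ndarray:
    """Minor-allele frequency per variant over all non-missing calls.

    Cases and controls are pooled.  The returned frequency is folded to
    the minor allele (≤ 0.5).  Variants with zero non-missing calls get
    NaN (undefined; they are excluded from classification).
    """
    called = matrix.geno != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, matrix.geno, 0).sum(axis=1, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.where(np.isnan(f), np.nan, np.minimum(f, 1.0 - f))


def is_likely_disruptive(
    csq_class,
    cadd,
    cadd_threshold: float = 20.0,
    splice_needs_cadd: bool = False,
):
    """Flag likely disruptive variants (vectorised over array inputs).

    True iff missense with CADD strictly above ``cadd_threshold``,
    nonsense, or splice-junction (the latter also requiring CADD above
    threshold when ``splice_needs_cadd``).  Unknown consequence classes
    yield False with a warning.
    """
    csq = np.asarray(csq_class, dtype=object)
    cadd = np.asarray(cadd, dtype=float)
    unknown = ~np.isin(csq, CSQ_CLASSES)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} variant(s) with unknown consequence class "
            "treated as non-disruptive",
            stacklevel=2,
        )
    high_cadd = cadd > cadd_threshold
    out = ((csq == "missense") & high_cadd) | (csq == "nonsense")
    splice = csq == "splice_junction"
    out |= splice & high_cadd if splice_needs_cadd else splice
    if out.ndim == 0:
        return bool(out)
    return out


def classify_variants(
    matrix: CohortMatrix,
    dataset_maf_threshold: float = 1e-3,
    pop_rare_threshold: float = 1e-2,
    pop_ultrarare_threshold: float = 1e-3,
    cadd_threshold: float = 20.0,
    splice_needs_cadd: bool = False,
) -> pd.DataFrame:
    """Classify every variant of a QC'd matrix into the nested categories.

    Returns a DataFrame aligned with ``matrix.variants`` carrying
    ``dataset_maf`` and boolean columns ``cat_A`` … ``cat_D``.  The
    nesting D ⊆ C ⊆ B ⊆ A holds by construction.  Classification is a
    pure function of (dataset MAF, population MAF, consequence class,
    CADD); variants with undefined dataset MAF qualify for nothing.
    """
    maf = dataset_maf(matrix)
    v = matrix.variants
    pop = v["popmax_af"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        cat_a = maf < dataset_maf_threshold
    cat_a &= ~np.isnan(maf)
    cat_b = cat_a & (pop < pop_rare_threshold)
    cat_c = cat_a & (pop < pop_ultrarare_threshold)
    disruptive = is_likely_disruptive(
        v["csq_class"].to_numpy(dtype=object),
        v["cadd"].to_numpy(dtype=float),
        cadd_threshold=cadd_threshold,
        splice_needs_cadd=splice_needs_cadd,
    )
    cat_d = cat_c & disruptive

    out = pd.DataFrame(
        {
            "variant_id": matrix.variant_ids.to_numpy(),
            "gene": v["gene"].to_numpy(),
            "csq_class": v["csq_class"].to_numpy(),
            "cadd": v["cadd"].to_numpy(),
            "dataset_maf": maf,
            "popmax_af": pop,
            "cat_A": cat_a,
            "cat_B": cat_b,
            "cat_C": cat_c,
            "cat_D": cat_d,
        }
    )
    return out


# ----------------------------------------------------------------------
# Packaged worked-example fixture: the six homozygous hits of the screen
# ----------------------------------------------------------------------

def load_table3_fixture() -> pd.DataFrame:
    """Load the packaged six-variant homozygous-hit table.

    The table transcribes, verbatim, the published list of rare variants
    found in a homozygous state (genomic position, affected/unaffected
    homozygote counts, gene, consequence class, dataset MAF with the
    number of genotyped individuals, maximum population MAF, CADD).
    """
    with resources.files("homburden.data").joinpath("table3_fixture.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def table3_cohort(n_cases: int = 4225, n_controls: int = 5834) -> CohortMatrix:
    """Expand the packaged hit table into a full synthetic cohort matrix.

    Each fixture row contributes one variant whose observed allele counts
    reproduce the printed dataset MAF: the alt-allele count is
    ``round(MAF × 2 × n_individuals)``, realised as one homozygote
    (placed in a case or control according to the affected/unaffected
    column) plus heterozygotes; calls beyond ``n_individuals`` are marked
    missing.  Heterozygous and missing calls are placed among controls,
    which leaves group-level homozygote counts exact.  All calls are
    clean (GQ 99, full-depth support) so the cohort passes QC unchanged.
    """
    fx = load_table3_fixture()
    n_sub = n_cases + n_controls
    n_var = len(fx)

    geno = np.zeros((n_var, n_sub), dtype=np.int8)
    chroms, poss, refs, alts = [], [], [], []
    for i, row in fx.iterrows():
        loc, change = row["genomic"].split(" ", 1)
        chrom, pos = loc.replace("chr", "").replace("Chr", "").split(":")
        ref, alt = change.split(">")
        chroms.append(chrom)
        poss.append(int(pos))
        refs.append(ref.strip())
        alts.append(alt.strip())

        n_ind = int(row["n_individuals"])
        alt_alleles = int(round(row["dataset_maf"] * 2 * n_ind))
        n_aff, n_unaff = (int(x) for x in row["affected_unaffected"].split("/"))
        n_hom = n_aff + n_unaff
        n_het = alt_alleles - 2 * n_hom
        if n_het < 0:
            raise ValueError(f"fixture row {i}: allele count below homozygote count")
        # homozygotes: affected first (case block), unaffected at start of
        # the control block
        for k in range(n_aff):
            geno[i, (i + k) % n_cases] = 2  # distinct case per fixture row
        for k in range(n_unaff):
            geno[i, n_cases + (i + k) % n_controls] = 2
        # heterozygotes and missing calls among the last controls
        geno[i, n_sub - n_het:] = 1
        n_missing = n_sub - n_ind
        geno[i, n_sub - n_het - n_missing : n_sub - n_het] = MISSING

    from .matrix import make_variant_table  # local import avoids cycle at init

    variants = make_variant_table(
        chrom=chroms,
        pos=poss,
        ref=refs,
        alt=alts,
        gene=fx["gene"],
        csq_class=fx["mutation_class"],
        cadd=fx["cadd"],
        popmax_af=fx["popmax_af"],
        is_indel=[False] * n_var,
    )
    subject_ids = np.array(
        [f"CASE{i + 1:06d}" for i in range(n_cases)]
        + [f"CTRL{i + 1:06d}" for i in range(n_controls)],
        dtype=object,
    )
    is_case = np.zeros(n_sub, dtype=bool)
    is_case[:n_cases] = True
    gq = np.full((n_var, n_sub), 99, dtype=np.int16)
    depth = 60
    alt_reads = np.where(geno == 2, depth, np.where(geno == 1, depth // 2, 0)).astype(
        np.int32
    )
    alt_reads[geno == MISSING] = 0
    ref_reads = (depth - alt_reads).astype(np.int32)
    return CohortMatrix(
        variants=variants,
        subject_ids=subject_ids,
        is_case=is_case,
        geno=geno,
        gq=gq,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
    )
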