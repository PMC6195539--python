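"""Synthetic case-control exome cohort generator.

Emulates the structure of a large case-control exome-sequencing dataset as
the downstream screen assumes it: two labelled groups, many genes each
carrying a handful of coding variants, per-variant alt-allele frequencies
spanning ultra-rare to common, per-call genotype quality (GQ) and ref/alt
read depths, and optional injected artefacts — contaminated homozygous
calls (ref reads exceeding 5% of depth) and low-GQ calls destined to be
masked by QC.  An optional planted excess of homozygous-qualifying-variant
carriers among cases in a designated gene set realises the alternative
hypothesis that the burden test targets.

Genotypes are drawn independently per variant under Hardy-Weinberg
equilibrium — the simplest exchangeable null consistent with the burden
test's assumptions.  No linkage disequilibrium, relatedness or population
structure is simulated, and depths are summary counts, not reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import CohortMatrix, CohortValidationError, make_variant_table

__all__ = ["CohortConfig", "TruthRecord", "generate_cohort"]


class ConfigError(CohortValidationError):
    """Raised when a cohort configuration is invalid."""


# Ref-read error rate on clean homozygous-alt calls (capped below the 5%
# contamination boundary so "clean" homs stay clean by construction), and
# the matching alt-read error rate on homozygous-reference calls.
_HOM_ERR = 0.001
# Contaminated hom-alt calls draw their ref-read fraction from this range,
# always above the 5% filter boundary.
_CONTAM_FRAC = (0.08, 0.30)


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    The defaults mirror the cohort the screen was designed for: 4,225 cases
    and 5,834 controls over 18,024 genes with a 120-gene target set.  All
    sizes scale down freely for testing.

    Attributes
    ----------
    n_cases, n_controls
        Group sizes.
    n_genes
        Number of autosomal genes in the simulated exome.
    variants_per_gene
        Mean of the per-gene Poisson variant count.
    maf_spectrum
        Per-variant alt-allele frequency distribution.  ``{"kind":
        "loguniform", "min": ..., "max": ...}`` (default; a crude neutral
        site-frequency spectrum placing substantial mass below 0.001),
        ``{"kind": "beta", "a": ..., "b": ...}`` or ``{"kind": "fixed",
        "value": ...}``.
    target_set_size
        Size of the designated gene set (the "target" of the screen).
    planted_case_hom_excess
        Number of extra case subjects made homozygous for an ultra-rare
        variant of the target set (0 = null cohort).  Plants are clean
        calls: high GQ, full-alt depth.
    gq_distribution
        ``{"low_max": 19, "high_max": 99}``: low-GQ calls draw uniformly
        on [0, low_max], ordinary calls on [low_max+1, high_max].
    depth_distribution
        ``{"mean": 40, "dispersion": 8}``: per-subject mean coverage is
        Gamma(dispersion, mean/dispersion) and per-call depth Poisson
        around it, i.e. marginally negative-binomial
        (variance = mean + mean²/dispersion) with within-subject
        coverage correlation.
    contamination_rate
        Fraction of (non-planted) hom-alt calls given >5% ref reads.
    missing_rate
        Fraction of calls given GQ below 20 (masked later by QC).
    indel_rate
        Fraction of variants flagged as indels (excluded later by QC).
    plant_max_freq
        Plants are inserted at target-set variants whose true alt-allele
        frequency is below this (ultra-rare by construction).
    seed
        Seed of the generator; fixed seed gives bit-identical cohorts.
    """

    n_cases: int = 4225
    n_controls: int = 5834
    n_genes: int = 18024
    variants_per_gene: float = 8.0
    maf_spectrum: dict = field(
        default_factory=lambda: {"kind": "loguniform", "min": 2.5e-5, "max": 0.5}
    )
    target_set_size: int = 120
    planted_case_hom_excess: int = 0
    gq_distribution: dict = field(
        default_factory=lambda: {"low_max": 19, "high_max": 99}
    )
    depth_distribution: dict = field(
        default_factory=lambda: {"mean": 40.0, "dispersion": 8.0}
    )
    contamination_rate: float = 0.02
    missing_rate: float = 0.02
    indel_rate: float = 0.05
    plant_max_freq: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_genes": self.n_genes,
            "target_set_size": self.target_set_size,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.target_set_size > self.n_genes:
            raise ConfigError("target_set_size exceeds n_genes")
        if not (self.variants_per_gene > 0 and math.isfinite(self.variants_per_gene)):
            raise ConfigError("variants_per_gene must be positive and finite")
        for name in ("contamination_rate", "missing_rate", "indel_rate"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.planted_case_hom_excess < 0:
            raise ConfigError("planted_case_hom_excess must be non-negative")
        if self.planted_case_hom_excess > self.n_cases:
            raise ConfigError("cannot plant more carriers than cases")
        if not (0.0 < self.plant_max_freq <= 0.5):
            raise ConfigError("plant_max_freq must lie in (0, 0.5]")
        kind = self.maf_spectrum.get("kind")
        if kind == "loguniform":
            lo, hi = self.maf_spectrum["min"], self.maf_spectrum["max"]
            if not (0 < lo <= hi <= 1):
                raise ConfigError("loguniform maf_spectrum needs 0 < min <= max <= 1")
        elif kind == "beta":
            if self.maf_spectrum["a"] <= 0 or self.maf_spectrum["b"] <= 0:
                raise ConfigError("beta maf_spectrum needs positive shape parameters")
        elif kind == "fixed":
            v = self.maf_spectrum["value"]
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigError("fixed maf_spectrum value must lie in [0, 1]")
        else:
            raise ConfigError(f"unknown maf_spectrum kind {kind!r}")
        d = self.depth_distribution
        if d["mean"] <= 0 or d["dispersion"] <= 0:
            raise ConfigError("depth mean and dispersion must be positive")
        g = self.gq_distribution
        if not (0 <= g["low_max"] < g["high_max"]):
            raise ConfigError("gq_distribution needs 0 <= low_max < high_max")


@dataclass
class TruthRecord:
    """Generator bookkeeping for parameter-recovery checks.

    Records exactly what was planted and injected so tests can verify that
    QC and the burden counts recover it.
    """

    target_genes: list
    true_freqs: np.ndarray
    planted_case_carriers: list
    planted_control_carriers: list
    planted_calls: list  # (variant_index, subject_index) pairs
    n_contaminated_calls: int
    n_low_gq_calls: int
    n_indels: int


def _draw_freqs(rng: np.random.Generator, spec: dict, n: int) -> np.ndarray:
    kind = spec["kind"]
    if kind == "loguniform":
        lo, hi = math.log(spec["min"]), math.log(spec["max"])
        return np.exp(rng.uniform(lo, hi, size=n))
    if kind == "beta":
        return rng.beta(spec["a"], spec["b"], size=n)
    if kind == "fixed":
        return np.full(n, float(spec["value"]))
    raise ConfigError(f"unknown maf_spectrum kind {kind!r}")


def generate_cohort(config: CohortConfig) -> tuple[CohortMatrix, TruthRecord]:
    """Generate a synthetic cohort and the truth record describing it.

    Returns
    -------
    (CohortMatrix, TruthRecord)
        The cohort before any QC, and the bookkeeping of planted carriers
        and injected artefacts.  Bit-identical for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub = config.n_cases + config.n_controls

    # --- gene and variant scaffold -----------------------------------
    gene_names = np.array([f"G{i + 1:06d}" for i in range(config.n_genes)])
    per_gene = rng.poisson(config.variants_per_gene, size=config.n_genes)
    n_var = int(per_gene.sum())
    gene_of_variant = np.repeat(np.arange(config.n_genes), per_gene)

    true_f = _draw_freqs(rng, config.maf_spectrum, n_var)
    is_indel = rng.random(n_var) < config.indel_rate
    csq = rng.choice(
        ["missense", "nonsense", "splice_junction", "other"],
        size=n_var,
        p=[0.55, 0.05, 0.05, 0.35],
    )
    # CADD phred loosely tied to consequence severity; purely cosmetic for
    # the null machinery, but exercises the likely-disruptive rule.
    cadd = np.clip(rng.gamma(2.0, 6.0, size=n_var), 0, 60)
    # Population panel frequency correlates with the simulated cohort's
    # true frequency on the log scale.
    with np.errstate(divide="ignore"):
        popmax = np.clip(
            np.exp(np.log(np.maximum(true_f, 1e-300)) + rng.normal(0, 0.7, size=n_var)),
            0,
            1.0,
        )

    variants = make_variant_table(
        chrom=np.full(n_var, "1"),
        pos=np.arange(1, n_var + 1) * 100,
        ref=np.full(n_var, "A"),
        alt=np.where(is_indel, "AT", "C"),
        gene=gene_names[gene_of_variant],
        csq_class=csq,
        cadd=cadd,
        popmax_af=popmax,
        is_indel=is_indel,
    )

    # --- subjects and genotypes --------------------------------------
    subject_ids = np.array(
        [f"CASE{i + 1:06d}" for i in range(config.n_cases)]
        + [f"CTRL{i + 1:06d}" for i in range(config.n_controls)],
        dtype=object,
    )
    is_case = np.zeros(n_sub, dtype=bool)
    is_case[: config.n_cases] = True

    geno = rng.binomial(2, true_f[:, None], size=(n_var, n_sub)).astype(np.int8)

    # --- target set and planted carriers -----------------------------
    target_idx = rng.choice(config.n_genes, size=config.target_set_size, replace=False)
    target_genes = sorted(gene_names[target_idx])
    planted_calls: list[tuple[int, int]] = []
    planted_cases: list[str] = []
    if config.planted_case_hom_excess > 0:
        in_target = np.isin(gene_of_variant, target_idx)
        eligible = np.flatnonzero(
            in_target & (true_f < config.plant_max_freq) & ~is_indel
        )
        # one plant per gene: shuffle, keep first variant of each gene
        rng.shuffle(eligible)
        seen: dict[int, int] = {}
        for v in eligible:
            seen.setdefault(int(gene_of_variant[v]), int(v))
        slots = list(seen.values())
        k = config.planted_case_hom_excess
        if len(slots) < k:
            raise ConfigError(
                f"target set offers only {len(slots)} ultra-rare plant sites "
                f"for {k} requested plants; increase variants_per_gene or "
                "plant_max_freq"
            )
        plant_vars = rng.choice(np.array(slots), size=k, replace=False)
        plant_subs = rng.choice(config.n_cases, size=k, replace=False)
        for v, s in zip(plant_vars, plant_subs):
            geno[v, s] = 2
            planted_calls.append((int(v), int(s)))
            planted_cases.append(str(subject_ids[s]))

    # --- genotype quality --------------------------------------------
    # single uniform draw, inverse-CDF split: a `missing_rate` fraction of
    # calls lands uniformly on [0, low_max], the rest on
    # [low_max+1, high_max]
    g = config.gq_distribution
    rate = config.missing_rate
    u = rng.random((n_var, n_sub), dtype=np.float32)
    low_gq = u < rate
    span_hi = g["high_max"] - g["low_max"]
    gq = (g["low_max"] + 1 + (u - rate) / max(1.0 - rate, 1e-12) * span_hi).astype(
        np.int16
    )
    if low_gq.any():
        gq[low_gq] = (u[low_gq] / max(rate, 1e-12) * (g["low_max"] + 1)).astype(
            np.int16
        )
    np.clip(gq, 0, g["high_max"], out=gq)

    # --- read depths --------------------------------------------------
    # per-subject mean coverage ~ Gamma(dispersion, mean/dispersion),
    # per-call depth Poisson around it: marginally negative-binomial with
    # the configured mean/dispersion, with realistic within-subject
    # coverage correlation
    d = config.depth_distribution
    r = d["dispersion"]
    coverage = rng.gamma(r, d["mean"] / r, size=n_sub)
    depth = rng.poisson(np.broadcast_to(coverage, (n_var, n_sub))).astype(np.int32)

    # reads drawn per genotype class (hom-ref calls carry pure reference
    # support; allelic balance only matters downstream on alt-carrying
    # calls)
    ref_reads = depth.copy()
    het_idx = np.nonzero(geno == 1)
    ref_reads[het_idx] = rng.binomial(depth[het_idx], 0.5)
    hom_idx = np.nonzero(geno == 2)
    d_hom = depth[hom_idx].astype(np.int64)
    # clean hom-alt: rare ref error reads, capped below the 5% boundary
    ref_hom = np.minimum(rng.binomial(d_hom, _HOM_ERR), (d_hom * 0.05).astype(np.int64))

    # --- contamination injection -------------------------------------
    contam_flat = rng.random(d_hom.size) < config.contamination_rate
    planted_set = set(planted_calls)
    if planted_set:  # plants stay clean
        for k in np.flatnonzero(contam_flat):
            if (int(hom_idx[0][k]), int(hom_idx[1][k])) in planted_set:
                contam_flat[k] = False
    n_contam = int(contam_flat.sum())
    if n_contam:
        d_c = np.maximum(d_hom[contam_flat], 1)
        d_hom[contam_flat] = d_c
        frac = rng.uniform(*_CONTAM_FRAC, size=n_contam)
        floor5 = (d_c * 0.05).astype(np.int64)
        ref_hom[contam_flat] = np.clip(
            np.rint(frac * d_c).astype(np.int64), floor5 + 1, d_c
        )
    depth[hom_idx] = d_hom.astype(np.int32)
    ref_reads[hom_idx] = ref_hom.astype(np.int32)

    # planted calls stay clean and confidently called
    for v, s in planted_calls:
        low_gq[v, s] = False
        gq[v, s] = g["high_max"]
        depth[v, s] = max(int(depth[v, s]), 20)
        ref_reads[v, s] = 0

    alt_reads = depth - ref_reads

    matrix = CohortMatrix(
        variants=variants,
        subject_ids=subject_ids,
        is_case=is_case,
        geno=geno,
        gq=gq,
        ref_reads=ref_reads.astype(np.int32),
        alt_reads=alt_reads.astype(np.int32),
    )
    truth = TruthRecord(
        target_genes=list(target_genes),
        true_freqs=true_f,
        planted_case_carriers=planted_cases,
        planted_control_carriers=[],
        planted_calls=planted_calls,
        n_contaminated_calls=n_contam,
        n_low_gq_calls=int(low_gq.sum()),
        n_indels=int(is_indel.sum()),
    )
    return matrix, truth
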