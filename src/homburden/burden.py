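"""Homozygous-carrier burden test, genome-complement control, and power.

The collapsing unit is the subject: a case or control is a *carrier* if it
is homozygous for the alternate allele of at least one qualifying variant
(QC-passing, in the requested rarity category, in a gene of the set).
Carrier counts form a 2×2 table tested with a one-tailed Fisher exact
test, direction fixed as enrichment in cases.  Power for a hypothesized
pair of carrier frequencies is computed by exact binomial enumeration of
the rejection region, or by seeded Monte-Carlo for arbitrary scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CohortMatrix

__all__ = [
    "GeneSet",
    "CarrierCounts",
    "BurdenResult",
    "count_hom_carriers",
    "fisher_one_tailed",
    "burden_test",
    "complement_burden",
    "fisher_power",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (non-empty, duplicates collapse)."""

    name: str
    genes: frozenset

    def __init__(self, name: str, genes):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(genes))
        if not self.genes:
            raise ValueError("gene set must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CarrierCounts:
    """Homozygous-carrier counts per group."""

    case_hom: int
    case_total: int
    control_hom: int
    control_total: int

    def __post_init__(self):
        if not (0 <= self.case_hom <= self.case_total):
            raise ValueError("case_hom must lie in [0, case_total]")
        if not (0 <= self.control_hom <= self.control_total):
            raise ValueError("control_hom must lie in [0, control_total]")

    @property
    def case_pct(self) -> float:
        return 100.0 * self.case_hom / self.case_total if self.case_total else np.nan

    @property
    def control_pct(self) -> float:
        return (
            100.0 * self.control_hom / self.control_total
            if self.control_total
            else np.nan
        )

    @property
    def diff(self) -> float:
        """Case minus control carrier proportion (not percentage)."""
        return self.case_hom / self.case_total - self.control_hom / self.control_total


@dataclass(frozen=True)
class BurdenResult:
    counts: CarrierCounts
    fisher_p: float

    @property
    def case_pct(self) -> float:
        return self.counts.case_pct

    @property
    def control_pct(self) -> float:
        return self.counts.control_pct


def _qualifying_variant_mask(
    classified: pd.DataFrame, category: str, genes=None, exclude=False
) -> np.ndarray:
    col = f"cat_{category.upper()}"
    if col not in classified.columns:
        raise KeyError(f"unknown category {category!r}")
    # copy: to_numpy may alias the DataFrame's backing array
    mask = classified[col].to_numpy(dtype=bool).copy()
    if genes is not None:
        in_set = classified["gene"].isin(genes).to_numpy()
        mask &= ~in_set if exclude else in_set
    return mask


def count_hom_carriers(
    matrix: CohortMatrix,
    classified: pd.DataFrame,
    gene_set: GeneSet,
    category: str,
) -> CarrierCounts:
    """Count subjects homozygous for ≥1 qualifying variant of the set.

    A subject is counted at most once however many qualifying homozygous
    genotypes it carries.  ``classified`` must align row-for-row with
    ``matrix.variants`` (as produced by
    :func:`homburden.classify.classify_variants` on the same matrix).
    """
    if len(classified) != matrix.n_variants:
        raise ValueError("classified table does not align with the matrix")
    if not gene_set.genes & set(matrix.variants["gene"]):
        warnings.warn(
            f"gene set {gene_set.name!r} shares no genes with the matrix",
            stacklevel=2,
        )
    mask = _qualifying_variant_mask(classified, category, gene_set.genes)
    carrier = (matrix.geno[mask] == 2).any(axis=0)
    return CarrierCounts(
        case_hom=int(carrier[matrix.is_case].sum()),
        case_total=matrix.n_cases,
        control_hom=int(carrier[~matrix.is_case].sum()),
        control_total=matrix.n_controls,
    )


def fisher_one_tailed(counts: CarrierCounts) -> float:
    """One-tailed Fisher exact p for carrier enrichment in cases.

    Upper-tail hypergeometric probability of observing at least
    ``case_hom`` carriers among the cases, conditioning on all margins.
    """
    if counts.case_total == 0 or counts.control_total == 0:
        raise ValueError("degenerate margins: empty case or control group")
    table = [
        [counts.case_hom, counts.control_hom],
        [
            counts.case_total - counts.case_hom,
            counts.control_total - counts.control_hom,
        ],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def burden_test(
    matrix: CohortMatrix,
    classified: pd.DataFrame,
    gene_set: GeneSet,
    category: str,
) -> BurdenResult:
    """Carrier counts plus one-tailed Fisher p for a gene set and category."""
    counts = count_hom_carriers(matrix, classified, gene_set, category)
    return BurdenResult(counts=counts, fisher_p=fisher_one_tailed(counts))


def complement_burden(
    matrix: CohortMatrix,
    classified: pd.DataFrame,
    excluded: GeneSet,
    category: str,
) -> BurdenResult:
    """Burden over every gene of the matrix *not* in ``excluded``.

    The control analysis: if the excess of homozygous cases were a
    genome-wide artefact rather than specific to the target set, this
    complement test would show it too.
    """
    if len(classified) != matrix.n_variants:
        raise ValueError("classified table does not align with the matrix")
    mask = _qualifying_variant_mask(classified, category, excluded.genes, exclude=True)
    carrier = (matrix.geno[mask] == 2).any(axis=0)
    counts = CarrierCounts(
        case_hom=int(carrier[matrix.is_case].sum()),
        case_total=matrix.n_cases,
        control_hom=int(carrier[~matrix.is_case].sum()),
        control_total=matrix.n_controls,
    )
    return BurdenResult(counts=counts, fisher_p=fisher_one_tailed(counts))


# ----------------------------------------------------------------------
# Power of the one-tailed Fisher test
# ----------------------------------------------------------------------

def _min_rejecting_case_count(
    b: int, n_case: int, n_control: int, alpha: float
) -> int:
    """Smallest case-carrier count rejecting at level alpha, given b control
    carriers (n_case + 1 if no count rejects).

    Uses the monotonicity of the one-tailed p in the case count at fixed
    margins (binary search).
    """
    lo, hi = 0, n_case
    if (
        fisher_one_tailed(CarrierCounts(n_case, n_case, b, n_control)) >= alpha
    ):
        return n_case + 1
    while lo < hi:
        mid = (lo + hi) // 2
        p = fisher_one_tailed(CarrierCounts(mid, n_case, b, n_control))
        if p < alpha:
            hi = mid
        else:
            lo = mid + 1
    return lo


def fisher_power(
    p_case: float,
    p_control: float,
    n_case: int,
    n_control: int,
    alpha: float = 0.05,
    method: str = "exact",
    n_reps: int = 100_000,
    seed: int | None = None,
) -> float:
    """Power of the one-tailed Fisher test for given carrier frequencies.

    Case and control carrier counts are drawn binomially at the stated
    frequencies; power is the probability that the resulting one-tailed
    Fisher p falls below ``alpha``.

    ``method="exact"`` sums binomial probabilities over the rejection
    region (enumerating the control-carrier support and, per control
    count, the minimal rejecting case count).  ``method="montecarlo"``
    uses seeded replicates and agrees with the exact sum within
    Monte-Carlo error.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    for name, p in (("p_case", p_case), ("p_control", p_control)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        a = rng.binomial(n_case, p_case, size=n_reps)
        b = rng.binomial(n_control, p_control, size=n_reps)
        hits = 0
        cache: dict[int, int] = {}
        for ai, bi in zip(a, b):
            amin = cache.get(bi)
            if amin is None:
                amin = _min_rejecting_case_count(int(bi), n_case, n_control, alpha)
                cache[int(bi)] = amin
            hits += ai >= amin
        return hits / n_reps

    if method != "exact":
        raise ValueError("method must be 'exact' or 'montecarlo'")

    # control-carrier support with non-negligible mass
    b_dist = stats.binom(n_control, p_control)
    if p_control == 0.0:
        b_values = np.array([0])
    else:
        lo = int(b_dist.ppf(1e-12))
        hi = int(b_dist.isf(1e-12))
        b_values = np.arange(lo, hi + 1)
    power = 0.0
    for b in b_values:
        amin = _min_rejecting_case_count(int(b), n_case, n_control, alpha)
        if amin > n_case:
            continue
        power += float(b_dist.pmf(b)) * float(
            stats.binom.sf(amin - 1, n_case, p_case)
        )
    return power
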