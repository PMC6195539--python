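"""Empirical null from random gene sets of matched size.

To ask whether an excess of homozygous cases is specific to a target gene
set rather than a genome-wide property of the cohort, the same statistic
— the case-control difference in the frequency of subjects homozygous
for ≥1 qualifying variant — is recomputed over many random gene sets of
the same size drawn uniformly, without replacement within a replicate and
independently across replicates, from the genes present in the matrix
(including genes contributing no qualifying variant, which can never add
carriers but are legitimate draws).  No matching on gene length or
variant count is applied.  The empirical p is the fraction of replicates
whose difference equals or exceeds the observed one (inclusive ≥); the
add-one corrected value (count+1)/(n+1) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import GeneSet, count_hom_carriers
from .matrix import CohortMatrix

__all__ = ["NullDistribution", "simulate_null", "empirical_p"]


@dataclass
class NullDistribution:
    """Per-replicate carrier-frequency differences plus the observed one."""

    diffs: np.ndarray
    observed_diff: float
    empirical_p: float
    empirical_p_corrected: float
    seed: int
    n_sims: int
    set_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(1, len(self.diffs) + 1), "diff": self.diffs}
        )

    def summary(self) -> dict:
        return {
            "observed_diff": self.observed_diff,
            "empirical_p": self.empirical_p,
            "empirical_p_corrected": self.empirical_p_corrected,
            "seed": self.seed,
            "n_sims": self.n_sims,
            "set_size": self.set_size,
        }


def empirical_p(diffs: np.ndarray, observed_diff: float) -> tuple[float, float]:
    """Fraction of replicate differences ≥ the observed (inclusive).

    Returns ``(raw, corrected)`` where raw has denominator ``n_sims`` and
    corrected is ``(count+1)/(n_sims+1)``, which avoids a literal zero.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("empty replicate vector")
    count = int((diffs >= observed_diff).sum())
    return count / diffs.size, (count + 1) / (diffs.size + 1)


def _carriers_by_gene(
    matrix: CohortMatrix, classified: pd.DataFrame, category: str
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (n_genes, n_subjects) carrier incidence for qualifying variants.

    Row g is True where the subject is hom-alt for ≥1 qualifying variant
    of gene g.  The gene universe is every gene present in the matrix.
    """
    col = f"cat_{category.upper()}"
    qual = classified[col].to_numpy(dtype=bool)
    genes, codes = np.unique(matrix.variants["gene"].to_numpy(), return_inverse=True)

    hom_q = ((matrix.geno == 2) & qual[:, None]).astype(np.uint8)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(len(genes)))
    merged = np.bitwise_or.reduceat(hom_q[order], starts, axis=0)
    return genes, merged.astype(bool)


def simulate_null(
    matrix: CohortMatrix,
    classified: pd.DataFrame,
    category: str,
    target_genes=None,
    set_size: int = 120,
    n_sims: int = 5000,
    seed: int = 0,
) -> NullDistribution:
    """Simulate the random-gene-set null for one rarity category.

    Parameters
    ----------
    matrix, classified
        QC'd cohort and its aligned classification table.
    category
        Rarity category defining qualifying variants ("A" … "D").
    target_genes
        Gene symbols of the observed set.  If given, the observed
        difference and the empirical p are filled in; otherwise they are
        NaN and can be computed later with :func:`empirical_p`.
    set_size, n_sims, seed
        Replicate gene-set size, number of replicates, RNG seed.  A fixed
        seed yields a bit-identical ``diffs`` vector.
    """
    if len(classified) != matrix.n_variants:
        raise ValueError("classified table does not align with the matrix")
    genes, carrier_by_gene = _carriers_by_gene(matrix, classified, category)
    n_genes = len(genes)
    if set_size > n_genes:
        raise ValueError(
            f"set_size {set_size} exceeds the {n_genes}-gene universe"
        )
    is_case = matrix.is_case
    n_case = matrix.n_cases
    n_ctrl = matrix.n_controls
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("carrier frequencies undefined with an empty group")

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_sims, dtype=float)
    for i in range(n_sims):
        idx = rng.choice(n_genes, size=set_size, replace=False)
        carrier = carrier_by_gene[idx].any(axis=0)
        diffs[i] = (
            carrier[is_case].sum() / n_case - carrier[~is_case].sum() / n_ctrl
        )

    observed = float("nan")
    p_raw = p_corr = float("nan")
    if target_genes is not None:
        target = GeneSet("target", target_genes)
        counts = count_hom_carriers(matrix, classified, target, category)
        observed = counts.diff
        p_raw, p_corr = empirical_p(diffs, observed)

    return NullDistribution(
        diffs=diffs,
        observed_diff=observed,
        empirical_p=p_raw,
        empirical_p_corrected=p_corr,
        seed=seed,
        n_sims=n_sims,
        set_size=set_size,
    )
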