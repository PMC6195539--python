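"""Genotype- and variant-level quality filters defining the analyzable set.

Four filters, applied in a fixed order:

1. ``filter_gq`` — calls with genotype quality below 20 become missing.
2. ``filter_hom_contamination`` — homozygous-alt calls whose reference
   reads exceed 5% of the total bases observed at the position are
   invalidated (possible false homozygous calls).
3. ``filter_missingness`` — variants with more than 10% missing filtered
   genotypes in either cases or controls are dropped.
4. ``exclude_indels`` — indels are removed outright (high false-positive
   call rate, ambiguous allele representation).

Missingness is computed on *filtered* genotypes, which is why it follows
the two call-level filters.  The contamination rule is applied per
genotype call, not per variant: dropping the whole site would also
discard valid heterozygotes.  All filters are idempotent and never turn a
missing call back into a called one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, CohortMatrix

__all__ = [
    "QCParams",
    "filter_gq",
    "filter_hom_contamination",
    "filter_missingness",
    "exclude_indels",
    "run_qc",
]


@dataclass
class QCParams:
    """Thresholds of the QC stage (defaults are the screen's standard)."""

    gq_threshold: int = 20
    max_missing_fraction: float = 0.10
    max_ref_fraction: float = 0.05
    drop_indels: bool = True


@dataclass
class QCSummary:
    """Per-filter tallies, serialisable as a TSV."""

    rows: list = field(default_factory=list)

    def add(self, filter_name: str, n_calls_invalidated: int, n_variants_dropped: int):
        self.rows.append(
            {
                "filter": filter_name,
                "n_calls_invalidated": n_calls_invalidated,
                "n_variants_dropped": n_variants_dropped,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["filter", "n_calls_invalidated", "n_variants_dropped"]
        )


def filter_gq(matrix: CohortMatrix, threshold: int = 20) -> CohortMatrix:
    """Mask calls with GQ strictly below ``threshold`` as missing.

    Calls whose GQ is unavailable (−1) are left untouched; the filter is
    strict, so a call at exactly the threshold is retained.  No variant is
    removed at this step.
    """
    if threshold < 0:
        raise ValueError("GQ threshold must be non-negative")
    out = matrix.copy()
    bad = (out.gq >= 0) & (out.gq < threshold) & (out.geno != MISSING)
    out.geno[bad] = MISSING
    return out


def filter_hom_contamination(
    matrix: CohortMatrix, max_ref_fraction: float = 0.05
) -> CohortMatrix:
    """Invalidate homozygous-alt calls with excess reference reads.

    A hom-alt call whose reference reads exceed ``max_ref_fraction`` of
    the total bases observed at the position is a possible false
    homozygous call and is set missing.  The boundary is strict: exactly
    5% does not exceed 5%.  Hom-alt calls with zero total depth are
    unverifiable and likewise invalidated.  Calls without read depths
    (−1) cannot be assessed and are retained.
    """
    if not (0 <= max_ref_fraction < 1):
        raise ValueError("max_ref_fraction must lie in [0, 1)")
    out = matrix.copy()
    hom_idx = np.nonzero(out.geno == 2)
    rr = out.ref_reads[hom_idx].astype(np.int64)
    ar = out.alt_reads[hom_idx].astype(np.int64)
    has_depth = (rr >= 0) & (ar >= 0)
    total = rr + ar
    # strict >: ref reads must exceed the fraction; zero-depth homs are
    # unverifiable and dropped too
    bad = has_depth & (rr > max_ref_fraction * total)
    bad |= has_depth & (total == 0)
    out.geno[hom_idx[0][bad], hom_idx[1][bad]] = MISSING
    return out


def filter_missingness(
    matrix: CohortMatrix, max_fraction: float = 0.10
) -> CohortMatrix:
    """Drop variants missing in more than ``max_fraction`` of either group.

    The fraction is evaluated separately in cases and in controls and the
    variant is dropped if it exceeds the bound in *either* group (strict
    >, so exactly 10% missing is retained).
    """
    if not (0 <= max_fraction <= 1):
        raise ValueError("max_fraction must lie in [0, 1]")
    if matrix.n_cases == 0 or matrix.n_controls == 0:
        raise ValueError(
            "missingness fractions are undefined with an empty case or control group"
        )
    miss = matrix.is_missing()
    frac_case = miss[:, matrix.is_case].mean(axis=1)
    frac_ctrl = miss[:, ~matrix.is_case].mean(axis=1)
    keep = ~((frac_case > max_fraction) | (frac_ctrl > max_fraction))
    return matrix.take_variants(np.flatnonzero(keep))


def exclude_indels(matrix: CohortMatrix) -> CohortMatrix:
    """Remove all variants flagged as indels."""
    keep = ~matrix.variants["is_indel"].to_numpy(dtype=bool)
    return matrix.take_variants(np.flatnonzero(keep))


def run_qc(
    matrix: CohortMatrix,
    params: QCParams | None = None,
    summary: QCSummary | None = None,
) -> CohortMatrix:
    """Apply the full QC stack: GQ → contamination → missingness → indels.

    Call-level masking precedes the missingness filter because missingness
    is assessed on filtered genotypes.  The composition is idempotent.
    An optional :class:`QCSummary` collects per-filter tallies.
    """
    params = params or QCParams()

    step = filter_gq(matrix, params.gq_threshold)
    if summary is not None:
        n = int((step.geno == MISSING).sum() - (matrix.geno == MISSING).sum())
        summary.add("gq", n, 0)
    prev = step

    step = filter_hom_contamination(prev, params.max_ref_fraction)
    if summary is not None:
        n = int((step.geno == MISSING).sum() - (prev.geno == MISSING).sum())
        summary.add("hom_contamination", n, 0)
    prev = step

    step = filter_missingness(prev, params.max_missing_fraction)
    if summary is not None:
        summary.add("missingness", 0, prev.n_variants - step.n_variants)
    prev = step

    if params.drop_indels:
        step = exclude_indels(prev)
        if summary is not None:
            summary.add("indels", 0, prev.n_variants - step.n_variants)
    return step
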