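"""One-way ANOVA with Fisher LSD post hoc, from raw values or summaries.

Functional-assay read-outs (e.g. enzymatic product per sample, proximity
ligation spot counts per cell) are compared across conditions with a
one-way ANOVA followed by Fisher's Least Significant Difference tests —
unadjusted pairwise t-tests that pool the within-group mean square of the
omnibus ANOVA.

Published tables often print only the group summaries (n, mean, SD).
One-way ANOVA is a pure function of those summaries, so
:func:`anova_from_summary` reproduces the raw-data decomposition exactly:
the between-group sum of squares comes from group means and sizes, the
within-group sum of squares from the group variances.  SDs are read as
sample standard deviations (n−1 denominator, the convention for "(SD)" in
biology tables; switchable via ``ddof``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "anova_from_summary",
    "anova_raw",
    "lsd_pairwise",
    "normalize_per_sample",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one assay condition."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(
                f"group {self.label!r}: n must be ≥ 2 (within-group variance "
                "is undefined otherwise)"
            )
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be non-negative")


@dataclass
class AnovaResult:
    """One-way ANOVA decomposition plus the LSD pairwise p-value matrix."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    labels: list
    ns: np.ndarray
    means: np.ndarray
    lsd_pairs: pd.DataFrame
    degenerate: bool = False  # zero within-group variance

    def lsd_p(self, label_i: str, label_j: str) -> float:
        return float(self.lsd_pairs.loc[label_i, label_j])


def _lsd_matrix(
    labels, ns, means, ms_within: float, df_within: int
) -> pd.DataFrame:
    k = len(labels)
    mat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        mat[i, j] = mat[j, i] = lsd_pairwise(
            means[i], means[j], ns[i], ns[j], ms_within, df_within
        )
    return pd.DataFrame(mat, index=list(labels), columns=list(labels))


def lsd_pairwise(
    mean_i: float,
    mean_j: float,
    n_i: int,
    n_j: int,
    ms_within: float,
    df_within: int,
) -> float:
    """Fisher LSD p for one pair: two-sided t with the pooled MS_within.

    ``t = |m_i − m_j| / sqrt(MS_within · (1/n_i + 1/n_j))`` on
    ``df_within`` degrees of freedom.  Equal means give p = 1; zero
    pooled variance with unequal means gives p = 0 (degenerate).
    """
    delta = abs(mean_i - mean_j)
    if delta == 0.0:
        return 1.0
    if ms_within == 0.0:
        return 0.0
    t = delta / math.sqrt(ms_within * (1.0 / n_i + 1.0 / n_j))
    return float(2.0 * stats.t.sf(t, df_within))


def _assemble(labels, ns, means, ss_within) -> AnovaResult:
    ns = np.asarray(ns, dtype=int)
    means = np.asarray(means, dtype=float)
    k = len(ns)
    if k < 2:
        raise ValueError("need at least two groups")
    n_total = int(ns.sum())
    df_between = k - 1
    df_within = n_total - k
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    degenerate = ms_within == 0.0
    if degenerate:
        f = math.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    lsd = _lsd_matrix(labels, ns, means, ms_within, df_within)
    return AnovaResult(
        f_stat=f,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ms_within=ms_within,
        labels=list(labels),
        ns=ns,
        means=means,
        lsd_pairs=lsd,
        degenerate=degenerate,
    )


def anova_from_summary(groups: list[GroupSummary], ddof: int = 1) -> AnovaResult:
    """One-way ANOVA from (n, mean, SD) summaries.

    Algebraically identical to :func:`anova_raw` on any raw data matching
    the summaries.  ``ddof=1`` reads SDs as sample standard deviations;
    pass ``ddof=0`` for population SDs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups])
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    if ddof == 1:
        ss_within = float(((ns - 1) * sds**2).sum())
    elif ddof == 0:
        ss_within = float((ns * sds**2).sum())
    else:
        raise ValueError("ddof must be 0 or 1")
    return _assemble([g.label for g in groups], ns, means, ss_within)


def anova_raw(groups: dict[str, np.ndarray] | list[np.ndarray]) -> AnovaResult:
    """One-way ANOVA from raw measurement vectors.

    ``groups`` is a mapping label → values or a plain list of vectors
    (labelled ``group1`` …).  Each group needs at least two values.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i + 1}": g for i, g in enumerate(groups)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    values = [np.asarray(groups[l], dtype=float) for l in labels]
    for l, v in zip(labels, values):
        if v.size < 2:
            raise ValueError(f"group {l!r} needs at least two values")
        if not np.isfinite(v).all():
            raise ValueError(f"group {l!r} contains non-finite values")
    ns = np.array([v.size for v in values])
    means = np.array([v.mean() for v in values])
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    return _assemble(labels, ns, means, ss_within)


def normalize_per_sample(values, denominators) -> np.ndarray:
    """Generic per-sample normalization (e.g. analyte mass over total protein).

    Elementwise ratio with validation; precedes :func:`anova_raw` when the
    assay read-out needs scaling by a per-sample loading quantity.
    """
    values = np.asarray(values, dtype=float)
    denominators = np.asarray(denominators, dtype=float)
    if values.shape != denominators.shape:
        raise ValueError("values and denominators must align")
    if (denominators <= 0).any():
        raise ValueError("denominators must be positive")
    return values / denominators
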