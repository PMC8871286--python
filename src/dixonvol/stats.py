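"""Cohort-level statistics for the paired two-arm liver-fat analysis.

Covers the method-agreement layer (Spearman correlation, Bland–Altman
limits of agreement), threshold derivation (ROC against MRS-derived
steatosis labels with Youden-index-optimal cutoffs), and the dietary
comparison layer (paired Wilcoxon signed-rank within arm, Wilcoxon rank-sum
between arms, two-way repeated-measures ANOVA with diet as the
between-subject and time as the within-subject factor). Significance is
reported at alpha = 0.05 with no multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BlandAltmanResult",
    "ROCResult",
    "spearman_rho",
    "bland_altman",
    "roc_youden",
    "steatosis_label",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "rm_anova_two_way",
]

STEATOSIS_CUTOFF = 5.56  # % PDFF separating normal liver from fatty liver


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement MD ± 1.96 SD."""

    mean_difference: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int

    @classmethod
    def from_md_and_lower(cls, md: float, loa_lower: float, n: int = 0) -> "BlandAltmanResult":
        """Reconstruct the upper limit from MD and the lower limit using the
        symmetry of the limits about MD (upper = 2*MD - lower)."""
        sd = (md - loa_lower) / 1.96
        return cls(md, sd, loa_lower, 2.0 * md - loa_lower, n)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    #: (threshold, sensitivity, specificity) at every candidate threshold
    operating_points: tuple[tuple[float, float, float], ...]
    youden_threshold: float
    youden_j: float


def spearman_rho(x, y, name: str = "spearman") -> TestResult:
    """Spearman rank correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return TestResult(name=name, statistic=float(rho), p_value=float(p), n=x.size)


def bland_altman(a, b, name: str = "bland_altman") -> BlandAltmanResult:
    """Bland–Altman agreement of paired methods: d = a - b, MD ± 1.96 SD(d)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1D and equal length")
    if a.size < 2:
        raise ValueError(f"need at least 2 pairs, got {a.size}")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(md, sd, md - 1.96 * sd, md + 1.96 * sd, a.size)


def steatosis_label(pdff_percent: float, cutoff: float = STEATOSIS_CUTOFF) -> bool:
    """Steatotic iff PDFF is strictly above the cutoff (default 5.56%)."""
    if not 0.0 <= pdff_percent <= 100.0:
        raise ValueError(f"PDFF must lie in [0, 100], got {pdff_percent}")
    return bool(pdff_percent > cutoff)


def roc_youden(scores, labels) -> ROCResult:
    """Empirical ROC of scores against binary labels, with the Youden cutoff.

    Candidate thresholds are the midpoints between adjacent distinct sorted
    scores plus ±inf sentinels; a case is called positive when its score is
    strictly above the threshold. AUC is the trapezoidal area under the
    empirical curve (equal to the normalized Mann–Whitney U statistic). The
    Youden threshold maximizes J = sensitivity + specificity - 1, ties
    broken toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cands = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = scores[labels]
    neg = scores[~labels]
    sens = np.array([(pos > t).sum() / n_pos for t in cands])
    spec = np.array([(neg <= t).sum() / n_neg for t in cands])
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # monotone curve: vertical runs contribute no area
    auc = float(np.trapezoid(sens[order], fpr[order]))
    j = sens + spec - 1.0
    finite = np.isfinite(cands)
    jf, cf = j[finite], cands[finite]
    best = int(np.lexsort((cf, -jf))[0])  # max J, then lowest threshold
    return ROCResult(
        auc=auc,
        operating_points=tuple(zip(cands.tolist(), sens.tolist(), spec.tolist())),
        youden_threshold=float(cf[best]),
        youden_j=float(jf[best]),
    )


def wilcoxon_signed_rank(differences, name: str = "wilcoxon_signed_rank") -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped; ties get mid-ranks. The exact null
    distribution is used for n <= 25 when the absolute differences are
    untied, otherwise the normal approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        warnings.warn(f"only {n} nonzero differences; p-value is coarse", stacklevel=2)
    untied = np.unique(np.abs(d)).size == n
    method = "exact" if (n <= 25 and untied) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        extra={"method": method},
    )


def wilcoxon_rank_sum(group_a, group_b, name: str = "wilcoxon_rank_sum") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test between two groups.

    Exact enumeration when n_a + n_b <= 20 and the pooled values are untied,
    otherwise the normal approximation with continuity and tie correction.
    The statistic is the Mann–Whitney U of group A.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 values, got {a.size} and {b.size}")
    pooled = np.concatenate([a, b])
    untied = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 20 and untied) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=a.size + b.size,
        extra={"n_a": a.size, "n_b": b.size, "method": method},
    )


def rm_anova_two_way(table: pd.DataFrame, value: str = "value") -> dict[str, TestResult]:
    """Two-way repeated-measures (mixed) ANOVA: diet between, time within.

    ``table`` needs columns ``subject_id``, ``arm``, ``timepoint`` and the
    value column, with both timepoints present for every subject. Returns
    F/p for the diet main effect (between-subject error term), the time main
    effect and the diet × time interaction (subject-by-time residual).
    """
    import pingouin as pg

    required = {"subject_id", "arm", "timepoint", value}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby("subject_id")["timepoint"].nunique()
    bad = counts.index[counts != 2].tolist()
    if bad:
        raise ValueError(f"subjects without both timepoints: {bad}")
    if np.ptp(table[value].to_numpy()) == 0:
        raise ValueError("value is constant across all cells; ANOVA undefined")
    aov = pg.mixed_anova(
        data=table, dv=value, within="timepoint", subject="subject_id", between="arm"
    )
    aov = aov.set_index("Source")
    n = table["subject_id"].nunique()
    key_map = {"diet": "arm", "time": "timepoint", "interaction": "Interaction"}
    out = {}
    for key, src in key_map.items():
        row = aov.loc[src]
        out[key] = TestResult(
            name=f"rm_anova_{key}",
            statistic=float(row["F"]),
            p_value=float(row["p_unc"]),
            n=n,
            extra={"df1": float(row["DF1"]), "df2": float(row["DF2"])},
        )
    return out
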