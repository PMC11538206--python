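"""Agreement statistics between predicted and reference burden measurements.

Covers Bland-Altman mean difference with 1.96*SD limits of agreement,
the median relative mean difference (RMD = (pred - ref)/ref, which floors
at -1 when the prediction finds nothing), the intraclass correlation
coefficient with its interpretation bands, and a cluster-adjusted Wilcoxon
rank-sum test for comparing lesion populations (TP vs FN vs FP) when
lesions from one scan or patient are correlated.

Cluster-adjusted rank-sum test
------------------------------
The classical large-sample Wilcoxon z-statistic assumes every observation
carries its group label independently. With clustered data both the values
and the labels are correlated within a cluster, inflating the variance of
the rank sum. Writing s_i for the centered midranks, the permutation
variance of the group-1 rank sum W is

    Var(W) = n1*n2 / (N*(N-1)) * [ sum_i s_i^2
             + rho_g * sum_clusters sum_{i != j in c} s_i s_j ]

where rho_g is the within-cluster intraclass correlation of the 0/1 group
labels (one-way ANOVA estimator, clamped to [0, 1]). With singleton
clusters the cross-term vanishes and the statistic is exactly the ordinary
large-sample Wilcoxon rank-sum test; with label-correlated clusters the
within-cluster rank cross-products widen the null variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import InsufficientDataError, ParameterError

ICC_BANDS = (
    (0.8, "superior"),
    (0.61, "great"),
    (0.41, "moderate"),
    (0.21, "low"),
)


def icc_category(value: float) -> str:
    """Interpretation band: superior >= 0.8, great >= 0.61, moderate >= 0.41,
    low >= 0.21, else poor."""
    if np.isnan(value):
        return "undefined"
    for lo, name in ICC_BANDS:
        if value >= lo:
            return name
    return "poor"


def _paired(ai, gt) -> tuple[np.ndarray, np.ndarray]:
    ai = np.asarray(ai, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if ai.shape != gt.shape or ai.ndim != 1:
        raise ParameterError("ai and gt must be equal-length 1D series")
    keep = ~(np.isnan(ai) | np.isnan(gt))
    return ai[keep], gt[keep]


@dataclass
class BlandAltman:
    md: float             # mean difference (ai - gt)
    sd: float
    loa_low: float        # md - 1.96 sd
    loa_high: float       # md + 1.96 sd
    n: int
    outliers: np.ndarray  # indices (into the valid pairs) outside the limits


def bland_altman(ai, gt) -> BlandAltman:
    """Mean difference and 95% limits of agreement of paired series.

    Pairs with an undefined entry are dropped; fewer than 3 valid pairs is
    an error. Outliers are the pairs falling strictly outside the limits.
    """
    a, g = _paired(ai, gt)
    if len(a) < 3:
        raise InsufficientDataError(f"need >= 3 valid pairs, got {len(a)}")
    d = a - g
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = md - 1.96 * sd, md + 1.96 * sd
    out = np.flatnonzero((d < lo) | (d > hi))
    return BlandAltman(md=md, sd=sd, loa_low=lo, loa_high=hi, n=len(d), outliers=out)


def median_rmd(ai, gt) -> tuple[float, float, float, int]:
    """Median (and range) of the relative mean difference (ai - gt)/gt.

    Pairs with gt == 0 are excluded and counted; returns
    (median, min, max, n_excluded). A prediction that finds nothing gives
    RMD = -1, the floor of the statistic.
    """
    a, g = _paired(ai, gt)
    nonzero = g != 0
    n_excl = int((~nonzero).sum())
    a, g = a[nonzero], g[nonzero]
    if len(a) == 0:
        raise InsufficientDataError("all pairs excluded (gt == 0 or undefined)")
    rmd = (a - g) / g
    return float(np.median(rmd)), float(rmd.min()), float(rmd.max()), n_excl


@dataclass
class ICCResult:
    value: float          # primary form (absolute agreement by default)
    category: str
    form: str             # "ICC2" (absolute agreement) or "ICC3" (consistency)
    value_consistency: float  # ICC3 companion value
    n: int


def icc(ai, gt, form: str = "ICC2") -> ICCResult:
    """Intraclass correlation between paired series.

    Primary form ICC2: two-way random effects, absolute agreement, single
    rater - the natural model when a prediction should reproduce the
    reference value itself, not just its ordering. The consistency form
    (ICC3) is reported alongside.
    """
    if form not in ("ICC2", "ICC3"):
        raise ParameterError("form must be 'ICC2' or 'ICC3'")
    a, g = _paired(ai, gt)
    if len(a) < 5:
        raise InsufficientDataError(f"need >= 5 valid pairs, got {len(a)}")
    if np.allclose(a, a[0]) and np.allclose(g, g[0]):
        return ICCResult(float("nan"), "undefined", form, float("nan"), len(a))
    df = pd.DataFrame({
        "target": np.tile(np.arange(len(a)), 2),
        "rater": np.repeat(["ai", "gt"], len(a)),
        "score": np.concatenate([a, g]),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(df, targets="target", raters="rater", ratings="score")
    res = res.set_index("Type")
    v2 = float(res.loc["ICC(A,1)", "ICC"])  # two-way random, absolute agreement
    v3 = float(res.loc["ICC(C,1)", "ICC"])  # consistency
    primary = v2 if form == "ICC2" else v3
    return ICCResult(primary, icc_category(primary), form, v3, len(a))


# ---------------------------------------------------------------------------
# cluster-adjusted Wilcoxon rank-sum
# ---------------------------------------------------------------------------


@dataclass
class ClusteredTestResult:
    group_a: str
    group_b: str
    statistic: float      # z statistic
    p_value: float
    n_a: int
    n_b: int
    n_clusters: int
    rho_labels: float     # estimated within-cluster label correlation


def _label_icc(g: np.ndarray, clusters: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation of 0/1 labels, clamped to [0, 1]."""
    ids, inv = np.unique(clusters, return_inverse=True)
    M = len(ids)
    N = len(g)
    if M >= N:  # all singletons
        return 0.0
    n_c = np.bincount(inv).astype(float)
    mean_c = np.bincount(inv, weights=g) / n_c
    gbar = g.mean()
    ssb = float(np.sum(n_c * (mean_c - gbar) ** 2))
    ssw = float(np.sum((g - mean_c[inv]) ** 2))
    if M < 2:
        return 1.0  # a single multi-member cluster: fully correlated design
    msb = ssb / (M - 1)
    msw = ssw / (N - M)
    n0 = (N - np.sum(n_c**2) / N) / (M - 1)
    denom = msb + (n0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float(np.clip((msb - msw) / denom, 0.0, 1.0))


def cluster_ranksum(x, y, clusters_x, clusters_y) -> ClusteredTestResult:
    """Two-sided cluster-adjusted Wilcoxon rank-sum test.

    ``x``/``y`` are the two samples; ``clusters_*`` give each observation's
    cluster id (ids may be shared across the two groups - e.g. TP and FN
    lesions from the same scan). Reduces exactly to the ordinary
    large-sample rank-sum test when every cluster has one member.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx = np.asarray(clusters_x)
    cy = np.asarray(clusters_y)
    if len(x) != len(cx) or len(y) != len(cy):
        raise ParameterError("values and cluster ids must have equal length")
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = np.concatenate([x, y])
    clusters = np.concatenate([cx, cy])
    glab = np.concatenate([np.ones(n1), np.zeros(n2)])

    r = stats.rankdata(pooled)  # midranks
    s = r - (N + 1) / 2.0
    W = float(r[:n1].sum())
    EW = n1 * (N + 1) / 2.0

    base = float(np.sum(s**2))
    ids, inv = np.unique(clusters, return_inverse=True)
    sum_c = np.bincount(inv, weights=s)
    sumsq_c = np.bincount(inv, weights=s**2)
    cross = float(np.sum(sum_c**2 - sumsq_c))  # sum over i != j within clusters

    rho = _label_icc(glab, clusters)
    var = n1 * n2 / (N * (N - 1.0)) * (base + rho * cross)
    if var <= 0:
        var = n1 * n2 / (N * (N - 1.0)) * base
    z = (W - EW) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ClusteredTestResult(
        group_a="x", group_b="y", statistic=float(z), p_value=float(p),
        n_a=n1, n_b=n2, n_clusters=len(ids), rho_labels=rho,
    )


def clustered_wilcoxon(
    values, groups, clusters, alpha: float = 0.05
) -> list[ClusteredTestResult]:
    """Pairwise cluster-adjusted rank-sum tests across lesion status groups.

    Parameters
    ----------
    values
        Per-lesion measurements (e.g. SUVmax or TTV).
    groups
        Status label per lesion (e.g. "TP"/"FN"/"FP").
    clusters
        Patient or scan id per lesion.

    Groups with fewer than 2 lesions are skipped. Returns one result per
    tested pair (no multiplicity correction, matching raw p < alpha usage).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    clusters = np.asarray(clusters)
    if not (len(values) == len(groups) == len(clusters)):
        raise ParameterError("values, groups, clusters must have equal length")
    names = [g for g in pd.unique(groups)]
    if len(names) < 2:
        raise InsufficientDataError("need at least 2 groups")
    out: list[ClusteredTestResult] = []
    for a, b in combinations(names, 2):
        ia, ib = groups == a, groups == b
        if ia.sum() < 2 or ib.sum() < 2:
            continue
        res = cluster_ranksum(values[ia], values[ib], clusters[ia], clusters[ib])
        res.group_a, res.group_b = str(a), str(b)
        out.append(res)
    return out
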