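"""Bland-Altman, relative mean difference, ICC, and clustered rank tests."""

import numpy as np
import pytest
from scipy import stats

from petleskit import bland_altman, cluster_ranksum, clustered_wilcoxon, icc, icc_category, median_rmd
from petleskit.errors import InsufficientDataError


def test_bland_altman_identity(rng):
    x = rng.random(10)
    ba = bland_altman(x, x)
    assert ba.md == 0.0
    assert ba.loa_low == ba.loa_high == 0.0
    assert len(ba.outliers) == 0


def test_bland_altman_unit_sd():
    gt = np.zeros(3)
    ai = np.array([-1.0, 0.0, 1.0])
    ba = bland_altman(ai, gt)
    assert ba.md == pytest.approx(0.0)
    assert ba.loa_high == pytest.approx(1.96)
    assert ba.loa_low == pytest.approx(-1.96)


def test_bland_altman_detects_systematic_shrinkage(rng):
    gt = rng.uniform(10, 100, 30)
    ai = 0.9 * gt + rng.normal(0, 0.5, 30)
    assert bland_altman(ai, gt).md < 0


def test_bland_altman_needs_three_pairs():
    with pytest.raises(InsufficientDataError):
        bland_altman([1.0, 2.0], [1.0, 2.0])


def test_bland_altman_limits_cover_95pct_gaussian(rng):
    """~95% of Gaussian differences fall inside the limits of agreement."""
    cover = []
    for _ in range(200):
        gt = rng.normal(50, 5, 100)
        ai = gt + rng.normal(0, 2, 100)
        ba = bland_altman(ai, gt)
        cover.append(1 - len(ba.outliers) / ba.n)
    assert abs(np.mean(cover) - 0.95) < 0.01


def test_median_rmd_zero_for_identity(rng):
    x = rng.uniform(1, 10, 8)
    med, lo, hi, n_excl = median_rmd(x, x)
    assert med == 0.0 and lo == 0.0 and hi == 0.0 and n_excl == 0


def test_median_rmd_constant_ratio(rng):
    gt = rng.uniform(1, 10, 8)
    med, lo, hi, _ = median_rmd(0.9 * gt, gt)
    assert med == pytest.approx(-0.10)
    assert lo == pytest.approx(-0.10) and hi == pytest.approx(-0.10)


def test_median_rmd_total_miss_floors_at_minus_one(rng):
    gt = rng.uniform(1, 10, 6)
    ai = gt.copy()
    ai[2] = 0.0  # the prediction found nothing on one scan
    _, lo, _, _ = median_rmd(ai, gt)
    assert lo == pytest.approx(-1.0)


def test_median_rmd_excludes_zero_gt(rng):
    gt = np.array([0.0, 2.0, 4.0])
    ai = np.array([1.0, 2.0, 4.0])
    med, _, _, n_excl = median_rmd(ai, gt)
    assert n_excl == 1 and med == 0.0


def test_icc_perfect_agreement(rng):
    x = rng.uniform(1, 50, 12)
    res = icc(x, x)
    assert res.value == pytest.approx(1.0, abs=1e-9)
    assert res.category == "superior"


def test_icc_null_near_zero(rng):
    x = rng.normal(0, 1, 200)
    y = rng.normal(0, 1, 200)
    res = icc(x, y)
    assert abs(res.value) < 2.5 / np.sqrt(200)


def test_icc_absolute_agreement_penalizes_offset(rng):
    """A constant offset hurts absolute agreement (ICC2) but not consistency."""
    gt = rng.uniform(0, 2, 40)
    ai = gt + 5.0
    res = icc(ai, gt)
    assert res.value < 0.5
    assert res.value_consistency > 0.99


@pytest.mark.parametrize(
    "value,expected",
    [(0.85, "superior"), (0.80, "superior"), (0.79, "great"), (0.61, "great"),
     (0.5, "moderate"), (0.3, "low"), (0.2, "poor"), (-0.1, "poor")],
)
def test_icc_interpretation_bands(value, expected):
    assert icc_category(value) == expected


def test_singleton_clusters_reduce_to_plain_ranksum(rng):
    x = rng.normal(0, 1, 18)
    y = rng.normal(0.4, 1, 25)
    res = cluster_ranksum(x, y, np.arange(18), 100 + np.arange(25))
    ref = stats.ranksums(x, y)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)


def test_clustered_shift_detected(rng):
    """A 50% downward shift is detected at n >= 50 per group."""
    n_cl = 25
    tp, fn, cl_tp, cl_fn = [], [], [], []
    for c in range(n_cl):
        eff = rng.normal(0, 0.1)
        tp.extend(np.exp(eff) * rng.uniform(8, 30, 4))
        fn.extend(np.exp(eff) * rng.uniform(4, 15, 2))
        cl_tp.extend([c] * 4)
        cl_fn.extend([c] * 2)
    res = cluster_ranksum(fn, tp, cl_fn, cl_tp)
    assert res.p_value < 0.05
    assert res.statistic < 0


def test_clustered_wilcoxon_pairs_and_skips(rng):
    values = np.concatenate([rng.normal(10, 1, 30), rng.normal(5, 1, 30), [1.0]])
    groups = np.array(["TP"] * 30 + ["FN"] * 30 + ["FP"])
    clusters = np.concatenate([rng.integers(0, 6, 60), [0]])
    results = clustered_wilcoxon(values, groups, clusters)
    tested = {(r.group_a, r.group_b) for r in results}
    assert ("TP", "FN") in tested
    # FP group has one lesion only: skipped
    assert not any("FP" in pair for pair in tested)


def test_clustered_type_i_error_calibrated(rng):
    """Null rejection rate stays near alpha with correlated clusters."""
    rej, used = 0, 0
    for _ in range(400):
        sizes = rng.integers(1, 11, size=20)
        vals, cl, lab = [], [], []
        for c, n in enumerate(sizes):
            eff = rng.normal(0, 1)
            vals.append(eff + rng.normal(0, 1, n))
            pi = rng.beta(2, 2)
            lab.append(rng.random(n) < pi)
            cl.append(np.full(n, c))
        vals, cl, lab = map(np.concatenate, (vals, cl, lab))
        if lab.sum() < 2 or (~lab).sum() < 2:
            continue
        used += 1
        if cluster_ranksum(vals[lab], vals[~lab], cl[lab], cl[~lab]).p_value < 0.05:
            rej += 1
    assert 0.02 <= rej / used <= 0.08
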