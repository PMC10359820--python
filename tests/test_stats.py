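"""Diagnostic statistics against hand-computed values and independent oracles
(brute force, bootstrap, permutation, scikit-learn, statsmodels, scipy)."""

import numpy as np
import pytest
from scipy import stats as sps

from ksvasc.stats import (
    ConfusionTable,
    auc_mann_whitney,
    auc_with_ci,
    build_confusion,
    chi2_2x2,
    cohen_kappa,
    confusion_metrics,
    delong_components,
    delong_paired_test,
    roc_points,
    round_percent,
    trapezoid_auc,
)


# ---------------------------------------------------------------------- 2x2

@pytest.mark.parametrize(
    "num,den,expected",
    [(72, 104, 69.2), (91, 119, 76.5), (1, 3, 33.3), (1, 16, 6.3), (1, 8, 12.5), (5, 1000, 0.5)],
)
def test_round_percent_half_up(num, den, expected):
    assert round_percent(num, den) == expected


def test_round_percent_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        round_percent(1, 0)


def test_build_confusion_basics():
    t = build_confusion([True, False, True], [True, False, True])
    assert (t.tp, t.fp, t.fn, t.tn) == (2, 0, 0, 1)
    t = build_confusion([False, False], [True, False])
    assert (t.tp, t.fp) == (0, 0)
    with pytest.raises(ValueError):
        build_confusion([True], [True, False])


def test_vascularity_table_reproduces_printed_metrics():
    """All-lesions vascularity 2x2: sens 69.2%, spec 76.5%, acc 73.1%."""
    m = confusion_metrics(ConfusionTable(tp=72, fp=28, fn=32, tn=91))
    assert m.sensitivity.display == 69.2
    assert m.specificity.display == 76.5
    assert m.accuracy.display == 73.1
    assert m.ppv.display == 72.0
    assert m.npv.display == 74.0


def test_avs_table_reproduces_printed_metrics():
    m = confusion_metrics(ConfusionTable(tp=86, fp=28, fn=18, tn=91))
    assert (m.sensitivity.display, m.specificity.display, m.accuracy.display) == (
        82.7, 76.5, 79.4,
    )


def test_undefined_metrics_flagged_not_zero():
    m = confusion_metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=10))
    assert m.specificity.display == 100.0
    assert not m.sensitivity.defined and m.sensitivity.display is None
    assert not m.ppv.defined


def test_metrics_conserve_n_and_range():
    rng = np.random.default_rng(5)
    for _ in range(50):
        cells = rng.integers(1, 40, size=4)
        t = ConfusionTable(*map(int, cells))
        assert t.n == cells.sum()
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            v = getattr(confusion_metrics(t), name).value
            assert 0 <= v <= 1


# ---------------------------------------------------------------------- ROC / AUC

def test_roc_perfect_separation_passes_upper_left():
    pts = roc_points([1, 1, 5, 5], [False, False, True, True])
    assert [0.0, 1.0] in pts.tolist()
    assert auc_mann_whitney([1, 1, 5, 5], [False, False, True, True]) == 1.0


def test_roc_all_ties_is_diagonal():
    pts = roc_points([3, 3, 3, 3], [False, True, False, True])
    assert pts.tolist() == [[0.0, 0.0], [1.0, 1.0]]
    assert auc_mann_whitney([3, 3, 3, 3], [False, True, False, True]) == 0.5


def test_roc_hand_enumerated_operating_point():
    scores = [1, 2, 2, 3]
    truth = [False, False, True, True]
    pts = roc_points(scores, truth)
    assert [0.0, 0.5] in pts.tolist()  # threshold "score > 2"
    assert auc_mann_whitney(scores, truth) == pytest.approx(3.5 / 4, abs=1e-15)


def test_roc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_points([1, 2], [True, True])
    with pytest.raises(ValueError):
        auc_mann_whitney([1, 2], [False, False])


def _brute_force_auc(scores, truth):
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    x, y = scores[truth], scores[~truth]
    total = 0.0
    for xi in x:
        for yj in y:
            total += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return total / (len(x) * len(y))


def test_auc_equals_brute_force_on_random_instances():
    """Rank-based AUC == pairwise psi-summation on 100 random ordinal
    instances, to 1e-12."""
    rng = np.random.default_rng(2718)
    for _ in range(100):
        n = int(rng.integers(6, 40))
        scores = rng.integers(1, 12, size=n)
        truth = rng.random(n) < 0.5
        if truth.all() or (~truth).all():
            continue
        assert auc_mann_whitney(scores, truth) == pytest.approx(
            _brute_force_auc(scores, truth), abs=1e-12
        )


def test_auc_equals_trapezoid_and_negation_identity():
    rng = np.random.default_rng(99)
    for _ in range(50):
        n = int(rng.integers(8, 60))
        scores = rng.integers(1, 12, size=n).astype(float)
        truth = rng.random(n) < 0.4
        if truth.all() or (~truth).all():
            continue
        a = auc_mann_whitney(scores, truth)
        assert a == pytest.approx(trapezoid_auc(roc_points(scores, truth)), abs=1e-12)
        assert a + auc_mann_whitney(-scores, truth) == pytest.approx(1.0, abs=1e-12)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(10)
    for _ in range(20):
        n = 80
        truth = rng.random(n) < 0.5
        if truth.all() or (~truth).all():
            continue
        scores = rng.integers(1, 12, size=n) + truth * rng.integers(0, 4, size=n)
        assert auc_mann_whitney(scores, truth) == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-12
        )


# ---------------------------------------------------------------------- DeLong

def test_delong_perfect_separation_has_zero_variance():
    auc, var = delong_components([1, 1, 9, 9], [False, False, True, True])
    assert auc == 1.0 and var == 0.0


def test_delong_hand_computed_components():
    """benign {1,2}, malignant {2,3}: V10=(0.75,1.0), V01=(1.0,0.75),
    variance = 0.03125/2 + 0.03125/2."""
    auc, var = delong_components([1, 2, 2, 3], [False, False, True, True])
    assert auc == pytest.approx(0.875, abs=1e-15)
    assert var == pytest.approx(0.03125, abs=1e-15)


def test_delong_requires_two_per_class():
    with pytest.raises(ValueError):
        delong_components([1, 2, 3], [False, False, True])


def test_delong_variance_agrees_with_bootstrap():
    """DeLong variance within 20% relative error of a 2000-resample
    bootstrap on a seeded n=200 cohort."""
    rng = np.random.default_rng(314)
    n = 200
    truth = np.arange(n) < 90
    scores = np.clip(rng.integers(1, 9, size=n) + truth * rng.integers(0, 4, size=n), 1, 11)
    _, var = delong_components(scores, truth)
    boot = []
    for _ in range(2000):
        idx = rng.integers(n, size=n)
        t = truth[idx]
        if t.all() or (~t).all():
            continue
        boot.append(auc_mann_whitney(scores[idx], t))
    assert var == pytest.approx(np.var(boot, ddof=1), rel=0.20)


def test_paired_test_identical_scores():
    truth = [False, False, True, True, False, True]
    res = delong_paired_test([1, 2, 5, 6, 3, 4], [1, 2, 5, 6, 3, 4], truth)
    assert res.z == 0.0 and res.p == 1.0


def test_paired_test_antisymmetry():
    rng = np.random.default_rng(21)
    n = 60
    truth = rng.random(n) < 0.5
    truth[:2] = [True, False]
    s1 = rng.integers(1, 12, size=n) + truth * 2
    s2 = rng.integers(1, 12, size=n) + truth * 1
    a = delong_paired_test(s1, s2, truth)
    b = delong_paired_test(s2, s1, truth)
    assert a.z == pytest.approx(-b.z, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)


def test_paired_test_agrees_with_permutation_oracle(small_cohort, t1):
    """DeLong p within 0.01 of a 5000-permutation label-preserving swap test
    on a seeded synthetic cohort."""
    from ksvasc.pipeline import score_cohort

    scored = score_cohort(small_cohort, t1)
    truth = (scored["truth"] == "malignant").to_numpy()
    s1 = scored["ks_star"].to_numpy().astype(float)
    s2 = scored["ks"].to_numpy().astype(float)
    res = delong_paired_test(s1, s2, truth)
    observed = abs(res.auc1 - res.auc2)
    rng = np.random.default_rng(4321)
    hits = 0
    n_perm = 5000
    for _ in range(n_perm):
        swap = rng.random(truth.size) < 0.5
        p1 = np.where(swap, s2, s1)
        p2 = np.where(swap, s1, s2)
        stat = abs(auc_mann_whitney(p1, truth) - auc_mann_whitney(p2, truth))
        hits += stat >= observed - 1e-12
    assert res.p == pytest.approx(hits / n_perm, abs=0.01)


def test_paired_test_type_i_error_calibrated():
    """Under the null (two equally informative, independently drawn scores)
    the empirical alpha at 0.05 lies in [0.03, 0.08] over 500 replicates."""
    rng = np.random.default_rng(1618)
    n, rejections, reps = 200, 0, 500
    truth = np.arange(n) < 95
    for _ in range(reps):
        shift = truth * rng.integers(0, 4, size=n)
        s1 = np.clip(rng.integers(1, 9, size=n) + shift, 1, 11)
        s2 = np.clip(rng.integers(1, 9, size=n) + truth * rng.integers(0, 4, size=n), 1, 11)
        rejections += delong_paired_test(s1, s2, truth).p < 0.05
    assert 0.03 <= rejections / reps <= 0.08


# ---------------------------------------------------------------------- kappa

def test_kappa_perfect_agreement():
    k = cohen_kappa([True, False, True, False], [True, False, True, False])
    assert k.kappa == 1.0 and k.band == "excellent"


def test_kappa_independent_ratings():
    r1 = [True] * 50 + [False] * 50
    r2 = ([True] * 25 + [False] * 25) * 2
    k = cohen_kappa(r1, r2)
    assert k.kappa == pytest.approx(0.0, abs=1e-15)
    assert k.band == "bad"


def test_kappa_hand_computed_table():
    """Agreement table (a=50, b=5, c=10, d=35): kappa = 0.34/0.49."""
    r1 = [True] * 55 + [False] * 45
    r2 = [True] * 50 + [False] * 5 + [True] * 10 + [False] * 35
    k = cohen_kappa(r1, r2)
    assert k.kappa == pytest.approx(0.34 / 0.49, abs=1e-12)
    assert k.band == "good"


def test_kappa_symmetry_and_bands():
    rng = np.random.default_rng(12)
    r1 = rng.random(200) < 0.4
    r2 = r1 ^ (rng.random(200) < 0.2)
    a, b = cohen_kappa(r1, r2), cohen_kappa(r2, r1)
    assert a.kappa == pytest.approx(b.kappa, abs=1e-15)
    assert a.se == pytest.approx(b.se, abs=1e-12)
    for kappa, band in [(0.39, "bad"), (0.4, "good"), (0.7, "good"), (0.71, "excellent")]:
        from ksvasc.stats import _kappa_band

        assert _kappa_band(kappa) == band


def test_kappa_matches_statsmodels():
    from statsmodels.stats.inter_rater import cohens_kappa

    rng = np.random.default_rng(7)
    for _ in range(10):
        r1 = rng.random(150) < 0.5
        r2 = r1 ^ (rng.random(150) < 0.15)
        table = np.array(
            [
                [np.sum(~r1 & ~r2), np.sum(~r1 & r2)],
                [np.sum(r1 & ~r2), np.sum(r1 & r2)],
            ]
        )
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            continue
        ours = cohen_kappa(r1, r2)
        ref = cohens_kappa(table, return_results=True)
        assert ours.kappa == pytest.approx(ref.kappa, abs=1e-10)
        assert ours.se == pytest.approx(np.sqrt(ref.var_kappa), abs=1e-10)


def test_kappa_constant_identical_ratings():
    k = cohen_kappa([True] * 10, [True] * 10)
    assert k.kappa == 1.0


# ---------------------------------------------------------------------- chi2

def test_chi2_equal_proportions():
    res = chi2_2x2([[10, 10], [10, 10]])
    assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 1


def test_chi2_reproduces_printed_avs_specificity_comparison():
    """Mass vs non-mass AVS specificity (65/79 vs 26/40): chi2 ~ 4.41,
    p ~ 0.036 with the uncorrected Pearson statistic."""
    res = chi2_2x2([[65, 14], [26, 14]])
    assert res.chi2 == pytest.approx(4.41, abs=0.02)
    assert 0.030 <= res.p <= 0.040


def test_chi2_swap_invariance():
    a = chi2_2x2([[30, 12], [18, 25]])
    b = chi2_2x2([[25, 18], [12, 30]])  # rows and columns both swapped
    assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)


def test_chi2_zero_marginal_rejected():
    with pytest.raises(ValueError):
        chi2_2x2([[0, 0], [5, 3]])


def test_chi2_equals_squared_two_proportion_z():
    rng = np.random.default_rng(3)
    for _ in range(25):
        t = rng.integers(1, 50, size=(2, 2)).astype(float)
        res = chi2_2x2(t)
        n1, n2 = t[0].sum(), t[1].sum()
        p1, p2 = t[0, 0] / n1, t[1, 0] / n2
        pp = (t[0, 0] + t[1, 0]) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert res.chi2 == pytest.approx(z**2, abs=1e-10)


def test_chi2_matches_scipy_with_and_without_correction():
    table = np.array([[65, 14], [26, 14]])
    ref = sps.chi2_contingency(table, correction=False)
    res = chi2_2x2(table)
    assert res.chi2 == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
    ref_c = sps.chi2_contingency(table, correction=True)
    res_c = chi2_2x2(table, continuity_correction=True)
    assert res_c.chi2 == pytest.approx(ref_c.statistic, abs=1e-12)


# ---------------------------------------------------------------------- CI

def test_auc_ci_contains_estimate():
    rng = np.random.default_rng(44)
    truth = rng.random(120) < 0.45
    truth[:2] = [True, False]
    scores = rng.integers(1, 12, size=120) + truth * 3
    est = auc_with_ci(scores, truth)
    assert est.ci95[0] <= est.auc <= est.ci95[1]
    assert 0.0 <= est.ci95[0] and est.ci95[1] <= 1.0
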