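"""Statistical kernels: transforms, Hochberg, KM, Cox, dichotomization, joints."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

import ctdna_monitor as cm
from ctdna_monitor.association import LARGE_REDUCTION, NOT_LARGE, AnalysisSpec
from ctdna_monitor.association import test_bor_association as fit_bor_association
from ctdna_monitor.association import test_survival_association as fit_survival_association
from ctdna_monitor.errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def test_transform_identity_passthrough():
    x, meta = cm.transform_metric(np.array([0.1, 0.2]), "identity")
    assert np.allclose(x, [0.1, 0.2])
    assert meta["delta"] is None


def test_transform_log_shifted_delta_rule():
    x, meta = cm.transform_metric(np.array([0.0, 1.0]), "log_shifted")
    assert meta["delta"] == pytest.approx(0.5)
    assert np.allclose(x, [math.log(0.5), math.log(1.5)])


def test_transform_log_shifted_all_zero_errors():
    with pytest.raises(DataError):
        cm.transform_metric(np.zeros(4), "log_shifted")


def test_transform_preserves_rank_order(rng):
    for _ in range(50):
        v = rng.exponential(size=20) * (rng.random(20) > 0.2)
        x, _ = cm.transform_metric(v, "log_shifted")
        assert np.array_equal(np.argsort(x, kind="stable"), np.argsort(v, kind="stable"))


# ---------------------------------------------------------------------------
# Hochberg
# ---------------------------------------------------------------------------

def _hochberg_stepup_reject(p, alpha):
    """Hand-enumerated step-up decision rule (independent oracle)."""
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, bool)
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha / (m - k + 1):
            best_k = k
    reject[order[:best_k]] = True
    return reject


def test_hochberg_four_test_family():
    p = [0.001, 0.012, 0.020, 0.251]
    adjusted, reject = cm.hochberg_adjust(p, alpha=0.05)
    assert list(reject) == [True, True, True, False]
    assert adjusted[3] > 0.05 and adjusted[2] <= 0.05


def test_hochberg_single_test_is_raw():
    adjusted, reject = cm.hochberg_adjust([0.03], alpha=0.05)
    assert adjusted[0] == pytest.approx(0.03)
    assert reject[0]


def test_hochberg_rejects_bad_p():
    with pytest.raises(DataError):
        cm.hochberg_adjust([0.5, 1.2])


def test_hochberg_matches_statsmodels_and_dominates_bonferroni(rng):
    for _ in range(300):
        m = int(rng.integers(1, 9))
        p = rng.random(m)
        adjusted, reject = cm.hochberg_adjust(p, alpha=0.05)
        sm_reject, sm_adj, *_ = multipletests(p, alpha=0.05, method="simes-hochberg")
        assert np.allclose(adjusted, sm_adj)
        assert np.array_equal(reject, sm_reject)
        assert np.array_equal(reject, _hochberg_stepup_reject(p, 0.05))
        bonf = p <= 0.05 / m
        assert np.all(reject | ~bonf)  # Hochberg rejections contain Bonferroni's
        # adjusted p monotone in raw p rank
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_no_censoring_is_empirical_survival():
    curve = cm.km_estimate([1, 2, 3], [1, 1, 1])
    assert np.allclose(curve.times, [1, 2, 3])
    assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    assert curve.median == pytest.approx(2.0)


def test_km_product_limit_with_censoring():
    # hand-computed: S(1) = 2/3; censored at 2; S(3) = 2/3 * (1 - 1/1) = 0
    curve = cm.km_estimate([1, 2, 3], [1, 0, 1])
    assert np.allclose(curve.times, [1, 3])
    assert np.allclose(curve.survival, [2 / 3, 0.0])
    assert np.allclose(curve.at_risk, [3, 1])


def test_km_all_censored():
    curve = cm.km_estimate([5, 6, 7], [0, 0, 0])
    assert len(curve.times) == 0
    assert curve.median is None


def test_km_rejects_empty_and_nonpositive():
    with pytest.raises(DataError):
        cm.km_estimate([], [])
    with pytest.raises(DataError):
        cm.km_estimate([0.0, 1.0], [1, 1])


def test_km_matches_empirical_survival_randomized(rng):
    for _ in range(30):
        t = rng.exponential(10, size=int(rng.integers(3, 30)))
        curve = cm.km_estimate(t, np.ones_like(t, dtype=int))
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > time).mean())


# ---------------------------------------------------------------------------
# Cox: brute-force partial likelihood oracle
# ---------------------------------------------------------------------------

def _efron_neg_loglik(beta, times, events, x):
    """Hand-written Efron partial log-likelihood over enumerated risk sets."""
    ll = 0.0
    eta = np.asarray(x, float) * beta
    r = np.exp(eta)
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = tied.sum()
        ll += eta[tied].sum()
        sum_risk = r[risk].sum()
        sum_tied = r[tied].sum()
        for j in range(d):
            ll -= math.log(sum_risk - (j / d) * sum_tied)
    return -ll


def _brute_force_cox(times, events, x):
    res = optimize.minimize_scalar(
        _efron_neg_loglik, args=(times, events, x), bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


def _survival_frame(times, events, x, arm="A_immuno"):
    return pd.DataFrame(
        {"arm": arm, "os_time": times, "os_event": events, "metric": x}
    )


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_cox_matches_brute_force_on_tiny_fixtures(seed):
    """Fitted log-hazard coefficient equals brute-force Efron partial-likelihood
    maximization on <=6-subject data, including tied event times."""
    rng = np.random.default_rng(seed)
    n = 6
    times = np.round(rng.exponential(5, n), 1) + 0.5
    if seed == 3:  # force a tie
        times[1] = times[0]
    events = (rng.random(n) < 0.8).astype(int)
    events[0] = 1
    x = rng.normal(size=n)
    spec = AnalysisSpec("metric", "OS", arm=None, adjust=(), transform="identity")
    res = fit_survival_association(_survival_frame(times, events, x - x.min()), spec)
    expected = _brute_force_cox(times, events, x - x.min())
    assert res.estimate == pytest.approx(expected, abs=1e-4)


def test_cox_two_group_exponential_hazard_ratio():
    """Exponential rates lambda vs 2*lambda give HR ~ 2 at large n."""
    rng = np.random.default_rng(42)
    n = 2000
    group = np.repeat([0.0, 1.0], n // 2)
    times = rng.exponential(1.0 / (0.1 * np.exp(math.log(2) * group)))
    spec = AnalysisSpec("metric", "OS", adjust=(), transform="identity")
    res = fit_survival_association(_survival_frame(times, np.ones(n, int), group), spec)
    assert res.estimate == pytest.approx(math.log(2), abs=3 * res.se)


def test_cox_no_events_not_estimable():
    spec = AnalysisSpec("metric", "OS", adjust=(), transform="identity")
    res = fit_survival_association(
        _survival_frame([1, 2, 3], [0, 0, 0], [0.1, 0.2, 0.3]), spec
    )
    assert not res.estimable
    assert "no_events" in res.note


# ---------------------------------------------------------------------------
# logistic / one-sided orientation
# ---------------------------------------------------------------------------

def _bor_frame(x, responder, arm="A_immuno"):
    return pd.DataFrame(
        {"arm": arm, "bor": np.where(responder, "PR", "PD"), "metric": x}
    )


def test_bor_one_sided_p_flips_under_metric_reflection(rng):
    """Reflecting the metric (c - x) negates the Wald z, so p -> 1 - p."""
    x = rng.exponential(size=80)
    responder = rng.random(80) < 1 / (1 + np.exp(1.5 * (x - 1)))
    spec = AnalysisSpec("metric", "BOR", adjust=(), transform="identity")
    p_fwd = fit_bor_association(_bor_frame(x, responder), spec).p_one_sided
    p_rev = fit_bor_association(_bor_frame(x.max() - x, responder), spec).p_one_sided
    assert p_fwd + p_rev == pytest.approx(1.0, abs=1e-6)


def test_bor_zero_responders_not_estimable():
    spec = AnalysisSpec("metric", "BOR", adjust=(), transform="identity")
    res = fit_bor_association(_bor_frame([0.1, 0.2, 0.3], [False] * 3), spec)
    assert not res.estimable
    assert "all_one_class" in res.note


def test_bor_complete_separation_flagged_not_silent():
    x = np.concatenate([np.zeros(10), np.ones(10)])
    responder = x > 0.5
    spec = AnalysisSpec("metric", "BOR", adjust=(), transform="identity")
    res = fit_bor_association(_bor_frame(x, responder), spec)
    assert res.estimable
    assert "penalized" in res.note
    assert 0.0 <= res.p_one_sided <= 1.0


def test_one_sided_orientation_by_outcome():
    # positive estimate: harmful for survival (small p), against benefit for BOR
    assert cm.one_sided_p(2.0, 1.0, "OS") == pytest.approx(stats.norm.sf(2.0))
    assert cm.one_sided_p(2.0, 1.0, "BOR") == pytest.approx(stats.norm.cdf(2.0))


# ---------------------------------------------------------------------------
# dichotomization / between-arm HR / joint models
# ---------------------------------------------------------------------------

def test_dichotomize_examples():
    labels, cutoff = cm.dichotomize_by_pooled_median([0.1, 0.2, 0.3, 0.4])
    assert cutoff == pytest.approx(0.25)
    assert list(labels) == [LARGE_REDUCTION, LARGE_REDUCTION, NOT_LARGE, NOT_LARGE]


def test_dichotomize_tie_goes_to_not_large():
    labels, cutoff = cm.dichotomize_by_pooled_median([0.1, 0.2, 0.3])
    assert cutoff == pytest.approx(0.2)
    assert labels[1] == NOT_LARGE


def test_dichotomize_permutation_invariant(rng):
    v = rng.exponential(size=21)
    labels, _ = cm.dichotomize_by_pooled_median(v)
    perm = rng.permutation(21)
    labels_p, _ = cm.dichotomize_by_pooled_median(v[perm])
    assert np.array_equal(labels[perm], labels_p)


def test_dichotomize_needs_two_evaluable():
    with pytest.raises(DataError):
        cm.dichotomize_by_pooled_median([0.4, float("nan")])


def test_between_arm_hr_label_swap_inverts(small_analysis):
    out = cm.between_arm_hr(small_analysis, "OS")
    swapped = small_analysis.assign(
        arm=small_analysis["arm"].map({"A_immuno": "Z", "B_chemo": "A"})
    )
    out2 = cm.between_arm_hr(swapped, "OS")
    assert out2["hr"] == pytest.approx(1.0 / out["hr"], rel=1e-6)


def test_between_arm_hr_single_arm_errors(small_analysis):
    with pytest.raises(DataError):
        cm.between_arm_hr(small_analysis[small_analysis["arm"] == "A_immuno"], "OS")


def test_joint_model_constant_radiographic_reduces_to_unadjusted(small_analysis):
    df = small_analysis.copy()
    df["tumor_change_9wk"] = 5.0
    spec = AnalysisSpec("ratio_maxvaf_informed", "OS", arm="A_immuno", adjust=())
    metric_res, rad_res = cm.joint_orthogonality_test(df, spec, "tumor_change_9wk")
    plain = fit_survival_association(df, spec)
    assert metric_res.estimate == pytest.approx(plain.estimate, rel=1e-8)
    assert "degenerate" in rad_res.note


def test_joint_model_returns_both_terms(small_analysis):
    spec = AnalysisSpec("ratio_maxvaf_informed", "OS", arm="B_chemo", adjust=("ecog_ps",))
    metric_res, rad_res = cm.joint_orthogonality_test(small_analysis, spec, "bor")
    assert metric_res.p_one_sided is not None
    assert rad_res.p_two_sided is not None
    assert metric_res.n == rad_res.n


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

def test_analysis_spec_validation():
    with pytest.raises(ConfigError):
        AnalysisSpec("m", "BOR", adjust=("bor",))
    with pytest.raises(ConfigError):
        AnalysisSpec("m", "OS", alpha=1.5)
    with pytest.raises(ConfigError):
        AnalysisSpec("m", "XYZ")


def test_model_fit_summary_contract(small_cohort):
    results = cm.CtdnaAssociationModel.from_cohort(small_cohort).fit()
    table = results.summary()
    assert {"metric", "outcome", "arm", "p_one_sided", "p_adjusted", "reject"} <= set(table.columns)
    est = table.dropna(subset=["p_adjusted"])
    # Hochberg adjustment never lowers a p value below the raw one
    assert (est["p_adjusted"] >= est["p_one_sided"] - 1e-12).all()
    # rejection equivalent to adjusted p <= alpha
    assert (est["reject"] == (est["p_adjusted"] <= 0.05)).all()


def test_km_by_median_reduction_display(small_cohort):
    results = cm.CtdnaAssociationModel.from_cohort(small_cohort).fit()
    info = results.km_by_median_reduction("ratio_maxvaf_informed", "OS", arm="B_chemo")
    assert set(info["curves"]) <= {LARGE_REDUCTION, NOT_LARGE}
    for curve in info["curves"].values():
        assert np.all(np.diff(curve.survival) <= 1e-12)  # non-increasing
        assert np.all(curve.survival <= 1.0)
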