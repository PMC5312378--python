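"""Cox partial-likelihood fitting: oracle agreement, invariants, cross-checks."""

import numpy as np
import pytest
from lifelines import CoxPHFitter
import pandas as pd

import oracles
from conftest import make_survival_data
from mirsurv import survival as sv
from mirsurv.errors import AlignmentError, DataError, InferenceError, RankError


def _tiny_dataset(rng, n):
    """Continuous times (no ties), one continuous covariate, >=2 events."""
    while True:
        x = rng.normal(size=n)
        time = rng.exponential(10.0, n) + 0.01
        event = (rng.random(n) < 0.7).astype(int)
        if event.sum() >= 2 and len(np.unique(time)) == n:
            return time, event, x


def test_newton_matches_gridsearch_oracle_on_tiny_datasets(rng):
    """Fitted beta equals a grid-search maximizer of the explicitly coded
    partial likelihood on small untied one-covariate datasets."""
    checked = 0
    attempts = 0
    while checked < 25 and attempts < 200:
        attempts += 1
        n = int(rng.integers(4, 9))
        time, event, x = _tiny_dataset(rng, n)
        beta_grid = oracles.grid_search_beta(time, event, x)
        if abs(beta_grid) > 6.0:  # monotone likelihood; no interior maximum
            continue
        fit = sv.cox_fit(time, event, x)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(beta_grid, abs=1e-4)
        checked += 1
    assert checked == 25


def test_score_test_equals_logrank_for_binary_covariate(rng):
    """Rao score chi-square at beta=0 coincides with the two-group log-rank
    statistic when the single covariate is binary and times are untied."""
    for _ in range(20):
        n = int(rng.integers(20, 60))
        time = rng.exponential(10.0, n) + 0.01
        event = (rng.random(n) < 0.6).astype(int)
        x = (rng.random(n) < 0.5).astype(float)
        if event.sum() < 2 or x.std() == 0 or len(np.unique(time)) < n:
            continue
        score_stat, _ = sv.cox_score_test(time, event, x)
        chi2, df, _ = sv.logrank_test(time, event, x.astype(int))
        assert df == 1
        assert score_stat == pytest.approx(chi2, abs=1e-9)


def test_efron_and_breslow_coincide_without_ties(rng):
    time, event, x, Z = make_survival_data(rng, n=120, beta_x=0.4)
    X = np.column_stack([Z, x])
    fe = sv.cox_fit(time, event, X, ties="efron")
    fb = sv.cox_fit(time, event, X, ties="breslow")
    assert fe.loglik == pytest.approx(fb.loglik, abs=1e-10)
    np.testing.assert_allclose(fe.beta, fb.beta, atol=1e-8)


def test_fitted_loglik_never_below_null(rng):
    """Guaranteed ascent: the maximized partial likelihood is at least its
    value at beta = 0."""
    for _ in range(10):
        time, event, x, Z = make_survival_data(rng, n=80, beta_x=rng.normal())
        fit = sv.cox_fit(time, event, np.column_stack([Z, x]))
        assert fit.loglik >= fit.loglik_null - 1e-12


def test_matches_lifelines_on_moderate_data(rng):
    """Cross-check coefficients, standard errors and log-likelihood against
    an independent Cox implementation, including tied times (Efron)."""
    time, event, x, Z = make_survival_data(rng, n=300, beta_x=0.5, n_cov=3)
    time = np.ceil(time)  # force ties
    X = np.column_stack([Z, x])
    fit = sv.cox_fit(time, event, X)
    df = pd.DataFrame(X, columns=["z0", "z1", "z2", "x"])
    df["time"], df["event"] = time, event
    cph = CoxPHFitter().fit(df, "time", "event")
    np.testing.assert_allclose(fit.beta, cph.params_.values, atol=2e-5)
    np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=2e-5)
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_error_conditions(rng):
    time, event, x, Z = make_survival_data(rng, n=40)
    with pytest.raises(RankError):
        sv.cox_fit(time, event, np.ones_like(x))  # constant covariate
    with pytest.raises(InferenceError):
        sv.cox_fit(time, np.zeros_like(event), x)  # no events
    with pytest.raises(DataError):
        sv.cox_fit(np.zeros_like(time), event, x)  # non-positive times
    with pytest.raises(RankError):
        sv.cox_fit(time, event, np.column_stack([x, x]))  # collinear


def test_lrt_statistic_contracts(rng):
    time, event, x, Z = make_survival_data(rng, n=150, beta_x=0.8)
    full = sv.cox_fit(time, event, np.column_stack([Z, x]), names=["z0", "z1", "x"])
    reduced = sv.cox_fit(time, event, Z, names=["z0", "z1"])
    assert sv.lrt_statistic(full, full) == 0.0
    assert sv.lrt_statistic(full, reduced) > 0.0  # planted strong effect
    other_time, other_event, ox, oZ = make_survival_data(rng, n=120)
    other = sv.cox_fit(other_time, other_event, oZ, names=["z0", "z1"])
    with pytest.raises(AlignmentError):
        sv.lrt_statistic(full, other)


def test_null_lrt_is_approximately_chi_square_1(rng):
    """With a pure-noise focal covariate the LRT follows chi-square(1):
    its mean over replicates is close to 1."""
    stats = []
    for _ in range(500):
        time, event, x, Z = make_survival_data(rng, n=300, beta_x=0.0, n_cov=1)
        full = sv.cox_fit(time, event, np.column_stack([Z, x]), names=["z", "x"])
        reduced = sv.cox_fit(time, event, Z, names=["z"])
        stats.append(sv.lrt_statistic(full, reduced))
    assert 0.85 < np.mean(stats) < 1.15


def test_iqr_hazard_ratio():
    fit = sv.CoxFit(
        beta=np.array([np.log(2.0)]), cov=np.array([[0.0]]), loglik=0.0,
        loglik_null=0.0, ties="efron", n=10, n_events=5, converged=True, n_iter=3,
    )
    hr, lo, hi = sv.iqr_hazard_ratio(fit, q1=-1.0, q3=1.0)
    assert hr == pytest.approx(4.0)
    assert lo == pytest.approx(4.0) and hi == pytest.approx(4.0)  # se = 0
    hr, lo, hi = sv.iqr_hazard_ratio(fit, q1=0.5, q3=0.5)
    assert (hr, lo, hi) == (1.0, 1.0, 1.0)  # zero span
    fit.beta[0] = 0.0
    hr, _, _ = sv.iqr_hazard_ratio(fit, q1=-3.0, q3=7.0)
    assert hr == 1.0
    with pytest.raises(DataError):
        sv.iqr_hazard_ratio(fit, q1=1.0, q3=0.0)


def test_rare_fit_floor_and_recovery(rng):
    time, event, x, Z = make_survival_data(rng, n=60)
    with pytest.raises(InferenceError):
        sv.rare_mirna_fit(time, event, Z, np.zeros_like(x))  # zero expressors
    with pytest.raises(InferenceError):
        expr = np.zeros_like(x)
        expr[:4] = 1.0
        sv.rare_mirna_fit(time, event, Z, expr)  # below 5-expressor floor

    # planted binary effect is recovered inside its Wald CI most of the time
    hits = 0
    n_sims = 120
    for _ in range(n_sims):
        n = 1000
        expr = (rng.random(n) < 0.03).astype(float)
        Zc = rng.normal(size=(n, 2))
        eta = np.log(2.2) * expr + 0.2 * Zc[:, 0]
        t_ev = rng.exponential(50.0 * np.exp(-eta))
        cens = np.minimum(rng.exponential(150.0, n), 60.0)
        t = np.maximum(np.minimum(t_ev, cens), 1e-6)
        e = (t_ev <= cens).astype(int)
        if expr.sum() < 5:
            continue
        res = sv.rare_mirna_fit(t, e, Zc, expr)
        if res["ci_low"] <= 2.2 <= res["ci_high"]:
            hits += 1
    assert hits / n_sims >= 0.90


def test_rare_fit_null_wald_p_is_uniform(rng):
    """Under beta = 0 the Wald p-value for any-vs-no expression is uniform."""
    from scipy import stats as sps

    pvals = []
    for _ in range(400):
        n = 300
        expr = (rng.random(n) < 0.25).astype(float)
        Zc = rng.normal(size=(n, 1))
        t_ev = rng.exponential(50.0, n)
        cens = np.minimum(rng.exponential(150.0, n), 60.0)
        t = np.maximum(np.minimum(t_ev, cens), 1e-6)
        e = (t_ev <= cens).astype(int)
        pvals.append(sv.rare_mirna_fit(t, e, Zc, expr)["p"])
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_site_interaction(rng):
    """Interaction LRT: rank error when not identifiable, null mean ~ 1,
    and decent power against a planted interaction."""
    from scipy import stats as sps

    time, event, x, Z = make_survival_data(rng, n=100)
    with pytest.raises(RankError):
        sv.site_interaction_test(time, event, x, np.ones_like(x), Z)

    def one_sim(planted, n=800):
        site = rng.integers(1, 6, n).astype(float)  # cecum..sigmoid
        x = rng.normal(size=n)
        Zc = rng.normal(size=(n, 1))
        eta = 0.1 * x + 0.05 * site + planted * x * (site - 3.0)
        t_ev = rng.exponential(50.0 * np.exp(-eta))
        cens = np.minimum(rng.exponential(150.0, n), 60.0)
        t = np.maximum(np.minimum(t_ev, cens), 1e-6)
        e = (t_ev <= cens).astype(int)
        return sv.site_interaction_test(t, e, x, site, Zc)

    null_stats = [one_sim(0.0)[0] for _ in range(500)]
    assert 0.85 < np.mean(null_stats) < 1.15  # chi-square(1) null

    power_hits = sum(one_sim(np.log(1.5))[1] < 0.05 for _ in range(150))
    assert power_hits / 150 > 0.8
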