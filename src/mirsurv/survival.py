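"""Cox proportional hazards, permutation inference, Kaplan-Meier and log-rank.

This module is the inferential core of the package.  The Cox model is fit
from the partial likelihood (Efron tie handling by default, Breslow
switchable) by Newton-Raphson with step halving; per-miRNA p-values for
continuous differential-expression exposures come from a permutation
distribution of the 1-df likelihood-ratio statistic, mirroring survival
analyses that report "permutation LRT" p-values.  Hazard ratios for
continuous exposures are reported per interquartile range of the exposure;
rarely-expressed miRNAs are analyzed as any-vs-no expression with ordinary
Wald p-values.

Conventions
-----------
* Times are follow-up months, strictly positive.
* ``event`` is 1 for a cause-specific death, 0 for censoring (other-cause
  death, loss to follow-up, administrative cutoff).
* Subjects censored at an event time remain in the risk set for that time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import _coxcore
from .errors import AlignmentError, DataError, InferenceError, RankError

MAX_ITER = 60
SCORE_TOL = 1e-8
LL_TOL = 1e-10
_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def _prepare(time, event, X):
    """Validate, sort by time ascending and delimit tied-time blocks."""
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != time.shape[0]:
        X = X.T
    if X.shape[0] != time.shape[0] or event.shape[0] != time.shape[0]:
        raise AlignmentError(
            f"time ({time.shape[0]}), event ({event.shape[0]}) and covariates "
            f"({X.shape[0]}) have inconsistent lengths"
        )
    if time.shape[0] == 0:
        raise DataError("empty survival data")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise DataError("survival times must be finite and strictly positive")
    event = event.astype(bool)
    if not event.any():
        raise InferenceError("no events in the data; the partial likelihood is flat")
    order = np.argsort(time, kind="stable")
    time_s = time[order]
    event_s = event[order]
    X_s = np.ascontiguousarray(X[order])
    is_new = np.empty(time_s.shape[0], dtype=bool)
    is_new[0] = True
    is_new[1:] = time_s[1:] != time_s[:-1]
    starts = np.flatnonzero(is_new).astype(np.int64)
    counts = np.diff(np.append(starts, time_s.shape[0])).astype(np.int64)
    return time_s, event_s, X_s, starts, counts, order


def _check_rank(info, names):
    """Reject collinear / zero-information designs via eigenvalue conditioning."""
    if info.shape[0] == 0:
        return
    eig = np.linalg.eigvalsh(info)
    if eig[-1] <= 0 or eig[0] <= 1e-10 * max(eig[-1], 1.0):
        raise RankError(
            "information matrix is singular (constant or collinear covariates): "
            + ", ".join(names)
        )


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox proportional hazards model.

    ``beta`` are log hazard ratios per unit covariate; ``cov`` is the
    inverse observed information at the optimum.  ``capped`` marks a
    monotone-likelihood (perfect separation) fit whose diverging
    coefficient(s) were stopped at +-30.
    """

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    ties: str
    n: int
    n_events: int
    converged: bool
    n_iter: int
    names: list = field(default_factory=list)
    capped: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self, j: int = -1) -> float:
        z = self.beta[j] / self.se[j]
        return 2.0 * sps.norm.sf(abs(z))


@dataclass
class KMEstimate:
    """Product-limit survival curve evaluated at the distinct event times."""

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.shape[0] > 1 else float(out[0])

    def truncated(self, horizon: float) -> "KMEstimate":
        keep = self.times <= horizon
        return KMEstimate(
            self.times[keep], self.at_risk[keep], self.n_events[keep], self.survival[keep]
        )


@dataclass
class PermutationResult:
    p: float
    observed_stat: float
    n_permutations: int
    n_exceed: int
    exhaustive: bool = False


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------


def cox_fit(time, event, X, names=None, ties="efron", warm_start=None) -> CoxFit:
    """Fit a Cox proportional hazards model by maximum partial likelihood.

    Parameters
    ----------
    time, event : array-like
        Follow-up months and cause-specific death indicator.
    X : array-like, shape (n, p)
        Covariate matrix (no intercept; the baseline hazard absorbs it).
    ties : {"efron", "breslow"}
        Approximation for tied event times.
    warm_start : array-like, optional
        Initial coefficient vector (defaults to zero).
    """
    if ties not in ("efron", "breslow"):
        raise DataError(f"unknown ties method {ties!r}")
    time_s, event_s, X_s, starts, counts, _ = _prepare(time, event, X)
    p = X_s.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]
    efron = ties == "efron"
    ll0, _, info0 = _coxcore.loglik_grad_info(
        np.zeros(p), X_s, event_s, starts, counts, efron
    )
    _check_rank(info0, names)
    beta0 = np.zeros(p) if warm_start is None else np.asarray(warm_start, dtype=float).copy()
    beta, ll, grad, info, converged, n_iter = _coxcore.newton_raphson(
        X_s, event_s, starts, counts, beta0, efron, MAX_ITER, SCORE_TOL, LL_TOL
    )
    # monotone likelihood: a diverging coefficient was stopped at the cap;
    # its information entry collapses, so invert defensively and flag the fit
    capped = bool(np.any(np.abs(beta) >= 30.0 - 1e-9))
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return CoxFit(
        beta=beta,
        cov=cov,
        loglik=float(ll),
        loglik_null=float(ll0),
        ties=ties,
        n=int(time_s.shape[0]),
        n_events=int(event_s.sum()),
        converged=bool(converged) and not capped,
        n_iter=int(n_iter),
        names=list(names),
        capped=capped,
    )


def cox_loglik(time, event, X, beta, ties="efron") -> float:
    """Log partial likelihood at an arbitrary coefficient vector."""
    time_s, event_s, X_s, starts, counts, _ = _prepare(time, event, X)
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _coxcore.loglik_grad_info(
        beta, X_s, event_s, starts, counts, ties == "efron"
    )
    return float(ll)


def cox_score_test(time, event, X, ties="efron") -> tuple[float, float]:
    """Score (Rao) test of beta = 0.  Returns (chi_square, p).

    For a single binary covariate with no tied event times this statistic
    coincides exactly with the two-group log-rank chi-square.
    """
    time_s, event_s, X_s, starts, counts, _ = _prepare(time, event, X)
    p = X_s.shape[1]
    _, grad, info = _coxcore.loglik_grad_info(
        np.zeros(p), X_s, event_s, starts, counts, ties == "efron"
    )
    _check_rank(info, [f"x{j}" for j in range(p)])
    stat = float(grad @ np.linalg.solve(info, grad))
    return stat, float(sps.chi2.sf(stat, p))


def lrt_statistic(full: CoxFit, reduced: CoxFit) -> float:
    """Likelihood-ratio statistic 2*(ll_full - ll_reduced), floored at 0."""
    if full.n != reduced.n or full.n_events != reduced.n_events:
        raise AlignmentError("full and reduced fits are not on the same data")
    if len(reduced.names) > len(full.names) or not set(reduced.names) <= set(full.names):
        raise AlignmentError("reduced covariates are not a subset of the full model")
    return max(0.0, 2.0 * (full.loglik - reduced.loglik))


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


def permutation_pvalue(
    time,
    event,
    covariates,
    focal,
    B=10_000,
    seed=None,
    ties="efron",
    exhaustive=False,
) -> PermutationResult:
    """Permutation p-value for the focal exposure's 1-df likelihood-ratio test.

    The focal exposure vector is permuted across subjects while times,
    events and adjustment covariates stay fixed; every replicate refits the
    full Cox model and the p-value is the add-one estimator
    ``(1 + #{perm LRT >= observed LRT}) / (1 + B)``, so p is always in
    (0, 1].  With ``exhaustive=True`` all n! permutations are enumerated
    (tiny n only) and the exact proportion is returned.
    """
    focal = np.asarray(focal, dtype=float)
    if focal.ndim != 1:
        raise DataError("focal exposure must be a vector")
    if np.ptp(focal) == 0:
        raise InferenceError("focal exposure is constant; nothing to permute")
    covariates = np.asarray(covariates, dtype=float)
    if covariates.size == 0:
        covariates = np.empty((focal.shape[0], 0))
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    X_full = np.column_stack([covariates, focal])
    time_s, event_s, Xf_s, starts, counts, _ = _prepare(time, event, X_full)
    q = covariates.shape[1]
    efron = ties == "efron"

    if q:
        beta_red, ll_red, _, _, conv_r, _ = _coxcore.newton_raphson(
            Xf_s[:, :q].copy(), event_s, starts, counts, np.zeros(q), efron,
            MAX_ITER, SCORE_TOL, LL_TOL,
        )
    else:
        beta_red = np.zeros(0)
        ll_red, _, _ = _coxcore.loglik_grad_info(
            np.zeros(0), Xf_s[:, :0].copy(), event_s, starts, counts, efron
        )
    beta_warm = np.append(beta_red, 0.0)

    _, _, info0 = _coxcore.loglik_grad_info(
        np.zeros(q + 1), Xf_s, event_s, starts, counts, efron
    )
    _check_rank(info0, [f"x{j}" for j in range(q)] + ["focal"])

    _, ll_obs, _, _, _, _ = _coxcore.newton_raphson(
        Xf_s, event_s, starts, counts, beta_warm, efron, MAX_ITER, SCORE_TOL, LL_TOL
    )
    observed = max(0.0, 2.0 * (ll_obs - ll_red))

    if exhaustive:
        n = time_s.shape[0]
        focal_s = Xf_s[:, q].copy()
        n_exceed = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            _, ll, _, _, _, _ = _coxcore.fit_with_exposure(
                Xf_s, focal_s[np.array(perm)], event_s, starts, counts,
                beta_warm, efron, MAX_ITER, SCORE_TOL, LL_TOL,
            )
            if max(0.0, 2.0 * (ll - ll_red)) >= observed:
                n_exceed += 1
        return PermutationResult(
            p=n_exceed / total,
            observed_stat=observed,
            n_permutations=total,
            n_exceed=n_exceed,
            exhaustive=True,
        )

    if B < 1:
        raise DataError("B must be >= 1")
    if seed is None:
        seed = 0
    n_exceed, _ = _coxcore.permutation_lrt(
        Xf_s, event_s, starts, counts, beta_warm, ll_red, observed,
        int(B), int(seed) % (2**31), efron, MAX_ITER, SCORE_TOL, LL_TOL,
    )
    return PermutationResult(
        p=(1 + n_exceed) / (1 + B),
        observed_stat=observed,
        n_permutations=int(B),
        n_exceed=int(n_exceed),
    )


# ---------------------------------------------------------------------------
# hazard-ratio reporting
# ---------------------------------------------------------------------------


def iqr_hazard_ratio(fit: CoxFit, q1: float, q3: float, index: int = -1):
    """Hazard ratio across the interquartile span of the focal exposure.

    HR = exp(beta * (q3 - q1)) with a 95% Wald interval
    exp((beta +- 1.96 se) * (q3 - q1)).
    """
    if q3 < q1:
        raise DataError(f"q3 ({q3}) < q1 ({q1})")
    span = q3 - q1
    b = fit.beta[index]
    se = fit.se[index]
    with np.errstate(over="ignore"):
        hr = float(np.exp(b * span))
        lo = float(np.exp((b - _Z95 * se) * span))
        hi = float(np.exp((b + _Z95 * se) * span))
    return hr, min(lo, hi), max(lo, hi)


def rare_mirna_fit(
    time, event, covariates, any_expression, min_expressors=5, ties="efron"
):
    """Any-vs-no expression Cox model for rarely expressed miRNAs.

    Returns a dict with the per-unit HR (= exp(beta) for the binary
    exposure), 95% Wald CI and non-permuted Wald p-value.
    """
    any_expression = np.asarray(any_expression).astype(float)
    n_expr = int((any_expression > 0).sum())
    if n_expr < min_expressors:
        raise InferenceError(
            f"only {n_expr} expressors; analysis floor is {min_expressors}"
        )
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    X = np.column_stack([covariates, (any_expression > 0).astype(float)])
    fit = cox_fit(time, event, X, ties=ties)
    b, se = fit.beta[-1], fit.se[-1]
    if abs(b) >= 30.0 - 1e-9 or se > 50.0:
        raise InferenceError(
            "any-vs-no expression effect is not estimable (monotone likelihood; "
            "e.g. no events among expressors)"
        )
    return {
        "hr": math.exp(b),
        "ci_low": math.exp(b - _Z95 * se),
        "ci_high": math.exp(b + _Z95 * se),
        "p": fit.wald_p(-1),
        "n_expressors": n_expr,
        "fit": fit,
    }


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def km_estimate(time, event) -> KMEstimate:
    """Product-limit (Kaplan-Meier) estimate of the survival function.

    Censored subjects leave the risk set after their censoring time;
    censoring tied with an event time is counted at risk for that event.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.shape[0] == 0:
        raise DataError("empty survival data")
    if np.any(time <= 0):
        raise DataError("times must be strictly positive")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.shape[0]
    ev_times = np.unique(t[e])
    at_risk = np.empty(ev_times.shape[0], dtype=np.int64)
    d = np.empty(ev_times.shape[0], dtype=np.int64)
    surv = np.empty(ev_times.shape[0])
    s = 1.0
    for k, tk in enumerate(ev_times):
        nk = int((t >= tk).sum())
        dk = int(e[t == tk].sum())
        s *= 1.0 - dk / nk
        at_risk[k] = nk
        d[k] = dk
        surv[k] = s
    return KMEstimate(times=ev_times, at_risk=at_risk, n_events=d, survival=surv)


def logrank_test(time, event, group):
    """Mantel-Haenszel / log-rank test of equal survival across groups.

    Observed-minus-expected with the multivariate hypergeometric covariance
    at each distinct event time; chi-square with (n_groups - 1) df.
    Returns (chi_square, df, p).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    labels = np.unique(group)
    G = labels.shape[0]
    if G < 2:
        raise DataError("log-rank test needs at least two groups")
    gidx = np.searchsorted(labels, group)
    ev_times = np.unique(time[event])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for tk in ev_times:
        at_risk = time >= tk
        nk = int(at_risk.sum())
        dk = int((event & (time == tk)).sum())
        if nk <= 0 or dk == 0:
            continue
        ngk = np.bincount(gidx[at_risk], minlength=G).astype(float)
        dgk = np.bincount(gidx[event & (time == tk)], minlength=G).astype(float)
        pk = ngk / nk
        O += dgk
        E += dk * pk
        if nk > 1:
            c = dk * (nk - dk) / (nk - 1)
            V += c * (np.diag(pk) - np.outer(pk, pk))
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    stat = float(z @ np.linalg.solve(Vr, z)) if np.any(z != 0) else 0.0
    df = G - 1
    return stat, df, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# site-by-exposure interaction
# ---------------------------------------------------------------------------


def site_interaction_test(
    time, event, focal, ordinal_site, covariates, ties="efron"
):
    """1-df LRT for an exposure-by-ordinal-site interaction (continuous coding).

    Compares the model (exposure, site, covariates) against the same model
    plus the exposure*site product term.  The ordinal site runs along the
    colon (e.g. cecum -> sigmoid as consecutive integers); returns
    (lrt_statistic, p) against chi-square(1).
    """
    focal = np.asarray(focal, dtype=float)
    site = np.asarray(ordinal_site, dtype=float)
    if np.ptp(site) == 0:
        raise RankError("ordinal site is constant; interaction not identifiable")
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    X_red = np.column_stack([covariates, site, focal])
    X_full = np.column_stack([X_red, focal * site])
    reduced = cox_fit(time, event, X_red, ties=ties)
    full = cox_fit(time, event, X_full, ties=ties)
    stat = lrt_statistic(full, reduced)
    return stat, float(sps.chi2.sf(stat, 1))
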