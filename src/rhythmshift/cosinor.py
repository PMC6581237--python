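"""Single-period (24-h) cosinor fitting, fixed- and mixed-effects.

The linearised cosinor model for a metabolite's log2 concentration is

    y_ij = a + b * cos(2*pi*t_ij/24) + c * sin(2*pi*t_ij/24) [+ u_i] + e_ij

with an optional random intercept u_i ~ N(0, sigma_u^2) per subject (a random
mesor) and residual e_ij ~ N(0, sigma_e^2). Amplitude and acrophase follow
from the coefficients: A = sqrt(b^2 + c^2), phi = (24/2pi) atan2(c, b), so the
fitted curve is a + A*cos(2*pi*(t - phi)/24) and phi is the time of peak.

Rhythmicity is tested as the joint null b = c = 0: an F-test for the
fixed-effects (single-series) fit, a chi-square(2) likelihood-ratio test for
the mixed fit. Mixed models are estimated by maximum likelihood (not REML) so
that the LRT against the reduced fixed-effects structure is valid; the random
intercept reduces to a single variance ratio, which is profiled out and
optimised as a bounded scalar problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

PERIOD_H = 24.0
_OMEGA = 2.0 * np.pi / PERIOD_H


class SingularDesignError(ValueError):
    """Raised when the cosinor design matrix is rank-deficient (e.g. all
    observations at a single sampling time)."""


@dataclass
class CosinorFit:
    """Result of a cosinor fit (fixed- or mixed-effects).

    ``phase_h`` is NaN when the fitted amplitude is exactly zero (time of peak
    undefined). ``q_rhythm`` is filled in by pipeline code after BH correction
    across metabolites. ``random_mesor_sd`` is NaN for fixed-effects fits.
    """

    mesor: float
    beta_cos: float
    beta_sin: float
    amplitude: float
    phase_h: float
    loglik: float
    bic: float
    n_obs: int
    p_rhythm: float
    residual_sd: float
    random_mesor_sd: float = float("nan")
    q_rhythm: float = float("nan")
    converged: bool = True
    model: str = "fixed"  # "fixed" | "mixed"

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        return self.mesor + self.beta_cos * np.cos(_OMEGA * t) + self.beta_sin * np.sin(_OMEGA * t)


def phase_amplitude(b: float, c: float) -> tuple[float, float]:
    """Amplitude and acrophase (hours, time of peak) from cosinor coefficients.

    Returns ``(A, phi)`` with ``A = sqrt(b^2 + c^2)`` and
    ``phi = (24/2pi) * atan2(c, b) mod 24``. When ``A == 0`` the phase is
    undefined and returned as NaN, never as 0.
    """
    amp = float(np.hypot(b, c))
    if amp == 0.0:
        return 0.0, float("nan")
    phi = float(np.mod(np.arctan2(c, b) / _OMEGA, PERIOD_H))
    return amp, phi


def cosinor_design(times_h) -> np.ndarray:
    t = np.asarray(times_h, dtype=float)
    return np.column_stack([np.ones_like(t), np.cos(_OMEGA * t), np.sin(_OMEGA * t)])


def fit_cosinor_fixed(times_h: Sequence[float], values: Sequence[float]) -> CosinorFit:
    """Ordinary least-squares cosinor for a single series.

    Requires >= 4 observations at >= 3 distinct times so a residual degree of
    freedom remains. The rhythmicity p-value is the classical zero-amplitude
    F-test of the joint null b = c = 0 with (2, n - 3) degrees of freedom.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    n = y.size
    if n < 4:
        raise ValueError(f"need >= 4 observations, got {n}")
    if np.unique(np.mod(t, PERIOD_H)).size < 3:
        raise SingularDesignError("need >= 3 distinct sampling times within the period")
    X = cosinor_design(t)
    if np.linalg.matrix_rank(X) < 3:
        raise SingularDesignError("cosinor design is rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df2 = n - 3
    if rss1 <= 1e-12 * max(rss0, 1.0):
        # (near-)perfect fit: F degenerates; a flat perfect fit is non-rhythmic
        p = 1.0 if rss0 <= 1e-12 else 0.0
        f_stat = 0.0 if rss0 <= 1e-12 else float("inf")
    else:
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df2)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, 2, df2))
    sigma2 = rss1 / n  # ML variance
    loglik = -0.5 * n * (np.log(2.0 * np.pi * max(sigma2, 1e-300)) + 1.0)
    k = 4  # a, b, c, sigma^2
    bic = -2.0 * loglik + k * np.log(n)
    amp, phi = phase_amplitude(beta[1], beta[2])
    return CosinorFit(
        mesor=float(beta[0]),
        beta_cos=float(beta[1]),
        beta_sin=float(beta[2]),
        amplitude=amp,
        phase_h=phi,
        loglik=float(loglik),
        bic=float(bic),
        n_obs=n,
        p_rhythm=p,
        residual_sd=float(np.sqrt(sigma2)),
        model="fixed",
    )


def zero_amplitude_f(times_h, values) -> float:
    """F statistic of the zero-amplitude test for a single series (used by the
    permutation machinery, which needs the statistic without the full fit)."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    X = cosinor_design(t)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    if rss1 <= 1e-12 * max(rss0, 1.0):
        return 0.0 if rss0 <= 1e-12 else np.inf
    return max(((rss0 - rss1) / 2.0) / (rss1 / (n - 3)), 0.0)


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model, ML, profiled likelihood
# ---------------------------------------------------------------------------

def _group_slices(groups: np.ndarray):
    """Sort observations by group; return order and per-group index bounds."""
    order = np.argsort(groups, kind="stable")
    g = groups[order]
    bounds = np.flatnonzero(np.r_[True, g[1:] != g[:-1], True])
    return order, bounds


def _profile_loglik(lam: float, Xs, ys):
    """Profile log-likelihood of the random-intercept model at variance ratio
    ``lam = sigma_u^2 / sigma_e^2`` (beta and sigma_e^2 profiled out).

    Uses Sherman-Morrison: V_i^{-1} = I - lam/(1 + lam*n_i) * 1 1'.
    Returns (loglik, beta, sigma_e^2, sigma_u^2).
    """
    p = Xs[0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    n_tot = 0
    logdet = 0.0
    cs = []
    for X, y in zip(Xs, ys):
        ni = y.size
        c = lam / (1.0 + lam * ni)
        cs.append(c)
        x1 = X.sum(axis=0)
        y1 = y.sum()
        xtvx += X.T @ X - c * np.outer(x1, x1)
        xtvy += X.T @ y - c * x1 * y1
        logdet += np.log1p(lam * ni)
        n_tot += ni
    beta = np.linalg.solve(xtvx, xtvy)
    rss_v = 0.0
    for X, y, c in zip(Xs, ys, cs):
        r = y - X @ beta
        rss_v += r @ r - c * r.sum() ** 2
    sigma_e2 = max(rss_v / n_tot, 1e-12)
    ll = -0.5 * n_tot * (np.log(2.0 * np.pi * sigma_e2) + 1.0) - 0.5 * logdet
    return float(ll), beta, float(sigma_e2), float(lam * sigma_e2)


def fit_random_intercept_ml(X, y, groups):
    """ML fit of ``y = X beta + u_group + e`` with a scalar random intercept.

    The likelihood is profiled down to the variance ratio
    ``lam = sigma_u^2/sigma_e^2`` and maximised over ``log lam`` by bounded
    scalar optimisation; the boundary ``lam = 0`` (plain OLS) is always
    evaluated and kept when it wins, so a variance component estimated at
    zero is a valid result, not an error.

    Returns ``(beta, sigma_u2, sigma_e2, loglik, converged)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    order, bounds = _group_slices(groups)
    Xo, yo = X[order], y[order]
    Xs = [Xo[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]
    ys = [yo[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]

    def neg(u):
        return -_profile_loglik(np.exp(u), Xs, ys)[0]

    converged = True
    try:
        res = optimize.minimize_scalar(neg, bounds=(-14.0, 14.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam_hat = float(np.exp(res.x))
        ll_in = -float(res.fun)
        converged = bool(res.success)
    except Exception:  # pragma: no cover - defensive
        lam_hat, ll_in, converged = 0.0, -np.inf, False
    ll0 = _profile_loglik(0.0, Xs, ys)[0]
    if ll0 >= ll_in:
        lam_hat = 0.0
    ll, beta, s_e2, s_u2 = _profile_loglik(lam_hat, Xs, ys)
    return beta, s_u2, s_e2, float(ll), converged


def fit_cosinor_mixed(times_h, values, subjects) -> CosinorFit:
    """Population cosinor: fixed [1, cos, sin] plus a random mesor per subject.

    Estimated by maximum likelihood. ``p_rhythm`` is the likelihood-ratio test
    of the full model against the null with b = c = 0 (same random structure),
    referred to chi-square with 2 df. BIC uses the ML log-likelihood with
    n = number of observations and k = 5 (three fixed effects, two variances).

    A failed fit is returned flagged ``converged=False`` with ``p_rhythm`` NaN
    rather than raising, so pipelines can propagate it as non-rhythmic.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y, subjects = t[keep], y[keep], subjects[keep]
    n = y.size
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("mixed cosinor needs >= 2 subjects")
    if n < 4 or np.unique(np.mod(t, PERIOD_H)).size < 3:
        raise SingularDesignError("need >= 3 distinct sampling times within the period")
    X_full = cosinor_design(t)
    X_null = X_full[:, :1]
    try:
        beta, s_u2, s_e2, ll_full, conv_full = fit_random_intercept_ml(X_full, y, subjects)
        _, _, _, ll_null, conv_null = fit_random_intercept_ml(X_null, y, subjects)
    except np.linalg.LinAlgError:
        warnings.warn("mixed cosinor fit failed (singular system)", RuntimeWarning)
        return CosinorFit(*(float("nan"),) * 5, float("nan"), float("nan"), n,
                          float("nan"), float("nan"), converged=False, model="mixed")
    converged = conv_full and conv_null
    lrt = max(2.0 * (ll_full - ll_null), 0.0)
    p = float(stats.chi2.sf(lrt, 2)) if converged else float("nan")
    k = 5
    bic = -2.0 * ll_full + k * np.log(n)
    amp, phi = phase_amplitude(beta[1], beta[2])
    if not converged:
        warnings.warn("mixed cosinor did not converge; p_rhythm undefined", RuntimeWarning)
    return CosinorFit(
        mesor=float(beta[0]),
        beta_cos=float(beta[1]),
        beta_sin=float(beta[2]),
        amplitude=amp,
        phase_h=phi,
        loglik=ll_full,
        bic=float(bic),
        n_obs=n,
        p_rhythm=p,
        residual_sd=float(np.sqrt(s_e2)),
        random_mesor_sd=float(np.sqrt(s_u2)),
        converged=converged,
        model="mixed",
    )


def lrt_condition_effect(values, conditions, subjects):
    """ML mixed-model test for a condition effect on overall level.

    Fits ``y ~ 1 + condition + (1 | subject)`` against ``y ~ 1 + (1 | subject)``
    and returns ``(effect, p)`` where ``effect`` is the fitted coefficient of
    the second condition level (log2 units) and ``p`` the chi-square(1) LRT.
    """
    y = np.asarray(values, dtype=float)
    conditions = np.asarray(conditions)
    subjects = np.asarray(subjects)
    keep = np.isfinite(y)
    y, conditions, subjects = y[keep], conditions[keep], subjects[keep]
    levels = np.unique(conditions)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 condition levels, got {levels.tolist()}")
    ind = (conditions == levels[1]).astype(float)
    X_full = np.column_stack([np.ones_like(y), ind])
    beta, _, _, ll_full, _ = fit_random_intercept_ml(X_full, y, subjects)
    _, _, _, ll_null, _ = fit_random_intercept_ml(X_full[:, :1], y, subjects)
    lrt = max(2.0 * (ll_full - ll_null), 0.0)
    return float(beta[1]), float(stats.chi2.sf(lrt, 1))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
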