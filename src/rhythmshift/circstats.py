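"""Circular statistics on the 24-hour clock.

All angles are expressed in hours on [0, 24); internally they are mapped to
radians via ``theta = 2*pi*h/24``. Phase *differences* live on [-12, +12),
with the convention that a negative difference is a phase delay (the shifted
rhythm peaks later) and a positive difference a phase advance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

PERIOD_H = 24.0
_H2R = 2.0 * np.pi / PERIOD_H


class InsufficientDataError(ValueError):
    """Raised when a test is asked for fewer observations than it supports."""


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input (e.g. zero
    circular variance in a correlation)."""


@dataclass(frozen=True)
class PhaseShiftRecord:
    """Signed circular phase difference between two conditions.

    ``delta_phi_h`` is wrapped into [-12, +12); negative = delay (the shifted
    condition peaks later), positive = advance. A tie at exactly 12 h maps to
    -12 (delay), the direction imposed by a delayed schedule.
    """

    metabolite_id: str
    subject_id: str
    delta_phi_h: float
    direction: str  # "delay" | "advance" | "none"


def wrap_hours(h):
    """Reduce hours onto [0, 24)."""
    out = np.mod(h, PERIOD_H)
    # guard the float boundary: mod of a tiny negative can round to 24.0
    return np.where(out >= PERIOD_H, 0.0, out) if np.ndim(out) else \
        (0.0 if out >= PERIOD_H else out)


def wrap_difference(dh):
    """Wrap an hour difference onto [-12, +12)."""
    return np.mod(np.asarray(dh, dtype=float) + 12.0, PERIOD_H) - 12.0


def circ_mean_resultant(phases_h: Sequence[float]):
    """Circular mean, mean resultant length, circular SD and variance.

    Parameters
    ----------
    phases_h : sequence of float
        Angles in hours on the 24-h circle. At least one value.

    Returns
    -------
    (mean_h, r_bar, circ_sd_h, circ_var)
        ``mean_h`` in [0, 24) (NaN when the resultant vanishes), ``r_bar`` in
        [0, 1], ``circ_sd_h = sqrt(-2 ln r_bar)`` converted to hours (inf at
        r_bar = 0) and ``circ_var = 1 - r_bar``.
    """
    p = np.asarray(phases_h, dtype=float)
    if p.size == 0:
        raise InsufficientDataError("need at least one phase")
    z = np.exp(1j * p * _H2R)
    res = z.mean()
    r_bar = float(np.abs(res))
    if r_bar < 1e-12:
        return float("nan"), 0.0, float("inf"), 1.0
    mean_h = float(wrap_hours(np.angle(res) / _H2R))
    circ_sd_h = float(np.sqrt(-2.0 * np.log(min(r_bar, 1.0))) / _H2R)
    return mean_h, r_bar, circ_sd_h, 1.0 - r_bar


def rayleigh_test(phases_h: Sequence[float]):
    """Rayleigh test of circular uniformity against unimodal clustering.

    Returns ``(r_bar, p)``. The p-value uses the classical approximation with
    the finite-n correction terms, so small samples are handled sensibly.
    """
    p = np.asarray(phases_h, dtype=float)
    n = p.size
    if n < 3:
        raise InsufficientDataError("Rayleigh test needs n >= 3")
    _, r_bar, _, _ = circ_mean_resultant(p)
    z = n * r_bar**2
    pval = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return r_bar, float(np.clip(pval, 0.0, 1.0))


def rao_spacing_statistic(phases_h) -> float:
    """Rao spacing statistic U (hours): half the total deviation of sorted
    circular gaps from the uniform spacing 24/n."""
    p = np.sort(wrap_hours(np.asarray(phases_h, dtype=float)))
    n = p.size
    gaps = np.diff(p, append=p[0] + PERIOD_H)
    return float(0.5 * np.sum(np.abs(gaps - PERIOD_H / n)))


def _rao_null(n: int, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    draws = np.sort(rng.uniform(0.0, PERIOD_H, size=(n_mc, n)), axis=1)
    gaps = np.diff(draws, axis=1)
    wrap_gap = PERIOD_H - draws[:, -1] + draws[:, 0]
    total = np.abs(gaps - PERIOD_H / n).sum(axis=1) + np.abs(wrap_gap - PERIOD_H / n)
    return 0.5 * total


def rao_spacing_test(phases_h: Sequence[float], n_mc: int = 10_000, seed: int = 0):
    """Rao spacing test of uniformity, p-value by seeded Monte Carlo.

    Sensitive to multimodal departures from uniformity that the Rayleigh test
    misses. ``p = (1 + #{U_null >= U}) / (1 + n_mc)``.
    """
    p = np.asarray(phases_h, dtype=float)
    if p.size < 4:
        raise InsufficientDataError("Rao spacing test needs n >= 4")
    u = rao_spacing_statistic(p)
    null = _rao_null(p.size, n_mc, np.random.default_rng(seed))
    pval = (1.0 + np.count_nonzero(null >= u - 1e-12)) / (1.0 + n_mc)
    return u, float(pval)


def circ_circ_correlation(x_h: Sequence[float], y_h: Sequence[float]):
    """Jammalamadaka-SenGupta circular-circular correlation with asymptotic p.

    r = sum sin(x - mx) sin(y - my) / sqrt(sum sin^2(x - mx) sum sin^2(y - my))

    where mx, my are the circular means. Invariant to rotating either variable
    by a constant. Raises :class:`UndefinedStatisticError` when either
    variable has no angular dispersion.
    """
    x = np.asarray(x_h, dtype=float) * _H2R
    y = np.asarray(y_h, dtype=float) * _H2R
    if x.size != y.size or x.size < 5:
        raise InsufficientDataError("need paired samples with n >= 5")
    mx = np.angle(np.exp(1j * x).mean())
    my = np.angle(np.exp(1j * y).mean())
    sx = np.sin(x - mx)
    sy = np.sin(y - my)
    denom = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if denom < 1e-12:
        raise UndefinedStatisticError("zero circular variance in one variable")
    r = float(np.sum(sx * sy) / denom)
    n = x.size
    l20 = np.mean(sx**2)
    l02 = np.mean(sy**2)
    l22 = np.mean(sx**2 * sy**2)
    if l22 < 1e-15:
        raise UndefinedStatisticError("degenerate fourth moment")
    z = np.sqrt(n * l20 * l02 / l22) * r
    pval = 2.0 * stats.norm.sf(abs(z))
    return r, float(pval)


def phase_difference(
    phi_base_h: float,
    phi_shifted_h: float,
    metabolite_id: str = "",
    subject_id: str = "",
) -> PhaseShiftRecord:
    """Signed phase shift between conditions as ``phi_base - phi_shifted``
    wrapped to [-12, +12).

    A rhythm that peaks *later* in the shifted condition yields a negative
    value (delay); earlier yields positive (advance).
    """
    if phi_base_h is None or phi_shifted_h is None or not (
        np.isfinite(phi_base_h) and np.isfinite(phi_shifted_h)
    ):
        return PhaseShiftRecord(metabolite_id, subject_id, float("nan"), "none")
    d = float(wrap_difference(phi_base_h - phi_shifted_h))
    if d < 0:
        direction = "delay"
    elif d > 0:
        direction = "advance"
    else:
        direction = "none"
    return PhaseShiftRecord(metabolite_id, subject_id, d, direction)


def hypergeometric_overlap(n_a: int, n_b: int, n_overlap: int, n_universe: int) -> float:
    """Upper-tail probability of observing >= ``n_overlap`` shared elements
    between a set of size ``n_a`` and an independent draw of size ``n_b``
    from a universe of ``n_universe`` elements."""
    if not (0 <= n_overlap <= min(n_a, n_b) <= n_universe) or max(n_a, n_b) > n_universe:
        raise ValueError(
            f"inconsistent counts: n_a={n_a}, n_b={n_b}, overlap={n_overlap}, "
            f"universe={n_universe}"
        )
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))
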