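import math
from itertools import combinations

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmshift import circstats
from rhythmshift.circstats import (
    InsufficientDataError,
    UndefinedStatisticError,
    circ_circ_correlation,
    circ_mean_resultant,
    hypergeometric_overlap,
    phase_difference,
    rao_spacing_statistic,
    rao_spacing_test,
    rayleigh_test,
)

H2R = 2 * np.pi / 24


class TestCircMean:
    def test_symmetric_pair_around_midnight(self):
        mean, r_bar, _, _ = circ_mean_resultant([23.0, 1.0])
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert r_bar == pytest.approx(np.cos(np.pi / 12))

    def test_perfect_uniformity(self):
        mean, r_bar, sd, var = circ_mean_resultant([0.0, 6.0, 12.0, 18.0])
        assert r_bar == pytest.approx(0.0, abs=1e-12)
        assert var == pytest.approx(1.0)
        assert np.isnan(mean)

    def test_von_mises_concentration(self):
        rng = np.random.default_rng(8)
        draws = np.mod(rng.vonmises(8 * H2R, 2.0, 1000) / H2R, 24.0)
        mean, r_bar, _, _ = circ_mean_resultant(draws)
        assert abs((mean - 8.0 + 12) % 24 - 12) < 0.3
        assert 0.5 < r_bar < 0.85  # A1(2) ~ 0.70

    def test_matches_pingouin(self):
        rng = np.random.default_rng(9)
        h = rng.uniform(0, 24, 40)
        mean, r_bar, _, _ = circ_mean_resultant(h)
        assert r_bar == pytest.approx(float(pg.circ_r(h * H2R)))
        assert mean * H2R == pytest.approx(float(pg.circ_mean(h * H2R)) % (2 * np.pi),
                                           abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 24, exclude_max=True), min_size=2, max_size=30),
           st.floats(-24, 24))
    def test_rotation_equivariance(self, phases, rot):
        m1, r1, _, v1 = circ_mean_resultant(phases)
        m2, r2, _, v2 = circ_mean_resultant([p + rot for p in phases])
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert v1 == pytest.approx(v2, abs=1e-9)
        if np.isfinite(m1) and r1 > 1e-6:
            assert abs((m2 - m1 - rot + 12) % 24 - 12) < 1e-6


class TestRayleigh:
    def test_identical_phases_highly_significant(self):
        _, p = rayleigh_test([5.0] * 10)
        assert p < 1e-4

    def test_equally_spaced_is_uniform(self):
        r_bar, p = rayleigh_test([0.0, 6.0, 12.0, 18.0])
        assert r_bar == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            rayleigh_test([1.0, 2.0])

    def test_matches_pingouin(self):
        rng = np.random.default_rng(10)
        h = rng.uniform(0, 24, 24)
        _, p = rayleigh_test(h)
        _, p_ref = pg.circ_rayleigh(h * H2R)
        # approximations differ in higher-order small-n correction terms
        assert p == pytest.approx(float(p_ref), abs=1e-3)

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha=0.05 on uniform draws, n=24."""
        rng = np.random.default_rng(11)
        draws = rng.uniform(0, 24, (10_000, 24))
        z = np.abs(np.exp(1j * draws * H2R).mean(axis=1)) ** 2 * 24
        n = 24
        p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n)
                          - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2))
        rate = np.mean(p < 0.05)
        assert 0.04 <= rate <= 0.06


class TestRaoSpacing:
    def test_equally_spaced_statistic_zero(self):
        phases = np.arange(0, 24, 3.0)
        assert rao_spacing_statistic(phases) == pytest.approx(0.0, abs=1e-9)
        _, p = rao_spacing_test(phases, n_mc=2000, seed=0)
        assert p > 0.99

    def test_identical_phases_significant(self):
        _, p = rao_spacing_test([4.0] * 8, n_mc=2000, seed=0)
        assert p < 0.01

    def test_reproducible_under_seed(self):
        phases = [1.0, 2.0, 11.0, 14.0, 20.0]
        assert rao_spacing_test(phases, seed=123) == rao_spacing_test(phases, seed=123)

    def test_type_one_error_self_consistent(self):
        """Empirical rejection of the Monte-Carlo test on uniform data."""
        rng = np.random.default_rng(12)
        n = 51
        null = circstats._rao_null(n, 10_000, np.random.default_rng(999))
        crit = np.quantile(null, 0.95)
        stats_ = circstats._rao_null(n, 10_000, rng)  # fresh uniform draws
        rate = np.mean(stats_ > crit)
        assert 0.04 <= rate <= 0.06


class TestCircCircCorrelation:
    def test_identity_is_one(self):
        x = np.array([0.5, 3, 6, 8, 11, 14, 17, 19, 21, 23])
        r, _ = circ_circ_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_rotation_invariance(self):
        x = np.array([0.5, 3, 6, 8, 11, 14, 17, 19, 21, 23])
        r, _ = circ_circ_correlation(x, np.mod(x + 6.0, 24.0))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            circ_circ_correlation([1.0] * 6, [0, 4, 8, 12, 16, 20])

    def test_matches_pingouin(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 24, 20)
        y = np.mod(x + rng.normal(0, 2, 20), 24)
        r, _ = circ_circ_correlation(x, y)
        r_ref = pg.circ_corrcc(x * H2R, y * H2R)[0]
        assert r == pytest.approx(float(r_ref), abs=1e-9)

    def test_calibration_against_permutation_oracle(self):
        """Asymptotic p rejects ~5% of independent uniform pairs (n=12)."""
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.uniform(0, 24, 12)
            y = rng.uniform(0, 24, 12)
            _, p = circ_circ_correlation(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestPhaseDifference:
    @pytest.mark.parametrize("base,shifted,expected,direction", [
        (2.0, 12.0, -10.0, "delay"),
        (5.0, 5.0, 0.0, "none"),
        (1.0, 22.0, 3.0, "advance"),
        (0.0, 12.0, -12.0, "delay"),  # tie maps to delay
    ])
    def test_known_cases(self, base, shifted, expected, direction):
        rec = phase_difference(base, shifted)
        assert rec.delta_phi_h == pytest.approx(expected)
        assert rec.direction == direction

    def test_wrap_candidate_enumeration(self):
        """The returned shift is the representative with |delta| <= 12 among
        all 24h-equivalent differences."""
        rng = np.random.default_rng(15)
        for _ in range(200):
            a, b = rng.uniform(0, 24, 2)
            rec = phase_difference(a, b)
            candidates = [(a - b) + 24 * k for k in (-2, -1, 0, 1, 2)]
            best = min(candidates, key=lambda d: (abs(d), d))
            assert rec.delta_phi_h == pytest.approx(best)
            assert -12.0 <= rec.delta_phi_h < 12.0

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 24, exclude_max=True), st.floats(0, 24, exclude_max=True))
    def test_antisymmetry(self, a, b):
        d1 = phase_difference(a, b).delta_phi_h
        d2 = phase_difference(b, a).delta_phi_h
        if abs(d1) != pytest.approx(12.0, abs=1e-9):
            assert d1 == pytest.approx(-d2, abs=1e-9)

    def test_undefined_phase_flagged(self):
        rec = phase_difference(float("nan"), 3.0)
        assert rec.direction == "none"
        assert math.isnan(rec.delta_phi_h)


class TestHypergeometricOverlap:
    def test_study_sized_overlap_is_extreme(self):
        # 51 and 53 rhythmic sets sharing 32 of 130 metabolites
        assert hypergeometric_overlap(51, 53, 32, 130) < 1e-4

    def test_complete_containment_point_mass(self):
        assert hypergeometric_overlap(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        """Exact enumeration over all C(20,5) draws."""
        n_a, n_b, n_u = 5, 5, 20
        marked = set(range(n_a))
        total = 0
        at_least = {k: 0 for k in range(n_b + 1)}
        for draw in combinations(range(n_u), n_b):
            total += 1
            k = len(marked.intersection(draw))
            for kk in range(k + 1):
                at_least[kk] += 1
        for k in range(n_b + 1):
            expected = at_least[k] / total
            assert hypergeometric_overlap(n_a, n_b, k, n_u) == pytest.approx(expected)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(5, 5, 6, 20)
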