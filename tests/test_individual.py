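import numpy as np
import pandas as pd
import pytest

from rhythmshift import individual
from rhythmshift.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="module")
def indiv_results(small_dataset):
    samples, matrix, _ = small_dataset
    return individual.run_individual_rhythmicity(samples, matrix, n_perm=300, seed=3)


class TestPermutationCorrection:
    def test_monotone_in_raw_p(self, indiv_results):
        for _, grp in indiv_results.groupby(["subject_id", "condition"]):
            g = grp.sort_values("p_raw")
            assert g["p_corrected"].is_monotonic_increasing

    def test_reproducible_under_seed(self, small_dataset):
        samples, matrix, _ = small_dataset
        a = individual.run_individual_rhythmicity(samples, matrix, n_perm=100, seed=9)
        b = individual.run_individual_rhythmicity(samples, matrix, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_correction(self, small_dataset):
        samples, matrix, _ = small_dataset
        a = individual.run_individual_rhythmicity(samples, matrix, n_perm=100, seed=1)
        b = individual.run_individual_rhythmicity(samples, matrix, n_perm=100, seed=2)
        assert not np.allclose(a["p_corrected"], b["p_corrected"])

    def test_near_noiseless_rhythm_maximally_significant(self):
        cfg = SimulationConfig(
            n_subjects=2, n_behavioural=1, n_circadian=0, n_arrhythmic=10,
            residual_sd=0.01, amplitude_range=(1.0, 1.0),
            missing_rate=0.0, lod_quantile=0.0, seed=17,
        )
        samples, matrix, truth = simulate_dataset(cfg)
        n_perm = 200
        res = individual.run_individual_rhythmicity(samples, matrix,
                                                    n_perm=n_perm, seed=0)
        met = truth.metabolites.loc[truth.metabolites["regime"] == "behavioural",
                                    "metabolite_id"].iloc[0]
        rows = res[res["metabolite_id"] == met]
        # observed F beats every pooled permutation F
        pooled_size = 11 * n_perm
        assert (rows["p_corrected"] <= 1.0 / (1 + n_perm)).all() or \
            (rows["p_corrected"] == pytest.approx(1.0 / (1 + pooled_size))).all()

    def test_null_false_positive_rate_bounded(self):
        """Pure-noise subject: few metabolites called rhythmic after
        permutation correction."""
        cfg = SimulationConfig(
            n_subjects=1, n_behavioural=0, n_circadian=0, n_arrhythmic=130,
            residual_sd=0.3, missing_rate=0.0, lod_quantile=0.0, seed=23,
        )
        samples, matrix, _ = simulate_dataset(cfg)
        base = samples[samples["condition"] == "baseline"]
        res = individual.run_individual_rhythmicity(base, matrix, n_perm=500, seed=0)
        n_sig = int((res["p_corrected"] < 0.05).sum())
        assert n_sig <= 13  # ~5% of 130 expected, generous binomial bound

    def test_small_nperm_warns(self, small_dataset):
        samples, matrix, _ = small_dataset
        sub = samples[samples["subject_id"] == samples["subject_id"].iloc[0]]
        with pytest.warns(RuntimeWarning, match="n_perm"):
            individual.run_individual_rhythmicity(sub, matrix, n_perm=50, seed=0)


class TestPairwiseOverlap:
    def _results(self, sets, condition="baseline"):
        rows = []
        for subj, mets in sets.items():
            for m in ["m%d" % k for k in range(10)]:
                rows.append({"subject_id": subj, "condition": condition,
                             "metabolite_id": m,
                             "p_corrected": 0.01 if m in mets else 0.9,
                             "p_raw": 0.01 if m in mets else 0.9,
                             "phase_h": 1.0})
        return pd.DataFrame(rows)

    def test_identical_sets_full_overlap(self):
        res = self._results({"A": {"m1", "m2"}, "B": {"m1", "m2"}})
        mat = individual.pairwise_overlap(res, "baseline")
        assert mat.loc["A", "B"] == 100.0

    def test_disjoint_sets_zero(self):
        res = self._results({"A": {"m1"}, "B": {"m2"}})
        mat = individual.pairwise_overlap(res, "baseline")
        assert mat.loc["A", "B"] == 0.0

    def test_jaccard_value_and_symmetry(self):
        res = self._results({"A": {"m1", "m2", "m3"}, "B": {"m2", "m3", "m4"}})
        mat = individual.pairwise_overlap(res, "baseline")
        assert mat.loc["A", "B"] == pytest.approx(100 * 2 / 4)
        assert mat.loc["B", "A"] == mat.loc["A", "B"]
        assert mat.loc["A", "A"] == 100.0

    def test_min_denominator_option(self):
        res = self._results({"A": {"m1", "m2", "m3"}, "B": {"m2"}})
        mat = individual.pairwise_overlap(res, "baseline", method="min")
        assert mat.loc["A", "B"] == pytest.approx(100.0)

    def test_empty_sets_flagged_nan(self):
        res = self._results({"A": set(), "B": set()})
        mat = individual.pairwise_overlap(res, "baseline")
        assert np.isnan(mat.loc["A", "B"])
        assert np.isnan(mat.loc["A", "A"])


class TestPhaseDispersion:
    def _results(self, phases_by_subject, met="m1"):
        rows = []
        for subj, ph in phases_by_subject.items():
            rows.append({"subject_id": subj, "condition": "baseline",
                         "metabolite_id": met, "p_raw": 0.01,
                         "p_corrected": 0.01, "phase_h": ph})
        return pd.DataFrame(rows)

    def test_shared_phase_zero_variance(self):
        res = self._results({"A": 5.0, "B": 5.0, "C": 5.0})
        out = individual.per_metabolite_phase_dispersion(res)
        assert out["circ_var"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_variance_one(self):
        res = self._results({s: p for s, p in zip("ABCD", [0.0, 6.0, 12.0, 18.0])})
        out = individual.per_metabolite_phase_dispersion(res)
        assert out["circ_var"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_requires_min_subjects(self):
        res = self._results({"A": 5.0, "B": 6.0})
        out = individual.per_metabolite_phase_dispersion(res)
        assert out.empty

    def test_noise_increases_dispersion(self):
        """A low-noise metabolite has tighter cross-subject phase agreement
        than a high-noise one."""
        def variance_at(sigma, seed):
            cfg = SimulationConfig(
                n_subjects=8, n_behavioural=1, n_circadian=0, n_arrhythmic=0,
                residual_sd=sigma, amplitude_range=(0.5, 0.5),
                missing_rate=0.0, lod_quantile=0.0, seed=seed,
            )
            samples, matrix, _ = simulate_dataset(cfg)
            base = samples[samples["condition"] == "baseline"]
            res = individual.run_individual_rhythmicity(base, matrix,
                                                        n_perm=100, seed=0)
            out = individual.per_metabolite_phase_dispersion(res, raw_p=1.0)
            return out["circ_var"].iloc[0]
        assert variance_at(0.05, 51) < variance_at(1.5, 51)


class TestPerSubjectShifts:
    def test_fully_adapted_subject_shift_recovered(self):
        cfg = SimulationConfig(
            n_subjects=3, n_behavioural=12, n_circadian=0, n_arrhythmic=0,
            residual_sd=0.05, amplitude_range=(0.5, 1.0),
            adaptation_fraction=(1.0, 1.0, 1.0),
            missing_rate=0.0, lod_quantile=0.0, seed=61,
        )
        samples, matrix, _ = simulate_dataset(cfg)
        res = individual.run_individual_rhythmicity(samples, matrix,
                                                    n_perm=100, seed=0)
        out = individual.per_subject_phase_shifts(res)
        assert len(out["per_subject"]) == 3
        for subj, d in out["per_subject"].items():
            assert d["rayleigh_p"] < 0.01
            assert d["mean_shift_h"] == pytest.approx(-10.0, abs=0.5)

    def test_heterogeneous_adaptation_recovered(self):
        cfg = SimulationConfig(
            n_subjects=3, n_behavioural=12, n_circadian=0, n_arrhythmic=0,
            residual_sd=0.05, amplitude_range=(0.5, 1.0),
            adaptation_fraction=(0.0, 0.5, 1.0),
            missing_rate=0.0, lod_quantile=0.0, seed=62,
        )
        samples, matrix, truth = simulate_dataset(cfg)
        res = individual.run_individual_rhythmicity(samples, matrix,
                                                    n_perm=100, seed=0)
        out = individual.per_subject_phase_shifts(res)
        for _, row in truth.subjects.iterrows():
            d = out["per_subject"][row["subject_id"]]
            assert d["_mean_shift_any"] == pytest.approx(row["true_shift_h"], abs=0.5)

    def test_subject_with_too_few_common_metabolites_skipped(self):
        rows = [{"subject_id": "A", "condition": c, "metabolite_id": "m1",
                 "p_raw": 0.01, "p_corrected": 0.01, "phase_h": 2.0}
                for c in ("baseline", "nightshift")]
        with pytest.warns(RuntimeWarning, match="skipped"):
            out = individual.per_subject_phase_shifts(pd.DataFrame(rows))
        assert out["per_subject"] == {}
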