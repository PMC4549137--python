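"""Ground-truth construction and the statistical behavior of the generator."""
import numpy as np
import pytest
from scipy import stats as sp_stats

from scaconn import (BehaviorCoupling, SubjectRecord, apply_deltas,
                     block_correlation, generate_cohort, make_group_targets,
                     nearest_correlation, simulate_behavior, simulate_subject,
                     small_test_spec, subject_rng)
from scaconn.preprocess import framewise_displacement
from scaconn.simulate import SimulationSpec, default_study_spec


class TestGroupTargets:
    def test_no_perturbation_gives_identical_targets(self):
        spec = small_test_spec(perturbed_edges=[])
        control, patient = make_group_targets(spec)
        np.testing.assert_array_equal(control, patient)

    def test_delta_arithmetic_before_repair(self):
        base = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = apply_deltas(base, [(0, 1, -0.3)])
        assert out[0, 1] == pytest.approx(0.2)
        assert out[1, 0] == pytest.approx(0.2)
        assert base[0, 1] == 0.5  # input untouched

    def test_delta_out_of_range_rejected(self):
        base = np.array([[1.0, 0.8], [0.8, 1.0]])
        with pytest.raises(ValueError, match=">= 1"):
            apply_deltas(base, [(0, 1, 0.3)])

    def test_targets_are_valid_correlation_matrices(self):
        """Independent eigensolver confirms PSD after perturbation repair."""
        spec = small_test_spec()
        for target in make_group_targets(spec):
            assert np.allclose(target, target.T)
            np.testing.assert_allclose(np.diag(target), 1.0)
            assert np.linalg.eigvalsh(target).min() >= -1e-10
            assert np.abs(target).max() <= 1.0

    def test_patient_differs_only_at_perturbed_edges(self):
        spec = small_test_spec()
        control = block_correlation(spec.resolved_block_sizes(),
                                    spec.within_block_r, spec.between_block_r)
        perturbed = apply_deltas(control, spec.perturbed_edges)
        diff = np.abs(perturbed - control) > 1e-12
        expected = np.zeros_like(diff)
        for i, j, _ in spec.perturbed_edges:
            expected[i, j] = expected[j, i] = True
        np.testing.assert_array_equal(diff, expected)

    def test_nearest_correlation_repairs_indefinite_input(self):
        bad = np.array([[1.0, 0.9, -0.9],
                        [0.9, 1.0, 0.9],
                        [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        fixed = nearest_correlation(bad)
        np.testing.assert_allclose(np.diag(fixed), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10

    def test_study_spec_mirrors_emulated_design(self):
        spec, atlas = default_study_spec()
        assert (spec.n_per_group, spec.n_regions) == (26, 116)
        assert (spec.n_volumes, spec.tr) == (120, 2.0)
        assert len(spec.perturbed_edges) == 19
        assert all(abs(d) == pytest.approx(0.3)
                   for _, _, d in spec.perturbed_edges)
        control, patient = make_group_targets(spec)
        assert np.linalg.eigvalsh(patient).min() >= -1e-10


class TestSimulateSubject:
    def test_long_run_correlation_matches_target(self):
        spec = small_test_spec(n_volumes=10000, noise_sd=0.0,
                               drift_slope_sd=0.0,
                               global_confound_amplitude=0.0,
                               motion_spike_probability=0.0)
        _, patient = make_group_targets(spec)
        ts, _ = simulate_subject(patient, spec, subject_rng(123, 0))
        observed = np.corrcoef(ts.data, rowvar=False)
        for i, j, _ in spec.perturbed_edges:
            assert observed[i, j] == pytest.approx(patient[i, j], abs=0.03)

    def test_no_spikes_means_zero_motion(self):
        spec = small_test_spec(motion_spike_probability=0.0)
        control, _ = make_group_targets(spec)
        _, motion = simulate_subject(control, spec, subject_rng(1, 0))
        np.testing.assert_array_equal(motion.params, 0.0)
        np.testing.assert_array_equal(framewise_displacement(motion), 0.0)

    def test_fixed_seed_is_bit_identical(self):
        spec = small_test_spec()
        control, _ = make_group_targets(spec)
        ts1, m1 = simulate_subject(control, spec, subject_rng(9, 4))
        ts2, m2 = simulate_subject(control, spec, subject_rng(9, 4))
        np.testing.assert_array_equal(ts1.data, ts2.data)
        np.testing.assert_array_equal(m1.params, m2.params)

    def test_non_psd_target_rejected(self):
        spec = small_test_spec()
        bad = np.eye(spec.n_regions)
        bad[0, 1] = bad[1, 0] = 2.0
        with pytest.raises(ValueError, match="PSD"):
            simulate_subject(bad, spec, subject_rng(0, 0))

    def test_cohort_generation_is_order_independent(self):
        """Per-subject seeding is counter-based, so each subject's data only
        depend on (master seed, subject index)."""
        spec = small_test_spec(n_per_group=2)
        a = generate_cohort(spec, master_seed=7)
        b = generate_cohort(spec, master_seed=7)
        for sid in a.series:
            np.testing.assert_array_equal(a.series[sid].data,
                                          b.series[sid].data)


class TestSimulateBehavior:
    def _patients(self, n):
        return [SubjectRecord(f"P{i:02d}", "patient", 30 + i, "F",
                              years_of_symptoms=5, cag_expansion=45, sara=10)
                for i in range(n)]

    def test_noiseless_negative_slope_gives_perfect_anticorrelation(self):
        records = self._patients(10)
        edge_values = {r.id: 0.1 + 0.02 * i
                       for i, r in enumerate(records)}
        coupling = BehaviorCoupling((0, 1), "sara", slope=-50.0,
                                    intercept=25.0, noise_sd=0.0)
        out = simulate_behavior(records, edge_values, coupling,
                                np.random.default_rng(0))
        saras = [r.sara for r in out]
        r = np.corrcoef(list(edge_values.values()), saras)[0, 1]
        assert r == pytest.approx(-1.0)

    def test_zero_slope_yields_null_correlations(self):
        """Monte-Carlo null: at n=26 the sample |r| stays below 0.5 in at
        least 95% of replicates when the covariate ignores the edge."""
        rng = np.random.default_rng(2024)
        n, hits = 26, 0
        reps = 1000
        edge = rng.normal(0.2, 0.1, size=n)
        for _ in range(reps):
            cov = 15 + 3 * rng.standard_normal(n)
            if abs(np.corrcoef(edge, cov)[0, 1]) < 0.5:
                hits += 1
        assert hits / reps >= 0.95

    def test_missing_edge_value_is_an_error(self):
        records = self._patients(3)
        coupling = BehaviorCoupling((0, 1), "sara", slope=-50.0,
                                    intercept=25.0, noise_sd=0.0)
        with pytest.raises(ValueError, match="P02"):
            simulate_behavior(records, {"P00": 0.1, "P01": 0.2}, coupling,
                              np.random.default_rng(0))

    def test_sara_clipped_to_legal_range(self):
        records = self._patients(4)
        edge_values = {r.id: 1.0 for r in records}
        coupling = BehaviorCoupling((0, 1), "sara", slope=-500.0,
                                    intercept=0.0, noise_sd=0.0)
        out = simulate_behavior(records, edge_values, coupling,
                                np.random.default_rng(0))
        assert all(r.sara == 0.0 for r in out)

    def test_coupled_cohorts_recover_negative_sign(self):
        """At moderate noise the patient-level SARA-edge correlation comes
        out negative in every seeded replicate."""
        coupling = BehaviorCoupling((0, 5), "sara", slope=-40.0,
                                    intercept=25.0, noise_sd=3.0)
        spec = small_test_spec(behavior_couplings=[coupling])
        signs = []
        for seed in range(10):
            cohort = generate_cohort(spec, master_seed=100 + seed)
            patients = [r for r in cohort.records if r.group == "patient"]
            edge = [np.corrcoef(cohort.series[r.id].data[:, 0],
                                cohort.series[r.id].data[:, 5])[0, 1]
                    for r in patients]
            saras = [r.sara for r in patients]
            r, _ = sp_stats.pearsonr(edge, saras)
            signs.append(r < 0)
        assert np.mean(signs) >= 0.95
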