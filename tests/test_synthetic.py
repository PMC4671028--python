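import numpy as np
import pytest

from restnet.degree_dist import fit_all_models, select_model
from restnet.preprocess import framewise_displacement
from restnet.synthetic import (
    MotionTrace,
    SyntheticCohortSpec,
    generate_cohort,
    generate_degree_sequence,
    generate_motion,
    generate_reference_graph,
)


class TestSpecValidation:
    def test_bad_module_sizes(self):
        with pytest.raises(ValueError, match="module_sizes"):
            SyntheticCohortSpec(module_sizes=(40, 40))

    def test_bad_correlation_order(self):
        with pytest.raises(ValueError, match="between_module_r"):
            SyntheticCohortSpec(within_module_r=0.2, between_module_r=0.3)

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="n_frames"):
            SyntheticCohortSpec(n_frames=1)


class TestGenerateCohort:
    def test_deterministic_for_seed(self):
        spec = SyntheticCohortSpec(n_subjects=2, seed=5)
        a, b = generate_cohort(spec), generate_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.timeseries, sb.timeseries)
            assert np.array_equal(sa.motion.params, sb.motion.params)

    def test_shapes_and_labels(self, small_cohort):
        assert len(small_cohort.subjects) == 8
        assert small_cohort.subjects[0].timeseries.shape == (196, 90)
        assert len(small_cohort.roi_labels) == 90
        assert small_cohort.module_labels.tolist() == sum(
            ([m] * s for m, s in enumerate((26, 26, 18, 20))), []
        )

    def test_planted_correlation_targets_large_n_frames(self):
        # oracle bound: at n_frames=5000 the sampling error of a mean over
        # >300 pairs is well under 0.05, so the block means must land
        # within +/-0.05 of the calibrated targets
        spec = SyntheticCohortSpec(
            n_subjects=2, n_frames=5000, within_module_r=0.9, between_module_r=0.0, seed=3
        )
        cohort = generate_cohort(spec)
        ts = cohort.subjects[0].timeseries
        C = np.corrcoef(ts, rowvar=False)
        lab = cohort.module_labels
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(90, dtype=bool)
        assert 0.85 <= C[same & off].mean() <= 0.95

    def test_default_targets_hit(self):
        spec = SyntheticCohortSpec(n_subjects=3, n_frames=5000, seed=4)
        cohort = generate_cohort(spec)
        C = np.mean(
            [np.corrcoef(s.timeseries, rowvar=False) for s in cohort.subjects], axis=0
        )
        lab = cohort.module_labels
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(90, dtype=bool)
        assert C[same & off].mean() == pytest.approx(spec.within_module_r, abs=0.05)
        assert C[~same].mean() == pytest.approx(spec.between_module_r, abs=0.05)

    def test_noise_free_single_module_perfectly_correlated(self):
        spec = SyntheticCohortSpec(
            n_subjects=1, n_rois=10, n_frames=50, module_sizes=(10,),
            noise_sd=0.0, hub_fraction=0.0, seed=1,
        )
        ts = generate_cohort(spec).subjects[0].timeseries
        C = np.corrcoef(ts, rowvar=False)
        np.testing.assert_allclose(C, 1.0, atol=1e-10)

    def test_population_correlation_matches_empirical(self):
        spec = SyntheticCohortSpec(n_subjects=1, n_frames=20000, seed=8)
        cohort = generate_cohort(spec)
        emp = np.corrcoef(cohort.subjects[0].timeseries, rowvar=False)
        pop = cohort.population_correlation()
        iu = np.triu_indices(90, 1)
        assert np.corrcoef(emp[iu], pop[iu])[0, 1] > 0.99

    def test_band_limited_option(self):
        spec = SyntheticCohortSpec(
            n_subjects=1, n_rois=12, module_sizes=(12,), n_frames=200,
            band_limited=True, hub_fraction=0.0, seed=2,
        )
        ts = generate_cohort(spec).subjects[0].timeseries
        freqs = np.fft.rfftfreq(200, d=2.0)
        power = np.abs(np.fft.rfft(ts, axis=0)) ** 2
        in_band = (freqs > 0.01) & (freqs < 0.1)
        assert power[in_band].sum() / power.sum() > 0.95


class TestGenerateMotion:
    def test_no_spikes_all_zero(self):
        m = generate_motion(50, spike_prob=0.0, spike_mm=0.5, seed=0)
        assert np.all(m.params == 0.0)

    def test_all_spikes_fd_above_threshold(self):
        m = generate_motion(100, spike_prob=1.0, spike_mm=0.5, seed=0)
        fd = framewise_displacement(m)
        assert np.all(fd[1:] >= 0.3)

    def test_reproducible(self):
        a = generate_motion(80, 0.1, 0.6, seed=7)
        b = generate_motion(80, 0.1, 0.6, seed=7)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.outlier_fraction, b.outlier_fraction)

    def test_outlier_fraction_in_unit_interval(self):
        m = generate_motion(200, 0.3, 1.0, seed=1)
        assert np.all((m.outlier_fraction >= 0) & (m.outlier_fraction <= 1))

    def test_motion_trace_validation(self):
        with pytest.raises(ValueError, match="6"):
            MotionTrace(params=np.zeros((5, 4)), outlier_fraction=np.zeros(5))


class TestReferenceGraphs:
    def test_complete(self):
        g = generate_reference_graph("complete", 4)
        assert g.n_edges == 6 and np.all(g.degrees == 3)

    def test_star(self):
        g = generate_reference_graph("star", 10)
        degs = sorted(g.degrees)
        assert degs == [1] * 9 + [9]

    def test_path(self):
        g = generate_reference_graph("path", 5)
        assert sorted(g.degrees) == [1, 1, 2, 2, 2]

    def test_ring_lattice_regular(self):
        g = generate_reference_graph("ring_lattice", 20, {"k": 6})
        assert np.all(g.degrees == 6)

    def test_ws_preserves_edge_count(self):
        g = generate_reference_graph("ws_small_world", 30, {"k": 4, "p": 0.2}, seed=0)
        assert g.n_edges == 60

    def test_er_edges_param(self):
        g = generate_reference_graph("er_random", 20, {"edges": 30}, seed=1)
        assert g.n_edges == 30

    def test_ba_beats_exponential_under_fitter(self):
        g = generate_reference_graph("ba_scale_free", 90, {"density": 0.10}, seed=4)
        fits = {f.model: f for f in fit_all_models(g.degrees)}
        assert min(
            fits["power_law"].aic, fits["truncated_power_law"].aic
        ) < fits["exponential"].aic

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown reference graph"):
            generate_reference_graph("mystery", 5)

    def test_impossible_er_params(self):
        with pytest.raises(ValueError):
            generate_reference_graph("er_random", 5, {"edges": 99})


class TestDegreeSequences:
    def test_exponential_large_rate_degenerates_to_one(self):
        ks = generate_degree_sequence("exponential", {"rate": 20.0}, 500, seed=0)
        assert np.mean(ks == 1) > 0.99

    def test_truncated_alpha_recovery_at_large_n(self):
        ks = generate_degree_sequence(
            "truncated_power_law", {"alpha": 0.2, "kc": 40.0}, 10000, seed=1
        )
        best = select_model(fit_all_models(ks))
        assert best.model == "truncated_power_law"
        assert best.parameters["alpha"] == pytest.approx(0.2, abs=0.6)

    def test_reproducible(self):
        a = generate_degree_sequence("power_law", {"alpha": 2.5}, 100, seed=3)
        b = generate_degree_sequence("power_law", {"alpha": 2.5}, 100, seed=3)
        assert np.array_equal(a, b)

    def test_all_positive(self):
        for model, params in [
            ("power_law", {"alpha": 2.0}),
            ("exponential", {"rate": 0.5}),
            ("truncated_power_law", {"alpha": 0.5, "kc": 10.0}),
        ]:
            ks = generate_degree_sequence(model, params, 200, seed=5)
            assert np.all(ks >= 1)

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown degree-sequence model"):
            generate_degree_sequence("weibull", {}, 10)
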