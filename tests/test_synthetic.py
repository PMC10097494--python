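"""Ground-truth generation, noisy acquisition simulation, study designs."""

import numpy as np
import pytest

from speedcap import (
    DeadRegion,
    ParameterError,
    SyntheticStudySpec,
    epsilon_within,
    half_mask,
    make_profiles,
    simulate_dataset,
    simulate_matrix,
)
from speedcap.synthetic import simulate_blocked_matrices, simulate_frameset
from speedcap.waveforms import extract_ecap_waveform, measure_p2n1_amplitude


def tiny_spec(**kw):
    kw.setdefault("n_electrodes", 6)
    kw.setdefault("seed", 11)
    return SyntheticStudySpec(**kw)


class TestProfiles:
    def test_dead_region_imposed_exactly(self):
        spec = tiny_spec(n_electrodes=16, dead_regions=(DeadRegion(10, 3, 0.05),))
        model = make_profiles(spec)
        np.testing.assert_array_equal(model.eta[9:12], 0.05)

    def test_same_seed_identical_profiles(self):
        m1 = make_profiles(tiny_spec())
        m2 = make_profiles(tiny_spec())
        np.testing.assert_array_equal(m1.sigma, m2.sigma)
        np.testing.assert_array_equal(m1.eta, m2.eta)

    def test_constant_profiles_exact(self):
        spec = tiny_spec(sigma_profile="constant", sigma_params={"value": 2.0},
                         eta_profile="constant", eta_params={"value": 0.8})
        model = make_profiles(spec)
        assert np.all(model.sigma == 2.0)
        assert np.all(model.eta == 0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_smooth_profiles_respect_solver_caps(self, seed):
        model = make_profiles(tiny_spec(n_electrodes=22, seed=seed))
        assert np.abs(np.diff(model.sigma)).max() <= 1.0
        assert np.abs(np.diff(model.eta)).max() <= 0.5

    def test_dead_region_outside_array_rejected(self):
        with pytest.raises(ParameterError):
            tiny_spec(dead_regions=(DeadRegion(5, 4, 0.05),))


class TestNoiselessSimulation:
    def test_repeats_identical_and_epsilon_zero(self):
        spec = tiny_spec(per_sweep_noise_sd_uv=0.0,
                         designs=("speedcap_half", "speedcap_half"))
        model = make_profiles(spec)
        ds = simulate_dataset(model, spec)
        m1, m2 = ds.speedcap
        np.testing.assert_array_equal(m1.values, m2.values)
        assert epsilon_within(m1, m2).percent == 0.0

    def test_half_matrix_equals_full_matrix_triangle(self):
        """The generative model is symmetric: at zero noise the fast
        half-matrix acquisition reproduces the full acquisition exactly."""
        spec = tiny_spec(per_sweep_noise_sd_uv=0.0)
        model = make_profiles(spec)
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(1)
        n = spec.n_electrodes
        full = simulate_matrix(model, spec, np.ones((n, n), dtype=bool), 50, rng1)
        half = simulate_matrix(model, spec, half_mask(n), 50, rng2)
        tri = half.recorded_mask
        np.testing.assert_allclose(half.values[tri], full.values[tri], atol=1e-9)

    def test_measured_amplitudes_match_model_prediction(self):
        from speedcap import predict_matrix

        spec = tiny_spec(per_sweep_noise_sd_uv=0.0)
        model = make_profiles(spec)
        n = spec.n_electrodes
        M = simulate_matrix(model, spec, np.ones((n, n), dtype=bool), 50,
                            np.random.default_rng(0))
        expected = spec.amplitude_scale_uv * predict_matrix(model).values
        np.testing.assert_allclose(M.values, expected, atol=1e-9)


class TestNoiseScaling:
    def test_amplitude_sd_scales_inverse_sqrt_sweeps(self):
        """log(SD) vs log(n_sweeps) regression slope ≈ −1/2."""
        spec = tiny_spec()
        rng = np.random.default_rng(99)
        sds = []
        sweeps = [12, 48, 50]
        for nsw in sweeps:
            amps = [
                measure_p2n1_amplitude(
                    extract_ecap_waveform(simulate_frameset(3, 3, 80.0, spec, rng, nsw))
                ).amplitude_uv
                for _ in range(300)
            ]
            sds.append(np.std(amps))
        slope = np.polyfit(np.log(sweeps), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_half_average_noise_sqrt2_of_full(self):
        """SD of 24-sweep half-averages ≈ √2 × SD of the 48-sweep average."""
        spec = tiny_spec(n_electrodes=3)
        rng = np.random.default_rng(5)
        model = make_profiles(spec)
        mask = np.eye(3, dtype=bool)
        halves, fulls = [], []
        for _ in range(300):
            blocks = simulate_blocked_matrices(model, spec, mask, rng)
            halves.append(blocks["Ma"].values[0, 0])
            fulls.append(blocks["M"].values[0, 0])
        ratio = np.std(halves) / np.std(fulls)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.15)


class TestStudyDesigns:
    def test_dataset_determinism(self):
        spec = tiny_spec(designs=("slowcap_full", "speedcap_half", "diagonal_only"))
        model = make_profiles(spec)
        d1 = simulate_dataset(model, spec)
        d2 = simulate_dataset(model, spec)
        np.testing.assert_array_equal(d1.slowcap["M"].values, d2.slowcap["M"].values)
        np.testing.assert_array_equal(d1.speedcap[0].values, d2.speedcap[0].values)
        np.testing.assert_array_equal(d1.diagonal["Mb"].values, d2.diagonal["Mb"].values)

    def test_design_masks(self):
        spec = tiny_spec()
        model = make_profiles(spec)
        ds = simulate_dataset(model, spec)
        n = spec.n_electrodes
        assert ds.slowcap["M"].is_full
        assert len(ds.speedcap) == 2
        np.testing.assert_array_equal(ds.speedcap[0].recorded_mask, half_mask(n))
        np.testing.assert_array_equal(ds.diagonal["Ma"].recorded_mask, np.eye(n, dtype=bool))

    def test_repeats_use_independent_noise(self):
        spec = tiny_spec()
        model = make_profiles(spec)
        ds = simulate_dataset(model, spec)
        m1, m2 = ds.speedcap
        tri = m1.recorded_mask
        assert not np.allclose(m1.values[tri], m2.values[tri])

    def test_symmetry_error_shrinks_with_averaging(self):
        """With symmetric truth, εsym is pure recording noise and falls
        as more sweeps are averaged."""
        spec = tiny_spec(n_electrodes=5)
        model = make_profiles(spec)
        n = 5
        eps = []
        for nsw, seed in [(12, 0), (400, 1)]:
            M = simulate_matrix(model, spec, np.ones((n, n), dtype=bool), nsw,
                                np.random.default_rng(seed))
            from speedcap import epsilon_sym

            eps.append(epsilon_sym(M.values).percent)
        assert eps[0] > eps[1] > 0.0

    def test_asymmetry_injection(self):
        spec = tiny_spec(per_sweep_noise_sd_uv=0.0, asymmetry_bias=0.2)
        model = make_profiles(spec)
        n = spec.n_electrodes
        M = simulate_matrix(model, spec, np.ones((n, n), dtype=bool), 50,
                            np.random.default_rng(0))
        from speedcap import epsilon_sym

        assert epsilon_sym(M.values).percent > 1.0
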