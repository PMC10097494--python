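"""Four-frame artifact cancelation and P2-N1 amplitude measurement."""

import numpy as np
import pytest

from speedcap import (
    ECAPFrameSet,
    ECAPWaveform,
    ParameterError,
    StructuralError,
    ecap_template,
    extract_ecap_waveform,
    measure_p2n1_amplitude,
)

from conftest import frameset_from_traces


class TestExtraction:
    def test_constant_frames_direct_arithmetic(self, const_frames):
        wf = extract_ecap_waveform(const_frames)
        assert np.all(wf.trace == -1.0)
        assert wf.probe_electrode == const_frames.probe_electrode
        assert wf.n_sweeps == const_frames.n_sweeps

    def test_pure_linear_artifacts_cancel_exactly(self, rng):
        """A = aₚ + d, B = aₚ + aₘ + d, C = aₘ + d, D = d → all-zero trace."""
        n = 24
        a_p, a_m, d = rng.normal(size=(3, n)) * 100
        fs = frameset_from_traces(a_p + d, a_p + a_m + d, a_m + d, d)
        assert np.allclose(extract_ecap_waveform(fs).trace, 0.0, atol=1e-10)

    def test_template_in_frame_a_recovered_exactly(self, template_32, rng):
        """A response injected into frame A passes through sample-for-sample."""
        a_p, a_m, d = rng.normal(size=(3, 32)) * 50
        fs = frameset_from_traces(a_p + d + template_32, a_p + a_m + d, a_m + d, d)
        np.testing.assert_allclose(extract_ecap_waveform(fs).trace, template_32, atol=1e-9)

    def test_linearity(self, rng):
        traces1 = rng.normal(size=(4, 16))
        traces2 = rng.normal(size=(4, 16))
        alpha = 2.5
        w1 = extract_ecap_waveform(frameset_from_traces(*traces1)).trace
        w2 = extract_ecap_waveform(frameset_from_traces(*traces2)).trace
        w12 = extract_ecap_waveform(frameset_from_traces(*(alpha * (traces1 + traces2)))).trace
        np.testing.assert_allclose(w12, alpha * (w1 + w2), atol=1e-9)

    def test_common_signal_on_cancelling_pair_is_invariant(self, rng):
        """Adding g to both A and B leaves the extracted waveform unchanged."""
        traces = rng.normal(size=(4, 16))
        g = rng.normal(size=16) * 10
        base = extract_ecap_waveform(frameset_from_traces(*traces)).trace
        a, b, c, d = traces
        shifted = extract_ecap_waveform(frameset_from_traces(a + g, b + g, c, d)).trace
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    @pytest.mark.parametrize("missing", ["A", "B", "C", "D"])
    def test_missing_frame_is_structural_error(self, missing):
        frames = {lab: np.zeros(16) for lab in "ABCD" if lab != missing}
        with pytest.raises(StructuralError):
            ECAPFrameSet(1, 2, frames)

    def test_unequal_lengths_is_structural_error(self):
        with pytest.raises(StructuralError):
            frameset_from_traces(np.zeros(16), np.zeros(16), np.zeros(16), np.zeros(17))

    def test_too_short_traces_rejected(self):
        with pytest.raises(StructuralError):
            frameset_from_traces(*np.zeros((4, 8)))


class TestAmplitude:
    def _waveform(self, trace, sample_rate=20_000.0):
        return ECAPWaveform(1, 1, np.asarray(trace, float), sample_rate, 50)

    def test_min_then_max_definition(self):
        """Trace dipping to −50 µV then peaking at +30 µV measures 80 µV."""
        trace = np.zeros(32)
        trace[5] = -50.0  # 250 µs
        trace[13] = 30.0  # 650 µs
        meas = measure_p2n1_amplitude(self._waveform(trace))
        assert meas.amplitude_uv == pytest.approx(80.0)
        assert meas.n1_time_us == pytest.approx(250.0)
        assert meas.p2_time_us == pytest.approx(650.0)

    def test_all_zero_trace_gives_zero_low_quality(self):
        meas = measure_p2n1_amplitude(self._waveform(np.zeros(32)))
        assert meas.amplitude_uv == 0.0
        assert meas.low_quality

    def test_amplitude_invariant_to_dc_offset_and_nonnegative(self, rng):
        trace = rng.normal(size=32) * 20
        m0 = measure_p2n1_amplitude(self._waveform(trace))
        m1 = measure_p2n1_amplitude(self._waveform(trace + 500.0))
        assert m0.amplitude_uv == pytest.approx(m1.amplitude_uv)
        assert m0.amplitude_uv >= 0

    def test_known_template_amplitude_under_noise(self):
        """100 µV template + 1 µV per-sample noise measures 100 ± 5 µV."""
        template = ecap_template(n_samples=32, amplitude_uv=100.0)
        rng = np.random.default_rng(0)
        amps = []
        for _ in range(100):
            trace = template + rng.normal(0, 1.0, size=32)
            amps.append(measure_p2n1_amplitude(self._waveform(trace)).amplitude_uv)
        assert np.all(np.abs(np.array(amps) - 100.0) <= 5.0)

    def test_p2_searched_after_n1_only(self):
        """A positive peak before N1 is not taken as P2."""
        trace = np.zeros(32)
        trace[3] = 40.0  # 150 µs, before the N1 dip
        trace[8] = -50.0  # 400 µs
        trace[13] = 10.0  # 650 µs
        meas = measure_p2n1_amplitude(self._waveform(trace))
        assert meas.amplitude_uv == pytest.approx(60.0)
        assert meas.p2_time_us == pytest.approx(650.0)

    @pytest.mark.parametrize(
        "n1_window, p2_end",
        [((300.0, 100.0), 900.0), ((-10.0, 500.0), 900.0), ((100.0, 500.0), 50.0),
         ((5000.0, 6000.0), 7000.0)],
    )
    def test_bad_windows_are_parameter_errors(self, n1_window, p2_end):
        with pytest.raises(ParameterError):
            measure_p2n1_amplitude(self._waveform(np.zeros(32)), n1_window, p2_end)

    def test_tie_broken_by_earliest_sample(self):
        trace = np.zeros(32)
        trace[[4, 6]] = -50.0
        trace[[10, 12]] = 30.0
        meas = measure_p2n1_amplitude(self._waveform(trace))
        assert meas.n1_time_us == pytest.approx(200.0)
        assert meas.p2_time_us == pytest.approx(500.0)
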