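"""Four-frame artifact cancelation and P2-N1 amplitude measurement.

Synthesizes the four stimulation frames for one masker-probe condition —
a 60 µV biphasic neural response buried under ~300 µV of stimulus artifact
plus recording noise — then cancels the artifact with the A − B + C − D
combination and measures the P2-N1 amplitude.
"""

import numpy as np

from speedcap import extract_ecap_waveform, measure_p2n1_amplitude
from speedcap.synthetic import SyntheticStudySpec, simulate_frameset

spec = SyntheticStudySpec(n_electrodes=8, per_sweep_noise_sd_uv=8.0, seed=0)
rng = np.random.default_rng(0)
frames = simulate_frameset(probe=3, masker=5, amplitude_uv=60.0, spec=spec, rng=rng, n_sweeps=50)

artifact_peak = max(frames.frames[lab].max() for lab in "ABCD")
print(f"raw frame peak (artifact-dominated): {artifact_peak:.0f} µV")

waveform = extract_ecap_waveform(frames)
meas = measure_p2n1_amplitude(waveform)
print(
    f"extracted ECAP: N1 {waveform.trace.min():.1f} µV at {meas.n1_time_us:.0f} µs, "
    f"P2 at {meas.p2_time_us:.0f} µs"
)
print(
    f"P2-N1 amplitude: {meas.amplitude_uv:.1f} µV "
    f"(target 60, noise floor {meas.noise_floor_uv:.2f} µV, "
    f"low-quality flag: {meas.low_quality})"
)
# The four-frame combination removes the shared artifacts exactly; the
# residual deviation from 60 µV is the averaged recording noise (SD
# 8/sqrt(50) µV per frame sample).
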