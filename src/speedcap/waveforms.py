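"""Forward-masked ECAP extraction and P2-N1 amplitude measurement.

Electrically evoked compound action potentials (ECAPs) recorded through a
cochlear implant's own telemetry are dominated by stimulus artifact.  The
forward-masking paradigm records four stimulation frames per masker/probe
condition:

* ``A`` — probe alone (probe artifact + unmasked probe response),
* ``B`` — masker then probe (both artifacts + masker response + the probe
  response as masked by the preceding pulse),
* ``C`` — masker alone (masker artifact + masker response),
* ``D`` — no stimulus (system signature).

The combination ``A - B + C - D`` cancels every component that appears
consistently across frames (artifacts, masker response, system signature)
and leaves the part of the probe response that the masker suppressed — the
neural quantity of interest.  The ECAP amplitude is then the voltage
difference between the first negative peak (N1) and the following positive
peak (P2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ParameterError, StructuralError

FRAME_LABELS = ("A", "B", "C", "D")

#: Default peak-search windows, µs from trace start.  The clinical system's
#: latency conventions are not standardized; these cover typical N1
#: latencies (0.2–0.4 ms post-probe) at the default 20 kHz sampling.
DEFAULT_N1_WINDOW_US = (100.0, 500.0)
DEFAULT_P2_END_US = 900.0


@dataclass(frozen=True)
class ECAPFrameSet:
    """The four stimulation/recording frames for one masker-probe condition.

    Parameters
    ----------
    probe_electrode, masker_electrode
        1-based electrode numbers of the probe and masker pulses.
    frames
        Mapping from frame label (``"A".."D"``) to the sweep-averaged
        voltage trace in µV.  All four traces must be present, equally
        long and at least 16 samples.
    sample_rate
        Sampling rate of the traces, Hz.
    n_sweeps
        Number of sweeps averaged into each trace.
    gain_db, delay_us, probe_level_cu
        Acquisition parameters, carried as metadata.
    """

    probe_electrode: int
    masker_electrode: int
    frames: Mapping[str, np.ndarray]
    sample_rate: float = 20_000.0
    n_sweeps: int = 50
    gain_db: float = 50.0
    delay_us: float = 98.0
    probe_level_cu: float = 200.0

    def __post_init__(self):
        missing = [lab for lab in FRAME_LABELS if lab not in self.frames]
        if missing:
            raise StructuralError(f"missing frame label(s): {missing}")
        arrs = {lab: np.asarray(self.frames[lab], dtype=float) for lab in FRAME_LABELS}
        lengths = {arr.shape for arr in arrs.values()}
        if len(lengths) != 1 or arrs["A"].ndim != 1:
            raise StructuralError(f"frame traces must be equal-length 1-D arrays, got shapes {lengths}")
        if arrs["A"].size < 16:
            raise StructuralError(f"frame traces must have >= 16 samples, got {arrs['A'].size}")
        if self.n_sweeps < 1:
            raise StructuralError(f"n_sweeps must be >= 1, got {self.n_sweeps}")
        if self.sample_rate <= 0:
            raise StructuralError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "frames", arrs)

    @property
    def n_samples(self) -> int:
        return self.frames["A"].size

    @property
    def condition_id(self) -> str:
        return f"p{self.probe_electrode:02d}m{self.masker_electrode:02d}"


@dataclass(frozen=True)
class ECAPWaveform:
    """Artifact-canceled ECAP trace (µV) with its acquisition metadata."""

    probe_electrode: int
    masker_electrode: int
    trace: np.ndarray
    sample_rate: float
    n_sweeps: int

    def __post_init__(self):
        object.__setattr__(self, "trace", np.asarray(self.trace, dtype=float))

    @property
    def times_us(self) -> np.ndarray:
        """Sample times in µs from trace start."""
        return np.arange(self.trace.size) * 1e6 / self.sample_rate

    @property
    def condition_id(self) -> str:
        return f"p{self.probe_electrode:02d}m{self.masker_electrode:02d}"


@dataclass(frozen=True)
class AmplitudeMeasurement:
    """P2-N1 amplitude (µV) plus peak latencies and a quality flag."""

    amplitude_uv: float
    n1_time_us: float
    p2_time_us: float
    low_quality: bool
    noise_floor_uv: float


def extract_ecap_waveform(frames: ECAPFrameSet) -> ECAPWaveform:
    """Cancel stimulus artifact by the four-frame combination A - B + C - D.

    Any voltage component common to (A, B) or to (C, D) — probe artifact,
    masker artifact and response, amplifier signature — cancels exactly;
    the result is the masker-suppressed portion of the probe response.
    """
    f = frames.frames
    trace = f["A"] - f["B"] + f["C"] - f["D"]
    return ECAPWaveform(
        probe_electrode=frames.probe_electrode,
        masker_electrode=frames.masker_electrode,
        trace=trace,
        sample_rate=frames.sample_rate,
        n_sweeps=frames.n_sweeps,
    )


def measure_p2n1_amplitude(
    waveform: ECAPWaveform,
    n1_window_us: tuple[float, float] = DEFAULT_N1_WINDOW_US,
    p2_end_us: float = DEFAULT_P2_END_US,
    noise_multiple: float = 3.0,
) -> AmplitudeMeasurement:
    """Measure the P2-N1 peak-to-peak ECAP amplitude of a waveform.

    N1 is the most negative sample inside ``n1_window_us``; P2 is the most
    positive sample between N1 and ``p2_end_us``.  Ties are broken by the
    earliest sample.  The amplitude ``V(P2) - V(N1)`` is non-negative by
    construction.  The measurement is flagged low-quality when the
    amplitude falls below ``noise_multiple`` times the trace SD estimated
    outside the search windows (the noise floor).

    Raises
    ------
    ParameterError
        If a window is empty or lies outside the trace.
    """
    t = waveform.times_us
    lo, hi = float(n1_window_us[0]), float(n1_window_us[1])
    if lo < 0 or hi <= lo:
        raise ParameterError(f"invalid N1 window [{lo}, {hi}] µs")
    if p2_end_us <= lo:
        raise ParameterError(f"P2 window end {p2_end_us} µs precedes N1 window start {lo} µs")
    if lo >= t[-1]:
        raise ParameterError(f"N1 window starts after trace end ({t[-1]:.0f} µs)")

    n1_mask = (t >= lo) & (t <= hi)
    if not n1_mask.any():
        raise ParameterError(f"N1 window [{lo}, {hi}] µs contains no samples")
    v = waveform.trace
    n1_idx = np.flatnonzero(n1_mask)[np.argmin(v[n1_mask])]

    p2_mask = (t >= t[n1_idx]) & (t <= p2_end_us)
    p2_candidates = np.flatnonzero(p2_mask)
    # Noise floor: SD of samples outside both search windows.
    outside = ~((t >= lo) & (t <= p2_end_us))
    noise_floor = float(np.std(v[outside])) if outside.sum() >= 2 else 0.0

    if p2_candidates.size == 0:
        return AmplitudeMeasurement(0.0, float(t[n1_idx]), float(t[n1_idx]), True, noise_floor)

    p2_idx = p2_candidates[np.argmax(v[p2_candidates])]
    amplitude = float(v[p2_idx] - v[n1_idx])
    low_quality = amplitude < noise_multiple * noise_floor or amplitude == 0.0
    return AmplitudeMeasurement(
        amplitude_uv=amplitude,
        n1_time_us=float(t[n1_idx]),
        p2_time_us=float(t[p2_idx]),
        low_quality=bool(low_quality),
        noise_floor_uv=noise_floor,
    )


def ecap_template(
    n_samples: int = 32,
    sample_rate: float = 20_000.0,
    n1_time_us: float = 300.0,
    n1_width_us: float = 80.0,
    p2_time_us: float = 650.0,
    p2_width_us: float = 120.0,
    amplitude_uv: float = 1.0,
) -> np.ndarray:
    """Difference-of-Gaussians ECAP waveform template.

    A negative Gaussian at the N1 latency plus a positive one at the P2
    latency, scaled so the sampled P2-N1 peak-to-peak value equals
    ``amplitude_uv`` exactly.  Used by the synthetic-data generator; real
    ECAP morphology varies but shares this biphasic shape.
    """
    t = np.arange(n_samples) * 1e6 / sample_rate
    shape = -np.exp(-0.5 * ((t - n1_time_us) / n1_width_us) ** 2) + 0.8 * np.exp(
        -0.5 * ((t - p2_time_us) / p2_width_us) ** 2
    )
    pp = shape.max() - shape.min()
    return shape * (amplitude_uv / pp)
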