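"""Acquisition scheduling: condition enumeration, frame batching, timing.

Cochlear Ltd.'s research telemetry transfers recorded frames in batches
whose size is limited by the processor buffer (19 frames), with roughly one
second of command upload and one second of data download per batch.  The
fast half-matrix scheme ("SpeedCAP") exploits three redundancies:

1. the amplitude matrix is assumed symmetric, so only the diagonal plus one
   triangle is recorded (n(n+1)/2 of the n² conditions);
2. frames for several conditions are packed into one telemetry batch,
   amortizing the per-transaction overhead;
3. the probe-alone (A) and no-stimulus (D) frames are identical for every
   masker position of a given probe, so one shared A and one shared D frame
   serve every condition in the batch.

With a shared A and D plus one masker (B) and one masker-alone (C) frame
per condition, a batch of ``b`` frames covers ``(b - 2) // 2`` conditions —
8 for the 19-frame buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

from .errors import ParameterError

MAX_ELECTRODES = 22
DEFAULT_BUFFER_LIMIT = 19
DEFAULT_RATE_HZ = 80.0
DEFAULT_N_SWEEPS = 50


class Frame(NamedTuple):
    """One stimulation/recording frame inside a telemetry batch.

    ``probe``/``masker`` are 1-based electrode numbers or None when the
    frame does not deliver that pulse (A: no masker; C: no probe; D:
    neither — recording parameters still follow the probe electrode).
    """

    label: str  # "A", "B", "C" or "D"
    probe: int | None
    masker: int | None
    n_sweeps: int


@dataclass
class RecordingSchedule:
    """Ordered telemetry batches of frames realizing one acquisition mode."""

    mode: Literal["slowcap", "speedcap", "diagonal"]
    n_electrodes: int
    conditions: list[tuple[int, int]]  # (probe, masker)
    batches: list[list[Frame]]
    buffer_limit: int = DEFAULT_BUFFER_LIMIT
    rate_hz: float = DEFAULT_RATE_HZ
    n_sweeps: int = DEFAULT_N_SWEEPS

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_frames(self) -> int:
        return sum(len(b) for b in self.batches)

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def max_ecaps_per_batch(self) -> int:
        """Largest number of ECAP conditions any single batch supports.

        Each condition contributes exactly one masker+probe (B) frame, so
        B frames count conditions in both dedicated and shared-frame batches.
        """
        return max((sum(1 for f in b if f.label == "B") for b in self.batches), default=0)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_electrodes": self.n_electrodes,
            "n_conditions": self.n_conditions,
            "n_frames": self.n_frames,
            "n_batches": self.n_batches,
            "buffer_limit": self.buffer_limit,
            "rate_hz": self.rate_hz,
            "n_sweeps": self.n_sweeps,
            "conditions": [list(c) for c in self.conditions],
            "batches": [[f._asdict() for f in b] for b in self.batches],
        }


@dataclass
class ScheduleSummary:
    """Counts and estimated acquisition time for a schedule."""

    n_conditions: int
    n_frames: int
    n_batches: int
    est_stimulation_s: float
    est_communication_s: float

    @property
    def est_total_s(self) -> float:
        return self.est_stimulation_s + self.est_communication_s

    def to_dict(self) -> dict:
        d = self.__dict__ | {"est_total_s": self.est_total_s}
        return d


def _check_n(n: int) -> None:
    if not (1 <= n <= MAX_ELECTRODES):
        raise ParameterError(f"electrode count must be in 1..{MAX_ELECTRODES}, got {n}")


def half_matrix_conditions(n: int, triangle: str = "upper") -> list[tuple[int, int]]:
    """Diagonal + one-triangle (probe, masker) pairs, probes ascending.

    ``triangle="upper"`` takes maskers with index >= probe; ``"lower"``
    flips the convention (maskers on the other side of the probe).
    """
    if triangle == "upper":
        return [(p, m) for p in range(1, n + 1) for m in range(p, n + 1)]
    if triangle == "lower":
        return [(p, m) for p in range(1, n + 1) for m in range(1, p + 1)]
    raise ParameterError(f"triangle must be 'upper' or 'lower', got {triangle!r}")


def full_matrix_conditions(n: int) -> list[tuple[int, int]]:
    """All n² ordered (probe, masker) pairs."""
    return [(p, m) for p in range(1, n + 1) for m in range(1, n + 1)]


def _condition_frames(p: int, m: int, n_sweeps: int) -> list[Frame]:
    return [
        Frame("A", p, None, n_sweeps),
        Frame("B", p, m, n_sweeps),
        Frame("C", None, m, n_sweeps),
        Frame("D", p, None, n_sweeps),
    ]


def build_slowcap_schedule(
    n: int,
    symmetric_half: bool = False,
    n_sweeps: int = DEFAULT_N_SWEEPS,
    rate_hz: float = DEFAULT_RATE_HZ,
    conditions_per_batch: int = 1,
    triangle: str = "upper",
) -> RecordingSchedule:
    """Standard acquisition: four dedicated frames per condition.

    The clinical software transfers one condition per transaction
    (``conditions_per_batch=1``); setting it to 4 models the
    batch-transfer technique without frame recycling.
    """
    _check_n(n)
    if conditions_per_batch < 1:
        raise ParameterError("conditions_per_batch must be >= 1")
    conditions = (
        half_matrix_conditions(n, triangle) if symmetric_half else full_matrix_conditions(n)
    )
    batches: list[list[Frame]] = []
    for i in range(0, len(conditions), conditions_per_batch):
        batch: list[Frame] = []
        for p, m in conditions[i : i + conditions_per_batch]:
            batch.extend(_condition_frames(p, m, n_sweeps))
        batches.append(batch)
    buffer_limit = max(DEFAULT_BUFFER_LIMIT, 4 * conditions_per_batch)
    return RecordingSchedule("slowcap", n, conditions, batches, buffer_limit, rate_hz, n_sweeps)


def build_speedcap_schedule(
    n: int,
    buffer_limit: int = DEFAULT_BUFFER_LIMIT,
    n_sweeps: int = DEFAULT_N_SWEEPS,
    rate_hz: float = DEFAULT_RATE_HZ,
    triangle: str = "upper",
) -> RecordingSchedule:
    """Half-matrix acquisition with shared A/D frames and batch transfer.

    Conditions are the diagonal plus one triangle.  For each probe the
    maskers are grouped into batches of at most ``(buffer_limit - 2) // 2``
    ECAPs; each batch holds one shared A frame, one B and one C frame per
    masker, and one shared D frame, so every condition's four frames are
    jointly available within its batch.
    """
    _check_n(n)
    if buffer_limit < 4:
        raise ParameterError(f"buffer_limit must be >= 4 to fit one ECAP, got {buffer_limit}")
    k_max = (buffer_limit - 2) // 2
    conditions = half_matrix_conditions(n, triangle)
    batches: list[list[Frame]] = []
    probes = sorted({p for p, _ in conditions})
    for p in probes:
        maskers = [m for q, m in conditions if q == p]
        for i in range(0, len(maskers), k_max):
            group = maskers[i : i + k_max]
            batch = [Frame("A", p, None, n_sweeps)]
            for m in group:
                batch.append(Frame("B", p, m, n_sweeps))
                batch.append(Frame("C", None, m, n_sweeps))
            batch.append(Frame("D", p, None, n_sweeps))
            batches.append(batch)
    return RecordingSchedule("speedcap", n, conditions, batches, buffer_limit, rate_hz, n_sweeps)


def build_diagonal_schedule(
    n: int,
    n_sweeps: int = 12,
    rate_hz: float = DEFAULT_RATE_HZ,
    conditions_per_batch: int = 4,
) -> RecordingSchedule:
    """Diagonal-only acquisition (masker = probe), e.g. intraoperative
    screening recorded in batches of four 12-sweep ECAPs."""
    _check_n(n)
    if conditions_per_batch < 1:
        raise ParameterError("conditions_per_batch must be >= 1")
    conditions = [(e, e) for e in range(1, n + 1)]
    batches: list[list[Frame]] = []
    for i in range(0, n, conditions_per_batch):
        batch: list[Frame] = []
        for p, m in conditions[i : i + conditions_per_batch]:
            batch.extend(_condition_frames(p, m, n_sweeps))
        batches.append(batch)
    buffer_limit = max(DEFAULT_BUFFER_LIMIT, 4 * conditions_per_batch)
    return RecordingSchedule("diagonal", n, conditions, batches, buffer_limit, rate_hz, n_sweeps)


def estimate_times(
    schedule: RecordingSchedule,
    overhead_up_s: float = 1.0,
    overhead_down_s: float = 1.0,
) -> ScheduleSummary:
    """Acquisition-time model: stimulation plus per-batch communication.

    Stimulation time is ``n_frames × n_sweeps / rate_hz`` (every sweep of
    every frame is one stimulus presentation at the pulse-train rate);
    communication time is one command upload plus one data download per
    telemetry batch.
    """
    if overhead_up_s < 0 or overhead_down_s < 0:
        raise ParameterError("communication overheads must be >= 0")
    stim = schedule.n_frames * schedule.n_sweeps / schedule.rate_hz
    comm = schedule.n_batches * (overhead_up_s + overhead_down_s)
    return ScheduleSummary(
        n_conditions=schedule.n_conditions,
        n_frames=schedule.n_frames,
        n_batches=schedule.n_batches,
        est_stimulation_s=stim,
        est_communication_s=comm,
    )


def communication_reduction(
    baseline: RecordingSchedule,
    improved: RecordingSchedule,
    overhead_up_s: float = 1.0,
    overhead_down_s: float = 1.0,
) -> float:
    """Fractional reduction in communication time of one schedule vs another."""
    a = estimate_times(baseline, overhead_up_s, overhead_down_s).est_communication_s
    b = estimate_times(improved, overhead_up_s, overhead_down_s).est_communication_s
    if a <= 0:
        raise ParameterError("baseline schedule has zero communication time")
    return 1.0 - b / a
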