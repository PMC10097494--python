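"""Synthetic ground truths, frame sets, matrices and paired study designs.

No public ECAP recordings exist for the acquisition designs this package
implements, so every stage is exercised on synthetic data built from the
same generative model the inversion assumes: Gaussian current spread,
per-electrode neural health (optionally with dead regions — contiguous
stretches of strongly depressed responsiveness), biphasic ECAP waveform
templates, and white per-sweep recording noise whose trace-level SD scales
as 1/√(sweeps averaged).

Two simulation paths are provided.  The *waveform* path synthesizes all
four stimulation frames per condition (template + linear artifacts +
noise), runs them through the artifact-cancelation and peak-picking code,
and assembles measured amplitude matrices — including split-sweep block
averages (four 12-sweep blocks per the standard 48-sweep design).  The
*amplitude* path perturbs noiseless model amplitudes with multiplicative
noise directly and is used for large parameter-recovery sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics
from .errors import ParameterError
from .forward_model import ExcitationModel, predict_matrix
from .matrix import ECAPMatrix, diagonal_mask, half_mask
from .solver import SolverConfig, solve_pecap
from .waveforms import (
    ECAPFrameSet,
    ecap_template,
    extract_ecap_waveform,
    measure_p2n1_amplitude,
)


@dataclass(frozen=True)
class DeadRegion:
    """Contiguous stretch of depressed neural health.

    ``start`` is the 1-based first electrode, ``width`` the number of
    electrodes, ``floor`` the η value imposed there (0–1).
    """

    start: int
    width: int
    floor: float = 0.05

    def __post_init__(self):
        if self.width < 1:
            raise ParameterError(f"dead-region width must be >= 1, got {self.width}")
        if not (0.0 <= self.floor <= 1.0):
            raise ParameterError(f"dead-region floor must be in [0, 1], got {self.floor}")

    def electrodes(self) -> range:
        return range(self.start, self.start + self.width)


@dataclass
class SyntheticStudySpec:
    """Conditions of a synthetic acquisition study.

    Defaults emulate the clinical designs: a 22-electrode array, 50-sweep
    fast half-matrix recordings repeated twice, and a standard full-matrix
    recording acquired as four 12-sweep blocks (48 sweeps total) whose
    halves support split-half repeatability.  The per-sweep noise SD (8 µV)
    and 100 µV amplitude scale put simulated repeatability errors in the
    few-percent-of-maximum range typical of clinical recordings.
    """

    n_electrodes: int = 22
    sigma_profile: str = "smooth"
    sigma_params: dict = field(default_factory=dict)
    eta_profile: str = "smooth"
    eta_params: dict = field(default_factory=dict)
    dead_regions: tuple[DeadRegion, ...] = ()
    per_sweep_noise_sd_uv: float = 8.0
    n_sweeps_speedcap: int = 50
    subsample_blocks: int = 4
    sweeps_per_block: int = 12
    amplitude_scale_uv: float = 100.0
    designs: tuple[str, ...] = ("slowcap_full", "speedcap_half", "speedcap_half", "diagonal_only")
    triangle: str = "upper"
    asymmetry_bias: float = 0.0  # multiplicative bias on the upper triangle; 0 = symmetric
    sample_rate: float = 20_000.0
    n_samples: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.per_sweep_noise_sd_uv < 0:
            raise ParameterError("per-sweep noise SD must be >= 0")
        self.dead_regions = tuple(
            dr if isinstance(dr, DeadRegion) else DeadRegion(*dr) for dr in self.dead_regions
        )
        for dr in self.dead_regions:
            if dr.start < 1 or dr.start + dr.width - 1 > self.n_electrodes:
                raise ParameterError(
                    f"dead region {dr} lies outside the {self.n_electrodes}-electrode array"
                )

    def child_seed(self, offset: int) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return int((self.seed * 10_007 + offset) % 2**31)


def _walk(rng: np.random.Generator, n: int, lo: float, hi: float, step: float) -> np.ndarray:
    v = np.empty(n)
    v[0] = rng.uniform(lo, hi)
    for i in range(1, n):
        v[i] = np.clip(v[i - 1] + rng.uniform(-step, step), lo, hi)
    return v


def _profile(rng, kind, params, n, default_range, default_step, default_const):
    lo, hi = params.get("range", default_range)
    if kind == "constant":
        return np.full(n, params.get("value", default_const))
    if kind == "smooth":
        return _walk(rng, n, lo, hi, params.get("step", default_step))
    if kind == "piecewise":
        seg = int(params.get("segment", max(2, n // 4)))
        levels = params.get("levels", (lo, hi))
        v = np.empty(n)
        for i in range(n):
            v[i] = levels[(i // seg) % len(levels)]
        return v
    raise ParameterError(f"unknown profile kind {kind!r}")


def make_profiles(spec: SyntheticStudySpec) -> ExcitationModel:
    """Ground-truth σ/η profiles for a study spec.

    Smooth-random profiles are bounded random walks whose step sizes
    (default σ: 0.3 spacings, η: 0.1) stay within the solver's default
    smoothness caps by construction.  Dead regions are imposed on η last
    and may violate those caps at their edges — that is the point: they are
    abrupt lesions the inversion can only approximate.
    """
    rng = np.random.default_rng(spec.child_seed(1))
    n = spec.n_electrodes
    sigma = _profile(rng, spec.sigma_profile, spec.sigma_params, n, (1.5, 4.0), 0.3, 2.0)
    eta = _profile(rng, spec.eta_profile, spec.eta_params, n, (0.3, 1.0), 0.1, 0.8)
    for dr in spec.dead_regions:
        eta[dr.start - 1 : dr.start - 1 + dr.width] = dr.floor
    return ExcitationModel(sigma, eta)


def simulate_frameset(
    probe: int,
    masker: int,
    amplitude_uv: float,
    spec: SyntheticStudySpec,
    rng: np.random.Generator,
    n_sweeps: int,
) -> ECAPFrameSet:
    """Four-frame recording for one condition at a target ECAP amplitude.

    The net neural response (a biphasic template scaled to the target
    P2-N1 amplitude) is injected into frame A; exponentially decaying
    stimulus artifacts are shared between the frames so that the
    A − B + C − D combination cancels them exactly; each frame carries
    independent white noise of SD ``per_sweep_noise_sd_uv / √n_sweeps``
    (the trace is a sweep average)."""
    t = np.arange(spec.n_samples) / spec.sample_rate
    probe_artifact = (150.0 + 8.0 * probe) * np.exp(-t / 2e-4)
    masker_artifact = (150.0 + 8.0 * masker) * np.exp(-t / 2e-4)
    response = ecap_template(
        n_samples=spec.n_samples, sample_rate=spec.sample_rate, amplitude_uv=amplitude_uv
    )
    sd = spec.per_sweep_noise_sd_uv / np.sqrt(n_sweeps)
    noise = rng.normal(0.0, sd, size=(4, spec.n_samples)) if sd > 0 else np.zeros((4, spec.n_samples))
    frames = {
        "A": probe_artifact + response + noise[0],
        "B": probe_artifact + masker_artifact + noise[1],
        "C": masker_artifact + noise[2],
        "D": noise[3],
    }
    return ECAPFrameSet(
        probe_electrode=probe,
        masker_electrode=masker,
        frames=frames,
        sample_rate=spec.sample_rate,
        n_sweeps=n_sweeps,
    )


def _target_amplitudes(model: ExcitationModel, spec: SyntheticStudySpec) -> np.ndarray:
    amps = spec.amplitude_scale_uv * predict_matrix(model).values
    if spec.asymmetry_bias:
        n = model.n_electrodes
        upper = np.triu(np.ones((n, n), dtype=bool), k=1)
        amps = amps.copy()
        amps[upper] *= 1.0 + spec.asymmetry_bias
    return amps


def _measure(frames: ECAPFrameSet) -> float:
    return measure_p2n1_amplitude(extract_ecap_waveform(frames)).amplitude_uv


def simulate_matrix(
    model: ExcitationModel,
    spec: SyntheticStudySpec,
    mask: np.ndarray,
    n_sweeps: int,
    rng: np.random.Generator,
) -> ECAPMatrix:
    """Measured amplitude matrix over the masked conditions (waveform path)."""
    amps = _target_amplitudes(model, spec)
    n = model.n_electrodes
    values = np.zeros((n, n))
    for p in range(1, n + 1):
        for m in range(1, n + 1):
            if not mask[p - 1, m - 1]:
                continue
            fs = simulate_frameset(p, m, amps[p - 1, m - 1], spec, rng, n_sweeps)
            values[p - 1, m - 1] = _measure(fs)
    return ECAPMatrix(values, mask.copy(), {"units": "uV", "n_sweeps": n_sweeps})


def simulate_blocked_matrices(
    model: ExcitationModel,
    spec: SyntheticStudySpec,
    mask: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, ECAPMatrix]:
    """Block-averaged acquisition: amplitude matrices from sweep subsets.

    Each condition is recorded as ``subsample_blocks`` independent blocks
    of ``sweeps_per_block`` sweeps.  Returns amplitudes measured from the
    full average (``M``), the first-half average (``Ma``, e.g. sweeps
    1–24) and the second-half average (``Mb``, sweeps 25–48), supporting
    split-half repeatability with the 1/√2 sweep correction.
    """
    amps = _target_amplitudes(model, spec)
    n = model.n_electrodes
    nb = spec.subsample_blocks
    half = nb // 2
    out = {k: np.zeros((n, n)) for k in ("M", "Ma", "Mb")}
    for p in range(1, n + 1):
        for m in range(1, n + 1):
            if not mask[p - 1, m - 1]:
                continue
            blocks = [
                simulate_frameset(p, m, amps[p - 1, m - 1], spec, rng, spec.sweeps_per_block)
                for _ in range(nb)
            ]

            def avg(subset):
                traces = {
                    lab: np.mean([b.frames[lab] for b in subset], axis=0) for lab in "ABCD"
                }
                fs = ECAPFrameSet(
                    probe_electrode=p,
                    masker_electrode=m,
                    frames=traces,
                    sample_rate=spec.sample_rate,
                    n_sweeps=spec.sweeps_per_block * len(subset),
                )
                return _measure(fs)

            out["M"][p - 1, m - 1] = avg(blocks)
            out["Ma"][p - 1, m - 1] = avg(blocks[:half])
            out["Mb"][p - 1, m - 1] = avg(blocks[half:])
    sweeps = spec.sweeps_per_block * nb
    return {
        "M": ECAPMatrix(out["M"], mask.copy(), {"units": "uV", "n_sweeps": sweeps}),
        "Ma": ECAPMatrix(out["Ma"], mask.copy(), {"units": "uV", "n_sweeps": sweeps // 2}),
        "Mb": ECAPMatrix(out["Mb"], mask.copy(), {"units": "uV", "n_sweeps": sweeps - sweeps // 2}),
    }


@dataclass
class SyntheticDataset:
    """Everything one synthetic participant yields across the study designs."""

    spec: SyntheticStudySpec
    model: ExcitationModel
    slowcap: dict[str, ECAPMatrix] | None = None  # M, Ma, Mb (full matrix, 4x12 sweeps)
    speedcap: list[ECAPMatrix] = field(default_factory=list)  # half matrices, repeats
    diagonal: dict[str, ECAPMatrix] | None = None  # M, Ma, Mb restricted to the diagonal


def simulate_dataset(model: ExcitationModel, spec: SyntheticStudySpec) -> SyntheticDataset:
    """Run every design in ``spec.designs`` with independent noise streams.

    Deterministic given ``spec.seed``: each design instance draws from its
    own child generator with a fixed offset.
    """
    n = spec.n_electrodes
    ds = SyntheticDataset(spec=spec, model=model)
    sp_repeat = 0
    for i, design in enumerate(spec.designs):
        rng = np.random.default_rng(spec.child_seed(100 + i))
        if design == "slowcap_full":
            ds.slowcap = simulate_blocked_matrices(model, spec, np.ones((n, n), dtype=bool), rng)
        elif design == "speedcap_half":
            mask = half_mask(n, spec.triangle)
            ds.speedcap.append(simulate_matrix(model, spec, mask, spec.n_sweeps_speedcap, rng))
            sp_repeat += 1
        elif design == "diagonal_only":
            ds.diagonal = simulate_blocked_matrices(model, spec, diagonal_mask(n), rng)
        else:
            raise ParameterError(f"unknown design {design!r}")
    return ds


def noisy_amplitude_matrix(
    model: ExcitationModel,
    mask: np.ndarray,
    rel_noise: float,
    rng: np.random.Generator,
    amplitude_scale_uv: float = 100.0,
) -> ECAPMatrix:
    """Amplitude-path simulation: multiplicative noise on model amplitudes.

    Each recorded cell is ``scale · M_norm(p, m) · (1 + rel_noise · z)``
    with independent standard-normal ``z``, clipped at zero.
    """
    amps = amplitude_scale_uv * predict_matrix(model).values
    if rel_noise > 0:
        amps = amps * (1.0 + rel_noise * rng.standard_normal(amps.shape))
    vals = np.clip(np.where(mask, amps, 0.0), 0.0, None)
    return ECAPMatrix(vals, np.asarray(mask, dtype=bool).copy(), {"units": "uV"})


def sweep_correction_experiment(
    n_replicates: int = 500,
    n_electrodes: int = 8,
    seed: int = 0,
    path: str = "averaging",
) -> dict[str, float]:
    """Validate the 1/√2 split-half sweep correction by simulation.

    Each replicate records one condition set twice: once as four 12-sweep
    blocks (yielding the 48-sweep average and its two 24-sweep halves) and
    once more independently.  The split-half error with the 1/√2
    correction should estimate the error between two independent 48-sweep
    recordings, because halving the sweeps inflates measurement noise
    by √2 — the premise behind the corrected split-half repeatability
    metric.

    ``path="averaging"`` applies block noise directly to amplitudes, so
    the experiment isolates the sweep-averaging arithmetic the correction
    is derived from.  ``path="waveform"`` runs the full frame-synthesis /
    peak-picking pipeline; extremum picking grows slightly sub-linearly
    with trace noise, so the ratio falls a few percent below 1 there.

    Returns the mean corrected split-half ε, the mean direct
    between-recording ε, and their ratio (≈ 1 when the correction holds).
    """
    spec = SyntheticStudySpec(n_electrodes=n_electrodes, seed=seed)
    model = make_profiles(spec)
    mask = diagonal_mask(n_electrodes)
    rng = np.random.default_rng(spec.child_seed(4))
    eps_half, eps_direct = [], []
    if path == "waveform":
        for _ in range(n_replicates):
            rec1 = simulate_blocked_matrices(model, spec, mask, rng)
            rec2 = simulate_blocked_matrices(model, spec, mask, rng)
            eps_half.append(
                metrics.rmse_normalized(rec1["Ma"], rec1["Mb"], half_sweep_correction=True).percent
            )
            eps_direct.append(metrics.rmse_normalized(rec1["M"], rec2["M"]).percent)
    elif path == "averaging":
        truth = np.diag(_target_amplitudes(model, spec))
        nb, spb = spec.subsample_blocks, spec.sweeps_per_block
        # amplitude noise of one block: 4-frame combination doubles the
        # trace SD, the two-point P2-N1 difference adds another sqrt(2)
        block_sd = 2.0 * np.sqrt(2.0) * spec.per_sweep_noise_sd_uv / np.sqrt(spb)
        def record():
            blocks = truth + rng.normal(0.0, block_sd, size=(nb, truth.size))
            return (blocks.mean(axis=0), blocks[: nb // 2].mean(axis=0),
                    blocks[nb // 2 :].mean(axis=0))
        def as_matrix(diag_vals):
            return ECAPMatrix(np.diag(np.clip(diag_vals, 0.0, None)), mask)
        for _ in range(n_replicates):
            m1, m1a, m1b = record()
            m2, _, _ = record()
            eps_half.append(
                metrics.rmse_normalized(as_matrix(m1a), as_matrix(m1b),
                                        half_sweep_correction=True).percent
            )
            eps_direct.append(metrics.rmse_normalized(as_matrix(m1), as_matrix(m2)).percent)
    else:
        raise ParameterError(f"unknown path {path!r}")
    mean_half = float(np.mean(eps_half))
    mean_direct = float(np.mean(eps_direct))
    return {
        "mean_corrected_split_half_pct": mean_half,
        "mean_direct_48_sweep_pct": mean_direct,
        "ratio": mean_half / mean_direct,
        "n_replicates": n_replicates,
    }


def run_recovery_benchmark(
    n_electrodes: Sequence[int] = (8, 12, 16),
    noise_levels: Sequence[float] = (0.0,),
    n_seeds: int = 10,
    master_seed: int = 0,
    dead_region: DeadRegion | None = None,
    solver_config: SolverConfig | None = None,
    triangle: str = "upper",
    noise_model: str = "multiplicative",
) -> pd.DataFrame:
    """Generate → acquire (half matrix) → mirror → invert → score, per cell.

    For every (array size, noise level, seed) cell a smooth ground truth is
    drawn, a half-matrix acquisition simulated, mirrored to full, and
    inverted; the row records the truth-vs-estimate Pearson correlations,
    the parameter RMS errors and the fit diagnostics.  Failures are
    isolated per run (recorded in the ``error`` column).

    ``noise_model`` selects the acquisition path: ``"multiplicative"``
    perturbs model amplitudes by the given relative SDs (noise_levels as
    fractions); ``"recording"`` runs the full waveform path — frames with
    additive per-sweep recording noise (noise_levels as µV SDs), 50-sweep
    averaging, artifact cancelation and peak picking — i.e. the study's
    own noise structure.
    """
    if noise_model not in ("multiplicative", "recording"):
        raise ParameterError(f"unknown noise_model {noise_model!r}")
    from scipy import stats

    rows = []
    run = 0
    for n in n_electrodes:
        for noise in noise_levels:
            for k in range(n_seeds):
                run += 1
                seed = int((master_seed * 10_007 + run) % 2**31)
                row = {"n": n, "noise": noise, "seed": seed, "error": ""}
                try:
                    spec = SyntheticStudySpec(
                        n_electrodes=n,
                        dead_regions=(dead_region,) if dead_region else (),
                        seed=seed,
                        triangle=triangle,
                    )
                    model = make_profiles(spec)
                    rng = np.random.default_rng(spec.child_seed(2))
                    if noise_model == "multiplicative":
                        half = noisy_amplitude_matrix(
                            model, half_mask(n, triangle), noise, rng, spec.amplitude_scale_uv
                        )
                    else:
                        spec = replace(spec, per_sweep_noise_sd_uv=noise)
                        half = simulate_matrix(
                            model, spec, half_mask(n, triangle), spec.n_sweeps_speedcap, rng
                        )
                    full = metrics.mirror_half(half)
                    cfg = solver_config or SolverConfig(seed=spec.child_seed(3))
                    est = solve_pecap(full, cfg)
                    eta_true = model.eta / model.eta.max()
                    row["r_eta"] = float(stats.pearsonr(est.eta_hat_normalized, eta_true)[0])
                    row["r_sigma"] = float(stats.pearsonr(est.sigma_hat, model.sigma)[0])
                    eps_s, eps_e = metrics.estimate_errors(
                        est.sigma_hat, model.sigma, eta_a=est.eta_hat_normalized, eta_b=eta_true
                    )
                    row["eps_sigma"] = eps_s.value
                    row["eps_eta"] = eps_e.value
                    row["objective_rmse"] = est.objective_rmse
                    row["converged"] = est.converged
                    tol = cfg.constraint_tol
                    row["sigma_min"] = float(est.sigma_hat.min())
                    row["sigma_max"] = float(est.sigma_hat.max())
                    row["eta_min"] = float(est.eta_hat.min())
                    row["eta_max"] = float(est.eta_hat.max())
                    row["feasible"] = bool(
                        est.sigma_hat.min() >= cfg.sigma_bounds[0] - tol
                        and est.sigma_hat.max() <= cfg.sigma_bounds[1] + tol
                        and est.eta_hat.min() >= cfg.eta_bounds[0] - tol
                        and est.eta_hat.max() <= cfg.eta_bounds[1] + tol
                        and np.abs(np.diff(est.sigma_hat)).max() <= cfg.d_sigma_max + tol
                        and np.abs(np.diff(est.eta_hat)).max() <= cfg.d_eta_max + tol
                    )
                    if dead_region is not None:
                        argmin = int(np.argmin(est.eta_hat)) + 1
                        row["eta_min_electrode"] = argmin
                        row["dead_region_hit"] = argmin in dead_region.electrodes()
                except Exception as exc:  # noqa: BLE001 — run-level isolation
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)
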