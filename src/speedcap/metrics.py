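"""Matrix preparation and the normalized-RMSE repeatability/comparison metrics.

Half-recorded matrices are completed by mirroring across the diagonal
(the symmetry assumption); fully recorded matrices are made symmetric by
averaging with their transpose.  Repeatability and between-method errors
are cell-wise RMSEs normalized by the maximum amplitude over both matrices
and reported in percent:

    ε = factor · sqrt(mean((Ma − Mb)²)) / max(Ma, Mb) · 100

The factor is 1/√2 when the two matrices are built from half the sweeps of
a single recording (split-half repeatability): halving the sweep count
inflates the measurement noise by √2, and the correction restores the error
scale of the full-sweep measurement.  Parameter-estimate errors (εσ, εη)
are plain RMSEs in native units, also expressed as percent of the
parameter ranges (σ: 6 − 1 = 5 spacings; η: 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    ParameterError,
    StructuralError,
    UndefinedCorrelationError,
)
from .matrix import ECAPMatrix
from .solver import ExcitationEstimate

HALF_SWEEP_FACTOR = 1.0 / np.sqrt(2.0)
SIGMA_RANGE = 5.0  # spacings: bounds are [1, 6]
ETA_RANGE = 1.0


@dataclass(frozen=True)
class ErrorReport:
    """One ε metric with its normalization provenance.

    ``value`` is in native units (fraction of max amplitude for matrix
    metrics; spacings or η units for parameter metrics); ``percent`` is the
    same quantity × 100 (of the max amplitude, or of the parameter range).
    """

    metric_name: str
    value: float
    percent: float
    normalizer: float
    n_cells: int
    half_sweep_correction: bool = False

    def __str__(self) -> str:
        return f"{self.metric_name} = {self.percent:.2f}%"


def _as_matrix(M) -> ECAPMatrix:
    return M if isinstance(M, ECAPMatrix) else ECAPMatrix(np.asarray(M, dtype=float))


def mirror_half(M_half: ECAPMatrix) -> ECAPMatrix:
    """Complete a half-recorded matrix by copying cells across the diagonal.

    Requires the recorded mask to cover the diagonal plus exactly one
    triangle; the output is exactly symmetric with an all-true mask.
    """
    M_half = _as_matrix(M_half)
    if not np.diag(M_half.recorded_mask).all():
        raise StructuralError("half matrix is missing diagonal cells")
    if M_half.is_full:
        raise StructuralError("matrix is already full: use symmetrize, not mirror_half")
    if not M_half.is_half():
        raise StructuralError("recorded mask is not diagonal + exactly one triangle")
    vals = M_half.values.copy()
    rec = M_half.recorded_mask
    vals[~rec] = vals.T[~rec]
    return ECAPMatrix(vals, np.ones_like(rec), dict(M_half.meta, mirrored=True))


def symmetrize(M_asym: ECAPMatrix) -> ECAPMatrix:
    """Average a fully recorded matrix with its transpose: (M + Mᵀ) / 2.

    This is the orthogonal projection onto symmetric matrices (hence
    idempotent) and the format submitted to the inversion.
    """
    M_asym = _as_matrix(M_asym)
    if not M_asym.is_full:
        raise StructuralError("symmetrize requires a fully recorded matrix; mirror halves first")
    vals = 0.5 * (M_asym.values + M_asym.values.T)
    return ECAPMatrix(vals, np.ones_like(M_asym.recorded_mask), dict(M_asym.meta, symmetrized=True))


def _resolve_cells(Ma: ECAPMatrix, Mb: ECAPMatrix, cells) -> np.ndarray:
    n = Ma.n_electrodes
    if Mb.n_electrodes != n:
        raise StructuralError(f"matrix sizes differ: {n} vs {Mb.n_electrodes}")
    common = Ma.recorded_mask & Mb.recorded_mask
    if cells is None or (isinstance(cells, str) and cells == "all"):
        mask = common
    elif isinstance(cells, str) and cells == "diagonal":
        mask = common & np.eye(n, dtype=bool)
    elif isinstance(cells, str) and cells == "triangle":
        mask = common & np.triu(np.ones((n, n), dtype=bool))
    elif isinstance(cells, str):
        raise ParameterError(f"unknown cell selector {cells!r}")
    else:
        mask = np.asarray(cells, dtype=bool)
        if mask.shape != (n, n):
            raise StructuralError(f"cells mask shape {mask.shape} != {(n, n)}")
        if (mask & ~common).any():
            raise ParameterError("cells mask includes unrecorded cells")
    if not mask.any():
        raise ParameterError("empty cell set")
    return mask


def rmse_normalized(
    Ma: ECAPMatrix | np.ndarray,
    Mb: ECAPMatrix | np.ndarray,
    cells=None,
    half_sweep_correction: bool = False,
    metric_name: str = "epsilon",
) -> ErrorReport:
    """Normalized cell-wise RMSE between two amplitude matrices, in percent.

    The normalizer is the maximum amplitude over the included cells of both
    matrices.  ``half_sweep_correction`` applies the 1/√2 factor for
    split-half (half-sweep) comparisons.
    """
    Ma, Mb = _as_matrix(Ma), _as_matrix(Mb)
    mask = _resolve_cells(Ma, Mb, cells)
    a, b = Ma.values[mask], Mb.values[mask]
    normalizer = float(max(a.max(), b.max()))
    if normalizer <= 0:
        raise DegenerateInputError("zero normalizer: all included amplitudes are 0")
    factor = HALF_SWEEP_FACTOR if half_sweep_correction else 1.0
    value = factor * float(np.sqrt(np.mean((a - b) ** 2))) / normalizer
    return ErrorReport(
        metric_name=metric_name,
        value=value,
        percent=100.0 * value,
        normalizer=normalizer,
        n_cells=int(mask.sum()),
        half_sweep_correction=half_sweep_correction,
    )


def epsilon_within(M1, M2, half_sweep_correction: bool = False, cells=None,
                   metric_name: str | None = None) -> ErrorReport:
    """Within-condition repeatability ε between two repeats of one method.

    Use ``half_sweep_correction=True`` when the repeats are the two
    half-sweep averages of a single recording (split-half design).
    """
    name = metric_name or ("epsilon_0" if half_sweep_correction else "epsilon_Sp")
    return rmse_normalized(M1, M2, cells=cells, half_sweep_correction=half_sweep_correction,
                           metric_name=name)


def epsilon_between(Ma, Mb, cells=None, metric_name: str = "epsilon_0Sp") -> ErrorReport:
    """Between-condition ε comparing two acquisition methods on full sweeps."""
    return rmse_normalized(Ma, Mb, cells=cells, half_sweep_correction=False, metric_name=metric_name)


def epsilon_sym(M_asym: ECAPMatrix | np.ndarray) -> ErrorReport:
    """Symmetry-assumption error: ε between a matrix and its symmetrized form."""
    M_asym = _as_matrix(M_asym)
    return rmse_normalized(M_asym, symmetrize(M_asym), metric_name="epsilon_sym")


def estimate_errors(
    est_a: ExcitationEstimate | np.ndarray,
    est_b: ExcitationEstimate | np.ndarray,
    eta_a: np.ndarray | None = None,
    eta_b: np.ndarray | None = None,
) -> tuple[ErrorReport, ErrorReport]:
    """RMS differences between two (σ, η) estimates: (εσ, εη).

    εσ is in electrode spacings and as percent of the 5-spacing parameter
    range; εη in η units and as percent of the unit range.  Accepts either
    two :class:`ExcitationEstimate` objects or explicit (σ, η) vectors.
    """
    if isinstance(est_a, ExcitationEstimate):
        sig_a, eta_a = est_a.sigma_hat, est_a.eta_hat_normalized
    else:
        sig_a = np.asarray(est_a, dtype=float)
        eta_a = np.asarray(eta_a, dtype=float)
    if isinstance(est_b, ExcitationEstimate):
        sig_b, eta_b = est_b.sigma_hat, est_b.eta_hat_normalized
    else:
        sig_b = np.asarray(est_b, dtype=float)
        eta_b = np.asarray(eta_b, dtype=float)
    if sig_a.shape != sig_b.shape or eta_a.shape != eta_b.shape:
        raise StructuralError("estimate lengths differ")
    eps_sigma = float(np.sqrt(np.mean((sig_a - sig_b) ** 2)))
    eps_eta = float(np.sqrt(np.mean((eta_a - eta_b) ** 2)))
    rep_sigma = ErrorReport("epsilon_sigma", eps_sigma, 100.0 * eps_sigma / SIGMA_RANGE,
                            SIGMA_RANGE, sig_a.size)
    rep_eta = ErrorReport("epsilon_eta", eps_eta, 100.0 * eps_eta / ETA_RANGE,
                          ETA_RANGE, eta_a.size)
    return rep_sigma, rep_eta


def mean_signed_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Mean of elementwise (a − b); positive means ``a`` is larger on average.

    Distinguishes systematic over/under-estimation from the unsigned RMS
    errors: antisymmetric differences cancel here but not in εσ/εη.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StructuralError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(a - b))


def demeaned_correlation(groups) -> tuple[float, int, float]:
    """Pooled within-participant Pearson correlation.

    Each element of ``groups`` is an ``(x, y)`` pair of equal-length vectors
    for one participant.  Both vectors are demeaned within participant,
    pooled, and correlated — removing between-participant offsets so the
    correlation reflects within-participant covariation only.

    Returns ``(r, df, p)`` with ``df = N_pooled − 2`` and a two-sided p
    from the t distribution.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ParameterError("need >= 2 participants")
    xs, ys = [], []
    for x, y in groups:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise StructuralError("x and y lengths differ within a participant")
        xs.append(x - x.mean())
        ys.append(y - y.mean())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise ParameterError("need >= 3 pooled points")
    if np.allclose(x, 0) or np.allclose(y, 0):
        raise UndefinedCorrelationError("zero variance after demeaning")
    r, _ = stats.pearsonr(x, y)
    df = x.size - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), int(df), float(p)
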