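"""Generative overlap model of the ECAP amplitude matrix.

The panoramic-ECAP model explains the masker×probe amplitude matrix by two
per-electrode quantities:

* **current spread** σₑ — the standard deviation, in electrode spacings, of
  a Gaussian excitation profile centered on electrode ``e`` (bounded to
  [1, 6] spacings), and
* **neural health** ηₑ — the relative responsiveness (0–1) of the neurons
  near electrode ``e``.

Each electrode's excitation pattern is the Gaussian row of the spread
matrix ``C`` multiplied pointwise by η.  A forward-masked ECAP reflects the
neurons excited by *both* the masker and the probe, so the predicted
amplitude for probe ``p`` and masker ``m`` is the summed pointwise minimum
of the two excitation patterns.  Predicted matrices are reported
max-normalized: η carries relative, not absolute, amplitude information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError, StructuralError
from .matrix import ECAPMatrix

SIGMA_BOUNDS = (1.0, 6.0)
ETA_BOUNDS = (0.0, 1.0)


@dataclass
class ExcitationModel:
    """Per-electrode current spread and neural health on a cochlear grid.

    Parameters
    ----------
    sigma
        Current-spread SDs, electrode-spacing units, each in [1, 6].
    eta
        Neural-health values, each in [0, 1].
    oversample
        Spatial grid points per electrode spacing (>= 1).  η is linearly
        interpolated onto oversampled grids.
    """

    sigma: np.ndarray
    eta: np.ndarray
    oversample: int = 1

    def __post_init__(self):
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        if self.sigma.shape != self.eta.shape or self.sigma.ndim != 1:
            raise StructuralError(
                f"sigma and eta must be equal-length vectors, got {self.sigma.shape} and {self.eta.shape}"
            )
        lo, hi = SIGMA_BOUNDS
        if ((self.sigma < lo) | (self.sigma > hi)).any():
            raise ParameterError(f"sigma values must lie in [{lo}, {hi}]")
        lo, hi = ETA_BOUNDS
        if ((self.eta < lo) | (self.eta > hi)).any():
            raise ParameterError(f"eta values must lie in [{lo}, {hi}]")
        if self.oversample < 1 or int(self.oversample) != self.oversample:
            raise ParameterError(f"oversample must be a positive integer, got {self.oversample}")

    @property
    def n_electrodes(self) -> int:
        return self.sigma.size

    @property
    def positions(self) -> np.ndarray:
        """Electrode positions: 1..n in electrode-spacing units."""
        return np.arange(1, self.n_electrodes + 1, dtype=float)

    @property
    def grid(self) -> np.ndarray:
        """Spatial grid, strictly increasing, spanning the electrode array."""
        n, g = self.n_electrodes, int(self.oversample)
        if g == 1:
            return self.positions
        return np.linspace(1.0, float(n), (n - 1) * g + 1)

    @property
    def eta_grid(self) -> np.ndarray:
        """η sampled (linearly interpolated) on the spatial grid."""
        if self.oversample == 1:
            return self.eta
        return np.interp(self.grid, self.positions, self.eta)


def gaussian_current_spread(
    sigma: np.ndarray, grid: np.ndarray | None = None, positions: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian spread matrix C: one unit-peak Gaussian row per electrode.

    ``C[e, x] = exp(-(grid[x] - pos_e)² / (2 σₑ²))``.  Rows peak at 1 over
    their electrode position and are truncated at the grid bounds without
    renormalization.
    """
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    lo, hi = SIGMA_BOUNDS
    if ((sigma < lo) | (sigma > hi)).any():
        raise ParameterError(f"sigma values must lie in [{lo}, {hi}]")
    if positions is None:
        positions = np.arange(1, sigma.size + 1, dtype=float)
    if grid is None:
        grid = positions
    grid = np.asarray(grid, dtype=float)
    if (np.diff(grid) <= 0).any():
        raise StructuralError("grid must be strictly increasing")
    d = grid[None, :] - np.asarray(positions, dtype=float)[:, None]
    return np.exp(-(d**2) / (2.0 * sigma[:, None] ** 2))


def excitation_patterns(C: np.ndarray, eta_grid: np.ndarray) -> np.ndarray:
    """Excitation matrix A: each spread row scaled pointwise by η.

    ``A[e, x] = C[e, x] · η_grid[x]``.
    """
    C = np.asarray(C, dtype=float)
    eta_grid = np.asarray(eta_grid, dtype=float)
    if C.ndim != 2 or eta_grid.ndim != 1 or C.shape[1] != eta_grid.size:
        raise StructuralError(
            f"grid-length mismatch: C is {C.shape}, eta_grid has {eta_grid.size} points"
        )
    return C * eta_grid[None, :]


def overlap_matrix(A: np.ndarray) -> np.ndarray:
    """Raw predicted matrix: summed pointwise minimum of excitation patterns.

    ``raw[p, m] = Σ_x min(A[p, x], A[m, x])`` — the neural population
    excited by both the probe and the masker.  Symmetric by construction.
    """
    A = np.asarray(A, dtype=float)
    # (n, n, g) pairwise minima; n <= 22 so memory is trivial.
    return np.minimum(A[:, None, :], A[None, :, :]).sum(axis=2)


def predict_matrix(model: ExcitationModel, normalize: bool = True) -> ECAPMatrix:
    """Predicted ECAP amplitude matrix for a current-spread/health model.

    Returns a symmetric matrix in normalized units (max 1) whose diagonal
    weakly dominates its row and column.

    Raises
    ------
    DegenerateInputError
        If η is identically zero (normalization undefined).
    """
    C = gaussian_current_spread(model.sigma, grid=model.grid, positions=model.positions)
    A = excitation_patterns(C, model.eta_grid)
    raw = overlap_matrix(A)
    if normalize:
        mx = raw.max()
        if mx <= 0:
            raise DegenerateInputError("all-zero eta: predicted matrix cannot be normalized")
        raw = raw / mx
    return ECAPMatrix(raw, meta={"units": "normalized" if normalize else "raw overlap"})
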