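"""The ECAP amplitude matrix container.

An n×n matrix ``M`` holds P2-N1 ECAP amplitudes with rows indexed by probe
electrode and columns by masker electrode.  Acquisition modes record
different subsets of cells — the full matrix, the diagonal plus one
triangle (the fast half-matrix mode), or the diagonal only (intraoperative
screening) — tracked by a boolean ``recorded_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import StructuralError


@dataclass
class ECAPMatrix:
    """n×n matrix of ECAP amplitudes with a recorded-cell mask.

    Parameters
    ----------
    values
        Amplitudes (µV or normalized units); entries at unrecorded cells
        are ignored (conventionally NaN or 0).
    recorded_mask
        Boolean matrix, True where a cell was actually measured.  Defaults
        to all-True.
    meta
        Free-form metadata (participant id, sweeps, units, ...).
    """

    values: np.ndarray
    recorded_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise StructuralError(f"values must be square, got shape {self.values.shape}")
        n = self.values.shape[0]
        if self.recorded_mask is None:
            self.recorded_mask = np.ones((n, n), dtype=bool)
        else:
            self.recorded_mask = np.asarray(self.recorded_mask, dtype=bool)
            if self.recorded_mask.shape != (n, n):
                raise StructuralError(
                    f"recorded_mask shape {self.recorded_mask.shape} != values shape {(n, n)}"
                )
        rec = self.values[self.recorded_mask]
        if rec.size and not np.all(np.isfinite(rec)):
            raise StructuralError("recorded cells must be finite")
        if rec.size and (rec < 0).any():
            raise StructuralError("recorded ECAP amplitudes must be >= 0")

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def is_full(self) -> bool:
        return bool(self.recorded_mask.all())

    def is_half(self) -> bool:
        """True when the recorded cells are exactly the diagonal plus one triangle."""
        m = self.recorded_mask
        upper = np.triu(np.ones_like(m))
        lower = np.tril(np.ones_like(m))
        return bool(np.array_equal(m, upper.astype(bool)) or np.array_equal(m, lower.astype(bool)))

    def is_symmetric(self, rtol: float = 1e-9) -> bool:
        """True when mask and recorded values are symmetric across the diagonal."""
        if not np.array_equal(self.recorded_mask, self.recorded_mask.T):
            return False
        both = self.recorded_mask & self.recorded_mask.T
        a, b = self.values[both], self.values.T[both]
        scale = max(np.abs(a).max(initial=0.0), 1e-30)
        return bool(np.allclose(a, b, rtol=rtol, atol=rtol * scale))

    def max_recorded(self) -> float:
        return float(self.values[self.recorded_mask].max())

    def normalized(self) -> "ECAPMatrix":
        """Copy with recorded values divided by the maximum recorded amplitude."""
        from .errors import DegenerateInputError

        mx = self.max_recorded()
        if mx <= 0:
            raise DegenerateInputError("cannot normalize: maximum recorded amplitude is 0")
        vals = self.values / mx
        return ECAPMatrix(vals, self.recorded_mask.copy(), dict(self.meta, normalized_by=mx))

    def copy(self) -> "ECAPMatrix":
        return ECAPMatrix(self.values.copy(), self.recorded_mask.copy(), dict(self.meta))


def half_mask(n: int, triangle: str = "upper", include_diagonal: bool = True) -> np.ndarray:
    """Boolean mask covering the diagonal plus one triangle of an n×n matrix."""
    if triangle not in ("upper", "lower"):
        raise ValueError(f"triangle must be 'upper' or 'lower', got {triangle!r}")
    m = np.triu(np.ones((n, n), dtype=bool), k=0 if include_diagonal else 1)
    return m.T if triangle == "lower" else m


def diagonal_mask(n: int) -> np.ndarray:
    """Boolean mask covering only the diagonal of an n×n matrix."""
    return np.eye(n, dtype=bool)
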