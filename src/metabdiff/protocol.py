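"""Diffusion acquisition protocol: b-values, encoding directions, timings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 6 b-values of the tetrahedral semi-LASER protocol, ms/um^2
DEFAULT_B_VALUES = (0.01, 1.012, 4.03, 9.06, 16.09, 25.1)

_TETRA_RAW = np.array(
    [[-1, -1, -1], [-1, 1, 1], [1, -1, 1], [1, 1, -1]], dtype=float
)
DEFAULT_DIRECTIONS = tuple(
    tuple(v) for v in _TETRA_RAW / np.linalg.norm(_TETRA_RAW, axis=1)[:, None]
)


@dataclass(frozen=True)
class DiffusionProtocol:
    """Acquisition design for a diffusion-weighted MRS experiment.

    Parameters
    ----------
    b_values : tuple of float
        Diffusion weightings in ms/um^2, strictly increasing, all >= 0.
    directions : tuple of unit vectors
        Gradient encoding directions (default: 4 tetrahedral vertices).
    delta_eff : float
        Effective gradient duration in ms.
    Delta_eff : float
        Effective gradient separation in ms.
    transients_per_condition : int
        Number of individually stored transients per (b, direction).
    """

    b_values: tuple = DEFAULT_B_VALUES
    directions: tuple = DEFAULT_DIRECTIONS
    delta_eff: float = 26.4
    Delta_eff: float = 62.5
    transients_per_condition: int = 24

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size == 0:
            raise ValueError("protocol needs at least one b-value")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        for d in self.directions:
            if abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise ValueError(f"direction {d} is not a unit vector")
        if self.transients_per_condition < 1:
            raise ValueError("transients_per_condition must be positive")

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)
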