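"""Shared container for position-sweep surfaces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SweepSurface"]


@dataclass(frozen=True)
class SweepSurface:
    """Normalized total pressure loss over a grid of crossvein positions.

    ``values[i, j]`` is Δp_total(a_values[i], p_values[j]) divided by the
    crossvein-absent loss ``baseline_loss``; cells whose network could not
    be solved are NaN.  Axis names follow the wing convention (a: anterior
    connection fraction, p: posterior); the idealized circuits reuse the
    container with (u, v).
    """

    a_values: np.ndarray
    p_values: np.ndarray
    values: np.ndarray
    baseline_loss: float

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.a_values), len(self.p_values)):
            raise ValueError("surface shape does not match its grids")

    def argmin(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmin(self.values), self.values.shape)
        return float(self.a_values[i]), float(self.p_values[j])

    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmax(self.values), self.values.shape)
        return float(self.a_values[i]), float(self.p_values[j])

    def argmin_along_p(self) -> np.ndarray:
        """For each a, the p minimizing the normalized loss."""
        return self.p_values[np.nanargmin(self.values, axis=1)]

    def profile_at_a(self, a: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.a_values - a)))
        return self.values[i]
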