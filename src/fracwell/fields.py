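"""Complex-valued fields sampled on uniform 1-D grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["GridField", "uniform_grid"]


def uniform_grid(l: float, n_points: int) -> np.ndarray:
    """A uniform grid of ``n_points`` covering [−l, l], walls included."""
    if n_points < 3:
        raise InvalidInputError(f"need at least 3 grid points, got {n_points}")
    return np.linspace(-l, l, n_points)


@dataclass
class GridField:
    """A complex field sampled on a strictly increasing uniform grid.

    Used for wavefunctions ψ, densities ρ, currents J and complex velocity
    fields.  Wavefunction-role fields vanish at the walls (hard-wall
    boundary); that contract is enforced by the consumers that require it,
    not by the container.
    """

    z: np.ndarray
    values: np.ndarray
    time_stamp: float = 0.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.z.ndim != 1 or self.z.size < 3:
            raise InvalidInputError("grid must be 1-D with at least 3 points")
        if self.values.shape != self.z.shape:
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match grid {self.z.shape}"
            )
        steps = np.diff(self.z)
        if np.any(steps <= 0):
            raise InvalidInputError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-12, atol=0.0):
            raise InvalidInputError("grid must be uniform to machine precision")

    @property
    def h(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def n(self) -> int:
        return self.z.size

    def norm(self) -> float:
        """L² norm by the trapezoid rule."""
        return float(np.sqrt(np.trapezoid(np.abs(self.values) ** 2, self.z)))

    def same_grid(self, other: "GridField") -> bool:
        return self.z.shape == other.z.shape and bool(np.allclose(self.z, other.z))

    def copy_with(self, values: np.ndarray, time_stamp: float | None = None) -> "GridField":
        return GridField(
            z=self.z.copy(),
            values=np.asarray(values, dtype=complex),
            time_stamp=self.time_stamp if time_stamp is None else time_stamp,
        )
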