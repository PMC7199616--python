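"""Fractal increment statistics and the scale-covariant derivative.

The coordinate differential splits into a differentiable part and a fractal
fluctuation d±ξ with ⟨d±ξ⟩ = 0 and, in the isotropic Markov realization,
⟨d±ξ²⟩ = 2·λ·dt^(2/DF).  The fluctuations are realized here as zero-mean
Gaussians: the model's covariance law requires finite second moments, and the
Gaussian is the unique stable law with finite variance, which keeps every
moment test sharp.

The scale-covariant derivative replaces d/dt so the motion laws keep their
form across scale resolutions.  In the isotropic 1-D reduction it reads

    d̂Q/dt = ∂t Q + V·∂z Q − i·D_coef·∂zz Q,

with complex velocity V and D_coef = λ·dt^(2/DF−1).  The general constant
anisotropic tensor version (coefficients d, d̄ with D = d − i·d̄) is exposed
through the optional ``tensor`` argument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fields import GridField
from .scale import FractalScale, derive_coefficients

__all__ = [
    "PathEnsemble",
    "sample_increments",
    "estimate_DF",
    "covariant_derivative",
]

Direction = Literal["forward", "backward"]


@dataclass(frozen=True)
class PathEnsemble:
    """A seeded ensemble of fractal increments d±ξ.

    ``increments[i, j]`` is the fluctuation of path ``i`` over one step at
    resolution ``dt_values[j]``; each column is i.i.d. N(0, 2·λ·dt^(2/DF)).
    """

    n_paths: int
    dt_values: np.ndarray
    increments: np.ndarray
    direction: Direction
    seed: int
    scale: FractalScale = field(repr=False)

    def __post_init__(self) -> None:
        if self.increments.shape != (self.n_paths, len(self.dt_values)):
            raise InvalidInputError(
                f"increments shape {self.increments.shape} inconsistent with "
                f"(n_paths={self.n_paths}, n_dt={len(self.dt_values)})"
            )

    def theoretical_variance(self) -> np.ndarray:
        """Per-column second moment 2·λ·dt^(2/DF) of the isotropic Markov law."""
        return 2.0 * self.scale.lam * self.dt_values ** (2.0 / self.scale.DF)

    def sample_mean(self) -> np.ndarray:
        return self.increments.mean(axis=0)

    def sample_second_moment(self) -> np.ndarray:
        return np.mean(self.increments**2, axis=0)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write long-format CSV (path_id, step, dt, increment) + JSON metadata."""
        path = Path(path)
        n, m = self.increments.shape
        frame = pd.DataFrame(
            {
                "path_id": np.repeat(np.arange(n), m),
                "step": np.tile(np.arange(m), n),
                "dt": np.tile(self.dt_values, n),
                "increment": self.increments.ravel(),
            }
        )
        frame.to_csv(path, index=False)
        if sidecar:
            meta = {
                "seed": self.seed,
                "lam": self.scale.lam,
                "DF": self.scale.DF,
                "direction": self.direction,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def sample_increments(
    scale: FractalScale,
    dt_values: Sequence[float],
    n_paths: int,
    direction: Direction = "forward",
    seed: int = 0,
) -> PathEnsemble:
    """Draw a seeded ensemble of fractal fluctuations d±ξ.

    The forward branch corresponds to dt > 0 and the backward branch to
    dt < 0; both share identical magnitude statistics, so the direction is a
    bookkeeping flag on the ensemble.
    """
    dt_arr = np.asarray(dt_values, dtype=float)
    if dt_arr.size == 0:
        raise InvalidInputError("dt_values must be non-empty")
    if np.any(dt_arr <= 0):
        raise InvalidInputError("all dt_values must be > 0")
    if n_paths < 1:
        raise InvalidInputError(f"n_paths must be >= 1, got {n_paths}")
    if direction not in ("forward", "backward"):
        raise InvalidInputError(f"direction must be 'forward' or 'backward', got {direction!r}")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * scale.lam * dt_arr ** (2.0 / scale.DF))
    increments = rng.standard_normal((n_paths, dt_arr.size)) * sigma
    return PathEnsemble(
        n_paths=n_paths,
        dt_values=dt_arr,
        increments=increments,
        direction=direction,
        seed=seed,
        scale=scale,
    )


def estimate_DF(ensemble: PathEnsemble) -> float:
    """Recover the fractal dimension from the increment scaling law.

    Fits log⟨dξ²⟩ against log dt by least squares; the second-moment law
    ⟨dξ²⟩ ∝ dt^(2/DF) makes the slope 2/DF, so the estimate is 2/slope.
    Reliable recovery needs ≥ 4 distinct dt values spanning at least a
    decade.
    """
    dt = ensemble.dt_values
    if np.unique(dt).size < 2:
        raise InvalidInputError("estimate_DF needs at least 2 distinct dt values")
    m2 = ensemble.sample_second_moment()
    slope = np.polyfit(np.log(dt), np.log(m2), 1)[0]
    return 2.0 / slope


def covariant_derivative(
    Q: GridField,
    V: GridField,
    scale: FractalScale,
    time_derivative: GridField | None = None,
    tensor: tuple[float, float] | None = None,
) -> GridField:
    """Apply the scale-covariant derivative d̂/dt to a field on a uniform grid.

    Returns ∂tQ + V·∂zQ − i·D_coef·∂zzQ with centered second-order
    differences on interior points; the two boundary points are flagged NaN
    (undefined under a centered stencil).  ``tensor=(d, dbar)`` selects the
    constant anisotropic coefficient ¼·dt^(2/DF−1)·(d − i·d̄) in place of the
    isotropic −i·λ·dt^(2/DF−1); the isotropic case is ``(0, 4λ)``.
    """
    if Q.z.shape != V.z.shape or not np.allclose(Q.z, V.z):
        raise InvalidInputError("Q and V must share one uniform grid")
    if time_derivative is not None and (
        time_derivative.z.shape != Q.z.shape or not np.allclose(time_derivative.z, Q.z)
    ):
        raise InvalidInputError("time_derivative must share Q's grid")

    coeffs = derive_coefficients(scale)
    h = Q.h
    q = Q.values
    dq = np.full_like(q, np.nan + 0j)
    d2q = np.full_like(q, np.nan + 0j)
    dq[1:-1] = (q[2:] - q[:-2]) / (2.0 * h)
    d2q[1:-1] = (q[2:] - 2.0 * q[1:-1] + q[:-2]) / h**2

    if tensor is None:
        second_coef = -1j * coeffs.D_coef
    else:
        d_aniso, dbar_aniso = tensor
        prefac = 0.25 * scale.dt_res ** (2.0 / scale.DF - 1.0)
        second_coef = prefac * (d_aniso - 1j * dbar_aniso)

    out = V.values * dq + second_coef * d2q
    if time_derivative is not None:
        out = out + time_derivative.values
    out[0] = out[-1] = np.nan + 0j
    return GridField(z=Q.z.copy(), values=out, time_stamp=Q.time_stamp)
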