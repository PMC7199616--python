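"""Fractal scale-resolution parameters and derived effective coefficients.

The model describes motion on continuous, nowhere-differentiable trajectories
whose increments scale as ``dt**(1/DF)`` with the scale resolution ``dt``.
Four parameters fix a scale regime:

``m0``
    rest mass of the particle (arbitrary mass unit),
``lam``
    the fractal/non-fractal transition coefficient λ,
``dt_res``
    the scale resolution dt at which dynamics are observed,
``DF``
    the fractal dimension of the motion curves; ``DF = 2`` is the coherence
    regime (Wiener-like scaling) in which the scale machinery reduces to
    standard diffusion-type coefficients.

Everything downstream only needs three derived combinations:

``D_coef = lam * dt_res**(2/DF - 1)``
    the complex-diffusion coefficient multiplying second derivatives,
``hbar_eff = 2 * m0 * D_coef``
    the effective action quantum (Planck-constant analogue),
``mu = 2 * m0 * D_coef**2 = hbar_eff**2 / (2*m0)``
    the kinetic coefficient of the stationary eigenproblem
    ``-mu * theta'' + U * theta = E * theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["FractalScale", "EffectiveCoefficients", "derive_coefficients"]


@dataclass(frozen=True)
class FractalScale:
    """Scale-resolution parameters (m0, λ, dt, D_F), all strictly positive."""

    m0: float
    lam: float
    dt_res: float
    DF: float

    def __post_init__(self) -> None:
        for name in ("m0", "lam", "dt_res", "DF"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"FractalScale.{name} must be finite and > 0, got {value!r}"
                )

    @property
    def D_coef(self) -> float:
        """λ·dt^(2/DF − 1); at DF = 2 this equals λ for every dt_res."""
        return self.lam * self.dt_res ** (2.0 / self.DF - 1.0)

    @property
    def hbar_eff(self) -> float:
        return 2.0 * self.m0 * self.D_coef

    @property
    def mu(self) -> float:
        return 2.0 * self.m0 * self.D_coef**2


@dataclass(frozen=True)
class EffectiveCoefficients:
    """The derived triple (D_coef, hbar_eff, mu) that all solvers consume.

    May be built from a :class:`FractalScale` (see :func:`derive_coefficients`)
    or directly from (mu, hbar_eff) when the microscopic parameters are not of
    interest; the identity ``mu = hbar_eff * D_coef`` fixes the third member.
    """

    D_coef: float
    hbar_eff: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("D_coef", "hbar_eff", "mu"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"EffectiveCoefficients.{name} must be finite and > 0, got {value!r}"
                )

    @classmethod
    def from_mu_hbar(cls, mu: float, hbar_eff: float) -> "EffectiveCoefficients":
        if not (math.isfinite(mu) and mu > 0):
            raise InvalidParameterError(f"mu must be finite and > 0, got {mu!r}")
        if not (math.isfinite(hbar_eff) and hbar_eff > 0):
            raise InvalidParameterError(f"hbar_eff must be finite and > 0, got {hbar_eff!r}")
        return cls(D_coef=mu / hbar_eff, hbar_eff=hbar_eff, mu=mu)

    @property
    def m0_implied(self) -> float:
        """Rest mass consistent with (mu, hbar_eff): hbar_eff²/(2·mu)."""
        return self.hbar_eff**2 / (2.0 * self.mu)


def derive_coefficients(scale: FractalScale | EffectiveCoefficients) -> EffectiveCoefficients:
    """Derive (D_coef, hbar_eff, mu) from a scale-parameter set.

    Satisfies ``mu == hbar_eff**2 / (2*m0)`` to machine precision; passing an
    :class:`EffectiveCoefficients` through is the identity, which lets every
    solver accept either parameterization.
    """
    if isinstance(scale, EffectiveCoefficients):
        return scale
    return EffectiveCoefficients(
        D_coef=scale.D_coef, hbar_eff=scale.hbar_eff, mu=scale.mu
    )
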