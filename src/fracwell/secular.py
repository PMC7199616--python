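"""Stationary double-well tunneling eigenproblem and the LDL/HDL doublet.

The effective potential is a symmetric square double well: hard walls at
z = ±l, a barrier of height V0 on |z| < d, and flat wells on d ≤ |z| < l.
The stationary equation is

    -mu * theta''(z) + U(z) * theta(z) = E * theta(z),

with mu = 2·m0·λ²·dt^(4/DF−2).  Sub-barrier states (0 < E < V0) oscillate in
the wells with wavenumber k = sqrt(E/mu) and decay under the barrier with
q = sqrt((V0−E)/mu).  Matching values and derivatives at z = ±d forces the
interior coefficient ratio ρ = C/B to ρ² = 1, splitting the spectrum into a
symmetric (ρ = +1, interior ∝ cosh qz) and an antisymmetric (ρ = −1,
interior ∝ sinh qz) family with secular equations

    tan(k(l−d)) = −(k/q)·coth(qd)   (symmetric),
    tan(k(l−d)) = −(k/q)·tanh(qd)   (antisymmetric).

The lowest root of each family forms the tunneling doublet (E_S, E_A): the
splitting ΔE = E_A − E_S collapses as the barrier grows (independent wells)
and the state-transfer times τ_X = hbar_eff / E_X obey

    E_A / E_S = τ_S / τ_A > 1,

the model's identification of the slow symmetric state with LDL and the
fast antisymmetric state with HDL.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    MatchingInconsistencyError,
    NoSubBarrierStateError,
    OutOfRangeError,
)
from .scale import EffectiveCoefficients, FractalScale, derive_coefficients

__all__ = [
    "DoubleWellGeometry",
    "WaveNumbers",
    "StationaryState",
    "TunnelingDoublet",
    "wavenumbers",
    "secular_residual",
    "solve_matching_ratio",
    "solve_doublet",
    "assemble_state",
    "transfer_times",
    "splitting_sweep",
    "degeneracy_ratio",
]

Parity = Literal["symmetric", "antisymmetric"]
_PARITIES = ("symmetric", "antisymmetric")


@dataclass(frozen=True)
class DoubleWellGeometry:
    """Square double well: hard walls at ±l, barrier V0 on |z| < d."""

    l: float
    d: float
    V0: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.l) and self.l > 0):
            raise InvalidParameterError(f"l must be finite and > 0, got {self.l!r}")
        if not (math.isfinite(self.d) and 0 <= self.d < self.l):
            raise InvalidParameterError(f"d must satisfy 0 <= d < l, got d={self.d!r}, l={self.l!r}")
        if not (math.isfinite(self.V0) and self.V0 > 0):
            raise InvalidParameterError(f"V0 must be finite and > 0, got {self.V0!r}")

    def potential(self, z: np.ndarray) -> np.ndarray:
        """U(z): +inf beyond the walls, V0 inside the barrier, 0 in the wells."""
        z = np.asarray(z, dtype=float)
        out = np.where(np.abs(z) < self.d, self.V0, 0.0)
        return np.where(np.abs(z) >= self.l, np.inf, out)

    @property
    def well_width(self) -> float:
        return self.l - self.d


@dataclass(frozen=True)
class WaveNumbers:
    """Oscillatory (k) and evanescent (q) wavenumbers; k² + q² = V0/mu."""

    k: float
    q: float


def wavenumbers(E: float, geometry: DoubleWellGeometry, mu: float) -> WaveNumbers:
    """k = sqrt(E/mu), q = sqrt((V0−E)/mu) for a sub-barrier energy.

    Above-barrier energies are rejected: the construction assumes an
    evanescent interior solution.
    """
    if mu <= 0:
        raise InvalidParameterError(f"mu must be > 0, got {mu!r}")
    if E < 0 or E > geometry.V0:
        raise OutOfRangeError(
            f"E must lie in [0, V0]={[0, geometry.V0]}, got {E!r} "
            "(above-barrier states unsupported)"
        )
    return WaveNumbers(k=math.sqrt(E / mu), q=math.sqrt((geometry.V0 - E) / mu))


def secular_residual(
    E: float | np.ndarray,
    geometry: DoubleWellGeometry,
    mu: float,
    parity: Parity,
) -> float | np.ndarray:
    """Pole-free secular residual; zero exactly at eigenenergies of ``parity``.

    The tan/coth forms have poles, so the residuals are the cleared,
    cosh-normalized combinations

        F_sym  = q·tanh(qd)·sin(k(l−d)) + k·cos(k(l−d)),
        F_anti = q·sin(k(l−d)) + k·tanh(qd)·cos(k(l−d)),

    which share roots and signs with the cleared-denominator forms but stay
    bounded for arbitrarily large q·d.  At d = 0 they reduce to the
    barrierless-box conditions k·cos(kl) and q·sin(kl).
    """
    if parity not in _PARITIES:
        raise InvalidInputError(f"parity must be one of {_PARITIES}, got {parity!r}")
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr <= 0) or np.any(E_arr >= geometry.V0):
        raise OutOfRangeError("secular_residual requires 0 < E < V0")
    k = np.sqrt(E_arr / mu)
    q = np.sqrt((geometry.V0 - E_arr) / mu)
    w = geometry.well_width
    t = np.tanh(q * geometry.d)
    if parity == "symmetric":
        res = q * t * np.sin(k * w) + k * np.cos(k * w)
    else:
        res = q * np.sin(k * w) + k * t * np.cos(k * w)
    return float(res) if np.isscalar(E) else res


def solve_matching_ratio(
    k: float, q: float, geometry: DoubleWellGeometry
) -> tuple[float, float]:
    """Solve the interface consistency equation for the ratio ρ = C/B.

    Dividing the value-matching by the derivative-matching equation at each
    interface and summing gives

        (a·ρ+1)/(a·ρ−1) + (ρ/a+1)/(ρ/a−1) = 0,   a = exp(2qd),

    which is solved here numerically by bracketing sign changes away from
    the poles ρ = 1/a and ρ = a.  The two admissible ratios are +1
    (symmetric) and −1 (antisymmetric); the returned pair is the numerically
    found root set, ordered (+1, −1).
    """
    if q <= 0:
        raise InvalidInputError(f"q must be > 0, got {q!r}")
    if geometry.d <= 0:
        raise InvalidInputError("matching-ratio equation needs d > 0 (q·d > 0)")
    two_qd = 2.0 * q * geometry.d
    a = math.exp(min(two_qd, 700.0))

    def g(rho: float) -> float:
        return (a * rho + 1.0) / (a * rho - 1.0) + (rho / a + 1.0) / (rho / a - 1.0)

    poles = sorted({1.0 / a, a})
    # Scan [-5, 5] excluding pole neighbourhoods; g is smooth elsewhere.
    edges = [-5.0]
    for p in poles:
        if -5.0 < p < 5.0:
            edges.extend([p - 1e-9 * max(1.0, abs(p)), p + 1e-9 * max(1.0, abs(p))])
    edges.append(5.0)
    # Even-indexed pairs are the pole-free intervals; odd pairs straddle a pole.
    intervals = [(edges[i], edges[i + 1]) for i in range(0, len(edges) - 1, 2)]
    roots: list[float] = []
    for lo, hi in intervals:
        grid = np.linspace(lo, hi, 801)
        vals = np.array([g(r) for r in grid])
        sign = np.sign(vals)
        # a scan point may land exactly on a root (g == 0 in floating point)
        roots.extend(grid[vals == 0.0])
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        for i in idx:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16))
    # deduplicate near-coincident finds (an exact zero next to a bracketed root)
    roots = sorted(roots, reverse=True)
    deduped: list[float] = []
    for r in roots:
        if not deduped or abs(r - deduped[-1]) > 1e-6:
            deduped.append(r)
    roots = deduped
    if len(roots) != 2:
        raise MatchingInconsistencyError(
            f"expected exactly two admissible ratios, found {roots}"
        )
    return roots[0], roots[1]


def _lowest_root(geometry: DoubleWellGeometry, mu: float, parity: Parity) -> float:
    """Lowest sub-barrier root of the secular residual, polished to ~1e−12 rel."""
    V0 = geometry.V0
    eps = 1e-9 * V0
    # Roots are ~uniform in k (spacing ~pi/(l-d)), so scan uniformly in k with
    # at least 8 points per oscillation; a uniform-in-E scan aliases for large V0.
    k_lo, k_hi = math.sqrt(eps / mu), math.sqrt((V0 - eps) / mu)
    n_scan = max(400, 8 * math.ceil(k_hi * geometry.well_width / math.pi))
    grid = mu * np.linspace(k_lo, k_hi, n_scan) ** 2
    vals = secular_residual(grid, geometry, mu, parity)
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise NoSubBarrierStateError(
            parity,
            f"no sign change of the {parity} secular residual in (0, V0) for {geometry}",
        )
    i = int(idx[0])
    f = lambda E: secular_residual(E, geometry, mu, parity)
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-300, rtol=8.9e-16))


@dataclass(frozen=True)
class TunnelingDoublet:
    """The lowest symmetric/antisymmetric pair and its transfer times.

    ``E0_ref`` is the unsplit reference level, taken as the barrierless-box
    ground energy mu·(π/2l)²; ``q0`` the evanescent wavenumber evaluated at
    that level (NaN when E0_ref ≥ V0).  τ_X = hbar_eff/E_X per the model's
    energy–transfer-time relation, so E_A/E_S = τ_S/τ_A.
    """

    E_S: float
    E_A: float
    delta_E: float
    E0_ref: float
    q0: float
    tau_S: float
    tau_A: float
    ratio: float
    geometry: DoubleWellGeometry
    coefficients: EffectiveCoefficients = field(repr=False)


def solve_doublet(
    geometry: DoubleWellGeometry,
    scale: FractalScale | EffectiveCoefficients,
) -> TunnelingDoublet:
    """Solve for the lowest sub-barrier doublet (E_S, E_A).

    Each secular residual is scanned on 400 points in (0, V0), bracketed at
    its first sign change and polished by Brent's method to ~1e−12 relative.
    Raises :class:`NoSubBarrierStateError` if either parity has no
    sub-barrier root (barrier too low / wells too narrow).
    """
    coeffs = derive_coefficients(scale)
    mu, hbar = coeffs.mu, coeffs.hbar_eff
    E_S = _lowest_root(geometry, mu, "symmetric")
    E_A = _lowest_root(geometry, mu, "antisymmetric")
    E0_ref = mu * (math.pi / (2.0 * geometry.l)) ** 2
    q0 = math.sqrt((geometry.V0 - E0_ref) / mu) if geometry.V0 > E0_ref else float("nan")
    return TunnelingDoublet(
        E_S=E_S,
        E_A=E_A,
        delta_E=E_A - E_S,
        E0_ref=E0_ref,
        q0=q0,
        tau_S=hbar / E_S,
        tau_A=hbar / E_A,
        ratio=E_A / E_S,
        geometry=geometry,
        coefficients=coeffs,
    )


@dataclass(frozen=True)
class StationaryState:
    """One parity eigenstate of the double well, normalized to unit L² norm.

    The profile is piecewise:

        θ₁(z) = A·sin(k(z+l))        on −l ≤ z ≤ −d,
        θ₂(z) = B·e^{qz} + C·e^{−qz} on |z| ≤ d,
        θ₃(z) = D·sin(k(z−l))        on  d ≤ z ≤ l,

    with C/B = +1 and A = −D for the symmetric family, C/B = −1 and A = D
    for the antisymmetric one.  Evaluation of the interior uses the
    numerically stable parity form (cosh/sinh ratios) equivalent to the
    exponential amplitudes.
    """

    parity: Parity
    E: float
    wavenumbers: WaveNumbers
    A: float
    B: float
    C: float
    D: float
    norm: float
    geometry: DoubleWellGeometry
    mu: float

    def evaluate(self, z: np.ndarray | float) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        g = self.geometry
        k, q = self.wavenumbers.k, self.wavenumbers.q
        out = np.zeros_like(z)
        left = (z >= -g.l) & (z <= -g.d)
        right = (z >= g.d) & (z <= g.l)
        mid = np.abs(z) < g.d
        out[left] = self.A * np.sin(k * (z[left] + g.l))
        out[right] = self.D * np.sin(k * (z[right] - g.l))
        if np.any(mid):
            edge = self.A * math.sin(k * g.well_width)  # θ value at z = −d
            zm = z[mid]
            if self.parity == "symmetric":
                # θ2 = edge·cosh(qz)/cosh(qd), written overflow-safely
                ratio = np.exp(q * (np.abs(zm) - g.d)) * (
                    (1.0 + np.exp(-2.0 * q * np.abs(zm))) / (1.0 + math.exp(-2.0 * q * g.d))
                )
                out[mid] = edge * ratio
            else:
                # θ2 = −edge·sinh(qz)/sinh(qd)  (θ(−d) = edge, odd interior)
                sign = np.sign(zm)
                ratio = np.exp(q * (np.abs(zm) - g.d)) * (
                    (1.0 - np.exp(-2.0 * q * np.abs(zm)))
                    / (1.0 - math.exp(-2.0 * q * g.d))
                )
                out[mid] = -edge * sign * ratio
        return out

    __call__ = evaluate


def _matching_defect(A: float, B: float, C: float, D: float,
                     k: float, q: float, geometry: DoubleWellGeometry) -> float:
    """Max relative defect of the four interface matching equations."""
    d, w = geometry.d, geometry.well_width
    s, c = math.sin(k * w), math.cos(k * w)
    eqd, emqd = math.exp(q * d), math.exp(-q * d)
    lhs = np.array([
        emqd * B + eqd * C,
        q * emqd * B - q * eqd * C,
        eqd * B + emqd * C,
        q * eqd * B - q * emqd * C,
    ])
    rhs = np.array([A * s, k * A * c, -D * s, k * D * c])
    scale_ref = max(abs(A) * (abs(s) + abs(c) * max(k, 1.0)), 1e-300)
    return float(np.max(np.abs(lhs - rhs)) / scale_ref)


def assemble_state(
    E: float,
    parity: Parity,
    geometry: DoubleWellGeometry,
    mu: float,
) -> StationaryState:
    """Build the normalized piecewise eigenfunction at an eigenenergy.

    The amplitudes are obtained from the z = −d matching pair with A as the
    free constant, checked against all four matching equations (relative
    defect ≤ 1e−9 required), normalized analytically to unit L² norm, and
    sign-fixed positive at the right-well midpoint z = (d+l)/2.
    """
    if parity not in _PARITIES:
        raise InvalidInputError(f"parity must be one of {_PARITIES}, got {parity!r}")
    wn = wavenumbers(E, geometry, mu)
    k, q = wn.k, wn.q
    if k == 0.0 or q == 0.0:
        raise MatchingInconsistencyError("E must lie strictly between 0 and V0")
    d, w = geometry.d, geometry.well_width
    s, c = math.sin(k * w), math.cos(k * w)

    A = 1.0
    # From the z=−d pair: B·e^{−qd} = (s + (k/q)c)/2, C·e^{qd} = (s − (k/q)c)/2.
    B = math.exp(min(q * d, 700.0)) * 0.5 * (s + (k / q) * c)
    C = math.exp(-q * d) * 0.5 * (s - (k / q) * c)
    D = -A if parity == "symmetric" else A

    if d > 0:
        defect = _matching_defect(A, B, C, D, k, q, geometry)
    else:
        # d = 0: interfaces coincide; the defect reduces to the secular residual.
        res = secular_residual(E, geometry, mu, parity)
        defect = abs(res) / max(k, q)
    if not defect <= 1e-9:
        raise MatchingInconsistencyError(
            f"E={E!r} is not a {parity} eigenenergy: matching defect {defect:.3e} > 1e-9"
        )

    # Analytic L² norm: wells contribute 2·A²·(w/2 − sin(2kw)/4k); the interior
    # cosh/sinh profile with edge value A·s contributes the stable forms below.
    I_well = A * A * (0.5 * w - math.sin(2.0 * k * w) / (4.0 * k))
    if d > 0:
        qd = q * d
        if parity == "symmetric":
            I_mid = (A * s) ** 2 * (d / math.cosh(min(qd, 350.0)) ** 2 + math.tanh(qd) / q)
        else:
            I_mid = (A * s) ** 2 * (
                1.0 / (q * math.tanh(qd)) - d / math.sinh(min(qd, 350.0)) ** 2
            )
    else:
        I_mid = 0.0
    norm = math.sqrt(2.0 * I_well + I_mid)

    A, B, C, D = (x / norm for x in (A, B, C, D))
    state = StationaryState(
        parity=parity, E=E, wavenumbers=wn, A=A, B=B, C=C, D=D,
        norm=1.0, geometry=geometry, mu=mu,
    )
    probe = float(state.evaluate(0.5 * (d + geometry.l))[0])
    if probe < 0:
        state = StationaryState(
            parity=parity, E=E, wavenumbers=wn, A=-A, B=-B, C=-C, D=-D,
            norm=1.0, geometry=geometry, mu=mu,
        )
    return state


def transfer_times(
    doublet: TunnelingDoublet,
    scale: FractalScale | EffectiveCoefficients | None = None,
) -> dict[str, float]:
    """State-transfer times τ_X = hbar_eff/E_X and the ratio τ_S/τ_A.

    The model's coherence condition for the LDL↔HDL transfer is DF = 2; a
    :class:`FractalScale` with DF ≠ 2 is accepted but flagged with a warning.
    The antisymmetric (HDL-labelled) state always has the shorter time.
    """
    if scale is None:
        coeffs = doublet.coefficients
    else:
        if isinstance(scale, FractalScale) and scale.DF != 2.0:
            warnings.warn(
                f"transfer times evaluated at DF={scale.DF}; the coherence "
                "condition of the state-transfer interpretation is DF=2",
                stacklevel=2,
            )
        coeffs = derive_coefficients(scale)
    hbar = coeffs.hbar_eff
    tau_S = hbar / doublet.E_S
    tau_A = hbar / doublet.E_A
    return {"tau_S": tau_S, "tau_A": tau_A, "ratio": tau_S / tau_A}


def splitting_sweep(
    geometries: Sequence[DoubleWellGeometry],
    scale: FractalScale | EffectiveCoefficients,
) -> pd.DataFrame:
    """Doublet table over a one-parameter family of geometries.

    All geometries must share l and vary exactly one of {V0, d}.  Columns:
    the varied parameter, E_S, E_A, delta_E, ratio; rows sorted by the
    varied parameter.  ΔE decreases as the barrier grows (higher V0 at fixed
    d > 0, or wider d at fixed V0): the independent-well limit removes the
    splitting.
    """
    geoms = list(geometries)
    if not geoms:
        raise InvalidInputError("empty geometry family")
    ls = {g.l for g in geoms}
    if len(ls) != 1:
        raise InvalidInputError(f"all geometries must share l, got {sorted(ls)}")
    ds = {g.d for g in geoms}
    v0s = {g.V0 for g in geoms}
    if len(ds) > 1 and len(v0s) > 1:
        raise InvalidInputError("family must vary exactly one of {V0, d}, not both")
    varied = "d" if len(ds) > 1 else "V0"
    rows = []
    for g in geoms:
        dbl = solve_doublet(g, scale)
        rows.append(
            {
                varied: getattr(g, varied),
                "E_S": dbl.E_S,
                "E_A": dbl.E_A,
                "delta_E": dbl.delta_E,
                "ratio": dbl.ratio,
            }
        )
    return pd.DataFrame(rows).sort_values(varied, ignore_index=True)


def degeneracy_ratio(q0: float, d: float) -> float:
    """coth(q0·d)/tanh(q0·d) = coth²(q0·d) > 1, the doublet non-degeneracy factor.

    Strictly decreasing in q0·d with limit 1: an impenetrable barrier
    (q0·d → ∞) makes the wells independent and the doublet degenerate.
    """
    x = q0 * d
    if not (math.isfinite(x) and x > 0):
        raise InvalidInputError(f"q0*d must be finite and > 0, got {x!r}")
    return 1.0 / math.tanh(x) ** 2
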