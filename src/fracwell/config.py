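"""Run configuration, flat config-file loading, and seeded fixture generation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, FracwellError
from .scale import EffectiveCoefficients, FractalScale
from .secular import DoubleWellGeometry, solve_doublet

__all__ = ["RunConfig", "load_config", "generate_fixtures"]

SCHEMA_VERSION = 1

_SCALE_FAMILY = ("m0", "lam", "dt_res", "DF")
_DIRECT_FAMILY = ("mu", "hbar_eff")
_GEOMETRY = ("l", "d", "V0")


@dataclass(frozen=True)
class RunConfig:
    """A validated parameter set for one solver run.

    Exactly one of the two parameterizations is supplied: the microscopic
    scale family (m0, lam, dt_res, DF) or the direct effective pair
    (mu, hbar_eff).  Geometry (l, d, V0) is always required.
    """

    l: float
    d: float
    V0: float
    m0: float | None = None
    lam: float | None = None
    dt_res: float | None = None
    DF: float | None = None
    mu: float | None = None
    hbar_eff: float | None = None
    seed: int = 0
    log_level: str = "INFO"
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_scale = any(getattr(self, k) is not None for k in _SCALE_FAMILY)
        has_direct = any(getattr(self, k) is not None for k in _DIRECT_FAMILY)
        if has_scale and has_direct:
            both = [k for k in _SCALE_FAMILY + _DIRECT_FAMILY if getattr(self, k) is not None]
            raise ConfigurationError(
                f"conflicting parameterizations: supply either {_SCALE_FAMILY} or "
                f"{_DIRECT_FAMILY}, got {both}"
            )
        if has_scale:
            missing = [k for k in _SCALE_FAMILY if getattr(self, k) is None]
            if missing:
                raise ConfigurationError(f"incomplete scale family, missing {missing}")
        elif has_direct:
            missing = [k for k in _DIRECT_FAMILY if getattr(self, k) is None]
            if missing:
                raise ConfigurationError(f"incomplete (mu, hbar_eff) pair, missing {missing}")
        else:
            raise ConfigurationError(
                f"no scale parameterization given: supply {_SCALE_FAMILY} or {_DIRECT_FAMILY}"
            )
        # Type invariants are enforced eagerly so bad values fail before any run.
        self.scale()
        self.geometry()

    def scale(self) -> FractalScale | EffectiveCoefficients:
        try:
            if self.mu is not None:
                return EffectiveCoefficients.from_mu_hbar(self.mu, self.hbar_eff)
            return FractalScale(m0=self.m0, lam=self.lam, dt_res=self.dt_res, DF=self.DF)
        except FracwellError as exc:
            raise ConfigurationError(str(exc)) from exc

    def geometry(self) -> DoubleWellGeometry:
        try:
            return DoubleWellGeometry(l=self.l, d=self.d, V0=self.V0)
        except FracwellError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_dict(self) -> dict[str, Any]:
        out = {"schema_version": SCHEMA_VERSION}
        for k in _GEOMETRY + _SCALE_FAMILY + _DIRECT_FAMILY + ("seed",):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a RunConfig from a flat key-value file plus overriding flags.

    The file is a flat YAML mapping (``key: value`` per line); ``overrides``
    entries that are not None replace file values.  Missing or conflicting
    fields raise :class:`ConfigurationError` naming the offenders.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a flat key-value mapping")
        data.update(raw)
    for k, v in (overrides or {}).items():
        if v is not None:
            data[k] = v

    known = set(_GEOMETRY) | set(_SCALE_FAMILY) | set(_DIRECT_FAMILY) | {"seed", "log_level"}
    extras = {k: data.pop(k) for k in list(data) if k not in known}
    missing = [k for k in _GEOMETRY if k not in data]
    if missing:
        raise ConfigurationError(f"missing required geometry field(s): {missing}")
    return RunConfig(extras=extras, **data)


def generate_fixtures(n: int, seed: int = 0) -> list[RunConfig]:
    """Seeded family of valid configurations, each admitting a sub-barrier doublet.

    Samples l in [1, 5], d/l in [0.05, 0.8], V0·l²/mu in [5, 500] and
    DF in {1.5, 2, 2.5, 3}.  The scale family is realized as
    (m0=0.5, lam=1, dt_res=1, DF): dt_res = 1 makes every DF share
    mu = hbar_eff = 1, so the V0 window applies directly.  Candidates whose
    doublet does not solve (or is numerically degenerate) are resampled, so
    the list is deterministic under the seed and every entry is solvable.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out: list[RunConfig] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("fixture generation failed to converge")
        l = float(rng.uniform(1.0, 5.0))
        d = float(rng.uniform(0.05, 0.8) * l)
        V0 = float(rng.uniform(5.0, 500.0) / l**2)  # mu = 1 by construction
        DF = float(rng.choice([1.5, 2.0, 2.5, 3.0]))
        cfg = RunConfig(l=l, d=d, V0=V0, m0=0.5, lam=1.0, dt_res=1.0, DF=DF,
                        seed=int(rng.integers(0, 2**31 - 1)))
        try:
            doublet = solve_doublet(cfg.geometry(), cfg.scale())
        except FracwellError:
            continue
        if doublet.delta_E <= 0:
            continue
        out.append(cfg)
    return out


def format_float(x: float) -> float:
    """Round-trip a float through 17 significant digits (stable JSON output)."""
    return float(f"{x:.17g}")


def jsonify(obj: Any) -> Any:
    """Recursively fix float formatting for byte-stable JSON serialization."""
    if isinstance(obj, dict):
        return {k: jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return format_float(float(obj))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def dump_json(obj: Any, path: str | Path | None) -> str:
    text = json.dumps(jsonify(obj), indent=1, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
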