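"""Canonical parameter sets, dimensionless combinations, and unit conversions.

The Schlögl model couples a single dynamic species ``X`` to two chemostatted
reservoirs ``A`` and ``B``::

    A      <-> X        (k_plus1 * A, k_minus1)
    2X + B <-> 3X       (k_minus2 * B, k_plus2)

Only the product ``k_plus1 * A`` ever enters the dynamics, so it is stored as a
single field.  The generalized (dimer-mediated) scheme adds ``2X <-> X2`` with
rate constants ``k_plus3`` / ``k_minus3``.

The "standard parameters" are the dimensionless reference set
``k_plus1*A = 0.5``, ``k_minus1 = 3``, ``k_plus2 = k_minus2 = 1`` (and
``k_plus3 = k_minus3 = 1`` for the generalized scheme); only the reservoir
concentration ``B``, the volume ``V``, and diffusion constants are varied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "RateParameters",
    "DimensionlessPoint",
    "UnitSystem",
    "standard_parameters",
    "to_dimensionless",
    "from_dimensionless",
    "to_physical_units",
    "params_to_config",
    "params_from_config",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class RateParameters:
    """Full rate-constant / reservoir-concentration set of the (generalized) model.

    Units follow the dimensionless convention: concentrations and times are
    measured in model units (1 length unit = 1 um, 1 time unit = 1 s when
    converting to physical units).
    """

    k_plus1_A: float  # production A -> X, zeroth order in X   [conc / time]
    k_minus1: float   # degradation X -> A                     [1 / time]
    k_plus2: float    # 3X -> 2X + B                           [1 / (conc^2 time)]
    k_minus2: float   # 2X + B -> 3X (enters as k_minus2 * B)  [1 / (conc^2 time)]
    B: float          # reservoir concentration, control parameter
    k_plus3: float = 1.0   # dimerization 2X -> X2              [1 / (conc time)]
    k_minus3: float = 1.0  # dissociation X2 -> 2X              [1 / time]
    A_conc: float = 1.0    # carried for serialization only; never used separately

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v!r}")
        if self.B <= 0:
            raise ValueError(f"B must be positive, got {self.B!r}")

    def with_B(self, B: float) -> "RateParameters":
        return replace(self, B=B)

    def replace(self, **kw: float) -> "RateParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class DimensionlessPoint:
    """Combination parameters locating a system in the cusp phase diagram."""

    beta: float   # k_minus1 k_plus2 / (k_minus2 B)^2
    gamma: float  # k_plus1 A k_plus2^2 / (k_minus2^3 B)
    v: float      # (k_minus2 B / k_plus2) V


def standard_parameters(B: float = 3.7, **overrides: float) -> RateParameters:
    """Standard parameter set with the requested control parameter ``B``.

    Individual rate constants may be overridden by keyword, e.g.
    ``standard_parameters(3.7, k_minus1=0.0)``.
    """
    base = dict(k_plus1_A=0.5, k_minus1=3.0, k_plus2=1.0, k_minus2=1.0,
                k_plus3=1.0, k_minus3=1.0)
    unknown = set(overrides) - set(base) - {"A_conc"}
    if unknown:
        raise ValueError(f"unknown rate-constant overrides: {sorted(unknown)}")
    base.update(overrides)
    return RateParameters(B=B, **base)


def to_dimensionless(params: RateParameters, V: float) -> DimensionlessPoint:
    """Map ``(params, V)`` onto the printed combination parameters (beta, gamma, v).

    Note the gamma definition carries a single power of ``k_minus2^3 B`` in the
    denominator exactly as published.
    """
    if params.k_minus2 == 0 or params.B == 0:
        raise ZeroDivisionError("beta/gamma undefined for k_minus2*B = 0")
    if params.k_plus2 == 0:
        raise ZeroDivisionError("v undefined for k_plus2 = 0")
    beta = params.k_minus1 * params.k_plus2 / (params.k_minus2 * params.B) ** 2
    gamma = params.k_plus1_A * params.k_plus2 ** 2 / (params.k_minus2 ** 3 * params.B)
    v = (params.k_minus2 * params.B / params.k_plus2) * V
    return DimensionlessPoint(beta=beta, gamma=gamma, v=v)


def from_dimensionless(point: DimensionlessPoint, *, B: float = 3.7
                       ) -> tuple[RateParameters, float]:
    """Inverse of :func:`to_dimensionless`, anchored at ``k_plus2 = k_minus2 = 1``.

    With the anchor ``B`` (default 3.7) the map is
    ``k_minus1 = beta B^2``, ``k_plus1_A = gamma B``, ``V = v / B``; at
    (0.22, 0.14, 37) this recovers the standard parameters with ``V = 10``.
    """
    k_minus1 = point.beta * B ** 2
    k_plus1_A = point.gamma * B
    if k_minus1 < 0 or k_plus1_A < 0:
        raise ValueError("dimensionless point maps to negative rates")
    params = RateParameters(k_plus1_A=k_plus1_A, k_minus1=k_minus1,
                            k_plus2=1.0, k_minus2=1.0, B=B)
    return params, point.v / B


@dataclass(frozen=True)
class UnitSystem:
    """Physical unit convention: lengths in um, times in s, concentrations in nM.

    The volume is ``V = eta * 10 um^3`` with ``eta`` a scale factor of order 1;
    one dimensionless time unit corresponds to one second, so a 10,000-unit run
    lasts 10,000 s = 2.78 h.
    """

    eta: float = 1.0
    length_um: float = 1.0
    time_s: float = 1.0
    conc_nM: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")

    @property
    def volume_um3(self) -> float:
        return self.eta * 10.0

    def duration_seconds(self, t: float) -> float:
        return t * self.time_s

    def duration_hours(self, t: float) -> float:
        return self.duration_seconds(t) / 3600.0


def to_physical_units(params: RateParameters, eta: float = 1.0) -> dict[str, float]:
    """Rate constants in physical (nM, s) units for volume ``V = eta * 10 um^3``.

    Reproduces the published conversion table verbatim, entry by entry:
    ``k_plus1_A = 5/(6 eta) [nM/s]``, ``k_minus1 = 1 [1/s]``,
    ``k_plus2 = B [1/s]`` (as published), ``k_minus2 = k_plus3 = 6 eta / 10
    [1/(nM s)]`` and ``k_minus3 = 1 [1/s]``, each scaled linearly when the
    dimensionless constant differs from its standard value.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    return {
        "k_plus1_A_nM_per_s": (5.0 / (6.0 * eta)) * (params.k_plus1_A / 0.5),
        "k_minus1_per_s": 1.0 * (params.k_minus1 / 3.0),
        "k_plus2_per_s": params.B * params.k_plus2,
        "k_minus2_per_nM_s": (6.0 * eta / 10.0) * params.k_minus2,
        "k_plus3_per_nM_s": (6.0 * eta / 10.0) * params.k_plus3,
        "k_minus3_per_s": 1.0 * params.k_minus3,
        "volume_um3": eta * 10.0,
    }


# --- flat key-value config serialization -------------------------------------

_CONFIG_KEYS = ("k_plus1_A", "k_minus1", "k_plus2", "k_minus2",
                "k_plus3", "k_minus3", "A_conc", "B_conc", "V", "eta")


def params_to_config(params: RateParameters, V: float | None = None,
                     eta: float | None = None) -> dict[str, float]:
    cfg: dict[str, float] = {
        "k_plus1_A": params.k_plus1_A,
        "k_minus1": params.k_minus1,
        "k_plus2": params.k_plus2,
        "k_minus2": params.k_minus2,
        "k_plus3": params.k_plus3,
        "k_minus3": params.k_minus3,
        "A_conc": params.A_conc,
        "B_conc": params.B,
    }
    if V is not None:
        cfg["V"] = float(V)
    if eta is not None:
        cfg["eta"] = float(eta)
    return cfg


def params_from_config(cfg: Mapping[str, Any]
                       ) -> tuple[RateParameters, float | None, float | None]:
    unknown = set(cfg) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = RateParameters(
        k_plus1_A=float(cfg["k_plus1_A"]),
        k_minus1=float(cfg["k_minus1"]),
        k_plus2=float(cfg["k_plus2"]),
        k_minus2=float(cfg["k_minus2"]),
        B=float(cfg["B_conc"]),
        k_plus3=float(cfg.get("k_plus3", 1.0)),
        k_minus3=float(cfg.get("k_minus3", 1.0)),
        A_conc=float(cfg.get("A_conc", 1.0)),
    )
    V = float(cfg["V"]) if "V" in cfg else None
    eta = float(cfg["eta"]) if "eta" in cfg else None
    return params, V, eta


def save_config(path: str | Path, params: RateParameters, V: float | None = None,
                eta: float | None = None) -> None:
    path = Path(path)
    cfg = params_to_config(params, V=V, eta=eta)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_config(path: str | Path
                ) -> tuple[RateParameters, float | None, float | None]:
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return params_from_config(cfg)
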