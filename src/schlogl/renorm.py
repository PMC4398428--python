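"""Diffusion-limited (Collins-Kimball-type) renormalization of rate constants.

Finite diffusion slows the encounter step of second-order reactions.  With
the diffusion-limited encounter rate ``k_D = 4 pi sigma D`` (``sigma`` the
reaction cross section, ``D`` the mean diffusion constant of the pair), both
members of a reversible second-order pair are scaled as

    k'_(+/-)i = k_(+/-)i * k_D / (k_+i + k_D),       i = 2, 3

with the forward constant in the denominator for both members, which
preserves the equilibrium constant k_+i / k_-i.  Only the second-order
channels (k_+-2, k_+-3) are renormalized; zeroth- and first-order channels
are untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import RateParameters

__all__ = ["RenormalizationSpec", "renormalize_pair", "renormalize_params"]


@dataclass(frozen=True)
class RenormalizationSpec:
    """Encounter-rate specification; sigmaD is the product sigma * D."""

    sigmaD: float = 0.5

    def __post_init__(self) -> None:
        if self.sigmaD < 0:
            raise ValueError("sigmaD must be nonnegative")

    @property
    def kD(self) -> float:
        return 4.0 * math.pi * self.sigmaD


def renormalize_pair(k_plus: float, k_minus: float,
                     spec: RenormalizationSpec = RenormalizationSpec()
                     ) -> tuple[float, float]:
    """Scale a reversible pair by kD / (k_plus + kD)."""
    if k_plus < 0:
        raise ValueError("k_plus must be nonnegative")
    denom = k_plus + spec.kD
    if denom == 0:
        raise ZeroDivisionError("k_plus + kD = 0: no encounter channel")
    f = spec.kD / denom
    return k_plus * f, k_minus * f


def renormalize_params(params: RateParameters,
                       spec: RenormalizationSpec = RenormalizationSpec()
                       ) -> RateParameters:
    """Parameters with diffusion-renormalized second-order constants k_+-2, k_+-3."""
    k2, km2 = renormalize_pair(params.k_plus2, params.k_minus2, spec)
    k3, km3 = renormalize_pair(params.k_plus3, params.k_minus3, spec)
    return params.replace(k_plus2=k2, k_minus2=km2, k_plus3=k3, k_minus3=km3)
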