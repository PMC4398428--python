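"""Macroscopic (V -> infinity) analysis of the Schlögl model.

The mean-field rate equation is the cubic

    dx/dt = -k_plus2 x^3 + k_minus2 B x^2 - k_minus1 x + k_plus1 A

whose one or three nonnegative roots give the steady states.  This module
provides steady states with stability, bifurcation scans in the control
parameter B with saddle-node location, the macroscopic entropy-production
rate, the deterministic (quartic) potential and its coexistence point, and
the beta-gamma phase diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import DimensionlessPoint, RateParameters, from_dimensionless

__all__ = [
    "SteadyStateSet",
    "BifurcationBranch",
    "PhaseDiagram",
    "drift",
    "drift_derivative",
    "steady_states",
    "bifurcation_scan",
    "entropy_production_macroscopic",
    "deterministic_potential",
    "coexistence_B_deterministic",
    "bistable_region",
]

_ROOT_TOL = 1e-10


def drift(x, params: RateParameters):
    """Net macroscopic production rate dx/dt at concentration x."""
    x = np.asarray(x, dtype=float)
    out = (-params.k_plus2 * x ** 3 + params.k_minus2 * params.B * x ** 2
           - params.k_minus1 * x + params.k_plus1_A)
    return out if out.ndim else float(out)


def drift_derivative(x, params: RateParameters):
    x = np.asarray(x, dtype=float)
    out = (-3.0 * params.k_plus2 * x ** 2
           + 2.0 * params.k_minus2 * params.B * x - params.k_minus1)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SteadyStateSet:
    """Nonnegative steady states in increasing order with stability flags."""

    roots: tuple[float, ...]
    stability: tuple[bool, ...]  # True = stable

    @property
    def bistable(self) -> bool:
        return len(self.roots) == 3

    @property
    def low(self) -> float:
        return self.roots[0]

    @property
    def high(self) -> float:
        return self.roots[-1]

    @property
    def middle(self) -> float:
        if not self.bistable:
            raise ValueError("no unstable intermediate state: system is monostable")
        return self.roots[1]


def _polish(x0: float, params: RateParameters) -> float:
    """A few Newton steps on the cubic; falls back to the input on stagnation."""
    x = x0
    for _ in range(50):
        f = drift(x, params)
        df = drift_derivative(x, params)
        if df == 0.0:
            break
        step = f / df
        x -= step
        if abs(step) < _ROOT_TOL * max(1.0, abs(x)):
            break
    return x if abs(drift(x, params)) <= abs(drift(x0, params)) + 1e-15 else x0


def steady_states(params: RateParameters) -> SteadyStateSet:
    """All real nonnegative roots of the drift, with linear-stability flags.

    For a genuine cubic the real-root count is decided by the sign of the
    cubic discriminant (robust near saddle nodes) before refinement.
    """
    coeffs = [-params.k_plus2, params.k_minus2 * params.B,
              -params.k_minus1, params.k_plus1_A]
    # trim to the true polynomial degree
    while len(coeffs) > 1 and coeffs[0] == 0.0:
        coeffs = coeffs[1:]
    if len(coeffs) == 1:
        raise ValueError("drift is identically constant; no steady state")
    a = np.array(coeffs, dtype=float)
    if len(a) == 4:
        p3, p2, p1, p0 = a
        disc = (18 * p3 * p2 * p1 * p0 - 4 * p2 ** 3 * p0 + p2 ** 2 * p1 ** 2
                - 4 * p3 * p1 ** 3 - 27 * p3 ** 2 * p0 ** 2)
        n_real = 3 if disc > 0 else 1
    else:
        n_real = None  # degenerate; accept whatever np.roots returns
    rts = np.roots(a)
    real = sorted(r.real for r in rts if abs(r.imag) <= 1e-7 * (1.0 + abs(r)))
    if n_real is not None and len(real) > n_real:
        # discriminant says a complex pair: keep the root(s) with smallest residual
        real = sorted(sorted(real, key=lambda r: abs(drift(r, params)))[:n_real])
    roots = [_polish(r, params) for r in real if r >= -1e-9]
    roots = sorted(max(r, 0.0) for r in roots)
    stab = tuple(bool(drift_derivative(r, params) < 0.0) for r in roots)
    return SteadyStateSet(roots=tuple(roots), stability=stab)


@dataclass(frozen=True)
class BifurcationBranch:
    """Steady-state branches x(B) plus located saddle-node B values."""

    B: np.ndarray          # one entry per (B, root) pair
    x: np.ndarray
    stability: np.ndarray  # boolean
    saddle_nodes: tuple[float, ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"B": self.B, "x": self.x,
                             "stability": self.stability.astype(int)})


def bifurcation_scan(params: RateParameters, B_min: float, B_max: float,
                     step: float = 0.01) -> BifurcationBranch:
    """Scan the steady-state set over ``B`` and bisect saddle-node locations."""
    if not (B_min < B_max):
        raise ValueError("empty B range")
    if step <= 0:
        raise ValueError("step must be positive")
    Bs = np.arange(B_min, B_max + 0.5 * step, step)
    rows_B, rows_x, rows_s = [], [], []
    counts = []
    for B in Bs:
        ss = steady_states(params.with_B(B))
        counts.append(len(ss.roots))
        for r, s in zip(ss.roots, ss.stability):
            rows_B.append(B)
            rows_x.append(r)
            rows_s.append(s)
    saddle = []
    nroots = lambda B: len(steady_states(params.with_B(B)).roots)  # noqa: E731
    for i in range(len(Bs) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = Bs[i], Bs[i + 1]
            nlo = counts[i]
            while hi - lo > 1e-6:
                mid = 0.5 * (lo + hi)
                if nroots(mid) == nlo:
                    lo = mid
                else:
                    hi = mid
            saddle.append(0.5 * (lo + hi))
    return BifurcationBranch(B=np.array(rows_B), x=np.array(rows_x),
                             stability=np.array(rows_s, dtype=bool),
                             saddle_nodes=tuple(saddle))


def entropy_production_macroscopic(x: float, params: RateParameters) -> float:
    """Macroscopic entropy-production rate sum_i (w_+i - w_-i) log(w_+i / w_-i).

    Fluxes: w_+1 = k_plus1 A, w_-1 = k_minus1 x, w_-2 = k_minus2 B x^2,
    w_+2 = k_plus2 x^3.  Nonnegative termwise; zero exactly at detailed
    balance.  Requires all four fluxes positive.
    """
    w_p1 = params.k_plus1_A
    w_m1 = params.k_minus1 * x
    w_m2 = params.k_minus2 * params.B * x ** 2
    w_p2 = params.k_plus2 * x ** 3
    if min(w_p1, w_m1, w_m2, w_p2) <= 0.0:
        raise ValueError("entropy production requires all four fluxes positive "
                         f"(got {w_p1, w_m1, w_m2, w_p2} at x={x})")
    return ((w_p1 - w_m1) * np.log(w_p1 / w_m1)
            + (w_p2 - w_m2) * np.log(w_p2 / w_m2))


def deterministic_potential(x, params: RateParameters):
    """Quartic potential Psi(x) = -int_0^x drift(u) du; Psi(0) = 0.

    Minima sit at the stable steady states, the maximum at the unstable one.
    """
    x = np.asarray(x, dtype=float)
    out = (params.k_plus2 * x ** 4 / 4.0
           - params.k_minus2 * params.B * x ** 3 / 3.0
           + params.k_minus1 * x ** 2 / 2.0 - params.k_plus1_A * x)
    return out if out.ndim else float(out)


def _potential_gap(B: float, params: RateParameters) -> float:
    ss = steady_states(params.with_B(B))
    if not ss.bistable:
        raise ValueError(f"monostable at B={B}: bracket must lie inside the "
                         "bistable window")
    p = params.with_B(B)
    return float(deterministic_potential(ss.high, p)
                 - deterministic_potential(ss.low, p))


def coexistence_B_deterministic(params: RateParameters,
                                bracket: tuple[float, float] = (3.3, 3.6),
                                xtol: float = 1e-6) -> float:
    """B where the deterministic potential is equal at the low and high states."""
    lo, hi = bracket
    f_lo, f_hi = _potential_gap(lo, params), _potential_gap(hi, params)
    if f_lo * f_hi > 0:
        raise ValueError("no potential-equality crossing inside bracket "
                         f"{bracket}: gaps ({f_lo:.3g}, {f_hi:.3g})")
    return float(brentq(_potential_gap, lo, hi, args=(params,), xtol=xtol))


@dataclass(frozen=True)
class PhaseDiagram:
    """Bistability mask over a (beta, gamma) grid at dimensionless volume v."""

    beta: np.ndarray
    gamma: np.ndarray
    bistable: np.ndarray  # 2D bool, shape (len(gamma), len(beta))
    valid: np.ndarray     # False where the inverse map failed
    v: float              # may be math.inf

    def to_frame(self):
        import pandas as pd

        bb, gg = np.meshgrid(self.beta, self.gamma)
        return pd.DataFrame({"beta": bb.ravel(), "gamma": gg.ravel(),
                             "bistable_flag": self.bistable.ravel().astype(int),
                             "valid": self.valid.ravel().astype(int)})


def bistable_region(beta_grid, gamma_grid, v: float = np.inf,
                    **bimodality_kw) -> PhaseDiagram:
    """Classify each (beta, gamma) grid point as bistable or not at volume v.

    For ``v = inf`` a point is bistable when the mapped cubic has three
    distinct positive roots; for finite ``v`` when the exact stationary
    distribution of the master equation at ``V = v / B`` is bimodal (see
    :func:`schlogl.cme.is_bimodal` for the criterion and its knobs).
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    mask = np.zeros((len(gamma_grid), len(beta_grid)), dtype=bool)
    valid = np.ones_like(mask)
    finite = np.isfinite(v)
    if finite:
        from . import cme  # deferred: cme depends on this module

    for i, g in enumerate(gamma_grid):
        for j, b in enumerate(beta_grid):
            try:
                p, V = from_dimensionless(DimensionlessPoint(b, g, v if finite else 1.0))
            except ValueError:
                valid[i, j] = False
                continue
            if not finite:
                ss = steady_states(p)
                mask[i, j] = ss.bistable
            else:
                dist = cme.stationary_distribution(p, V)
                mask[i, j] = cme.is_bimodal(dist, **bimodality_kw).bimodal
    return PhaseDiagram(beta=beta_grid, gamma=gamma_grid, bistable=mask,
                        valid=valid, v=float(v))
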