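"""Exact well-mixed stochastic layer for the Schlögl model.

The one-step chemical master equation for the copy number X at volume V has
the four transition channels

    W_+1(X -> X+1) = k_plus1 A V
    W_-2(X -> X+1) = k_minus2 B X(X-1) / V
    W_-1(X -> X-1) = k_minus1 X
    W_+2(X -> X-1) = k_plus2 X(X-1)(X-2) / V^2

This module provides the exact (recursion-based) stationary distribution, the
large-volume stochastic potential Phi with its volume-independent prefactor
N(x), mean-first-passage-time switching rates and the Maxwell-like
coexistence construction, the Schnakenberg entropy-production rate,
fluctuation curves, bimodality classification, and Gillespie simulation of
both the conventional and the generalized (dimer-mediated) scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from ._kernels import ssa_core
from .containers import Histogram1D, Trajectory
from .deterministic import steady_states
from .params import RateParameters

__all__ = [
    "CMEDistribution",
    "StochasticPotential",
    "SwitchingRates",
    "BimodalityResult",
    "cme_rates",
    "stationary_distribution",
    "stochastic_potential",
    "potential_derivative",
    "switching_rates",
    "coexistence_B_stochastic",
    "entropy_production_microscopic",
    "fluctuation_curve",
    "simulate_ssa",
    "trajectory_histogram",
    "is_bimodal",
    "bimodal_range",
]

SCHEMES = ("conventional", "generalized", "generalized-renormalized")


def cme_rates(X, params: RateParameters, V: float):
    """The four master-equation transition rates at copy number X.

    Returns ``(birth_const, birth_auto, death_linear, death_tri)`` =
    ``(k_plus1 A V, k_minus2 B X(X-1)/V, k_minus1 X, k_plus2 X(X-1)(X-2)/V^2)``.
    """
    X = np.asarray(X, dtype=float)
    birth_const = np.broadcast_to(params.k_plus1_A * V, X.shape).astype(float)
    birth_auto = params.k_minus2 * params.B * X * (X - 1) / V
    death_linear = params.k_minus1 * X
    death_tri = params.k_plus2 * X * (X - 1) * (X - 2) / V ** 2
    if X.ndim == 0:
        return (float(birth_const), float(birth_auto),
                float(death_linear), float(death_tri))
    return birth_const, birth_auto, death_linear, death_tri


@dataclass
class CMEDistribution:
    """Truncated exact stationary distribution p(X), X = 0..X_max."""

    V: float
    p: np.ndarray
    log_Z: float  # log of the normalizing sum of the unnormalized weights (pi_0 = 1)

    @property
    def X_max(self) -> int:
        return len(self.p) - 1

    @property
    def X(self) -> np.ndarray:
        return np.arange(len(self.p))

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))

    def x(self) -> np.ndarray:
        """Concentration grid x = X / V."""
        return self.X / self.V

    def mean_X(self) -> float:
        return float(np.sum(self.X * self.p))

    def var_X(self) -> float:
        return float(np.sum((self.X - self.mean_X()) ** 2 * self.p))

    def mean_x(self) -> float:
        return self.mean_X() / self.V

    def sd_x(self) -> float:
        return math.sqrt(self.var_X()) / self.V

    def p_at_x(self, x: float) -> float:
        """p(X) at the integer copy number nearest to concentration x."""
        return float(self.p[int(round(x * self.V))])

    def local_maxima(self) -> list[int]:
        p = self.p
        out = [i for i in range(1, len(p) - 1) if p[i] > p[i - 1] and p[i] >= p[i + 1]]
        if len(p) > 1 and p[0] > p[1]:
            out.insert(0, 0)
        return out


def _log_weights(params: RateParameters, V: float, X_max: int) -> np.ndarray:
    X = np.arange(X_max + 1, dtype=float)
    bc, ba, dl, dt = cme_rates(X, params, V)
    up = bc + ba                       # W(X -> X+1)
    down = dl + dt                     # W(X -> X-1)
    with np.errstate(divide="ignore"):
        steps = np.log(up[:-1]) - np.log(down[1:])
    logpi = np.zeros(X_max + 1)
    logpi[1:] = np.cumsum(steps)
    return logpi


def stationary_distribution(params: RateParameters, V: float,
                            X_max: int | None = None,
                            boundary_tol: float = 1e-12,
                            max_retries: int = 3) -> CMEDistribution:
    """Exact stationary distribution via the detailed-balance recursion
    p(X+1)/p(X) = [W_+1(X) + W_-2(X)] / [W_-1(X+1) + W_+2(X+1)].

    The truncation starts at ``ceil(4 x_high V)`` and doubles until the
    boundary probability is below ``boundary_tol`` times the maximum.
    """
    if V <= 0:
        raise ValueError("V must be positive")
    if X_max is None:
        if params.k_plus2 > 0:
            x_ref = steady_states(params).high
        else:
            x_ref = params.k_plus1_A / max(params.k_minus1, 1e-12)
        X_max = max(int(math.ceil(4.0 * x_ref * V)), 20)
    for attempt in range(max_retries + 1):
        logpi = _log_weights(params, V, X_max)
        log_Z = float(logsumexp(logpi))
        p = np.exp(logpi - log_Z)
        if p[-1] < boundary_tol * p.max():
            return CMEDistribution(V=V, p=p, log_Z=log_Z)
        X_max *= 2
    raise RuntimeError(f"stationary distribution not converged: boundary mass "
                       f"{p[-1]:.3g} at X_max={X_max // 2}")


@dataclass
class StochasticPotential:
    """Closed-form large-volume potential Phi(x) and prefactor N(x),
    defining p(x) ~ N(x) exp(-V Phi(x))."""

    x_grid: np.ndarray
    phi: np.ndarray
    prefactor: np.ndarray

    def density(self, V: float) -> np.ndarray:
        w = np.log(self.prefactor) - V * self.phi
        w = np.exp(w - w.max())
        dx = np.gradient(self.x_grid)
        return w / np.sum(w * dx)


def _phi_closed_form(x, params: RateParameters):
    k1A, km1 = params.k_plus1_A, params.k_minus1
    k2, km2B = params.k_plus2, params.k_minus2 * params.B
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Phi has a log singularity at x = 0; grid must be positive")
    return (x * (np.log(x) - 1.0)
            + x * np.log((k2 * x ** 2 + km1) / (km2B * x ** 2 + k1A))
            + 2.0 * np.sqrt(km1 / k2) * np.arctan(np.sqrt(k2 / km1) * x)
            - 2.0 * np.sqrt(k1A / km2B) * np.arctan(np.sqrt(km2B / k1A) * x))


def stochastic_potential(x_grid, params: RateParameters) -> StochasticPotential:
    """Phi(x) and the volume-independent prefactor N(x) on a positive grid.

    ``N(x) = (k_plus2 x^2 + k_minus1) / (x (x^2 + k_plus1 A / (k_minus2 B)))``
    up to the overall normalization that is fixed only once V is chosen.
    """
    x = np.asarray(x_grid, dtype=float)
    phi = _phi_closed_form(x, params)
    k1A, km1 = params.k_plus1_A, params.k_minus1
    k2, km2B = params.k_plus2, params.k_minus2 * params.B
    pref = (k2 * x ** 2 + km1) / (x * (x ** 2 + k1A / km2B))
    return StochasticPotential(x_grid=x, phi=np.asarray(phi), prefactor=pref)


def potential_derivative(x, params: RateParameters):
    """dPhi/dx = -log[(w_+1 + w_-2) / (w_-1 + w_+2)]; zero at steady states."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("dPhi/dx requires x > 0")
    up = params.k_plus1_A + params.k_minus2 * params.B * x ** 2
    down = params.k_minus1 * x + params.k_plus2 * x ** 3
    if np.any(down == 0):
        raise ZeroDivisionError("loss fluxes vanish")
    out = -np.log(up / down)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SwitchingRates:
    """Inverse mean first-passage times between the two stable basins."""

    rate_low_to_high: float
    rate_high_to_low: float
    V: float
    B: float


def switching_rates(params: RateParameters, V: float) -> SwitchingRates:
    """Exact switching rates of the birth-death chain between the two modes.

    Mean first-passage times are computed with the nested-sum formula over
    the unnormalized stationary weights: reflecting at X = 0 (resp. at the
    truncation boundary), absorbing at the destination state's copy number
    (the deterministic root scaled by V), started at the origin state.
    """
    ss = steady_states(params)
    if not ss.bistable:
        raise ValueError(f"switching rates undefined: monostable at B={params.B}")
    n_low = int(round(ss.low * V))
    n_high = int(round(ss.high * V))
    X_max = max(int(math.ceil(4.0 * ss.high * V)), n_high + 10)
    logpi = _log_weights(params, V, X_max)
    pi = np.exp(logpi - logpi.max())
    X = np.arange(X_max + 1, dtype=float)
    bc, ba, dl, dt = cme_rates(X, params, V)
    lam = bc + ba
    mu = dl + dt
    cs_up = np.cumsum(pi)
    T_lh = float(np.sum(cs_up[n_low:n_high] / (lam[n_low:n_high] * pi[n_low:n_high])))
    cs_down = np.cumsum(pi[::-1])[::-1]
    sl = slice(n_low + 1, n_high + 1)
    T_hl = float(np.sum(cs_down[sl] / (mu[sl] * pi[sl])))
    return SwitchingRates(rate_low_to_high=1.0 / T_lh, rate_high_to_low=1.0 / T_hl,
                          V=V, B=params.B)


def coexistence_B_stochastic(params: RateParameters, V: float = 30.0,
                             bracket: tuple[float, float] = (3.4, 4.0),
                             method: str = "equal-rates",
                             xtol: float = 1e-6) -> float:
    """Maxwell-like construction: the B at which the two states coexist.

    ``equal-rates``: bisection on rate_low_to_high = rate_high_to_low at the
    given volume.  ``equal-potential``: bisection on
    Phi(x_low) = Phi(x_high) of the closed-form potential (V-independent).
    """
    if method not in ("equal-rates", "equal-potential"):
        raise ValueError(f"unknown method {method!r}")

    def f(B: float) -> float:
        p = params.with_B(B)
        ss = steady_states(p)
        if not ss.bistable:
            raise ValueError(f"bracket leaves the bistable window at B={B}")
        if method == "equal-rates":
            r = switching_rates(p, V)
            return math.log(r.rate_low_to_high) - math.log(r.rate_high_to_low)
        phi = _phi_closed_form(np.array([ss.low, ss.high]), p)
        return float(phi[0] - phi[1])

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(f"no coexistence crossing in bracket {bracket}")
    return float(brentq(f, lo, hi, xtol=xtol))


def entropy_production_microscopic(dist: CMEDistribution,
                                   params: RateParameters) -> float:
    """Schnakenberg entropy-production rate over the stationary distribution.

    Each edge (X, X+1) is crossed by two channels (exchange with A, exchange
    with B); each contributes (J+ - J-) ln(J+/J-) with J+ = p(X) W_up(X),
    J- = p(X+1) W_down(X+1).  Edges with a vanishing one-way flux but a
    nonzero reverse flux are skipped with a warning (formally infinite).
    """
    import warnings

    p = dist.p
    X = np.arange(len(p), dtype=float)
    bc, ba, dl, dt = cme_rates(X, params, dist.V)
    total = 0.0
    for up, down in ((bc, dl), (ba, dt)):
        Jf = p[:-1] * up[:-1]
        Jb = p[1:] * down[1:]
        ok = (Jf > 0) & (Jb > 0)
        bad = (Jf > 0) ^ (Jb > 0)
        if np.any(bad):
            warnings.warn(f"{int(bad.sum())} edges with one-way flux skipped in "
                          "entropy production", stacklevel=2)
        total += float(np.sum((Jf[ok] - Jb[ok]) * np.log(Jf[ok] / Jb[ok])))
    return total


def fluctuation_curve(params: RateParameters, V: float, B_grid):
    """Exact stationary moments of x = X/V along a grid of B values.

    Returns a DataFrame with columns B, mean, sd, cv (= sd/mean) and var.
    """
    import pandas as pd

    rows = []
    for B in np.asarray(B_grid, dtype=float):
        d = stationary_distribution(params.with_B(B), V)
        m, s = d.mean_x(), d.sd_x()
        rows.append((B, m, s, s / m, s * s))
    return pd.DataFrame(rows, columns=["B", "mean", "sd", "cv", "var"])


# --------------------------------------------------------------------------
# stochastic simulation


def simulate_ssa(params: RateParameters, scheme: str = "conventional",
                 V: float = 10.0, t_max: float = 1000.0, seed: int = 0,
                 x0: float | None = None, x2_0: float | None = None,
                 record_dt: float | None = None,
                 max_records: int = 5_000_000) -> Trajectory:
    """Exact Gillespie (direct-method) simulation.

    ``scheme`` selects the conventional 4-channel system, the generalized
    6-channel dimer system, or the latter with diffusion-renormalized
    second-order rate constants (sigma*D = 0.5).  ``record_dt=None`` records
    every event; a positive value samples on a uniform grid.  Initial
    copy numbers default to the low deterministic root (and its
    quasi-equilibrium dimer count).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    run_params = params
    if scheme == "generalized-renormalized":
        from .renorm import RenormalizationSpec, renormalize_params

        run_params = renormalize_params(params, RenormalizationSpec())
    if x0 is None:
        ss = steady_states(run_params)
        x0 = ss.low
    X0 = int(round(x0 * V))
    if x2_0 is None:
        x2_0 = (run_params.k_plus3 / run_params.k_minus3) * x0 ** 2 \
            if run_params.k_minus3 > 0 else 0.0
    X20 = int(round(x2_0 * V)) if scheme != "conventional" else 0
    if record_dt is not None and record_dt <= 0:
        raise ValueError("record_dt must be positive (or None for every event)")
    cap = max_records
    if record_dt is not None:
        cap = min(cap, int(t_max / record_dt) + 2)
    times = np.empty(cap)
    Xs = np.empty(cap, dtype=np.int64)
    X2s = np.empty(cap, dtype=np.int64)
    n, overflow, _ = ssa_core(
        run_params.k_plus1_A * V, run_params.k_minus1,
        run_params.k_minus2 * run_params.B, run_params.k_plus2,
        run_params.k_plus3, run_params.k_minus3, V,
        scheme != "conventional", X0, X20, t_max, seed,
        -1.0 if record_dt is None else record_dt,
        times, Xs, X2s)
    if overflow:
        raise RuntimeError("record buffer exhausted; pass record_dt or raise "
                           "max_records")
    return Trajectory(times=times[:n].copy(), X=Xs[:n].copy(), X2=X2s[:n].copy(),
                      scheme=scheme, V=V, seed=seed, t_max=t_max)


def _occupancy_weights(traj: Trajectory, burn_in_fraction: float) -> np.ndarray:
    """Post-burn-in time each record is occupied (records clipped at t0)."""
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    t_end = traj.t_max if traj.t_max is not None else traj.times[-1]
    t0 = burn_in_fraction * t_end
    ends = np.append(traj.times[1:], t_end)
    w = np.clip(ends - np.maximum(traj.times, t0), 0.0, None)
    if w.sum() <= 0:
        raise ValueError("empty trajectory after burn-in")
    return w


def trajectory_histogram(traj: Trajectory, burn_in_fraction: float = 0.1,
                         bin_width: float = 0.1,
                         x_max: float | None = None) -> Histogram1D:
    """Time-weighted occupancy histogram of x = X/V (weights = holding times)."""
    w = _occupancy_weights(traj, burn_in_fraction)
    xs = traj.x()
    if x_max is None:
        x_max = float(xs[w > 0].max()) + bin_width
    edges = np.arange(0.0, x_max + 0.5 * bin_width, bin_width)
    weights, _ = np.histogram(xs, bins=edges, weights=w)
    return Histogram1D(edges=edges, weights=weights)


def trajectory_pmf(traj: Trajectory, burn_in_fraction: float = 0.1,
                   X_max: int | None = None) -> Histogram1D:
    """Exact time-weighted occupancy per copy number X.

    Bins are centered on the integers (edges at (X +- 1/2)/V on the
    concentration axis), so the result is directly comparable with
    :func:`distribution_histogram` of the exact stationary distribution.
    """
    w = _occupancy_weights(traj, burn_in_fraction)
    X = np.asarray(traj.X, dtype=np.int64)
    if X_max is None:
        X_max = int(X[w > 0].max())
    weights = np.bincount(X, weights=w, minlength=X_max + 1)[:X_max + 1]
    edges = (np.arange(X_max + 2) - 0.5) / traj.V
    return Histogram1D(edges=edges, weights=weights)


def distribution_histogram(dist: CMEDistribution,
                           X_max: int | None = None) -> Histogram1D:
    """Exact stationary p(X) as a histogram on integer-centered bins."""
    if X_max is None:
        X_max = dist.X_max
    p = np.zeros(X_max + 1)
    m = min(X_max + 1, len(dist.p))
    p[:m] = dist.p[:m]
    edges = (np.arange(X_max + 2) - 0.5) / dist.V
    return Histogram1D(edges=edges, weights=p)


# --------------------------------------------------------------------------
# bimodality classification


@dataclass(frozen=True)
class BimodalityResult:
    bimodal: bool
    modes: tuple[int, ...] = ()
    minimum: int | None = None
    minor_mass: float = 0.0
    prominence: float = float("inf")


def is_bimodal(dist: CMEDistribution, min_minor_mass: float = 0.01,
               min_prominence: float = 1.0) -> BimodalityResult:
    """Classify a stationary distribution as visibly bimodal.

    Criterion: two strict local maxima separated by a local minimum, the
    minor basin carrying at least ``min_minor_mass`` of the probability, and
    both peaks exceeding ``min_prominence`` times the intervening minimum.
    The mass threshold (1%) is the operative default; raise
    ``min_prominence`` (e.g. to 2) for a stricter "deep valley" variant.
    """
    maxima = dist.local_maxima()
    if len(maxima) < 2:
        return BimodalityResult(bimodal=False)
    top = sorted(sorted(maxima, key=lambda i: -dist.p[i])[:2])
    i1, i2 = top
    imin = i1 + int(np.argmin(dist.p[i1:i2 + 1]))
    minor_mass = float(min(dist.p[:imin].sum(), dist.p[imin:].sum()))
    pmin = dist.p[imin]
    prom = float(min(dist.p[i1], dist.p[i2]) / pmin) if pmin > 0 else float("inf")
    ok = minor_mass >= min_minor_mass and prom > min_prominence
    return BimodalityResult(bimodal=bool(ok), modes=(i1, i2), minimum=imin,
                            minor_mass=minor_mass, prominence=prom)


def bimodal_range(params: RateParameters, V: float,
                  B_range: tuple[float, float] = (3.0, 5.2),
                  step: float = 0.01,
                  **criterion_kw) -> tuple[float, float] | None:
    """Largest contiguous B interval with a visibly bimodal stationary p(X).

    Returns ``(B_low, B_high)`` or ``None`` when no grid point classifies as
    bimodal.
    """
    Bs = np.arange(B_range[0], B_range[1] + 0.5 * step, step)
    flags = np.array([
        is_bimodal(stationary_distribution(params.with_B(B), V), **criterion_kw).bimodal
        for B in Bs])
    if not flags.any():
        return None
    best = (0, -1)
    start = None
    for i, f in enumerate(np.append(flags, False)):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start > best[1] - best[0] + 1:
                best = (start, i - 1)
            start = None
    return float(Bs[best[0]]), float(Bs[best[1]])
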