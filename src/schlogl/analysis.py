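"""Spatial and statistical diagnostics: pair correlation, KL divergence,
kymographs, switch detection, and bistable-range classification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import Histogram1D, Trajectory
from .deterministic import steady_states
from .geometry import Box, Geometry, ParticleSnapshot, minimum_image
from .params import RateParameters

__all__ = [
    "PairCorrelation",
    "KymographMatrix",
    "SwitchRecord",
    "pair_correlation",
    "random_control_snapshot",
    "kl_divergence",
    "kymograph",
    "detect_switches",
    "classify_bistable",
    "bistable_range",
]


@dataclass
class PairCorrelation:
    """Radial pair-correlation g(r) on shells of width a (r = a, 2a, ...)."""

    r: np.ndarray
    g: np.ndarray
    n_snapshots: int


def pair_correlation(snapshots: Sequence[ParticleSnapshot],
                     a: float | None = None,
                     species: str = "X") -> PairCorrelation:
    """Shell-counted radial pair correlation averaged over snapshots.

    For each snapshot with N >= 2 particles,
    ``g(r) = V / (N(N-1)) * 1/V_shell(r) * sum_{i != j} I(r-a < |r_ij| <= r)``
    with minimum-image distances.  The shell volume is the exact
    ``(4 pi / 3)(r^3 - (r-a)^3)`` rather than the thin-shell approximation
    ``4 pi r^2 a``, so spatially random placements give g = 1 in expectation
    even on the first few shells.  Snapshots are averaged with their
    individual N, so for strongly fluctuating particle numbers the average
    can deviate systematically from 1 even for random placements.  Default
    mesh spacing is L/50; shells extend to L/2 (the minimum-image validity
    limit; beyond ~L/4 the spherical-shell volume overestimates the true
    periodic one).
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    geom = snapshots[0].geometry
    if not (isinstance(geom, Box) and geom.periodic):
        raise ValueError("pair correlation requires a periodic box")
    L = float(min(geom.lengths))
    if a is None:
        a = L / 50.0
    r_edges = np.arange(0.0, L / 2.0 + 0.5 * a, a)
    r = r_edges[1:]
    V = geom.volume
    acc = np.zeros(len(r))
    used = 0
    for snap in snapshots:
        pos = snap.x_positions if species == "X" else snap.x2_positions
        N = len(pos)
        if N < 2:
            warnings.warn(f"snapshot at t={snap.time} has N={N} < 2; skipped",
                          stacklevel=2)
            continue
        delta = pos[:, None, :] - pos[None, :, :]
        delta = minimum_image(delta.reshape(-1, 3), geom).reshape(N, N, 3)
        d = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
        d = d[~np.eye(N, dtype=bool)]  # ordered pairs, i != j
        counts, _ = np.histogram(d, bins=r_edges)
        shell_vol = 4.0 * np.pi / 3.0 * (r_edges[1:] ** 3 - r_edges[:-1] ** 3)
        acc += V / (N * (N - 1)) * counts / shell_vol
        used += 1
    if used == 0:
        raise ValueError("no snapshot had at least two particles")
    return PairCorrelation(r=r, g=acc / used, n_snapshots=used)


def random_control_snapshot(N: int, geometry: Geometry,
                            seed: int = 0) -> ParticleSnapshot:
    """Uniform i.i.d. particle placements — the spatially random control."""
    if N < 0:
        raise ValueError("N must be nonnegative")
    rng = np.random.default_rng(seed)
    pos = geometry.sample_uniform(N, rng) if N else np.empty((0, 3))
    return ParticleSnapshot(time=0.0, x_positions=pos,
                            x2_positions=np.empty((0, 3)), geometry=geometry)


def kl_divergence(p_ref: Histogram1D, p_test: Histogram1D,
                  pseudocount: float = 0.5) -> float:
    """Kullback-Leibler divergence D(p_ref || p_test) over common bins.

    A pseudocount (default 1/2) is added to every bin weight of both
    histograms before normalizing, keeping the divergence finite on empty
    bins; pass ``pseudocount=0`` for the raw definition (then bins where the
    test weight vanishes but the reference does not raise an error).
    """
    if len(p_ref.edges) != len(p_test.edges) or \
            not np.allclose(p_ref.edges, p_test.edges):
        raise ValueError("histograms must share bin edges")
    wr = p_ref.weights + pseudocount
    wt = p_test.weights + pseudocount
    pr = wr / wr.sum()
    pt = wt / wt.sum()
    if pseudocount == 0:
        if np.any((pr > 0) & (pt == 0)):
            raise ValueError("test histogram has zero mass where reference "
                             "does not; use a pseudocount")
        mask = pr > 0
        return float(np.sum(pr[mask] * np.log(pr[mask] / pt[mask])))
    return float(np.sum(np.where(pr > 0, pr * np.log(pr / pt), 0.0)))


@dataclass
class KymographMatrix:
    """Monomer counts per (time, spatial bin) along the box's major axis."""

    times: np.ndarray
    edges: np.ndarray
    counts: np.ndarray  # (n_times, n_bins)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=[
            f"bin_{i}" for i in range(self.counts.shape[1])])
        df.insert(0, "time", self.times)
        return df


def kymograph(snapshots: Sequence[ParticleSnapshot],
              n_bins: int = 20) -> KymographMatrix:
    """Monomer counts in equal-sized bins along the major axis vs time."""
    if not snapshots:
        raise ValueError("need at least one snapshot")
    geom = snapshots[0].geometry
    if not isinstance(geom, Box):
        raise ValueError("kymographs require a box geometry")
    axis = int(np.argmax(geom.lengths))
    L = geom.lengths[axis]
    edges = np.linspace(0.0, L, n_bins + 1)
    times = np.array([s.time for s in snapshots])
    counts = np.stack([
        np.histogram(s.x_positions[:, axis], bins=edges)[0] for s in snapshots])
    return KymographMatrix(times=times, edges=edges, counts=counts)


@dataclass
class SwitchRecord:
    """Detected state switches of a trajectory under hysteresis thresholding."""

    times: np.ndarray
    directions: tuple[str, ...]  # "low->high" / "high->low", strictly alternating
    initial_state: str
    thresholds: tuple[float, float]

    @property
    def n_switches(self) -> int:
        return len(self.directions)

    @property
    def has_reversible_switch(self) -> bool:
        """True when both directions were observed (one full round trip)."""
        return "low->high" in self.directions and "high->low" in self.directions


def detect_switches(traj: Trajectory, params: RateParameters,
                    V: float | None = None) -> SwitchRecord:
    """Hysteresis-thresholded switch detection.

    Thresholds are the midpoints between the deterministic unstable root and
    each stable root: a switch to high fires when x crosses above
    (x_mid + x_high)/2 having last been below (x_low + x_mid)/2, and
    symmetrically.  Oscillations inside one basin are suppressed by
    construction; directions alternate.
    """
    ss = steady_states(params)
    if not ss.bistable:
        raise ValueError("switch thresholds undefined: parameters are monostable")
    V = V if V is not None else traj.V
    lower = 0.5 * (ss.low + ss.middle)
    upper = 0.5 * (ss.middle + ss.high)
    x = traj.X / V
    state = "low" if x[0] < ss.middle else "high"
    initial = state
    t_sw, dirs = [], []
    for t, xi in zip(traj.times, x):
        if state == "low" and xi > upper:
            state = "high"
            t_sw.append(t)
            dirs.append("low->high")
        elif state == "high" and xi < lower:
            state = "low"
            t_sw.append(t)
            dirs.append("high->low")
    return SwitchRecord(times=np.array(t_sw), directions=tuple(dirs),
                        initial_state=initial, thresholds=(lower, upper))


def classify_bistable(traj_low: Trajectory, traj_high: Trajectory,
                      params: RateParameters,
                      V: float | None = None) -> bool:
    """Bistable iff both runs (started low and high) show a reversible switch."""
    rec_lo = detect_switches(traj_low, params, V)
    rec_hi = detect_switches(traj_high, params, V)
    return rec_lo.has_reversible_switch and rec_hi.has_reversible_switch


def bistable_range(params: RateParameters, V: float, B_grid,
                   mode: str = "well-mixed",
                   D: tuple[float, float] = (3.0, 1.0),
                   t_max: float = 10_000.0, seed: int = 0,
                   **kw) -> tuple[float, float] | None:
    """Bistable B interval, from the master equation or from particle runs.

    ``well-mixed`` delegates to the exact-distribution bimodality scan;
    ``spatial`` runs paired low/high-start particle simulations of length
    ``t_max`` per grid point and applies the reversible-switch
    classification.  Returns ``(B_low, B_high)`` or ``None``.
    """
    B_grid = np.asarray(B_grid, dtype=float)
    if mode == "well-mixed":
        from .cme import bimodal_range

        return bimodal_range(params, V, B_range=(B_grid[0], B_grid[-1]),
                             step=float(B_grid[1] - B_grid[0]), **kw)
    if mode != "spatial":
        raise ValueError("mode must be 'well-mixed' or 'spatial'")
    from .particles import SimConfig, simulate_particles

    flags = []
    for i, B in enumerate(B_grid):
        p = params.with_B(B)
        ss = steady_states(p)
        if not ss.bistable:
            flags.append(False)
            continue
        trajs = []
        for j, x_start in enumerate((ss.low, ss.high)):
            cfg = SimConfig(params=p, geometry=Box.cube(V),
                            D_X=D[0], D_X2=D[1], t_max=t_max,
                            seed=seed + 1000 * i + j, initial_x=x_start, **kw)
            traj, _ = simulate_particles(cfg)
            trajs.append(traj)
        flags.append(classify_bistable(trajs[0], trajs[1], p, V))
    flags = np.array(flags)
    if not flags.any():
        return None
    idx = np.flatnonzero(flags)
    return float(B_grid[idx[0]]), float(B_grid[idx[-1]])
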