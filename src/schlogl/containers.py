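"""Shared in-memory containers: trajectories and time-weighted histograms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "Histogram1D"]


@dataclass
class Trajectory:
    """Time-stamped copy numbers from an event-driven or particle simulation.

    ``times`` is strictly increasing; ``X`` (monomers) and ``X2`` (dimers) are
    nonnegative integers sampled either at every reaction event or on a
    uniform recording grid — downstream time-weighted statistics treat both
    the same way (each record holds until the next).
    """

    times: np.ndarray
    X: np.ndarray
    X2: np.ndarray
    scheme: str                 # conventional | generalized | generalized-renormalized | particle
    V: float
    seed: int | None = None
    t_max: float | None = None  # simulated horizon (>= times[-1])

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.X = np.asarray(self.X)
        self.X2 = np.asarray(self.X2)
        if not (len(self.times) == len(self.X) == len(self.X2)):
            raise ValueError("times, X, X2 must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.X) and (np.any(self.X < 0) or np.any(self.X2 < 0)):
            raise ValueError("copy numbers must be nonnegative")
        if self.t_max is None and len(self.times):
            self.t_max = float(self.times[-1])

    def __len__(self) -> int:
        return len(self.times)

    def x(self) -> np.ndarray:
        """Monomer concentration x = X / V."""
        return self.X / self.V

    def holding_times(self) -> np.ndarray:
        """Time each record persists (last record held until ``t_max``)."""
        if len(self.times) == 0:
            return np.empty(0)
        end = self.t_max if self.t_max is not None else self.times[-1]
        return np.diff(np.append(self.times, end))


@dataclass
class Histogram1D:
    """Histogram with explicit bin edges and (unnormalized) weights."""

    edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.edges) != len(self.weights) + 1:
            raise ValueError("need len(edges) == len(weights) + 1")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def masses(self) -> np.ndarray:
        tot = self.weights.sum()
        if tot == 0:
            raise ValueError("empty histogram")
        return self.weights / tot

    @property
    def density(self) -> np.ndarray:
        return self.masses / np.diff(self.edges)

    def mean(self) -> float:
        return float(np.sum(self.masses * self.centers))
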