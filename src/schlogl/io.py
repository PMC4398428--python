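"""Plain-text file I/O: CSV tables, XYZ-like snapshots, run manifests.

All writers are loss-free for integers and round-trip floats to 1e-12 or
better (``%.17g``); every CLI run drops a manifest (config echo + seed +
package version) next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import Histogram1D, Trajectory
from .geometry import Box, Cylinder, Geometry, ParticleSnapshot, Sphere

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_distribution", "read_distribution",
    "write_histogram", "read_histogram",
    "write_snapshots", "read_snapshots",
    "write_manifest",
]

_FMT = "%.17g"


def _write_csv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format=_FMT)


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh)
        except pd.errors.ParserError as exc:
            raise ValueError(f"corrupted CSV {path}: {exc}") from exc
    return df, meta


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    df = pd.DataFrame({"t": traj.times, "X": traj.X, "X2": traj.X2})
    _write_csv(Path(path), df, {
        "scheme": traj.scheme, "V": repr(traj.V),
        "seed": traj.seed, "t_max": repr(traj.t_max)})


def read_trajectory(path: str | Path) -> Trajectory:
    df, meta = _read_csv(Path(path))
    return Trajectory(
        times=df["t"].to_numpy(), X=df["X"].to_numpy(dtype=np.int64),
        X2=df["X2"].to_numpy(dtype=np.int64),
        scheme=meta.get("scheme", "unknown"), V=float(meta["V"]),
        seed=None if meta.get("seed") in (None, "None") else int(meta["seed"]),
        t_max=None if meta.get("t_max") in (None, "None") else float(meta["t_max"]))


def write_distribution(path: str | Path, dist) -> None:
    """Write a stationary CME distribution as (X, p) columns."""
    df = pd.DataFrame({"X": dist.X, "p": dist.p})
    _write_csv(Path(path), df, {"V": repr(dist.V), "log_Z": repr(dist.log_Z)})


def read_distribution(path: str | Path):
    from .cme import CMEDistribution

    df, meta = _read_csv(Path(path))
    return CMEDistribution(V=float(meta["V"]), p=df["p"].to_numpy(),
                           log_Z=float(meta.get("log_Z", "nan")))


def write_histogram(path: str | Path, hist: Histogram1D) -> None:
    df = pd.DataFrame({"edge_left": hist.edges[:-1], "edge_right": hist.edges[1:],
                       "weight": hist.weights})
    _write_csv(Path(path), df, {})


def read_histogram(path: str | Path) -> Histogram1D:
    df, _ = _read_csv(Path(path))
    edges = np.append(df["edge_left"].to_numpy(), df["edge_right"].to_numpy()[-1])
    return Histogram1D(edges=edges, weights=df["weight"].to_numpy())


# --- XYZ-like snapshot frames ------------------------------------------------


def _geometry_to_json(geom: Geometry) -> str:
    if isinstance(geom, Box):
        d = {"kind": "box", "Lx": geom.Lx, "Ly": geom.Ly, "Lz": geom.Lz,
             "periodic": geom.periodic}
    else:
        d = {"kind": "sphere", "radius": geom.radius}
        if geom.cylinder is not None:
            d["cylinder"] = {"radius": geom.cylinder.radius,
                             "half_length": geom.cylinder.half_length}
    return json.dumps(d)


def _geometry_from_json(text: str) -> Geometry:
    d = json.loads(text)
    if d["kind"] == "box":
        return Box(d["Lx"], d["Ly"], d["Lz"], periodic=d["periodic"])
    cyl = d.get("cylinder")
    return Sphere(radius=d["radius"],
                  cylinder=Cylinder(**cyl) if cyl else None)


def write_snapshots(path: str | Path,
                    snapshots: Sequence[ParticleSnapshot]) -> None:
    """Frame-separated XYZ-like text: species label then coordinates per line."""
    with open(path, "w") as fh:
        for snap in snapshots:
            fh.write(f"{snap.n_X + snap.n_X2}\n")
            fh.write(f"time={snap.time!r} geometry={_geometry_to_json(snap.geometry)}\n")
            for label, pos in (("X", snap.x_positions), ("X2", snap.x2_positions)):
                for row in pos:
                    fh.write(f"{label} {row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")


def read_snapshots(path: str | Path) -> list[ParticleSnapshot]:
    out: list[ParticleSnapshot] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected atom count") from exc
            comment = fh.readline()
            lineno += 1
            fields = dict(part.split("=", 1) for part in comment.strip().split(" ", 1))
            time = float(fields["time"])
            geom = _geometry_from_json(fields["geometry"])
            xs, x2s = [], []
            for _ in range(n):
                parts = fh.readline().split()
                lineno += 1
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed coordinate line")
                (xs if parts[0] == "X" else x2s).append(
                    [float(parts[1]), float(parts[2]), float(parts[3])])
            out.append(ParticleSnapshot(
                time=time,
                x_positions=np.array(xs).reshape(-1, 3),
                x2_positions=np.array(x2s).reshape(-1, 3),
                geometry=geom))
    return out


def _pythonize(obj):
    if isinstance(obj, dict):
        return {k: _pythonize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pythonize(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(out_dir: str | Path, subcommand: str, seed: int | None,
                   config: dict) -> Path:
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("schlogl")
    except PackageNotFoundError:
        ver = "unknown"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump({
        "subcommand": subcommand, "seed": seed, "version": ver,
        "config": _pythonize(config)}, sort_keys=True))
    return path
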