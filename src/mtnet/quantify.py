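"""Trajectory readouts: signed sliding speed and cluster sizes.

Two observables characterize the self-organized network state:

* **Signed microtubule speed** -- for each filament and each analysis
  window of length ``delta_t``, the unwrapped minus-end displacement is
  projected on the filament axis *at the window start*, oriented from
  the plus end toward the minus end; averaging over filaments and
  windows and dividing by ``delta_t`` gives the mean speed.  Positive
  speed means minus-end-leading sliding (the signature of plus-end
  directed cross-linker driven transport); negative means plus-end
  leading.  ``delta_t`` is chosen large (640 or 1,280 s at full scale)
  so diffusion is negligible against directed motion.

* **Bundle / aster size** -- filaments are nodes of a graph with an
  edge for every doubly-bound cross-linker of a given type; the largest
  connected component divided by the total filament count is reported
  (by convention the bundle size for KIF11 and the aster size for
  HSET).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "ClusterReport",
    "signed_mt_speed",
    "windowed_speeds",
    "crosslink_clusters",
    "timeseries_summary",
]


@dataclass
class Frame:
    """One sampled snapshot: filament vertices (unwrapped) and the
    cross-linker anchor table."""

    time: float
    vertices: list[np.ndarray]  # per filament, (nv, 3); vertex 0 = minus end
    link_spec: np.ndarray  # (NL,) spec index
    link_fil: np.ndarray  # (NL, 2) filament id or -1
    link_abs: np.ndarray  # (NL, 2) abscissa

    @property
    def n_filaments(self) -> int:
        return len(self.vertices)


@dataclass
class Trajectory:
    """Time-ordered frames plus provenance metadata."""

    frames: list[Frame]
    linker_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def frame_interval(self) -> float:
        if len(self.frames) < 2:
            raise ValueError("need >= 2 frames for an interval")
        return self.frames[1].time - self.frames[0].time

    def frame_at(self, time: float, tol: float = 1e-6) -> Frame:
        """Frame captured at a given time (exact match within tol)."""
        for f in self.frames:
            if abs(f.time - time) <= tol:
                return f
        raise KeyError(f"no frame at t = {time}")


@dataclass
class ClusterReport:
    """Connected components of the cross-link graph in one frame."""

    linker_type: str | None
    largest_fraction: float
    component_sizes: list[int]


def _axis_plus_to_minus(verts: np.ndarray) -> np.ndarray | None:
    a = verts[0] - verts[-1]
    n = np.linalg.norm(a)
    return a / n if n > 1e-12 else None


def _component_size_per_filament(frame: Frame) -> np.ndarray:
    """Size of the cross-link connected component each filament
    belongs to (any doubly-bound linker type)."""
    n = frame.n_filaments
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for li in range(frame.link_fil.shape[0]):
        a, b = frame.link_fil[li]
        if a >= 0 and b >= 0:
            g.add_edge(int(a), int(b))
    sizes = np.ones(n, dtype=int)
    for comp in nx.connected_components(g):
        for node in comp:
            sizes[node] = len(comp)
    return sizes


def _window_stride(traj: Trajectory, delta_t: float) -> int:
    fi = traj.frame_interval
    m = delta_t / fi
    if abs(m - round(m)) > 1e-6 or round(m) < 1:
        raise ValueError(
            f"delta_t = {delta_t} is not a multiple of the frame "
            f"interval {fi}")
    return int(round(m))


def windowed_speeds(traj: Trajectory, delta_t: float,
                    min_cluster_size: int = 1
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean signed speed in each disjoint window of length ``delta_t``.

    Returns ``(window_end_times, speeds)``; each window averages over
    the filaments existing at its start.  With ``min_cluster_size > 1``
    the average is restricted to filaments belonging, at the window
    start, to a cross-link connected component of at least that size —
    the sliding speed of the cross-linked (bundled) population, a much
    less diffusion-noisy readout in small systems where most filaments
    stay unlinked.  Windows with no qualifying filament are skipped.
    """
    m = _window_stride(traj, delta_t)
    n = len(traj.frames)
    times = []
    speeds = []
    for i0 in range(0, n - m, m):
        f0 = traj.frames[i0]
        f1 = traj.frames[i0 + m]
        dt_w = f1.time - f0.time
        sizes = (_component_size_per_filament(f0)
                 if min_cluster_size > 1 else None)
        vals = []
        for fi in range(f0.n_filaments):
            if sizes is not None and sizes[fi] < min_cluster_size:
                continue
            axis = _axis_plus_to_minus(f0.vertices[fi])
            if axis is None:
                continue
            disp = f1.vertices[fi][0] - f0.vertices[fi][0]
            vals.append(float(np.dot(disp, axis)) / dt_w)
        if vals:
            times.append(f1.time)
            speeds.append(float(np.mean(vals)))
    return np.array(times), np.array(speeds)


def signed_mt_speed(traj: Trajectory, delta_t: float,
                    min_cluster_size: int = 1) -> float:
    """Overall mean signed minus-end displacement speed (µm/s).

    Positive = minus-end-leading unidirectional sliding.
    """
    if len(traj.frames) < 2 or traj.frames[-1].time - traj.frames[0].time \
            < delta_t - 1e-9:
        raise ValueError("trajectory shorter than delta_t")
    _, speeds = windowed_speeds(traj, delta_t, min_cluster_size)
    if speeds.size == 0:
        raise ValueError("no filaments to average over")
    return float(np.mean(speeds))


def crosslink_clusters(frame: Frame, linker_type: str | None = None,
                       linker_names: list[str] | None = None
                       ) -> ClusterReport:
    """Connected components of filaments cross-linked by one linker type.

    An edge requires a *doubly bound* linker (both units engaged on two
    distinct filaments); ``linker_type`` None uses all types.  The
    largest component size is normalized by the total filament count.
    """
    n = frame.n_filaments
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if linker_type is not None:
        if linker_names is None:
            raise ValueError("linker_names required to select a type")
        wanted = {i for i, nm in enumerate(linker_names) if nm == linker_type}
    for li in range(frame.link_fil.shape[0]):
        a, b = frame.link_fil[li]
        if a < 0 or b < 0:
            continue
        if linker_type is not None and int(frame.link_spec[li]) not in wanted:
            continue
        g.add_edge(int(a), int(b))
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    largest = sizes[0] if sizes else 0
    return ClusterReport(
        linker_type=linker_type,
        largest_fraction=largest / n if n else 0.0,
        component_sizes=sizes)


def timeseries_summary(traj: Trajectory,
                       delta_t: float | None = None) -> pd.DataFrame:
    """Tabulate time versus mean signed speed and per-type largest
    cluster fractions.

    One row per captured frame on the analysis grid: cluster fractions
    are instantaneous; the speed column reports the disjoint window
    ending at that row (NaN before the first full window).  A
    single-frame trajectory yields cluster columns only.
    """
    if not traj.frames:
        raise ValueError("empty trajectory")
    types = sorted(set(traj.linker_names))
    m = _window_stride(traj, delta_t) if delta_t is not None \
        and len(traj.frames) > 1 else None
    rows = []
    for i, frame in enumerate(traj.frames):
        if m is not None and i % m != 0:
            continue
        row: dict = {"time_s": frame.time}
        if m is not None:
            row["speed_um_per_s"] = np.nan
        for t in types:
            rep = crosslink_clusters(frame, t, traj.linker_names)
            row[f"largest_{t}_fraction"] = rep.largest_fraction
        row["largest_any_fraction"] = crosslink_clusters(
            frame).largest_fraction
        rows.append(row)
    df = pd.DataFrame(rows)
    if m is not None:
        times, speeds = windowed_speeds(traj, delta_t)
        for t, s in zip(times, speeds):
            df.loc[np.isclose(df["time_s"], t), "speed_um_per_s"] = s
    return df
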