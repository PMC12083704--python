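"""School-level order parameters, structure statistics and clustering.

Covers the polar order parameter, per-frame geometry (school length,
nearest-neighbour and Voronoi-neighbour distances, density), the dominant
frequency of dP/dt used to time split/merge events, and density-based
cluster identification (HDBSCAN) with greedy frame-to-frame tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.cluster import HDBSCAN

from hydroschool.model_core import (
    DegenerateGeometryError,
    NeighborGraph,
    SchoolState,
    voronoi_neighbors,
    wrap_angle,
)
from hydroschool.simulator import Trajectory

__all__ = [
    "polarization",
    "FrameStats",
    "frame_stats",
    "stats_table",
    "dominant_frequency",
    "ClusterLabels",
    "cluster_frame",
    "ClusterTimeseries",
    "cluster_timeseries",
    "split_merge_events",
    "track_clusters",
]


def polarization(theta: np.ndarray, subset=None) -> float:
    """Polar order parameter ``P = |sum_j p_j| / n`` over a subset.

    1 for perfect alignment, ~0 for randomly oriented swimmers.
    """
    theta = np.asarray(theta, dtype=float)
    if subset is not None:
        theta = theta[np.asarray(subset, dtype=int)]
    if theta.size == 0:
        raise ValueError("polarization of an empty subset is undefined")
    return float(np.abs(np.exp(1j * theta).mean()))


@dataclass(frozen=True)
class FrameStats:
    P: float
    v_mean: np.ndarray
    heading: float
    speed: float
    L: float        # school length: max pairwise distance
    nnd: float      # mean nearest-neighbour distance
    vnd: float      # mean distance to Voronoi neighbours
    density: float  # swimmers per unit convex-hull area


def school_length(x: np.ndarray) -> float:
    """Max pairwise distance, computed on the convex hull vertices."""
    hull = ConvexHull(x)
    pts = x[hull.vertices]
    d = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", d, d).max()))


def frame_stats(state: SchoolState, graph: NeighborGraph | None = None) -> FrameStats:
    """All per-frame statistics for one school state.

    Density is N over the convex-hull area of the positions; VND averages,
    over swimmers, the mean distance to the swimmer's Voronoi neighbours.
    """
    x = state.x
    if state.n < 3:
        raise ValueError("frame statistics need at least 3 swimmers")
    if graph is None:
        graph = voronoi_neighbors(x)
    try:
        hull = ConvexHull(x)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate convex hull: {exc}") from exc
    v = state.v if state.v is not None else state.p
    v_mean = v.mean(axis=0)
    tree = cKDTree(x)
    dn, _ = tree.query(x, k=2)
    e = graph.edges
    elen = np.hypot(*(x[e[:, 0]] - x[e[:, 1]]).T)
    # per-swimmer mean over incident edges, then mean over swimmers
    s = np.bincount(e.ravel(), weights=np.repeat(elen, 2), minlength=state.n)
    deg = graph.degree()
    return FrameStats(
        P=polarization(state.theta),
        v_mean=v_mean,
        heading=float(np.arctan2(v_mean[1], v_mean[0])),
        speed=float(np.hypot(*v_mean)),
        L=school_length(x),
        nnd=float(dn[:, 1].mean()),
        vnd=float((s / deg).mean()),
        density=float(state.n / hull.volume),
    )


def stats_table(traj: Trajectory, min_cluster_size: int | None = None) -> pd.DataFrame:
    """Per-frame statistics of a trajectory as a DataFrame."""
    rows = []
    for f in range(traj.n_frames):
        st = traj.state(f)
        fs = frame_stats(st)
        row = {"frame": f, "t": traj.times[f], "P": fs.P, "speed": fs.speed,
               "heading": fs.heading, "L": fs.L, "nnd": fs.nnd, "vnd": fs.vnd,
               "density": fs.density}
        if min_cluster_size is not None:
            row["n_clusters"] = cluster_frame(st.x, min_cluster_size).n_clusters
        rows.append(row)
    return pd.DataFrame(rows)


def dominant_frequency(series: np.ndarray, dt_sample: float,
                       f_max: float = 0.5) -> float | None:
    """Dominant frequency of the time derivative of a series, low-passed.

    Differentiates by central differences, takes the FFT amplitude and
    returns the frequency of the largest peak in ``0 < f <= f_max``
    (frequencies above ``f_max`` are discarded; they reflect
    individual-level noise rather than split/merge events).  Returns None
    for a series with no spectral content below the cut.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 16:
        raise ValueError("need at least 16 samples")
    dsdt = np.gradient(series, dt_sample)
    amp = np.abs(np.fft.rfft(dsdt))
    freq = np.fft.rfftfreq(series.size, d=dt_sample)
    keep = (freq > 0) & (freq <= f_max)
    if not keep.any() or np.allclose(amp[keep], 0.0):
        return None
    k = np.flatnonzero(keep)[np.argmax(amp[keep])]
    return float(freq[k])


@dataclass
class ClusterLabels:
    """HDBSCAN labels for one frame; -1 marks noise points."""

    labels: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels[self.labels >= 0]).size)

    def sizes(self) -> np.ndarray:
        lab = self.labels[self.labels >= 0]
        return np.bincount(lab) if lab.size else np.array([], dtype=int)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def cluster_frame(x: np.ndarray, min_cluster_size: int = 20,
                  min_samples: int = 5) -> ClusterLabels:
    """Density-based clustering of raw 2-D positions (HDBSCAN, Euclidean).

    ``allow_single_cluster`` is enabled because a cohesive school is a
    single density mode, an outcome the algorithm's default tree-pruning
    rule can never report; ``min_samples`` is kept small so that border
    swimmers of a uniform school are not shed as noise.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < min_cluster_size:
        raise ValueError("fewer swimmers than min_cluster_size")
    labels = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=min_samples,
                     allow_single_cluster=True).fit_predict(x)
    return ClusterLabels(labels=np.asarray(labels))


@dataclass
class ClusterTimeseries:
    frames: np.ndarray
    labels: list            # ClusterLabels per frame
    counts: np.ndarray      # clusters per frame
    sizes: list             # array of cluster sizes per frame

    def size_distribution(self) -> np.ndarray:
        return np.concatenate([s for s in self.sizes if s.size]) \
            if any(s.size for s in self.sizes) else np.array([], dtype=int)


def cluster_timeseries(traj: Trajectory, min_cluster_size: int = 20) -> ClusterTimeseries:
    labels = [cluster_frame(traj.x[f], min_cluster_size)
              for f in range(traj.n_frames)]
    return ClusterTimeseries(
        frames=np.arange(traj.n_frames),
        labels=labels,
        counts=np.array([l.n_clusters for l in labels]),
        sizes=[l.sizes() for l in labels],
    )


def split_merge_events(counts: np.ndarray, persist: int = 10) -> list[dict]:
    """Debounced split/merge events from the cluster-count series.

    A split (merge) is a frame where the count increases (decreases) from
    the previous frame and the count stays away from the old value for at
    least ``persist`` subsequent frames.
    """
    counts = np.asarray(counts)
    events = []
    for f in range(1, counts.size):
        old, new = counts[f - 1], counts[f]
        if new == old:
            continue
        tail = counts[f:f + persist]
        if tail.size < persist or np.any(tail == old):
            continue
        events.append({"frame": f, "kind": "split" if new > old else "merge",
                       "from": int(old), "to": int(new)})
    return events


def track_clusters(labels_per_frame: list, min_overlap: float = 0.5) -> list[dict]:
    """Greedy frame-to-frame cluster tracking by maximal member overlap.

    Returns, per frame, a dict mapping persistent track id to the member
    index array.  A current cluster continues a track when it shares at
    least ``min_overlap`` of its members with the track's previous frame;
    pairs are matched greedily by descending overlap count.
    """
    tracks_prev: dict[int, np.ndarray] = {}
    next_id = 0
    out = []
    for cl in labels_per_frame:
        current = {int(l): cl.members(l) for l in np.unique(cl.labels) if l >= 0}
        cand = []
        for tid, prev_members in tracks_prev.items():
            prev_set = set(prev_members.tolist())
            for lab, mem in current.items():
                ov = sum(1 for m in mem if m in prev_set)
                if ov >= min_overlap * min(len(mem), len(prev_members)):
                    cand.append((ov, tid, lab))
        cand.sort(key=lambda c: (-c[0], c[1], c[2]))
        assigned: dict[int, np.ndarray] = {}
        used_tracks, used_labels = set(), set()
        for ov, tid, lab in cand:
            if tid in used_tracks or lab in used_labels:
                continue
            assigned[tid] = current[lab]
            used_tracks.add(tid)
            used_labels.add(lab)
        for lab, mem in sorted(current.items()):
            if lab not in used_labels:
                assigned[next_id] = mem
                next_id += 1
        out.append(assigned)
        tracks_prev = assigned
    return out


def mean_heading(theta: np.ndarray) -> float:
    """Circular mean of heading angles."""
    return float(np.angle(np.exp(1j * np.asarray(theta)).mean()))


def heading_change(theta_a: np.ndarray, theta_b: np.ndarray) -> float:
    """Wrapped change of the circular mean heading between two frames."""
    return float(wrap_angle(mean_heading(theta_b) - mean_heading(theta_a)))
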