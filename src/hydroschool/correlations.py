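"""Velocity-fluctuation correlations and the scale-free length diagnostic.

For a (sub)group with velocities ``v_i`` the fluctuations are
``dv_i = v_i - <v>`` (zero-sum by construction).  The spatial correlation

    C(r) = sum_{ij} dv_i . dv_j delta(r - r_ij) / sum_{ij} delta(r - r_ij)

is normalised so C(0) = 1; the correlation length ``xi`` is the first zero
crossing of C, i.e. the size of the positively correlated domain.  In
cohesive polarized schools ``xi`` grows linearly with the school length L
(scale-free correlation), and a drop of ``xi/L`` below the scale-free line
precedes fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from hydroschool.metrics import polarization, school_length, track_clusters
from hydroschool.simulator import Trajectory

__all__ = [
    "velocity_fluctuations",
    "CorrelationCurve",
    "correlation_function",
    "correlation_length",
    "scale_free_fit",
    "xi_L_points",
    "precursor_series",
]


def velocity_fluctuations(v: np.ndarray, subset=None) -> np.ndarray:
    """Fluctuations ``dv_i = v_i - mean(v)`` over a subset; zero-sum."""
    v = np.asarray(v, dtype=float)
    if subset is not None:
        v = v[np.asarray(subset)]
    if v.shape[0] < 2:
        raise ValueError("need at least 2 swimmers for fluctuations")
    return v - v.mean(axis=0)


@dataclass
class CorrelationCurve:
    """Binned C(r).  Bins with no pairs hold NaN; ``r`` gives bin centers."""

    r: np.ndarray
    C: np.ndarray
    n_pairs: np.ndarray
    L: float
    bin_width: float

    @property
    def xi(self) -> float | None:
        return correlation_length(self)


def correlation_function(dv: np.ndarray, x: np.ndarray,
                         bin_width: float | None = None) -> CorrelationCurve:
    """Distance-binned velocity-fluctuation correlation, C(0) = 1.

    The Dirac delta is realised as binning with ``bin_width`` (default
    L/50); the i = j pairs populate the r = 0 bin, whose value sets the
    normalisation.  Raises if all fluctuations vanish.
    """
    dv = np.asarray(dv, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 swimmers")
    if not np.any(np.abs(dv) > 0):
        raise ValueError("all velocity fluctuations vanish; C(r) undefined")
    L = school_length(x) if n > 3 else float(pdist(x).max())
    if bin_width is None:
        bin_width = L / 50.0
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = pdist(x)
    # pairwise dv_i . dv_j in condensed (pdist) order
    iu, ju = np.triu_indices(n, k=1)
    prod = np.einsum("ij,ij->i", dv[iu], dv[ju])
    # first bin is [0, bin_width/2): reserved for the i = j (r = 0) pairs
    edges = np.concatenate([[0.0, bin_width / 2.0],
                            np.arange(1.5, np.ceil(L / bin_width) + 1.5) * bin_width])
    idx = np.digitize(d, edges) - 1
    nbins = edges.size - 1
    num = np.bincount(idx, weights=2.0 * prod, minlength=nbins)[:nbins]
    cnt = np.bincount(idx, weights=None, minlength=nbins)[:nbins].astype(float)
    cnt *= 2.0
    # i = j pairs at r exactly 0
    num[0] += np.einsum("ij,ij->", dv, dv)
    cnt[0] += n
    C0 = num[0] / cnt[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(cnt > 0, num / np.maximum(cnt, 1) / C0, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    centers[0] = 0.0
    return CorrelationCurve(r=centers, C=C, n_pairs=cnt.astype(int), L=L,
                            bin_width=float(bin_width))


def correlation_length(curve: CorrelationCurve) -> float | None:
    """First zero crossing of C(r), by linear interpolation between bins.

    Returns None when C never becomes non-positive over the defined bins.
    """
    ok = np.isfinite(curve.C)
    r = curve.r[ok]
    C = curve.C[ok]
    if r.size < 2:
        return None
    below = np.flatnonzero(C <= 0.0)
    if below.size == 0:
        return None
    k = below[0]
    if k == 0:
        return float(r[0])
    r0, r1 = r[k - 1], r[k]
    c0, c1 = C[k - 1], C[k]
    if c0 == c1:
        return float(r1)
    return float(r0 + (r1 - r0) * c0 / (c0 - c1))


def scale_free_fit(points) -> tuple[float, float, float]:
    """OLS of xi on L over (L, xi) points; returns (slope, intercept, R^2)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 (L, xi) points")
    L, xi = pts[:, 0], pts[:, 1]
    if np.ptp(L) == 0:
        raise ValueError("degenerate spread in L")
    res = linregress(L, xi)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def xi_L_points(traj: Trajectory, p_min: float = 0.9,
                frame_range: slice | None = None,
                bin_width: float | None = None) -> list[tuple[float, float]]:
    """(L, xi) points from all snapshots of a cohesive run with P > p_min."""
    frames = range(traj.n_frames)[frame_range or slice(None)]
    pts = []
    for f in frames:
        if polarization(traj.theta[f]) <= p_min:
            continue
        dv = velocity_fluctuations(traj.v[f])
        curve = correlation_function(dv, traj.x[f], bin_width)
        xi = curve.xi
        if xi is not None:
            pts.append((curve.L, xi))
    return pts


def precursor_series(traj: Trajectory, labels_per_frame: list,
                     p_min: float = 0.9, min_size: int = 30) -> pd.DataFrame:
    """Per-tracked-cluster time series of P, L, xi and xi/L.

    Clusters are tracked across frames by greedy maximal-overlap matching.
    Frames where a cluster's polarization does not exceed ``p_min`` are
    flagged ``excluded`` and carry NaN for xi; a sustained decrease of
    xi/L while P stays high is the fragmentation precursor.
    """
    tracks = track_clusters(labels_per_frame)
    rows = []
    for f, assigned in enumerate(tracks):
        for tid, members in sorted(assigned.items()):
            if members.size < min_size:
                continue
            P = polarization(traj.theta[f], members)
            row = {"frame": f, "t": traj.times[f], "track": tid,
                   "n": members.size, "P": P, "excluded": P <= p_min,
                   "L": np.nan, "xi": np.nan, "xi_over_L": np.nan}
            if P > p_min:
                dv = velocity_fluctuations(traj.v[f], members)
                curve = correlation_function(dv, traj.x[f][members])
                row["L"] = curve.L
                xi = curve.xi
                if xi is not None:
                    row["xi"] = xi
                    row["xi_over_L"] = xi / curve.L
            rows.append(row)
    return pd.DataFrame(rows)
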