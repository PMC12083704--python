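"""Synthetic trajectories with known ground truth for the analysis stack.

Every analysis stage (clustering, correlation length, turn delays and
information speed) can be exercised against these generators without
running long simulations.  Fixtures are deterministic under their seed and
write the same trajectory container as the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hydroschool.model_core import ModelParams
from hydroschool.simulator import Trajectory

__all__ = [
    "ScriptedTurn",
    "make_scripted_turn",
    "CorrelatedFluctuations",
    "make_correlated_fluctuations",
    "TwoBlobSplit",
    "make_two_blob_split",
    "paper_presets",
    "PRESETS",
]


def _disk_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    a = rng.uniform(-np.pi, np.pi, size=n)
    return np.column_stack([r * np.cos(a), r * np.sin(a)])


def _fixture_params(seed: int) -> ModelParams:
    # noise/alignment/flow intensities are irrelevant to a scripted fixture
    return ModelParams(In=0.0, Ia=0.0, If=0.0, dt=0.01, seed=seed)


@dataclass
class ScriptedTurn:
    traj: Trajectory
    origin: int               # index of the swimmer that turns first
    t_start: np.ndarray       # scripted per-swimmer turn onset times
    c_star: float             # scripted information speed (rank-metric)
    rho: float                # true number density
    turn_angle: float


def make_scripted_turn(n: int = 400, rho: float = 1.0, c_star: float = 10.0,
                       turn_angle: float = np.pi / 2, noise: float = 0.0,
                       seed: int = 0, dt_sample: float = 0.1,
                       turn_duration: float = 4.0) -> ScriptedTurn:
    """A turn propagating radially outward from a central origin swimmer.

    Swimmers sit on a disk at density ``rho``, all initially heading +x at
    speed 1.  The swimmer nearest the disk centre turns first; a swimmer at
    physical radius r from it starts turning at ``sqrt(pi) * r / c_star``
    (plus Gaussian jitter of s.d. ``noise``).  The sqrt(pi) maps physical
    radius to the rank-derived information distance ``d = sqrt(o / rho)``
    used by the analysis (o(r) ~ rho*pi*r^2 on a disk), so the pipeline's
    fitted speed estimates ``c_star`` itself.

    The heading ramps smoothly (cosine) from 0 to ``turn_angle`` over
    ``turn_duration``, giving a single clean curvature peak per swimmer.
    """
    if c_star <= 0:
        raise ValueError("c_star must be positive")
    rng = np.random.default_rng(seed)
    R = np.sqrt(n / (np.pi * rho))
    x0 = _disk_points(n, R, rng)
    origin = int(np.argmin(np.hypot(x0[:, 0], x0[:, 1])))
    r = np.hypot(*(x0 - x0[origin]).T)
    t_start = np.sqrt(np.pi) * r / c_star
    if noise > 0:
        t_start = np.maximum(0.0, t_start + noise * rng.standard_normal(n))
    pad = 5.0
    T = float(t_start.max() + turn_duration + 2 * pad)
    times = np.arange(0.0, T + dt_sample / 2, dt_sample)
    s = np.clip((times[:, None] - pad - t_start[None, :]) / turn_duration, 0.0, 1.0)
    theta = turn_angle * 0.5 * (1.0 - np.cos(np.pi * s))      # (F, n)
    v = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    # positions by trapezoidal integration of the unit-speed headings
    steps = 0.5 * (v[1:] + v[:-1]) * dt_sample
    x = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)], axis=0)
    traj = Trajectory(params=_fixture_params(seed), times=times, x=x,
                      theta=theta, v=v, stride=1)
    return ScriptedTurn(traj=traj, origin=origin, t_start=t_start,
                        c_star=c_star, rho=rho, turn_angle=turn_angle)


@dataclass
class CorrelatedFluctuations:
    x: np.ndarray
    dv: np.ndarray
    xi_star: float
    L: float
    wavenumber: float


#: first zero of the Bessel function J0, which governs the azimuthally
#: averaged correlation of a plane-wave fluctuation mode
_J0_ZERO = 2.404825557695773


def _spiral_wavenumber(xi_star: float, R: float) -> float:
    """Wavenumber whose phase-spiral mode crosses zero at exactly xi_star.

    The mode ``dv = (cos kx, sin kx)`` has pair product ``cos(k dx)``,
    whose azimuthal average over a disk is ``J0(k r)``.  Removing the
    disk mean ``m(k) = 2 J1(kR)/(kR)`` lowers the curve by ``m^2``, so the
    expected crossing solves ``J0(k xi) = m(k)^2``.
    """
    from scipy.optimize import brentq
    from scipy.special import j0, j1

    def f(k):
        kr = k * R
        m = 2.0 * j1(kr) / kr if kr > 0 else 1.0
        return j0(k * xi_star) - m * m

    k0 = _J0_ZERO / xi_star
    return float(brentq(f, 0.3 * k0, 1.2 * k0))


def make_correlated_fluctuations(n: int = 1500, L: float = 30.0,
                                 xi_star: float = 10.0, noise: float = 0.0,
                                 seed: int = 0) -> CorrelatedFluctuations:
    """Fluctuation field with a prescribed correlation zero-crossing.

    Positions fill a disk of diameter ``L``; the fluctuations are a
    long-wavelength phase-spiral mode ``dv = (cos kx, sin kx)`` whose pair
    inner product is exactly ``cos(k(x_i - x_j))``, azimuthally averaging
    to ``J0(k r)``; ``k`` is chosen so that, after mean removal, the
    expected crossing sits at ``r = xi_star``.  Optional isotropic white
    noise rescales C without moving the crossing.  The mean is removed, so
    the fluctuations sum to zero exactly.
    """
    if not 0 < xi_star < 0.45 * L:
        raise ValueError("xi_star must be positive and well below L/2")
    rng = np.random.default_rng(seed)
    x = _disk_points(n, L / 2.0, rng)
    k = _spiral_wavenumber(xi_star, L / 2.0)
    dv = np.column_stack([np.cos(k * x[:, 0]), np.sin(k * x[:, 0])])
    if noise > 0:
        dv += noise * rng.standard_normal((n, 2))
    dv -= dv.mean(axis=0)
    return CorrelatedFluctuations(x=x, dv=dv, xi_star=xi_star, L=L, wavenumber=k)


@dataclass
class TwoBlobSplit:
    traj: Trajectory
    t_split: float
    partition: np.ndarray     # 0/1 group label per swimmer
    blob_radius: float


def make_two_blob_split(n: int = 400, separation_speed: float = 6.0,
                        t_split: float = 20.0, seed: int = 0,
                        dt_sample: float = 1.0, T: float | None = None) -> TwoBlobSplit:
    """A single rigid blob that splits into two receding blobs at t_split.

    All swimmers translate at unit speed along +x until ``t_split``; then
    the two scripted halves veer symmetrically so their centres recede at
    ``separation_speed``.
    """
    rng = np.random.default_rng(seed)
    R = np.sqrt(n / np.pi)    # unit density blob
    x0 = _disk_points(n, R, rng)
    half = np.zeros(n, dtype=int)
    half[n // 2:] = 1
    if T is None:
        T = t_split + 12.0 * R / max(separation_speed, 1e-6)
    times = np.arange(0.0, T + dt_sample / 2, dt_sample)
    after = times[:, None] > t_split                     # (F, 1)
    vy = after * np.where(half[None, :] == 0, 1.0, -1.0) * separation_speed / 2.0
    v = np.stack([np.ones((times.size, n)), vy], axis=-1)
    theta = np.arctan2(v[..., 1], v[..., 0])
    steps = 0.5 * (v[1:] + v[:-1]) * dt_sample
    x = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)], axis=0)
    traj = Trajectory(params=_fixture_params(seed), times=times, x=x,
                      theta=theta, v=v, stride=1)
    return TwoBlobSplit(traj=traj, t_split=t_split, partition=half, blob_radius=R)


#: published parameter sets for the model: the baseline cohesive school and
#: the five (Ia, In) pairs of the alignment/noise sweep; U = 1, dt = 0.01
#: throughout, If = 0.01 unless stated otherwise.
PRESETS: dict = {
    "baseline": ModelParams(Ia=9.0, In=0.5, If=0.01),
    "alignment_noise_sweep": tuple(
        ModelParams(Ia=Ia, In=In, If=0.01)
        for Ia, In in ((9.0, 0.5), (7.0, 0.5), (5.0, 0.5), (9.0, 0.3), (9.0, 0.7))
    ),
}


def paper_presets() -> dict:
    """Named reference parameter sets (swimmer count and duration are the
    caller's choice)."""
    return dict(PRESETS)
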