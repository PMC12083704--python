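"""Euler–Maruyama time integration of the school and trajectory persistence.

The full stochastic dynamics is

    dx_i     = (U p_i + U_i) dt
    dtheta_i = (<r_ij sin theta_ij + Ia sin phi_ij>_i + Omega_i) dt
               + In sqrt(dt) N(0, 1)

where ``<.>_i`` is the visual-weighted mean over Voronoi neighbours, ``U_i``
the superposed dipolar flow and ``Omega_i`` the flow-gradient reorientation.
The Voronoi graph is rebuilt every step.  Runs are deterministic under a
fixed seed (one normal draw per swimmer per step, serial pair-sum kernel).

Trajectories are stored in HDF5 (datasets ``times``, ``x``, ``y``,
``theta``, ``vx``, ``vy`` indexed ``[frame, swimmer]``, parameters as root
attributes) with a flat CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from hydroschool.model_core import (
    ModelParams,
    NeighborGraph,
    SchoolState,
    SingularConfigurationError,
    flow_field_and_omega,
    heading_drift_all,
    voronoi_neighbors,
    wrap_angle,
)

__all__ = [
    "SchemaError",
    "SimConfig",
    "Trajectory",
    "init_random",
    "euler_step",
    "run",
    "write_trajectory",
    "read_trajectory",
    "trajectory_to_csv",
    "load_config",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when a trajectory file does not match the expected layout."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation run specification."""

    N: int
    T: float
    params: ModelParams
    density: float = 1.0
    heading_mode: str = "uniform"   # "uniform" | "aligned"
    record_stride: int = 100

    def __post_init__(self):
        if self.N < 3:
            raise ValueError("N must be at least 3")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass
class Trajectory:
    """Uniformly sampled sequence of school states."""

    params: ModelParams
    times: np.ndarray          # (F,)
    x: np.ndarray              # (F, N, 2)
    theta: np.ndarray          # (F, N)
    v: np.ndarray              # (F, N, 2)
    stride: int = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        f, n = self.theta.shape
        if self.x.shape != (f, n, 2) or self.v.shape != (f, n, 2):
            raise ValueError("inconsistent trajectory array shapes")
        if self.times.shape != (f,):
            raise ValueError("times length does not match frame count")
        if f > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n(self) -> int:
        return self.theta.shape[1]

    @property
    def dt_sample(self) -> float:
        if self.n_frames < 2:
            return self.stride * self.params.dt
        return float(self.times[1] - self.times[0])

    def state(self, frame: int) -> SchoolState:
        return SchoolState(t=float(self.times[frame]), x=self.x[frame],
                           theta=self.theta[frame], v=self.v[frame])


def init_random(N: int, density: float, seed: int,
                heading_mode: str = "uniform") -> SchoolState:
    """Random initial condition: uniform positions in a disk, random headings.

    The disk area is ``N/density`` so the initial number density equals
    ``density``.  ``heading_mode='aligned'`` starts all headings at 0, which
    shortens the transient to the polarized steady state.
    """
    if N < 3:
        raise ValueError("N must be at least 3")
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    R = np.sqrt(N / (np.pi * density))
    r = R * np.sqrt(rng.uniform(size=N))
    ang = rng.uniform(-np.pi, np.pi, size=N)
    x = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    if heading_mode == "aligned":
        theta = np.zeros(N)
    elif heading_mode == "uniform":
        theta = rng.uniform(-np.pi, np.pi, size=N)
    else:
        raise ValueError(f"unknown heading_mode {heading_mode!r}")
    return SchoolState(t=0.0, x=x, theta=theta)


def euler_step(state: SchoolState, graph: NeighborGraph, params: ModelParams,
               rng: np.random.Generator) -> SchoolState:
    """One explicit Euler–Maruyama step of the full dynamics."""
    if state.n == 1:
        flow = np.zeros((1, 2))
        omega = np.zeros(1)
        drift = np.zeros(1)
    else:
        flow, omega = flow_field_and_omega(state.x, state.theta, params.If)
        drift = heading_drift_all(state, graph, params)
    v = params.U * state.p + flow
    dt = params.dt
    noise = params.In * np.sqrt(dt) * rng.standard_normal(state.n)
    x_new = state.x + v * dt
    theta_new = wrap_angle(state.theta + (drift + omega) * dt + noise)
    return SchoolState(t=state.t + dt, x=x_new, theta=theta_new, v=None)


def _record_velocity(state: SchoolState, params: ModelParams) -> np.ndarray:
    flow, _ = flow_field_and_omega(state.x, state.theta, params.If)
    return params.U * state.p + flow


def run(config: SimConfig, initial_state: SchoolState | None = None) -> Trajectory:
    """Integrate the school for time ``T`` and record every stride-th frame.

    The Voronoi graph is rebuilt every step.  Frame 0 is the initial state;
    identical configs and seeds give bitwise-identical trajectories.
    """
    params = config.params
    state = initial_state if initial_state is not None else init_random(
        config.N, config.density, params.seed, config.heading_mode)
    if state.n != config.N:
        raise ValueError("initial state size does not match config.N")
    rng = np.random.default_rng(params.seed + 1)  # noise stream, distinct from init
    n_steps = int(round(config.T / params.dt))
    times, xs, thetas, vs = [], [], [], []

    def record(s: SchoolState):
        times.append(s.t)
        xs.append(s.x.copy())
        thetas.append(s.theta.copy())
        vs.append(_record_velocity(s, params))

    record(state)
    for step in range(1, n_steps + 1):
        try:
            graph = voronoi_neighbors(state.x)
            state = euler_step(state, graph, params, rng)
        except (SingularConfigurationError, FloatingPointError) as exc:
            raise SingularConfigurationError(
                f"singular configuration at step {step} (t={state.t:.3f}): {exc}"
            ) from exc
        if step % config.record_stride == 0:
            record(state)
    return Trajectory(params=params, times=np.array(times), x=np.array(xs),
                      theta=np.array(thetas), v=np.array(vs),
                      stride=config.record_stride)


# ---------------------------------------------------------------------------
# persistence

_PARAM_ATTRS = ("In", "Ia", "If", "U", "gamma", "dt", "seed")


def write_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["stride"] = traj.stride
        for name in _PARAM_ATTRS:
            h5.attrs[name] = getattr(traj.params, name)
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("x", data=traj.x[:, :, 0])
        h5.create_dataset("y", data=traj.x[:, :, 1])
        h5.create_dataset("theta", data=traj.theta)
        h5.create_dataset("vx", data=traj.v[:, :, 0])
        h5.create_dataset("vy", data=traj.v[:, :, 1])


def read_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        version = h5.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported trajectory schema version {version!r} "
                f"(expected {SCHEMA_VERSION})")
        for ds in ("times", "x", "y", "theta"):
            if ds not in h5:
                raise SchemaError(f"trajectory file missing dataset {ds!r}")
        params = ModelParams(**{k: (int(h5.attrs[k]) if k == "seed"
                                    else float(h5.attrs[k]))
                                for k in _PARAM_ATTRS})
        times = h5["times"][:]
        x = np.stack([h5["x"][:], h5["y"][:]], axis=-1)
        theta = h5["theta"][:]
        if "vx" in h5 and "vy" in h5:
            v = np.stack([h5["vx"][:], h5["vy"][:]], axis=-1)
        else:
            p = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
            v = params.U * p
        return Trajectory(params=params, times=times, x=x, theta=theta, v=v,
                          stride=int(h5.attrs.get("stride", 1)))


def trajectory_to_csv(traj: Trajectory, path) -> pd.DataFrame:
    """Flat export: one row per (frame, swimmer)."""
    f, n = traj.theta.shape
    frames = np.repeat(np.arange(f), n)
    df = pd.DataFrame({
        "frame": frames,
        "t": np.repeat(traj.times, n),
        "id": np.tile(np.arange(n), f),
        "x": traj.x[:, :, 0].ravel(),
        "y": traj.x[:, :, 1].ravel(),
        "theta": traj.theta.ravel(),
    })
    df.to_csv(path, index=False)
    return df


def load_config(path) -> SimConfig:
    """Read a TOML run configuration with sections [model], [run], [init]."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    model = doc.get("model", {})
    runsec = doc.get("run", {})
    init = doc.get("init", {})
    params = ModelParams(**model)
    return SimConfig(
        N=int(runsec["N"]),
        T=float(runsec["T"]),
        params=params,
        density=float(init.get("density", 1.0)),
        heading_mode=init.get("heading_mode", "uniform"),
        record_stride=int(runsec.get("record_stride", 100)),
    )
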