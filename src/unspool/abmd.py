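"""Multi-walker adaptively biased sampling on a 1-D reaction coordinate.

A shared, history-dependent biasing potential tabulated on a uniform grid
is grown by depositing smooth Gaussian kernels at the walkers' current
coordinate values; regions already visited are thereby destabilized
("flooding") and the negative of the converged bias approximates the free
energy along the coordinate.  All walkers read and write one grid
(shared-bias multiple-walker scheme) and advance in lockstep, which makes
the run deterministic for a given seed.

Deposit normalization: each deposit integrates (sum over nodes x grid
spacing) to kBT * dt / tau per walker, so the total energy deposited over
any period equals kBT/tau times the summed in-range walker residence time
-- the conservation contract the diagnostics rely on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kbt
from .toy_systems import Trajectory, _baoab

logger = logging.getLogger(__name__)

__all__ = [
    "BiasGrid",
    "FloodingSchedule",
    "WalkerEnsemble",
    "MultiWalkerResult",
    "deposit_bias",
    "evaluate_bias",
    "wall_energy",
    "wall_force",
    "run_multiwalker",
    "dropped_energy_profile",
    "uniformity_metric",
    "free_energy_estimate",
]


@dataclass
class BiasGrid:
    """The shared adaptive bias U(d) on a uniform grid over [lo, hi].

    Node count is floor((hi-lo)/resolution) + 1; the bias evaluates to 0
    outside the range.  Node values only ever increase (deposits add).
    """

    lo: float
    hi: float
    resolution: float = 1.0  # A
    values: np.ndarray | None = None

    def __post_init__(self):
        if self.hi <= self.lo or self.resolution <= 0:
            raise ValueError("need hi > lo and resolution > 0")
        n = int(np.floor((self.hi - self.lo) / self.resolution + 1e-9)) + 1
        if self.values is None:
            self.values = np.zeros(n)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if len(self.values) != n:
                raise ValueError(f"expected {n} nodes, got {len(self.values)}")

    @property
    def nodes(self) -> np.ndarray:
        return self.lo + self.resolution * np.arange(len(self.values))

    @property
    def integral(self) -> float:
        """Integrated bias: sum of node values times the grid spacing."""
        return float(self.values.sum() * self.resolution)

    def copy(self) -> "BiasGrid":
        return BiasGrid(self.lo, self.hi, self.resolution, self.values.copy())

    def evaluate(self, d):
        """Smooth bias energy and exact interpolant derivative at d.

        Piecewise-cubic (Catmull-Rom) interpolation on the nodes, with
        replicated edge slopes; zero outside [lo, hi].
        """
        d = np.asarray(d, dtype=float)
        scalar = d.ndim == 0
        d = np.atleast_1d(d)
        y = self.values
        h = self.resolution
        n = len(y)
        inside = (d >= self.lo) & (d <= self.hi)
        s = np.clip((d - self.lo) / h, 0.0, n - 1 - 1e-12)
        k = np.floor(s).astype(int)
        t = s - k
        yext = np.concatenate(([y[0]], y, [y[-1]]))
        y0 = y[k]
        y1 = y[np.minimum(k + 1, n - 1)]
        m0 = 0.5 * (yext[k + 2] - yext[k])
        m1 = 0.5 * (yext[np.minimum(k + 3, n)] - yext[k + 1])
        t2, t3 = t * t, t * t * t
        h00 = 2 * t3 - 3 * t2 + 1
        h10 = t3 - 2 * t2 + t
        h01 = -2 * t3 + 3 * t2
        h11 = t3 - t2
        val = h00 * y0 + h10 * m0 + h01 * y1 + h11 * m1
        dh00 = 6 * t2 - 6 * t
        dh10 = 3 * t2 - 4 * t + 1
        dh01 = -6 * t2 + 6 * t
        dh11 = 3 * t2 - 2 * t
        der = (dh00 * y0 + dh10 * m0 + dh01 * y1 + dh11 * m1) / h
        val = np.where(inside, val, 0.0)
        der = np.where(inside, der, 0.0)
        if scalar:
            return float(val[0]), float(der[0])
        return val, der

    def __call__(self, d):
        return self.evaluate(d)

    def to_csv(self, path, meta: dict | None = None) -> None:
        path = Path(path)
        pd.DataFrame({"d_A": self.nodes, "U_kcal_mol": self.values}).to_csv(
            path, index=False, float_format="%.17g"
        )
        info = {"lo": self.lo, "hi": self.hi, "resolution": self.resolution}
        if meta:
            info.update(meta)
        path.with_suffix(".json").write_text(json.dumps(info, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "BiasGrid":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        info = json.loads(path.with_suffix(".json").read_text())
        return cls(info["lo"], info["hi"], info["resolution"], df["U_kcal_mol"].to_numpy())


@dataclass(frozen=True)
class FloodingSchedule:
    """Deposition schedule: flooding time tau (ps), cadence, kernel width."""

    tau: float = 100.0  # ps
    deposit_interval: int = 1  # steps between deposits ("updated every step")
    kernel_width: float = 1.0  # Gaussian sigma in units of the grid resolution
    kernel_cutoff: float = 4.0  # truncation, in sigmas

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.deposit_interval < 1:
            raise ValueError("deposit_interval must be >= 1")


def deposit_bias(
    bias: BiasGrid,
    d,
    dt: float,
    schedule: FloodingSchedule,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BiasGrid:
    """Add one Gaussian deposit per walker coordinate in ``d`` (in place).

    Each in-range deposit is a truncated Gaussian kernel (sigma =
    kernel_width * resolution, cut at kernel_cutoff sigmas, renormalized
    over the in-grid nodes) whose integrated weight is kBT * dt / tau.
    Out-of-range coordinates deposit nothing (a warning is logged; walls
    are expected to hold walkers inside).
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if dt == 0:
        return bias
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    inside = (d >= bias.lo) & (d <= bias.hi)
    if not np.all(inside):
        logger.warning("%d walker(s) outside bias range; no deposit", int((~inside).sum()))
        d = d[inside]
        if d.size == 0:
            return bias
    h = bias.resolution
    sigma = schedule.kernel_width * h
    halfn = int(np.ceil(schedule.kernel_cutoff * sigma / h)) + 1
    center = np.round((d - bias.lo) / h).astype(int)
    offsets = np.arange(-halfn, halfn + 1)
    idx = center[:, None] + offsets[None, :]
    nodes = bias.lo + idx * h
    dist = nodes - d[:, None]
    valid = (idx >= 0) & (idx < len(bias.values)) & (np.abs(dist) <= schedule.kernel_cutoff * sigma)
    kern = np.where(valid, np.exp(-0.5 * (dist / sigma) ** 2), 0.0)
    norm = kern.sum(axis=1, keepdims=True) * h
    weight = kbt(temperature) * dt / schedule.tau
    kern = kern * (weight / norm)
    np.add.at(bias.values, idx[valid], kern[valid])
    return bias


def evaluate_bias(bias: BiasGrid, d):
    """(energy, force-conjugate derivative dU/dd) of the bias at d."""
    return bias.evaluate(d)


def wall_energy(d, lo_wall: float, hi_wall: float, k_wall: float = 10.0):
    """One-sided harmonic range walls: k (d - wall)^2 beyond either wall."""
    if lo_wall >= hi_wall:
        raise ValueError("lo_wall must be below hi_wall")
    d = np.asarray(d, dtype=float)
    below = np.minimum(d - lo_wall, 0.0)
    above = np.maximum(d - hi_wall, 0.0)
    return k_wall * (below**2 + above**2)


def wall_force(d, lo_wall: float, hi_wall: float, k_wall: float = 10.0):
    """-dE/dd of :func:`wall_energy`."""
    d = np.asarray(d, dtype=float)
    below = np.minimum(d - lo_wall, 0.0)
    above = np.maximum(d - hi_wall, 0.0)
    return -2.0 * k_wall * (below + above)


@dataclass
class WalkerEnsemble:
    """Walkers sharing one bias grid (shared-bias multiple-walker contract)."""

    n_walkers: int
    positions: np.ndarray  # (n_walkers, *dof)
    velocities: np.ndarray
    bias: BiasGrid
    time: float = 0.0

    def __post_init__(self):
        if len(self.positions) != self.n_walkers:
            raise ValueError("positions must have one row per walker")


@dataclass
class MultiWalkerResult:
    """Per-walker sample series plus the shared-bias history."""

    trajectories: list  # list[Trajectory], one per walker
    bias: BiasGrid
    snapshot_times: np.ndarray
    snapshots: np.ndarray  # (n_snapshots, n_nodes)
    residence_time: float  # summed in-range walker time (ps)
    meta: dict = field(default_factory=dict)

    def final_states(self):
        """(walker id, final d) pairs for umbrella seeding."""
        return [(i, float(t.d[-1])) for i, t in enumerate(self.trajectories)]

    def frame_states(self):
        """(walker id, d, coordinates) for every stored frame (seed pool)."""
        out = []
        for i, t in enumerate(self.trajectories):
            if t.states is None:
                continue
            for r in range(t.n_samples):
                out.append((i, float(t.d[r]), t.states[r]))
        return out


def run_multiwalker(
    system,
    *,
    n_walkers: int,
    bias_range: tuple[float, float],
    walls: tuple[float, float],
    schedule: FloodingSchedule,
    total_time: float,
    seed: int,
    resolution: float = 1.0,
    wall_k: float = 10.0,
    dt: float | None = None,
    gamma: float | None = None,
    temperature: float | None = None,
    record_interval: int = 100,
    snapshot_interval: float | None = None,
    store_states: bool = True,
    x0: np.ndarray | None = None,
) -> MultiWalkerResult:
    """Run lockstep multi-walker flooding dynamics on ``system``.

    The bias and range walls act on the reaction coordinate through the
    chain rule.  Bias snapshots are saved every ``snapshot_interval`` ps
    (default: total_time / 15, the dropped-energy diagnostic cadence).
    Deterministic for a given seed and walker count.
    """
    spec = getattr(system, "spec", None)
    dt = dt if dt is not None else getattr(spec, "timestep", 0.01)
    gamma = gamma if gamma is not None else getattr(spec, "friction", 2.0)
    temperature = (
        temperature if temperature is not None else getattr(spec, "temperature", DEFAULT_TEMPERATURE)
    )
    n_steps = int(round(total_time / dt))
    if record_interval < 1 or n_steps % record_interval:
        raise ValueError("record_interval must divide the step count")
    if snapshot_interval is None:
        snapshot_interval = total_time / 15.0
    snap_steps = max(1, int(round(snapshot_interval / dt)))

    rng = np.random.default_rng(seed)
    bias = BiasGrid(bias_range[0], bias_range[1], resolution)
    x = system.initial_positions(n_walkers) if x0 is None else np.asarray(x0, dtype=float).copy()
    v = np.zeros_like(x)
    lo_wall, hi_wall = walls

    def total_force(q):
        dvals = system.reaction_coordinate(q)
        _, dedd = bias.evaluate(dvals)
        dedd = dedd - wall_force(dvals, lo_wall, hi_wall, wall_k)
        shape = dvals.shape + (1,) * len(system.dof_shape)
        return system.force(q) - np.reshape(dedd, shape) * system.rc_gradient(q)

    n_rec = n_steps // record_interval
    ds = np.empty((n_rec, n_walkers))
    energies = np.empty_like(ds)
    times = np.empty(n_rec)
    aux_template = system.auxiliaries(x)
    aux = {k: np.empty_like(ds) for k in aux_template}
    states = np.empty((n_rec,) + x.shape) if store_states else None
    snapshots = [bias.values.copy()]
    snap_times = [0.0]
    residence = 0.0

    f = total_force(x)
    for i in range(n_steps):
        x, v, f = _baoab(x, v, total_force, dt, gamma, temperature, system.mass, rng,
                         f_prev=f, mobile=system.mobile)
        if not np.all(np.isfinite(x)):
            bad = int(np.argwhere(~np.isfinite(x.reshape(n_walkers, -1)).all(axis=1))[0][0])
            raise FloatingPointError(
                f"walker {bad} diverged at t = {(i + 1) * dt:.3f} ps"
            )
        if (i + 1) % schedule.deposit_interval == 0:
            dvals = system.reaction_coordinate(x)
            inside = (dvals >= bias.lo) & (dvals <= bias.hi)
            residence += float(inside.sum()) * dt * schedule.deposit_interval
            deposit_bias(bias, dvals, dt * schedule.deposit_interval, schedule, temperature)
            f = total_force(x)  # bias changed under the walkers
        if (i + 1) % record_interval == 0:
            r = (i + 1) // record_interval - 1
            times[r] = (i + 1) * dt
            dvals = system.reaction_coordinate(x)
            ds[r] = dvals
            energies[r] = system.energy(x)
            for k, val in system.auxiliaries(x).items():
                aux[k][r] = val
            if store_states:
                states[r] = x
        if (i + 1) % snap_steps == 0:
            snapshots.append(bias.values.copy())
            snap_times.append((i + 1) * dt)

    trajectories = []
    for wkr in range(n_walkers):
        trajectories.append(
            Trajectory(
                times.copy(),
                ds[:, wkr].copy(),
                {k: a[:, wkr].copy() for k, a in aux.items()},
                energies[:, wkr].copy(),
                states[:, wkr].copy() if store_states else None,
                meta={"walker": wkr, "dt": dt, "gamma": gamma, "temperature": temperature},
            )
        )
    return MultiWalkerResult(
        trajectories,
        bias,
        np.asarray(snap_times),
        np.asarray(snapshots),
        residence,
        meta={
            "n_walkers": n_walkers,
            "tau": schedule.tau,
            "total_time": total_time,
            "seed": seed,
            "walls": walls,
            "temperature": temperature,
        },
    )


def dropped_energy_profile(snapshots: np.ndarray, snapshot_times=None):
    """Per-node deposited energy in each inter-snapshot interval.

    Returns a nonnegative (n_nodes, n_intervals) matrix of node-value
    increments; column sums times the grid spacing give the energy
    deposited per interval.
    """
    snapshots = np.asarray(snapshots, dtype=float)
    if snapshots.ndim != 2 or len(snapshots) < 2:
        raise ValueError("need at least two bias snapshots")
    return np.diff(snapshots, axis=0).T


def uniformity_metric(dropped: np.ndarray, node_mask=None) -> float:
    """Convergence metric of the final deposition interval.

    Max-over-nodes absolute deviation from the spatial mean of the last
    interval's deposits, divided by that mean; small values mean the bias
    is growing uniformly (flat residual landscape).
    """
    last = np.asarray(dropped, dtype=float)[:, -1]
    if node_mask is not None:
        last = last[np.asarray(node_mask, dtype=bool)]
    mean = last.mean()
    if mean <= 0:
        return np.inf
    return float(np.max(np.abs(last - mean)) / mean)


def free_energy_estimate(result: MultiWalkerResult, average_fraction: float = 0.5):
    """Free-energy estimate -<U_bias> from the late bias history.

    Averages the bias over the last ``average_fraction`` of snapshots
    (time-averaging suppresses the late-stage deposit fluctuations), then
    negates and min-anchors.  Returns (nodes, F_estimate).
    """
    if not 0 < average_fraction <= 1:
        raise ValueError("average_fraction in (0, 1]")
    n = len(result.snapshots)
    start = min(n - 1, int(np.floor(n * (1 - average_fraction))))
    mean_bias = result.snapshots[start:].mean(axis=0)
    f = -mean_bias
    return result.bias.nodes, f - f.min()
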