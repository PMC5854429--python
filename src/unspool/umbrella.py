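"""Umbrella-window construction, seeding and restrained sampling.

Windows restrain the reaction coordinate with a harmonic term (no 1/2
factor) on a uniform grid of centers, optionally on top of a frozen
adaptive bias taken from the final flooding stage:

    V_i(d) = k_i (d - c_i)^2 + U_abmd(d)

The frozen bias is shared bit-identically by every window of a stage, so
WHAM can remove the combined bias exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abmd import BiasGrid
from .constants import DEFAULT_TEMPERATURE
from .toy_systems import Trajectory, _baoab

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "UmbrellaWindow",
    "WindowSamples",
    "build_window_grid",
    "select_seeds",
    "combined_bias",
    "combined_bias_force",
    "run_windows",
    "filter_discard_regions",
    "save_window_samples",
]


@dataclass(frozen=True)
class WindowGrid:
    """Uniform inclusive grid of window centers c_i = lo + spacing * i."""

    lo: float
    spacing: float
    n_windows: int

    @property
    def centers(self) -> np.ndarray:
        return self.lo + self.spacing * np.arange(self.n_windows)

    @property
    def hi(self) -> float:
        return float(self.centers[-1])


def build_window_grid(lo: float, hi: float, spacing: float) -> WindowGrid:
    """Inclusive-endpoint window grid; (hi-lo) must be a multiple of spacing."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if hi < lo:
        raise ValueError("hi must be >= lo")
    ratio = (hi - lo) / spacing
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"range ({lo}, {hi}) is not commensurate with spacing {spacing}"
        )
    return WindowGrid(lo, spacing, int(round(ratio)) + 1)


@dataclass
class UmbrellaWindow:
    """One restrained window: center, force constant, frozen bias, seed id."""

    center: float
    k: float = 0.2  # kcal/mol/A^2
    bias: BiasGrid | None = None
    seed_id: int | None = None

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("force constant must be positive")


@dataclass
class WindowSamples:
    """Recorded samples of one umbrella window."""

    window_id: int
    window: UmbrellaWindow
    trajectory: Trajectory

    @property
    def d(self) -> np.ndarray:
        return self.trajectory.d

    @property
    def aux(self) -> dict:
        return self.trajectory.aux

    @property
    def n(self) -> int:
        return self.trajectory.n_samples


def select_seeds(walker_states, grid: WindowGrid):
    """Pick, per window center, the walker whose d lies closest to it.

    ``walker_states`` is a sequence of (walker_id, d) or (walker_id, d,
    coordinates) tuples -- final states or any recorded frame pool.  Ties
    break toward the lower walker id (and earlier entry).  A walker may
    seed several windows.
    """
    entries = list(walker_states)
    if not entries:
        raise ValueError("no walker states to seed from")
    entries.sort(key=lambda e: e[0])
    ids = np.asarray([e[0] for e in entries])
    ds = np.asarray([e[1] for e in entries], dtype=float)
    chosen = []
    for c in grid.centers:
        dist = np.abs(ds - c)
        best = np.flatnonzero(dist == dist.min())
        pick = best[np.argmin(ids[best])]
        chosen.append(entries[pick])
    return chosen


def combined_bias(d, window: UmbrellaWindow):
    """Window bias energy k (d - c)^2 + U_abmd(d)."""
    d = np.asarray(d, dtype=float)
    e = window.k * (d - window.center) ** 2
    if window.bias is not None:
        u, _ = window.bias.evaluate(d)
        e = e + u
    return e


def combined_bias_force(d, window: UmbrellaWindow):
    """(energy, dE/dd) of the combined window bias."""
    d = np.asarray(d, dtype=float)
    e = window.k * (d - window.center) ** 2
    g = 2.0 * window.k * (d - window.center)
    if window.bias is not None:
        u, du = window.bias.evaluate(d)
        e = e + u
        g = g + du
    return e, g


def run_windows(
    system,
    grid: WindowGrid,
    *,
    k: float = 0.2,
    frozen_bias: BiasGrid | None = None,
    duration: float,
    record_interval: int = 10,
    seed: int,
    seeds=None,
    dt: float | None = None,
    gamma: float | None = None,
    temperature: float | None = None,
    burn_in: float = 0.0,
) -> list[WindowSamples]:
    """Run all umbrella windows (batched, lockstep) and record samples.

    ``seeds`` is the output of :func:`select_seeds` (entries carrying
    coordinates) or None, in which case each window starts from the
    system's default initial positions.  ``burn_in`` ps are discarded from
    the front of each window's record (default 0: expose, don't assume).
    Deterministic for a given seed.
    """
    spec = getattr(system, "spec", None)
    dt = dt if dt is not None else getattr(spec, "timestep", 0.01)
    gamma = gamma if gamma is not None else getattr(spec, "friction", 2.0)
    temperature = (
        temperature if temperature is not None else getattr(spec, "temperature", DEFAULT_TEMPERATURE)
    )
    n_steps = int(round(duration / dt))
    if n_steps % record_interval:
        raise ValueError("record_interval must divide the step count")
    nw = grid.n_windows
    centers = grid.centers
    windows = [UmbrellaWindow(float(c), k, frozen_bias) for c in centers]

    if seeds is not None:
        if len(seeds) != nw:
            raise ValueError("need one seed entry per window")
        xs = []
        for w, entry in zip(windows, seeds):
            w.seed_id = int(entry[0])
            if len(entry) > 2 and entry[2] is not None:
                xs.append(np.asarray(entry[2], dtype=float))
            else:
                xs.append(system.initial_positions(1)[0])
        x = np.stack(xs)
    else:
        x = np.repeat(system.initial_positions(1), nw, axis=0)
    v = np.zeros_like(x)
    rng = np.random.default_rng(seed)

    def total_force(q):
        dvals = system.reaction_coordinate(q)
        e = 2.0 * k * (dvals - centers)
        if frozen_bias is not None:
            _, du = frozen_bias.evaluate(dvals)
            e = e + du
        shape = dvals.shape + (1,) * len(system.dof_shape)
        return system.force(q) - np.reshape(e, shape) * system.rc_gradient(q)

    n_rec = n_steps // record_interval
    ds = np.empty((n_rec, nw))
    energies = np.empty_like(ds)
    times = np.empty(n_rec)
    aux = {key: np.empty_like(ds) for key in system.auxiliaries(x)}

    f = total_force(x)
    for i in range(n_steps):
        x, v, f = _baoab(x, v, total_force, dt, gamma, temperature, system.mass, rng,
                         f_prev=f, mobile=system.mobile)
        if (i + 1) % record_interval == 0:
            r = (i + 1) // record_interval - 1
            times[r] = (i + 1) * dt
            ds[r] = system.reaction_coordinate(x)
            energies[r] = system.energy(x)
            for key, val in system.auxiliaries(x).items():
                aux[key][r] = val

    keep = times > burn_in
    out = []
    for j, w in enumerate(windows):
        traj = Trajectory(
            times[keep].copy(),
            ds[keep, j].copy(),
            {key: a[keep, j].copy() for key, a in aux.items()},
            energies[keep, j].copy(),
            meta={"window": j, "center": w.center, "k": k, "dt": dt,
                  "gamma": gamma, "temperature": temperature, "burn_in": burn_in},
        )
        out.append(WindowSamples(j, w, traj))
    return out


def filter_discard_regions(samples: list[WindowSamples], keep_range) -> list[WindowSamples]:
    """Drop samples whose d falls outside the closed interval keep_range.

    Mirrors the removal of corrupted-structure regions before WHAM; the
    boundary values themselves are retained (window centers sit exactly on
    the range limits).  The number of removed samples is logged.
    """
    lo, hi = keep_range
    if hi < lo:
        raise ValueError("invalid keep_range")
    removed = 0
    out = []
    for ws in samples:
        mask = (ws.d >= lo) & (ws.d <= hi)
        removed += int((~mask).sum())
        traj = ws.trajectory
        new = Trajectory(
            traj.time_ps[mask],
            traj.d[mask],
            {k: v[mask] for k, v in traj.aux.items()},
            None if traj.energy is None else traj.energy[mask],
            None if traj.states is None else traj.states[mask],
            dict(traj.meta),
        )
        out.append(WindowSamples(ws.window_id, ws.window, new))
    logger.info("discard filter removed %d samples outside [%g, %g]", removed, lo, hi)
    return out


def save_window_samples(samples: list[WindowSamples], path, manifest: dict | None = None):
    """Write all windows to one CSV (spec schema) plus a JSON manifest."""
    path = Path(path)
    frames = []
    for ws in samples:
        df = pd.DataFrame({
            "window_id": ws.window_id,
            "center_A": ws.window.center,
            "k": ws.window.k,
            "time_ps": ws.trajectory.time_ps,
            "d_A": ws.d,
        })
        for key in ("unwrapped_end1", "unwrapped_end2"):
            if key in ws.aux:
                df[key] = ws.aux[key]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    info = {"n_windows": len(samples)}
    if manifest:
        info.update(manifest)
    path.with_suffix(".json").write_text(json.dumps(info, indent=2, default=str))
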