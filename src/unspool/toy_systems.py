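"""Synthetic test systems with known free energies.

Two families of systems stand in for expensive molecular trajectories:

* 1-D analytic potentials (:class:`PotentialSpec`) whose free energy along
  the coordinate is the potential itself, giving closed-form oracles for
  every estimator in the package.

* A coarse bead-on-spool mimic of nucleosomal DNA (:class:`SpoolMimic`):
  two mirror-symmetric arms of beads wrapped on a core, each bead bound at
  discrete core sites with tunable binding energies, so that the free
  energy along the unwrapped-bead count rises in tunable steps, emulating
  the stepwise energetics of discrete protein-DNA binding sites.  The arm
  partition function is exactly computable (transfer-integral dynamic
  programming), so the mimic doubles as a parameter-recovery oracle for
  the full sampling pipeline.

Dynamics use a BAOAB-split Langevin integrator, chosen for accurate
configurational sampling at moderate time steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kbt
from .profiles import FreeEnergyProfile

__all__ = [
    "PotentialSpec",
    "ScalarSystem",
    "SpoolMimicSpec",
    "SpoolMimic",
    "SystemState",
    "Trajectory",
    "langevin_step",
    "simulate_trajectory",
    "analytic_free_energy",
    "boltzmann_density",
    "count_distribution",
    "reduced_count_distribution",
    "free_energy_vs_count",
]


# ---------------------------------------------------------------------------
# Analytic 1-D potentials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PotentialSpec:
    """A 1-D potential with closed-form energies.

    Kinds
    -----
    ``harmonic``
        V(x) = k (x - center)^2.  No 1/2 factor, matching the harmonic
        restraint convention used throughout the package, so the Boltzmann
        variance is kBT / (2k).
    ``double_well``
        V(x) = barrier * ((x - center)^2 - a^2)^2 / a^4 with wells at
        center +- a (a = half the well separation) and a barrier of height
        ``barrier`` at the center.
    ``tabulated``
        Cubic-spline interpolation of (x, V) tables.
    """

    kind: str
    params: dict
    domain: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError(f"empty domain {self.domain}")
        if self.kind == "harmonic":
            if self.params.get("k", 0.0) <= 0:
                raise ValueError("harmonic potential needs k > 0")
        elif self.kind == "double_well":
            for key in ("barrier", "half_separation"):
                if self.params.get(key, 0.0) <= 0:
                    raise ValueError(f"double_well potential needs {key} > 0")
        elif self.kind == "tabulated":
            x = np.asarray(self.params["x"], dtype=float)
            v = np.asarray(self.params["v"], dtype=float)
            if x.ndim != 1 or x.shape != v.shape or len(x) < 4:
                raise ValueError("tabulated potential needs matching 1-D tables, >= 4 points")
            if not np.all(np.isfinite(v)):
                raise ValueError("tabulated energies must be finite")
        else:
            raise ValueError(f"unknown potential kind {self.kind!r}")

    def _spline(self):
        from scipy.interpolate import CubicSpline

        return CubicSpline(self.params["x"], self.params["v"])

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "harmonic":
            c = self.params.get("center", 0.0)
            return self.params["k"] * (x - c) ** 2
        if self.kind == "double_well":
            c = self.params.get("center", 0.0)
            a = self.params["half_separation"]
            h = self.params["barrier"]
            return h * ((x - c) ** 2 - a**2) ** 2 / a**4
        return self._spline()(x)

    def force(self, x):
        """-dV/dx."""
        x = np.asarray(x, dtype=float)
        if self.kind == "harmonic":
            c = self.params.get("center", 0.0)
            return -2.0 * self.params["k"] * (x - c)
        if self.kind == "double_well":
            c = self.params.get("center", 0.0)
            a = self.params["half_separation"]
            h = self.params["barrier"]
            u = x - c
            return -4.0 * h * u * (u**2 - a**2) / a**4
        return -self._spline()(x, 1)

    def to_dict(self) -> dict:
        params = {
            k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        }
        return {"kind": self.kind, "params": params, "domain": list(self.domain)}

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialSpec":
        return cls(d["kind"], dict(d["params"]), tuple(d["domain"]))


def analytic_free_energy(
    spec: PotentialSpec, grid, temperature: float = DEFAULT_TEMPERATURE
) -> FreeEnergyProfile:
    """Exact free energy of a 1-D system on bin centers, min-anchored to 0.

    For a single particle on a 1-D potential the free energy along the
    coordinate equals the potential itself (up to the anchor constant).
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spec.domain
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(f"grid [{grid.min()}, {grid.max()}] outside domain {spec.domain}")
    v = spec.energy(grid)
    beta = 1.0 / kbt(temperature)
    w = np.exp(-beta * (v - v.min()))
    profile = FreeEnergyProfile.from_probability(
        (grid,), w, names=("d",), units=("A",), temperature=temperature
    )
    return profile


def boltzmann_density(spec: PotentialSpec, grid, temperature: float = DEFAULT_TEMPERATURE):
    """Normalized equilibrium density exp(-V/kBT)/Z on a uniform grid."""
    grid = np.asarray(grid, dtype=float)
    beta = 1.0 / kbt(temperature)
    w = np.exp(-beta * (spec.energy(grid) - spec.energy(grid).min()))
    dx = grid[1] - grid[0]
    return w / (w.sum() * dx)


# ---------------------------------------------------------------------------
# System protocol: scalar particle and spool mimic
# ---------------------------------------------------------------------------


class ScalarSystem:
    """A single particle on a 1-D :class:`PotentialSpec`.

    The reaction coordinate d is the particle position itself; dof arrays
    have shape ``(..., 1)`` so the same integrator drives both this and the
    multi-bead mimic.
    """

    def __init__(self, spec: PotentialSpec, mass: float = 1.0):
        self.spec = spec
        self.mass = mass
        self.dof_shape = (1,)
        self.mobile = None  # all dofs mobile

    def energy(self, x):
        return self.spec.energy(x[..., 0])

    def force(self, x):
        return self.spec.force(x)

    def reaction_coordinate(self, x):
        return x[..., 0]

    def rc_gradient(self, x):
        return np.ones_like(x)

    def initial_positions(self, n: int = 1, value: float | None = None):
        lo, hi = self.spec.domain
        if value is None:
            if self.spec.kind == "double_well":
                value = self.spec.params.get("center", 0.0) - self.spec.params["half_separation"]
            elif self.spec.kind == "harmonic":
                value = self.spec.params.get("center", 0.0)
            else:
                value = 0.5 * (lo + hi)
        return np.full((n, 1), float(value))

    def auxiliaries(self, x) -> dict:
        return {}


@dataclass(frozen=True)
class SpoolMimicSpec:
    """Geometry and energetics of the bead-on-spool nucleosome mimic.

    Each of the two arms is a chain of ``n_beads`` beads indexed from the
    free end inward (bead 0 = outermost).  Bead j carries a scalar radial
    displacement x_j >= 0 from its wrapped reference position.  Site beads
    (``site_beads``) sit in a binding well of depth ``site_energies[m]``
    that extends to the capture radius with a smooth cosine shoulder of
    width ``shoulder`` for force continuity.  A one-sided harmonic "bond"
    (rest length ``bond_rest_length``, stiffness ``bond_stiffness``) blocks
    bead j+1 from displacing beyond the rest length until bead j has
    unwrapped, enforcing progressive outside-in unwrapping, the toy analog
    of chain connectivity.  Soft walls confine each bead to
    [0, max_extension].

    The two arms are constructed identically (mirror symmetry); the
    end-to-end distance analog is d = base_extension + sum of all bead
    displacements, a deterministic function of the coordinates.
    """

    n_beads: int = 10
    n_sites: int = 4
    site_energies: tuple = (1.0, 1.0, 1.0, 1.0)  # kcal/mol per site
    site_beads: tuple | None = None  # bead indices, outermost first; default: evenly spaced
    capture_radius: float = 4.0  # A; also the unwrapped-bead threshold
    shoulder: float = 0.5  # A, cosine taper width of the binding well
    max_extension: float = 8.0  # A per bead
    bond_rest_length: float = 3.8  # A, slack before the sequential bond engages
    # (set two thermal penetration lengths below the threshold so a blocked
    # bead's accessible volume matches a free wrapped bead's, keeping the
    # count free-energy steps equal to the site energies)
    bond_stiffness: float = 50.0  # kcal/mol/A^2
    gate_ramp: float = 0.3  # A beyond the threshold over which a bead frees its neighbour
    wall_stiffness: float = 50.0  # kcal/mol/A^2
    base_extension: float = 20.0  # A, end-to-end distance of the fully wrapped state
    anchor_radius: float = 30.0  # A, spool radius for the 3-D embedding
    anchor_spacing_deg: float = 15.0  # angular bead spacing in the embedding
    temperature: float = DEFAULT_TEMPERATURE  # K
    friction: float = 2.0  # ps^-1
    timestep: float = 0.01  # ps
    mass: float = 1.0  # kcal/mol ps^2/A^2 per bead
    pinned_arms: tuple = ()  # arm indices held fully wrapped

    def __post_init__(self):
        if self.n_beads < 1 or self.n_sites < 1 or self.n_sites > self.n_beads:
            raise ValueError("need 1 <= n_sites <= n_beads")
        if len(self.site_energies) != self.n_sites:
            raise ValueError("site_energies length must equal n_sites")
        if self.site_beads is not None and len(self.site_beads) != self.n_sites:
            raise ValueError("site_beads length must equal n_sites")
        if self.capture_radius <= 0 or self.shoulder <= 0 or self.shoulder > self.capture_radius:
            raise ValueError("need 0 < shoulder <= capture_radius")
        if self.max_extension <= self.capture_radius:
            raise ValueError("max_extension must exceed capture_radius")

    @property
    def resolved_site_beads(self) -> np.ndarray:
        if self.site_beads is not None:
            return np.asarray(self.site_beads, dtype=int)
        return np.round(np.linspace(0, self.n_beads - 1, self.n_sites)).astype(int)

    @property
    def unwrap_threshold(self) -> float:
        return self.capture_radius

    @property
    def total_binding_energy(self) -> float:
        """Binding energy of the fully wrapped state: 2 arms x sum of site depths."""
        return 2.0 * float(np.sum(self.site_energies))

    def bead_site_energies(self) -> np.ndarray:
        """Per-bead well depth (0 for non-site beads), shape (n_beads,)."""
        eps = np.zeros(self.n_beads)
        eps[self.resolved_site_beads] = np.asarray(self.site_energies, dtype=float)
        return eps

    def shrink_arms(self, n_remove: int) -> "SpoolMimicSpec":
        """Drop the outermost ``n_remove`` beads of each arm (stage hand-off).

        Sites that sat on removed beads disappear; remaining site indices
        shift outward accordingly.
        """
        if not 0 <= n_remove < self.n_beads:
            raise ValueError("n_remove out of range")
        old_sites = self.resolved_site_beads
        keep = old_sites >= n_remove
        new_sites = tuple(int(s - n_remove) for s in old_sites[keep])
        new_eps = tuple(float(e) for e, k in zip(self.site_energies, keep) if k)
        if not new_sites:
            raise ValueError("shrinking would remove every binding site")
        return replace(
            self,
            n_beads=self.n_beads - n_remove,
            n_sites=len(new_sites),
            site_energies=new_eps,
            site_beads=new_sites,
        )

    def to_dict(self) -> dict:
        return {
            "n_beads": self.n_beads,
            "n_sites": self.n_sites,
            "site_energies": list(self.site_energies),
            "site_beads": None if self.site_beads is None else list(self.site_beads),
            "capture_radius": self.capture_radius,
            "shoulder": self.shoulder,
            "max_extension": self.max_extension,
            "bond_rest_length": self.bond_rest_length,
            "bond_stiffness": self.bond_stiffness,
            "gate_ramp": self.gate_ramp,
            "wall_stiffness": self.wall_stiffness,
            "base_extension": self.base_extension,
            "anchor_radius": self.anchor_radius,
            "anchor_spacing_deg": self.anchor_spacing_deg,
            "temperature": self.temperature,
            "friction": self.friction,
            "timestep": self.timestep,
            "mass": self.mass,
            "pinned_arms": list(self.pinned_arms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpoolMimicSpec":
        d = dict(d)
        for key in ("site_energies", "pinned_arms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("site_beads") is not None:
            d["site_beads"] = tuple(d["site_beads"])
        return cls(**d)


class SpoolMimic:
    """Force field and observables of the bead-on-spool mimic.

    Coordinate arrays have shape ``(..., 2, n_beads)`` (two arms).
    """

    def __init__(self, spec: SpoolMimicSpec):
        self.spec = spec
        self.mass = spec.mass
        self.dof_shape = (2, spec.n_beads)
        self._eps = spec.bead_site_energies()
        mob = np.ones((2, spec.n_beads))
        for a in spec.pinned_arms:
            mob[a] = 0.0
        self.mobile = None if np.all(mob == 1) else mob

    # -- smooth switching functions -------------------------------------
    def _well(self, x):
        """Binding well shape S(x): 1 inside, cosine taper to 0 at the capture radius."""
        s = self.spec
        x0 = s.capture_radius - s.shoulder
        t = np.clip((x - x0) / s.shoulder, 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * t))

    def _well_deriv(self, x):
        s = self.spec
        x0 = s.capture_radius - s.shoulder
        t = (x - x0) / s.shoulder
        inside = (t > 0) & (t < 1)
        return np.where(inside, -0.5 * np.pi / s.shoulder * np.sin(np.pi * np.clip(t, 0, 1)), 0.0)

    def _gate(self, x):
        """Release switch u(x): 0 when wrapped, ramping to 1 at the threshold.

        The ramp starts at the unwrap threshold, so a bead must itself be
        unwrapped before it releases its inner neighbour: non-contiguous
        unwrapping stays energetically blocked, at the price of a small
        (ramp-width) volume correction on consecutively unwrapped pairs.
        """
        s = self.spec
        t = np.clip((x - s.capture_radius) / s.gate_ramp, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * t))

    def _gate_deriv(self, x):
        s = self.spec
        t = (x - s.capture_radius) / s.gate_ramp
        inside = (t > 0) & (t < 1)
        return np.where(inside, 0.5 * np.pi / s.gate_ramp * np.sin(np.pi * np.clip(t, 0, 1)), 0.0)

    # -- energy / force ---------------------------------------------------
    def _per_bead_energy(self, x):
        s = self.spec
        wall = s.wall_stiffness * (np.minimum(x, 0.0) ** 2 + np.maximum(x - s.max_extension, 0.0) ** 2)
        site = -self._eps * self._well(x)
        return wall + site

    def energy(self, x):
        s = self.spec
        e = self._per_bead_energy(x).sum(axis=(-2, -1))
        stretch = np.maximum(x[..., 1:] - s.bond_rest_length, 0.0)
        bond = s.bond_stiffness * stretch**2 * (1.0 - self._gate(x[..., :-1]))
        return e + bond.sum(axis=(-2, -1))

    def force(self, x):
        s = self.spec
        f = -2.0 * s.wall_stiffness * (np.minimum(x, 0.0) + np.maximum(x - s.max_extension, 0.0))
        f += self._eps * self._well_deriv(x)
        stretch = np.maximum(x[..., 1:] - s.bond_rest_length, 0.0)
        blocked = 1.0 - self._gate(x[..., :-1])
        # bond pulls the over-stretched inner bead back ...
        f[..., 1:] += -2.0 * s.bond_stiffness * stretch * blocked
        # ... and pushes its outer neighbour open (gate derivative term)
        f[..., :-1] += s.bond_stiffness * stretch**2 * self._gate_deriv(x[..., :-1])
        if self.mobile is not None:
            f = f * self.mobile
        return f

    def reaction_coordinate(self, x):
        return self.spec.base_extension + x.sum(axis=(-2, -1))

    def rc_gradient(self, x):
        g = np.ones_like(x)
        if self.mobile is not None:
            g = g * self.mobile
        return g

    def initial_positions(self, n: int = 1, value: float = 1.0):
        x = np.full((n, 2, self.spec.n_beads), float(value))
        if self.mobile is not None:
            x = x * self.mobile
        return x

    # -- observables ------------------------------------------------------
    def counts_any(self, x):
        """Per-arm number of beads displaced beyond the unwrap threshold."""
        return (x > self.spec.unwrap_threshold).sum(axis=-1)

    def counts_contiguous(self, x):
        """Per-arm unwrapped count, counted contiguously from the free end."""
        unwrapped = x > self.spec.unwrap_threshold
        return np.cumprod(unwrapped, axis=-1).sum(axis=-1)

    def auxiliaries(self, x) -> dict:
        any_counts = self.counts_any(x)
        contig = self.counts_contiguous(x)
        return {
            "unwrapped_end1": any_counts[..., 0],
            "unwrapped_end2": any_counts[..., 1],
            "unwrapped_end1_contig": contig[..., 0],
            "unwrapped_end2_contig": contig[..., 1],
        }

    def anchor_geometry(self):
        """Reference anchor positions (2, n_beads, 3) and outward unit vectors."""
        s = self.spec
        j = np.arange(s.n_beads)
        theta0 = np.deg2rad(s.anchor_spacing_deg)
        angles = theta0 * (j + 1)
        units = []
        for sign in (+1.0, -1.0):
            a = sign * angles
            units.append(np.stack([np.cos(a), np.sin(a), np.zeros_like(a)], axis=-1))
        units = np.stack(units, axis=0)  # (2, n_beads, 3)
        anchors = s.anchor_radius * units
        return anchors, units

    def embed(self, x):
        """3-D bead positions for structural metrics, shape (..., 2, n_beads, 3)."""
        anchors, units = self.anchor_geometry()
        return anchors + x[..., None] * units


SystemT = ScalarSystem | SpoolMimic


@dataclass
class SystemState:
    """Instantaneous state of a simulated system."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must share a shape")


# ---------------------------------------------------------------------------
# BAOAB Langevin dynamics
# ---------------------------------------------------------------------------


def _check_finite(f, where: str):
    if not np.all(np.isfinite(f)):
        bad = np.argwhere(~np.isfinite(np.atleast_1d(f)))
        raise FloatingPointError(f"non-finite force at {where}, dof index {bad[0].tolist()}")


def _baoab(x, v, force, dt, gamma, temperature, mass, rng, f_prev=None, mobile=None):
    """One BAOAB step; ``force`` maps positions to forces (batched)."""
    if f_prev is None:
        f_prev = force(x)
    inv_m = 1.0 / mass
    v = v + 0.5 * dt * f_prev * inv_m
    if mobile is not None:
        v = v * mobile
    x = x + 0.5 * dt * v
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kbt(temperature) * (1.0 - c1 * c1) * inv_m)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        if mobile is not None:
            v = v * mobile
    x = x + 0.5 * dt * v
    f = force(x)
    _check_finite(f, f"t-step end (x range [{np.min(x):.3g}, {np.max(x):.3g}])")
    v = v + 0.5 * dt * f * inv_m
    if mobile is not None:
        v = v * mobile
    return x, v, f


def langevin_step(
    state: SystemState,
    force_evaluator,
    dt: float,
    gamma: float,
    temperature: float,
    rng: np.random.Generator,
    mass: float = 1.0,
) -> SystemState:
    """Advance one BAOAB Langevin step.

    With gamma = 0 the step reduces to velocity Verlet (deterministic,
    energy-conserving to integrator order).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    f0 = np.asarray(force_evaluator(state.positions), dtype=float)
    _check_finite(f0, "step start")
    x, v, _ = _baoab(
        state.positions.copy(),
        state.velocities.copy(),
        lambda q: np.asarray(force_evaluator(q), dtype=float),
        dt,
        gamma,
        temperature,
        mass,
        rng,
        f_prev=f0,
    )
    return SystemState(x, v, state.time + dt)


@dataclass
class Trajectory:
    """Recorded samples of one run (or one walker / one umbrella window)."""

    time_ps: np.ndarray
    d: np.ndarray
    aux: dict = field(default_factory=dict)
    energy: np.ndarray | None = None
    states: np.ndarray | None = None  # optional coordinate snapshots (n, *dof)
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.d)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ps": self.time_ps, "d_A": self.d}
        for key in ("unwrapped_end1", "unwrapped_end2"):
            if key in self.aux:
                data[key] = self.aux[key]
        if self.energy is not None:
            data["energy_kcal_mol"] = self.energy
        for key, val in self.aux.items():
            if key not in data:
                data[key] = val
        return pd.DataFrame(data)

    def to_csv(self, path, sidecar: dict | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        info = dict(self.meta)
        if sidecar:
            info.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(info, indent=2, default=str))


def simulate_trajectory(
    system: SystemT,
    bias=None,
    *,
    n_steps: int,
    record_interval: int,
    seed: int | np.random.Generator,
    dt: float | None = None,
    gamma: float | None = None,
    temperature: float | None = None,
    x0: np.ndarray | None = None,
    store_states: bool = False,
) -> Trajectory:
    """Run Langevin dynamics, optionally under a bias on the reaction coordinate.

    ``bias`` is a callable d -> (energy, dE/dd), applied through the chain
    rule on the reaction-coordinate gradient.  Records every
    ``record_interval`` steps (which must divide ``n_steps``).
    """
    if n_steps % record_interval != 0:
        raise ValueError("record_interval must divide n_steps")
    spec = getattr(system, "spec", None)
    dt = dt if dt is not None else getattr(spec, "timestep", 0.01)
    gamma = gamma if gamma is not None else getattr(spec, "friction", 2.0)
    temperature = (
        temperature if temperature is not None else getattr(spec, "temperature", DEFAULT_TEMPERATURE)
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if x0 is None:
        x = system.initial_positions(1)
        squeeze = True
    else:
        x = np.asarray(x0, dtype=float).copy()
        squeeze = x.ndim == len(system.dof_shape)
        if squeeze:
            x = x[None]
    v = np.zeros_like(x)

    def total_force(q):
        f = system.force(q)
        if bias is not None:
            d = system.reaction_coordinate(q)
            _, dedd = bias(d)
            f = f - np.reshape(dedd, d.shape + (1,) * len(system.dof_shape)) * system.rc_gradient(q)
        return f

    n_rec = n_steps // record_interval
    times = np.empty(n_rec)
    ds = np.empty((n_rec,) + x.shape[:1])
    energies = np.empty_like(ds)
    aux_keys = list(system.auxiliaries(x).keys())
    aux = {k: np.empty_like(ds) for k in aux_keys}
    states = np.empty((n_rec,) + x.shape) if store_states else None

    f = total_force(x)
    for i in range(n_steps):
        x, v, f = _baoab(x, v, total_force, dt, gamma, temperature, system.mass, rng,
                         f_prev=f, mobile=system.mobile)
        if (i + 1) % record_interval == 0:
            r = (i + 1) // record_interval - 1
            times[r] = (i + 1) * dt
            ds[r] = system.reaction_coordinate(x)
            energies[r] = system.energy(x)
            for k, val in system.auxiliaries(x).items():
                aux[k][r] = val
            if store_states:
                states[r] = x

    if squeeze:
        ds, energies = ds[:, 0], energies[:, 0]
        aux = {k: a[:, 0] for k, a in aux.items()}
        if store_states:
            states = states[:, 0]
    return Trajectory(
        times,
        ds,
        aux,
        energies,
        states,
        meta={"dt": dt, "gamma": gamma, "temperature": temperature, "n_steps": n_steps},
    )


# ---------------------------------------------------------------------------
# Exact count oracles for the spool mimic
# ---------------------------------------------------------------------------


def _quad_grid(spec: SpoolMimicSpec, n_quad: int):
    lo = -3.0 / np.sqrt(spec.wall_stiffness)  # a few wall penetration lengths
    hi = spec.max_extension - lo
    x = np.linspace(lo, hi, n_quad)
    w = np.full(n_quad, x[1] - x[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    return x, w


def count_distribution(
    spec: SpoolMimicSpec,
    temperature: float | None = None,
    n_quad: int = 600,
):
    """Exact distribution of the unwrapped-bead count, by transfer-integral DP.

    The per-arm Boltzmann integral factorizes over nearest-neighbour bond
    terms, so the joint distribution of (bead positions, unwrapped count)
    is computed exactly by dynamic programming over a quadrature grid with
    a count register.  The two arms are independent, so the total-count
    distribution is the convolution of the per-arm ones.

    Returns ``(counts, p_total, p_arm)`` with ``counts = 0..2*n_beads``.
    """
    temperature = temperature if temperature is not None else spec.temperature
    beta = 1.0 / kbt(temperature)
    mimic = SpoolMimic(replace(spec, pinned_arms=()))
    x, w = _quad_grid(spec, n_quad)
    eps = spec.bead_site_energies()
    s = spec
    wall = s.wall_stiffness * (np.minimum(x, 0.0) ** 2 + np.maximum(x - s.max_extension, 0.0) ** 2)
    well = mimic._well(x)
    ind = (x > s.unwrap_threshold).astype(int)
    stretch = np.maximum(x - s.bond_rest_length, 0.0)
    blocked = 1.0 - mimic._gate(x)
    # pair factor G[x_prev, x_next] from the one-sided gating bond
    log_g = -beta * s.bond_stiffness * np.outer(blocked, stretch**2)
    g = np.exp(log_g)

    def psi(j):
        v = wall - eps[j] * well
        return np.exp(-beta * (v - v.min())) * np.exp(-beta * v.min())

    nb = s.n_beads
    amp = np.zeros((nb + 1, len(x)))
    p0 = psi(0) * w
    amp[0] = np.where(ind == 0, p0, 0.0)
    amp[1] = np.where(ind == 1, p0, 0.0)
    for j in range(1, nb):
        t = amp @ g  # t[c, x_next] = sum_xprev amp[c, xprev] G[xprev, xnext]
        pj = psi(j) * w
        new = np.zeros_like(amp)
        new += np.where(ind == 0, t * pj, 0.0)
        new[1:] += np.where(ind == 1, t[:-1] * pj, 0.0)
        amp = new
    p_arm = amp.sum(axis=1)
    p_arm = p_arm / p_arm.sum()
    arms = []
    for a in range(2):
        if a in spec.pinned_arms:
            delta = np.zeros(nb + 1)
            delta[0] = 1.0
            arms.append(delta)
        else:
            arms.append(p_arm)
    p_total = np.convolve(arms[0], arms[1])
    counts = np.arange(2 * nb + 1)
    return counts, p_total, p_arm


def reduced_count_distribution(spec: SpoolMimicSpec, temperature: float | None = None,
                               n_quad: int = 600):
    """Site-occupancy reduced model of the per-arm count distribution.

    Treats unwrapping as strictly sequential occupancy release: the state
    of an arm is the number of released beads c, with statistical weight
    prod_{j<c} z_free(j) * prod_{j>=c} z_bound(j), where the one-bead
    partition functions z are quadratures of the single-bead potential on
    the unwrapped / wrapped side of the threshold.  Exact when the gating
    bond is hard; tests compare it with the transfer-integral computation
    and with long-run sampling.

    Returns ``(counts, p_total, p_arm)`` as :func:`count_distribution`.
    """
    temperature = temperature if temperature is not None else spec.temperature
    beta = 1.0 / kbt(temperature)
    mimic = SpoolMimic(replace(spec, pinned_arms=()))
    x, w = _quad_grid(spec, n_quad)
    eps = spec.bead_site_energies()
    s = spec
    wall = s.wall_stiffness * (np.minimum(x, 0.0) ** 2 + np.maximum(x - s.max_extension, 0.0) ** 2)
    well = mimic._well(x)
    wrapped = x <= s.unwrap_threshold
    nb = s.n_beads
    log_zw = np.empty(nb)
    log_zu = np.empty(nb)
    for j in range(nb):
        bw = np.exp(-beta * (wall - eps[j] * well))
        log_zw[j] = np.log((bw * w)[wrapped].sum())
        log_zu[j] = np.log((bw * w)[~wrapped].sum())
    log_warm = np.array(
        [log_zu[:c].sum() + log_zw[c:].sum() for c in range(nb + 1)]
    )
    p_arm = np.exp(log_warm - log_warm.max())
    p_arm /= p_arm.sum()
    arms = []
    for a in range(2):
        if a in spec.pinned_arms:
            delta = np.zeros(nb + 1)
            delta[0] = 1.0
            arms.append(delta)
        else:
            arms.append(p_arm)
    p_total = np.convolve(arms[0], arms[1])
    return np.arange(2 * nb + 1), p_total, p_arm


def free_energy_vs_count(
    spec: SpoolMimicSpec,
    temperature: float | None = None,
    per_end: bool = False,
    method: str = "exact",
) -> FreeEnergyProfile:
    """Oracle free-energy profile along the unwrapped-bead count.

    ``per_end=True`` returns the single-arm profile (whose site steps equal
    the configured site energies up to small shoulder/gating corrections);
    otherwise the total-count profile over both arms.
    """
    temperature = temperature if temperature is not None else spec.temperature
    fn = count_distribution if method == "exact" else reduced_count_distribution
    counts, p_total, p_arm = fn(spec, temperature)
    if per_end:
        coords = np.arange(spec.n_beads + 1, dtype=float)
        p = p_arm
    else:
        coords = counts.astype(float)
        p = p_total
    mask = p > 1e-300
    pm = np.where(mask, p, 0.0)
    return FreeEnergyProfile.from_probability(
        (coords,), pm, names=("n_unwrapped",), units=("beads",), temperature=temperature,
        meta={"method": method, "per_end": per_end},
    )
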