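"""Two-stage protocol orchestration: flooding -> window seeding -> umbrella
sampling -> WHAM -> reweighting -> structural metrics -> stage stitching.

A :class:`StageConfig` fully determines one stage; every source of
randomness flows from its single master seed, so deterministic outputs are
bitwise reproducible.  Each phase persists its outputs (CSV/JSON) plus a
``.done`` marker, making a stage resumable phase-by-phase, and the stage
manifest records a config hash, per-file checksums and the aggregate
sampling budgets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abmd as abmd_mod
from . import reweight as rw
from .structure_metrics import asymmetry_distribution, stitch_stage_profiles
from .toy_systems import PotentialSpec, ScalarSystem, SpoolMimic, SpoolMimicSpec, Trajectory
from .umbrella import (
    WindowSamples,
    build_window_grid,
    filter_discard_regions,
    run_windows,
    save_window_samples,
    select_seeds,
)
from .wham import HistogramGrid, solve_wham

logger = logging.getLogger(__name__)

PHASES = ("abmd", "seeds", "umbrella", "wham", "reweight", "metrics")

__all__ = [
    "StageConfig",
    "RunManifest",
    "run_stage",
    "run_full",
    "load_config",
    "PHASES",
]


@dataclass
class StageConfig:
    """Complete parameterization of one protocol stage."""

    stage_id: str
    system: dict  # {"type": "mimic"|"potential", "spec": {...}}
    abmd: dict
    umbrella: dict
    wham: dict
    metrics: dict
    seed: int
    dynamics: dict = field(default_factory=dict)  # optional dt/gamma/temperature overrides

    _ABMD_DEFAULTS = {
        "range": None,  # [lo, hi] on the reaction coordinate, required
        "walls": None,  # [lo, hi], required
        "wall_k": 10.0,
        "tau": 100.0,
        "resolution": 1.0,
        "n_walkers": 100,
        "duration": 15000.0,  # ps per walker
        "deposit_interval": 1,
        "record_interval": 100,
        "snapshot_interval": None,
    }
    _UMBRELLA_DEFAULTS = {
        "lo": None,
        "hi": None,
        "spacing": 2.0,
        "k": 0.2,
        "duration": 15000.0,
        "record_interval": 10,
        "discard_range": None,  # defaults to [lo, hi]
        "burn_in": 0.0,
    }
    _WHAM_DEFAULTS = {"temperature": 300.0, "tol": 1e-8, "max_iter": 200000, "bin_width": 1.0}
    _METRICS_DEFAULTS = {
        "unwrap_threshold": 4.0,
        "contact_cutoff": 4.0,
        "count_mode": "any",  # "any" or "contiguous" per-end counts
        "report_count": None,  # R2 at which the stage delta-F is read
    }

    def __post_init__(self):
        self.abmd = {**self._ABMD_DEFAULTS, **self.abmd}
        self.umbrella = {**self._UMBRELLA_DEFAULTS, **self.umbrella}
        self.wham = {**self._WHAM_DEFAULTS, **self.wham}
        self.metrics = {**self._METRICS_DEFAULTS, **self.metrics}
        for key in ("range", "walls"):
            if self.abmd[key] is None:
                raise ValueError(f"abmd.{key} is required")
        for key in ("lo", "hi"):
            if self.umbrella[key] is None:
                raise ValueError(f"umbrella.{key} is required")
        if self.umbrella["discard_range"] is None:
            self.umbrella["discard_range"] = [self.umbrella["lo"], self.umbrella["hi"]]
        if self.system.get("type") not in ("mimic", "potential"):
            raise ValueError("system.type must be 'mimic' or 'potential'")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StageConfig":
        return cls(
            stage_id=d["stage_id"],
            system=dict(d["system"]),
            abmd=dict(d.get("abmd", {})),
            umbrella=dict(d.get("umbrella", {})),
            wham=dict(d.get("wham", {})),
            metrics=dict(d.get("metrics", {})),
            seed=int(d["seed"]),
            dynamics=dict(d.get("dynamics", {})),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def build_system(self):
        spec = self.system["spec"]
        if self.system["type"] == "mimic":
            return SpoolMimic(SpoolMimicSpec.from_dict(spec))
        return ScalarSystem(PotentialSpec.from_dict(spec))

    def budgets(self) -> dict:
        """Aggregate sampling accounting (ps and microseconds)."""
        abmd_ps = self.abmd["n_walkers"] * self.abmd["duration"]
        grid = build_window_grid(self.umbrella["lo"], self.umbrella["hi"],
                                 self.umbrella["spacing"])
        umb_ps = grid.n_windows * self.umbrella["duration"]
        return {
            "abmd_walkers": self.abmd["n_walkers"],
            "abmd_ps_per_walker": self.abmd["duration"],
            "abmd_total_ps": abmd_ps,
            "abmd_total_us": abmd_ps * 1e-6,
            "n_windows": grid.n_windows,
            "umbrella_ps_per_window": self.umbrella["duration"],
            "umbrella_total_ps": umb_ps,
        }


def load_config(path) -> StageConfig:
    """Read a stage config from TOML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    return StageConfig.from_dict(data)


@dataclass
class RunManifest:
    """Run provenance: config hash, file inventory with checksums, budgets."""

    stage_id: str
    config_hash: str
    created: str
    files: dict = field(default_factory=dict)  # relative path -> sha256
    budgets: dict = field(default_factory=dict)
    phase_timings: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def add_file(self, outdir: Path, path: Path):
        rel = str(path.relative_to(outdir))
        self.files[rel] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, outdir: Path):
        (outdir / "manifest.json").write_text(json.dumps(asdict(self), indent=2))


def _dyn_kwargs(config: StageConfig) -> dict:
    out = {}
    for key in ("dt", "gamma", "temperature"):
        if key in config.dynamics:
            out[key] = config.dynamics[key]
    return out


def _marker(outdir: Path, phase: str) -> Path:
    return outdir / f"phase_{phase}.done"


def _load_window_samples(path: Path, grid, k, frozen_bias) -> list[WindowSamples]:
    from .umbrella import UmbrellaWindow

    df = pd.read_csv(path)
    out = []
    for wid, sub in df.groupby("window_id"):
        aux_cols = [c for c in sub.columns if c.startswith("unwrapped")]
        traj = Trajectory(
            sub["time_ps"].to_numpy(),
            sub["d_A"].to_numpy(),
            {c: sub[c].to_numpy() for c in aux_cols},
        )
        window = UmbrellaWindow(float(sub["center_A"].iloc[0]), float(sub["k"].iloc[0]),
                                frozen_bias)
        out.append(WindowSamples(int(wid), window, traj))
    return out


def run_stage(
    config: StageConfig,
    outdir,
    through: str = "metrics",
    resume: bool = True,
    x0=None,
) -> dict:
    """Execute the stage chain up to (and including) phase ``through``.

    Completed phases found on disk are reloaded rather than recomputed
    when ``resume`` is true.  Returns a dict of in-memory results keyed by
    phase name; the stage manifest is rewritten after every phase.
    """
    if through not in PHASES:
        raise ValueError(f"unknown phase {through!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    system = config.build_system()
    dyn = _dyn_kwargs(config)
    manifest = RunManifest(
        config.stage_id,
        config.config_hash(),
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        budgets=config.budgets(),
    )
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    manifest.add_file(outdir, outdir / "config.json")
    if isinstance(system, SpoolMimic):
        manifest.extra["arm_length"] = system.spec.n_beads
    results: dict = {}
    last = PHASES.index(through)

    def phase_done(name, files):
        for f in files:
            manifest.add_file(outdir, f)
        _marker(outdir, name).write_text("ok")
        manifest.save(outdir)

    # ----- phase: abmd ---------------------------------------------------
    phase = "abmd"
    t0 = time.perf_counter()
    a = config.abmd
    bias_path = outdir / "abmd_bias.csv"
    if resume and _marker(outdir, phase).exists() and bias_path.exists():
        results["bias"] = abmd_mod.BiasGrid.from_csv(bias_path)
        logger.info("[%s] abmd: reloaded bias from %s", config.stage_id, bias_path)
    else:
        try:
            mw = abmd_mod.run_multiwalker(
                system,
                n_walkers=int(a["n_walkers"]),
                bias_range=tuple(a["range"]),
                walls=tuple(a["walls"]),
                wall_k=a["wall_k"],
                schedule=abmd_mod.FloodingSchedule(a["tau"], int(a["deposit_interval"])),
                total_time=a["duration"],
                resolution=a["resolution"],
                seed=config.seed,
                record_interval=int(a["record_interval"]),
                snapshot_interval=a["snapshot_interval"],
                store_states=True,
                x0=x0,
                **dyn,
            )
        except FloatingPointError as err:
            raise RuntimeError(f"phase abmd failed: {err}") from err
        results["abmd"] = mw
        results["bias"] = mw.bias
        mw.bias.to_csv(bias_path, meta={**mw.meta, "resolution": a["resolution"]})
        pd.DataFrame(
            mw.snapshots.T,
            index=pd.Index(mw.bias.nodes, name="d_A"),
            columns=[f"t_{t:g}" for t in mw.snapshot_times],
        ).to_csv(outdir / "abmd_bias_snapshots.csv")
        walker_df = pd.concat(
            [t.to_frame().assign(walker=i) for i, t in enumerate(mw.trajectories)],
            ignore_index=True,
        )
        walker_df.to_csv(outdir / "abmd_walkers.csv", index=False)
        phase_done(phase, [bias_path, outdir / "abmd_bias_snapshots.csv",
                           outdir / "abmd_walkers.csv"])
    manifest.phase_timings[phase] = time.perf_counter() - t0
    if PHASES.index(phase) >= last:
        manifest.save(outdir)
        return results

    # ----- phase: seeds --------------------------------------------------
    phase = "seeds"
    t0 = time.perf_counter()
    u = config.umbrella
    grid = build_window_grid(u["lo"], u["hi"], u["spacing"])
    seeds_path = outdir / "window_seeds.csv"
    if resume and _marker(outdir, phase).exists() and seeds_path.exists():
        df = pd.read_csv(seeds_path)
        seeds = []
        for wid, sub in df.groupby("window_id"):
            coords = None
            if "coord" in sub.columns and sub["coord"].notna().any():
                coords = sub.sort_values(["dof"])["coord"].to_numpy().reshape(system.dof_shape)
            seeds.append((int(sub["walker_id"].iloc[0]), float(sub["d_A"].iloc[0]), coords))
        results["seeds"] = seeds
    else:
        if "abmd" not in results:
            raise RuntimeError("cannot select seeds: abmd phase was reloaded without "
                               "stored walker states; rerun with resume=False")
        pool = results["abmd"].frame_states() or results["abmd"].final_states()
        seeds = select_seeds(pool, grid)
        results["seeds"] = seeds
        rows = []
        for wid, entry in enumerate(seeds):
            coords = entry[2] if len(entry) > 2 else None
            flat = (np.asarray(coords).ravel() if coords is not None
                    else np.full(int(np.prod(system.dof_shape)), np.nan))
            for di, cval in enumerate(flat):
                rows.append({"window_id": wid, "walker_id": entry[0],
                             "d_A": entry[1], "dof": di, "coord": cval})
        pd.DataFrame(rows).to_csv(seeds_path, index=False)
        phase_done(phase, [seeds_path])
    manifest.phase_timings[phase] = time.perf_counter() - t0
    if PHASES.index(phase) >= last:
        manifest.save(outdir)
        return results

    # ----- phase: umbrella ----------------------------------------------
    phase = "umbrella"
    t0 = time.perf_counter()
    samples_path = outdir / "window_samples.csv"
    frozen = results["bias"]
    if resume and _marker(outdir, phase).exists() and samples_path.exists():
        samples = _load_window_samples(samples_path, grid, u["k"], frozen)
    else:
        try:
            samples = run_windows(
                system,
                grid,
                k=u["k"],
                frozen_bias=frozen,
                duration=u["duration"],
                record_interval=int(u["record_interval"]),
                seed=config.seed + 1,
                seeds=results["seeds"],
                burn_in=u["burn_in"],
                **dyn,
            )
        except FloatingPointError as err:
            raise RuntimeError(f"phase umbrella failed: {err}") from err
        samples = filter_discard_regions(samples, tuple(u["discard_range"]))
        save_window_samples(samples, samples_path,
                            manifest={"stage": config.stage_id, "k": u["k"]})
        phase_done(phase, [samples_path])
    results["umbrella"] = samples
    manifest.phase_timings[phase] = time.perf_counter() - t0
    if PHASES.index(phase) >= last:
        manifest.save(outdir)
        return results

    # ----- phase: wham ---------------------------------------------------
    phase = "wham"
    t0 = time.perf_counter()
    w = config.wham
    lo, hi = u["discard_range"]
    hgrid = HistogramGrid(lo, hi + 1e-9, w["bin_width"])
    try:
        solution = solve_wham(
            samples,
            temperature=w["temperature"],
            tol=w["tol"],
            max_iter=int(w["max_iter"]),
            grid=hgrid,
        )
    except RuntimeError as err:
        raise RuntimeError(f"phase wham failed: {err}") from err
    solution.save(outdir / "wham")
    results["wham"] = solution
    phase_done(phase, [outdir / "wham.profile.csv", outdir / "wham.windows.csv",
                       outdir / "wham.convergence.json"])
    manifest.phase_timings[phase] = time.perf_counter() - t0
    if PHASES.index(phase) >= last:
        manifest.save(outdir)
        return results

    # ----- phase: reweight ----------------------------------------------
    phase = "reweight"
    t0 = time.perf_counter()
    m = config.metrics
    weights = solution.weights
    d_all = np.concatenate([s.d for s in samples])
    suffix = "" if m["count_mode"] == "any" else "_contig"
    results["profile_d"] = solution.profile()
    if f"unwrapped_end1{suffix}" in samples[0].aux:
        e1 = np.concatenate([s.aux[f"unwrapped_end1{suffix}"] for s in samples]).astype(int)
        e2 = np.concatenate([s.aux[f"unwrapped_end2{suffix}"] for s in samples]).astype(int)
        total = e1 + e2
        prof_r2 = rw.pmf_along(total, weights, temperature=w["temperature"],
                               name="R2", unit="beads")
        fes = rw.fes_2d(d_all, total, weights, grid1=hgrid,
                        temperature=w["temperature"], names=("R1", "R2"),
                        units=("A", "beads"))
        prof_e1 = rw.pmf_along(e1, weights, temperature=w["temperature"],
                               name="n_end1", unit="beads")
        df = prof_r2.to_frame()
        df["n"] = np.bincount(total - total.min(), minlength=len(prof_r2.coords[0]))
        df.to_csv(outdir / "profile_R2.csv", index=False)
        fes.to_frame().rename(columns={"R1": "R1_A", "R2": "R2_bp"}).to_csv(
            outdir / "fes_2d.csv", index=False
        )
        prof_e1.to_csv(outdir / "profile_end1.csv")
        results["profile_r2"] = prof_r2
        results["profile_end1"] = prof_e1
        results["fes_2d"] = fes
        results["counts"] = np.stack([e1, e2], axis=1)
        phase_done(phase, [outdir / "profile_R2.csv", outdir / "fes_2d.csv",
                           outdir / "profile_end1.csv"])
    else:  # scalar system: only the d-profile exists
        phase_done(phase, [])
    manifest.phase_timings[phase] = time.perf_counter() - t0
    if PHASES.index(phase) >= last:
        manifest.save(outdir)
        return results

    # ----- phase: metrics -------------------------------------------------
    phase = "metrics"
    t0 = time.perf_counter()
    stage_delta = None
    if "counts" in results:
        asym = asymmetry_distribution(results["counts"], weights)
        asym.to_csv(outdir / "asymmetry.csv")
        results["asymmetry"] = asym
        prof = results["profile_r2"]
        report_count = m["report_count"]
        if report_count is None:
            report_count = int(prof.coords[0][prof.support].max())
        start = int(prof.coords[0][prof.support].min())
        stage_delta = prof.delta(start, report_count)
        results["stage_delta"] = stage_delta
        manifest.extra["report_count"] = report_count
    else:
        prof = results["profile_d"]
        stage_delta = float(np.nanmax(prof.f) - np.nanmin(prof.f))
        results["stage_delta"] = stage_delta
    report = {
        "stage_id": config.stage_id,
        "delta_f_kcal_mol": stage_delta,
        "budgets": manifest.budgets,
    }
    (outdir / "stage_report.json").write_text(json.dumps(report, indent=2))
    files = [outdir / "stage_report.json"]
    if (outdir / "asymmetry.csv").exists():
        files.append(outdir / "asymmetry.csv")
    phase_done(phase, files)
    manifest.phase_timings[phase] = time.perf_counter() - t0
    manifest.save(outdir)
    results["manifest"] = manifest
    return results


def run_full(configs: list[StageConfig], outdir, resume: bool = True) -> dict:
    """Run sequential stages and stitch the per-stage free-energy changes.

    For mimic systems a later stage's spec may carry fewer beads per arm
    (hand-off after partial unwrapping); the combined report records each
    stage's arm length and delta-F and the stitched total.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    deltas = []
    stage_infos = []
    for config in configs:
        stage_dir = outdir / config.stage_id
        res = run_stage(config, stage_dir, resume=resume)
        deltas.append(res["stage_delta"])
        info = {"stage_id": config.stage_id, "delta_f_kcal_mol": res["stage_delta"]}
        if config.system["type"] == "mimic":
            info["arm_length"] = config.build_system().spec.n_beads
        stage_infos.append(info)
    stitched = stitch_stage_profiles(deltas,
                                     boundaries=[s["stage_id"] for s in stage_infos])
    report = {
        "stages": stage_infos,
        "stitched_total_kcal_mol": stitched.total,
    }
    (outdir / "combined_report.json").write_text(json.dumps(report, indent=2))
    return {"stages": stage_infos, "stitched": stitched}
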