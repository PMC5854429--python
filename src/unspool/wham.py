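"""Self-consistent WHAM on 1-D binned window samples.

The unbiased probability on a histogram grid is recovered from restrained
window samples by iterating the coupled equations

    P(x_k) = sum_i H_i(x_k) / sum_j n_j exp([F_j - V_j(x_k)] / kBT)
    F_j    = -kBT ln sum_k P(x_k) exp(-V_j(x_k) / kBT)

to self-consistency on the window free energies F_j (default tolerance
1e-8 kcal/mol on max |dF_j|, the iterated quantity).  All sums are
accumulated in log space so biases of hundreds of kcal/mol cannot
overflow.  F is anchored to the first window during iteration; the final
profile is min-shifted to 0.  Zero-count bins are reported as missing
values, never imputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import kbt
from .profiles import FreeEnergyProfile
from .umbrella import UmbrellaWindow, WindowSamples, combined_bias

__all__ = [
    "HistogramGrid",
    "WHAMSolution",
    "solve_wham",
    "free_energy_1d",
    "sample_weights",
    "convergence_series",
]


@dataclass(frozen=True)
class HistogramGrid:
    """Uniform half-open bins [edge_k, edge_{k+1}) covering [lo, hi]."""

    lo: float
    hi: float
    width: float = 1.0

    def __post_init__(self):
        if self.hi <= self.lo or self.width <= 0:
            raise ValueError("need hi > lo and width > 0")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.hi - self.lo) / self.width - 1e-9))

    @property
    def edges(self) -> np.ndarray:
        return self.lo + self.width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.lo + self.width * (np.arange(self.n_bins) + 0.5)

    def assign(self, values) -> np.ndarray:
        """Bin index per value; values outside [lo, hi) raise."""
        values = np.asarray(values, dtype=float)
        idx = np.floor((values - self.lo) / self.width).astype(int)
        # the right edge belongs to the last bin so a closed data range fits
        idx = np.where(np.isclose(values, self.hi), self.n_bins - 1, idx)
        if np.any((idx < 0) | (idx >= self.n_bins)):
            raise ValueError("samples fall outside the histogram grid")
        return idx

    @classmethod
    def covering(cls, values, width: float = 1.0, pad: float = 0.0) -> "HistogramGrid":
        values = np.asarray(values, dtype=float)
        lo = np.floor((values.min() - pad) / width) * width
        hi = np.ceil((values.max() + pad) / width) * width
        if hi <= lo:
            hi = lo + width
        return cls(lo, hi, width)


@dataclass
class WHAMSolution:
    """Converged WHAM output.

    ``weights`` are per-sample unbiased weights (normalized to sum 1) in
    the concatenated sample order of the input windows; ``p`` is the
    unbiased bin probability mass (sums to 1).
    """

    grid: HistogramGrid
    f_windows: np.ndarray  # per-window shifts, first window = 0
    p: np.ndarray
    weights: np.ndarray
    sample_window: np.ndarray  # window index per concatenated sample
    sample_bin: np.ndarray
    counts: np.ndarray
    n_per_window: np.ndarray
    temperature: float
    n_iter: int
    residual: float
    residual_history: np.ndarray
    meta: dict = field(default_factory=dict)

    def profile(self) -> FreeEnergyProfile:
        return free_energy_1d(self.p, self.grid, self.temperature)

    def window_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_id": np.arange(len(self.f_windows)),
                "F_j": self.f_windows,
                "n_i": self.n_per_window,
            }
        )

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prof = self.profile()
        df = prof.to_frame()
        df["n_samples"] = self.counts
        df = df.rename(columns={"d": "d_A"})
        df.to_csv(prefix.with_suffix(".profile.csv"), index=False)
        self.window_table().to_csv(prefix.with_suffix(".windows.csv"), index=False)
        report = {
            "n_iter": self.n_iter,
            "residual": self.residual,
            "temperature": self.temperature,
            "tolerance": self.meta.get("tol"),
            "converged": bool(self.meta.get("converged", True)),
        }
        prefix.with_suffix(".convergence.json").write_text(json.dumps(report, indent=2))


def _window_overlap_warning(counts_per_window: np.ndarray):
    """Warn when a window shares no occupied bin with any other window."""
    occ = counts_per_window > 0
    lonely = []
    for j in range(occ.shape[0]):
        if not occ[j].any():
            continue  # empty window (e.g. fully discarded): no overlap hazard
        others = np.delete(occ, j, axis=0).any(axis=0)
        if not np.any(occ[j] & others) and occ.shape[0] > 1:
            lonely.append(j)
    if lonely:
        warnings.warn(f"windows {lonely} share no occupied bins with the rest; "
                      "WHAM free energies across the gap are undetermined")


def solve_wham(
    windows: list[WindowSamples],
    biases: list[UmbrellaWindow] | None = None,
    temperature: float = 300.0,
    tol: float = 1e-8,
    max_iter: int = 200000,
    grid: HistogramGrid | None = None,
) -> WHAMSolution:
    """Solve the WHAM equations for a set of biased windows.

    ``biases`` defaults to each window's own :class:`UmbrellaWindow`.
    Raises if ``max_iter`` is exhausted before ``tol`` is reached.
    """
    if not windows or all(w.n == 0 for w in windows):
        raise ValueError("need at least one window with at least one sample")
    if biases is None:
        biases = [w.window for w in windows]
    if len(biases) != len(windows):
        raise ValueError("one bias per window required")
    kt = kbt(temperature)
    beta = 1.0 / kt

    d_all = np.concatenate([w.d for w in windows])
    sample_window = np.concatenate(
        [np.full(w.n, j, dtype=int) for j, w in enumerate(windows)]
    )
    if grid is None:
        grid = HistogramGrid.covering(d_all, width=1.0)
    sample_bin = grid.assign(d_all)
    nbin = grid.n_bins
    nwin = len(windows)
    counts_jk = np.zeros((nwin, nbin))
    for j, w in enumerate(windows):
        if w.n:
            np.add.at(counts_jk[j], grid.assign(w.d), 1.0)
    counts = counts_jk.sum(axis=0)
    n_j = counts_jk.sum(axis=1)
    _window_overlap_warning(counts_jk)

    centers = grid.centers
    v_jk = np.stack([combined_bias(centers, b) for b in biases])  # (nwin, nbin)
    log_nj = np.where(n_j > 0, np.log(np.maximum(n_j, 1)), -np.inf)
    log_counts = np.where(counts > 0, np.log(np.maximum(counts, 1)), -np.inf)

    f = np.zeros(nwin)
    residuals = []
    converged = False
    occupied = counts > 0
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_j [ln n_j + beta (F_j - V_jk)]
        a = log_nj[:, None] + beta * (f[:, None] - v_jk)
        log_denom = logsumexp(a, axis=0)
        log_p = np.where(occupied, log_counts - log_denom, -np.inf)
        # window shifts: F_j = -kBT ln sum_k P_k exp(-beta V_jk)
        log_z = logsumexp(log_p[None, :] - beta * v_jk, axis=1)
        f_new = -kt * log_z
        f_new = f_new - f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        residuals.append(resid)
        f = f_new
        if resid < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {resid:.3e})"
        )

    a = log_nj[:, None] + beta * (f[:, None] - v_jk)
    log_denom = logsumexp(a, axis=0)
    log_p = np.where(occupied, log_counts - log_denom, -np.inf)
    log_p = log_p - logsumexp(log_p[occupied])
    p = np.exp(log_p)

    # per-sample unbiased weights, biases evaluated at the sample's bin center
    # so the weighted histogram reproduces p bin-for-bin
    w_s = np.exp(-log_denom[sample_bin])
    w_s = w_s / w_s.sum()

    return WHAMSolution(
        grid=grid,
        f_windows=f,
        p=p,
        weights=w_s,
        sample_window=sample_window,
        sample_bin=sample_bin,
        counts=counts,
        n_per_window=n_j,
        temperature=temperature,
        n_iter=it,
        residual=resid,
        residual_history=np.asarray(residuals),
        meta={"tol": tol, "converged": converged, "biases": v_jk},
    )


def free_energy_1d(p, grid: HistogramGrid, temperature: float = 300.0) -> FreeEnergyProfile:
    """F = -kBT ln P on the grid, min-shifted to 0; empty bins are NaN."""
    p = np.asarray(p, dtype=float)
    if np.all(p <= 0):
        raise ValueError("distribution has no support")
    return FreeEnergyProfile.from_probability(
        (grid.centers,), p, names=("d",), units=("A",), temperature=temperature
    )


def sample_weights(solution: WHAMSolution, sample_d=None) -> np.ndarray:
    """Per-sample unbiased weights (sum to 1).

    With ``sample_d`` given, weights are recomputed for those coordinate
    values (bin-center convention); otherwise the solution's own samples'
    weights are returned.
    """
    if sample_d is None:
        return solution.weights
    beta = 1.0 / kbt(solution.temperature)
    idx = solution.grid.assign(np.asarray(sample_d, dtype=float))
    # reconstruct log-denominator on the grid from the converged F_j
    raise_biases = solution.meta.get("biases")
    if raise_biases is None:
        raise ValueError("solution carries no bias table for external samples")
    v_jk = raise_biases
    log_nj = np.where(solution.n_per_window > 0,
                      np.log(np.maximum(solution.n_per_window, 1)), -np.inf)
    a = log_nj[:, None] + beta * (solution.f_windows[:, None] - v_jk)
    log_denom = logsumexp(a, axis=0)
    w = np.exp(-log_denom[idx])
    return w / w.sum()


def convergence_series(
    windows: list[WindowSamples],
    fractions=(1 / 3, 2 / 3, 0.8, 0.9333, 1.0),
    **wham_kwargs,
):
    """Profiles from growing prefixes of each window's samples.

    The analog of overlaying profiles computed from increasing sampling
    durations; returns (fractions, profiles, rmsd_between_consecutive).
    RMSD is computed on the common support after mean-alignment.
    """
    profiles = []
    for frac in fractions:
        sub = []
        for ws in windows:
            n = max(1, int(round(ws.n * frac)))
            traj = ws.trajectory
            from .toy_systems import Trajectory

            sub.append(
                WindowSamples(
                    ws.window_id,
                    ws.window,
                    Trajectory(traj.time_ps[:n], traj.d[:n],
                               {k: v[:n] for k, v in traj.aux.items()}),
                )
            )
        profiles.append(solve_wham(sub, **wham_kwargs).profile())
    rmsds = []
    for a, b in zip(profiles[:-1], profiles[1:]):
        mask = a.support & b.support
        diff = a.f[mask] - b.f[mask]
        diff = diff - diff.mean()
        rmsds.append(float(np.sqrt(np.mean(diff**2))))
    return list(fractions), profiles, rmsds
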