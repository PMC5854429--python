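"""Independent oracle implementations used only by the tests.

Everything here is written as a second, deliberately different path from
the package code: brute-force Python loops for the reweighting tallies and
contact scans, and a convex-minimization solution of the WHAM equations
(gradient-based, via scipy) to cross-check the package's fixed-point
iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from unspool.constants import kbt
from unspool.toy_systems import Trajectory
from unspool.umbrella import UmbrellaWindow, WindowSamples, combined_bias


def windows_from_arrays(sample_arrays, centers, k=0.2, bias=None) -> list[WindowSamples]:
    """Wrap raw per-window coordinate arrays as WindowSamples."""
    out = []
    for j, (d, c) in enumerate(zip(sample_arrays, centers)):
        d = np.asarray(d, dtype=float)
        traj = Trajectory(np.arange(len(d), dtype=float), d)
        out.append(WindowSamples(j, UmbrellaWindow(float(c), k, bias), traj))
    return out


def reference_wham(windows, temperature=300.0, grid=None):
    """WHAM by direct minimization of the convex log-likelihood.

    Solves for the window shifts g_j = F_j / kBT (first window fixed at 0)
    by minimizing  Phi(g) = sum_k H_k ln D_k - sum_j n_j g_j  with
    D_k = sum_j n_j exp(g_j - beta V_jk), whose stationary point is the
    WHAM fixed point.  Returns (bin centers, F profile min-anchored,
    F_j array in kcal/mol).
    """
    from unspool.wham import HistogramGrid

    kt = kbt(temperature)
    beta = 1.0 / kt
    d_all = np.concatenate([w.d for w in windows])
    if grid is None:
        grid = HistogramGrid.covering(d_all, width=0.05)
    counts = np.zeros(grid.n_bins)
    for w in windows:
        for x in w.d:
            counts[grid.assign(np.array([x]))[0]] += 1
    n_j = np.array([w.n for w in windows], dtype=float)
    keep = n_j > 0
    v_jk = np.stack([combined_bias(grid.centers, w.window) for w in windows])[keep]
    n_j = n_j[keep]
    nwin = len(n_j)
    ln_nj = np.log(n_j)
    occ = counts > 0

    def split(free):
        return np.concatenate([[0.0], free])

    def phi_and_grad(free):
        g = split(free)
        a = ln_nj[:, None] + g[:, None] - beta * v_jk  # (nwin, nbin)
        ln_dk = logsumexp(a, axis=0)
        phi = float(np.sum(counts[occ] * ln_dk[occ]) - np.sum(n_j * g))
        w_jk = np.exp(a - ln_dk[None, :])
        grad = (w_jk[:, occ] * counts[occ][None, :]).sum(axis=1) - n_j
        return phi, grad[1:]

    res = minimize(phi_and_grad, np.zeros(nwin - 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10})
    g = split(res.x)
    a = ln_nj[:, None] + g[:, None] - beta * v_jk
    ln_dk = logsumexp(a, axis=0)
    with np.errstate(divide="ignore"):
        ln_p = np.where(occ, np.log(np.maximum(counts, 1e-300)) - ln_dk, -np.inf)
    ln_p -= logsumexp(ln_p[occ])
    f = np.where(occ, -kt * ln_p, np.nan)
    f -= np.nanmin(f)
    return grid.centers, f, kt * g


# ---------------------------------------------------------------------------
# brute-force reweighting tallies
# ---------------------------------------------------------------------------


def brute_pmf(coordinate, weights):
    """Weighted tally per integer coordinate value, ordered python loop."""
    coordinate = np.round(np.asarray(coordinate)).astype(int)
    lo, hi = coordinate.min(), coordinate.max()
    p = np.zeros(hi - lo + 1)
    for c, w in zip(coordinate, weights):
        p[c - lo] += w
    return np.arange(lo, hi + 1, dtype=float), p / p.sum()


def brute_mean_spread(coordinate, weights, observable):
    coordinate = np.round(np.asarray(coordinate)).astype(int)
    lo, hi = coordinate.min(), coordinate.max()
    nbin = hi - lo + 1
    wsum = np.zeros(nbin)
    awsum = np.zeros(nbin)
    a2wsum = np.zeros(nbin)
    for c, w, a in zip(coordinate, weights, observable):
        wsum[c - lo] += w
        awsum[c - lo] += w * a
        a2wsum[c - lo] += w * a * a
    mask = wsum > 0
    mean = awsum[mask] / wsum[mask]
    sigma = np.sqrt(np.maximum(a2wsum[mask] / wsum[mask] - mean**2, 0.0))
    return np.arange(lo, hi + 1, dtype=float)[mask], mean, sigma


def brute_fes2d_p(coord1_idx, coord2_idx, weights, n1, n2):
    p = np.zeros((n1, n2))
    for i, j, w in zip(coord1_idx, coord2_idx, weights):
        p[i, j] += w
    return p / p.sum()


def brute_min_distance(group_a, group_b):
    """All-pairs minimal distance, explicit loops."""
    best = np.inf
    for a in np.asarray(group_a, dtype=float):
        for b in np.asarray(group_b, dtype=float):
            dist = float(np.sqrt(((a - b) ** 2).sum()))
            if dist < best:
                best = dist
    return best


def brute_contact_table(frames_a, frames_b, weights, strata, cutoff):
    """Stratified residue contact probabilities via explicit loops."""
    residues = list(frames_a[0].keys())
    rows = {}
    for stratum in sorted(set(strata)):
        idx = [i for i, s in enumerate(strata) if s == stratum]
        wsum = sum(weights[i] for i in idx)
        for rid in residues:
            acc = 0.0
            for i in idx:
                if brute_min_distance(frames_a[i][rid], frames_b[i]) <= cutoff:
                    acc += weights[i]
            rows[(rid, stratum)] = acc / wsum
    return rows
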