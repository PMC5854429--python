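"""Projection of WHAM-weighted ensembles onto alternative coordinates.

Given per-sample unbiased weights, these routines build free-energy
profiles along any per-sample coordinate (e.g. the total unwrapped-bead
count), per-bin weighted means and spreads of arbitrary observables, and
2-D landscapes over a coordinate pair.  Integer-valued coordinates (bead
or base-pair counts) are binned at unit width; continuous coordinates use
a :class:`~unspool.wham.HistogramGrid`.

Accumulation uses ordered in-place adds (``np.add.at``), which makes every
result bit-identical to a brute-force loop over samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import FreeEnergyProfile
from .wham import HistogramGrid

__all__ = [
    "pmf_along",
    "weighted_mean",
    "weighted_spread",
    "fes_2d",
    "marginal",
]


def _is_integer_coordinate(values: np.ndarray) -> bool:
    return np.issubdtype(values.dtype, np.integer) or np.allclose(
        values, np.round(values), atol=1e-9
    )


def _bin_coordinate(values, grid):
    """Map a coordinate series to (bin indices, bin centers, n_bins)."""
    values = np.asarray(values)
    if grid is None:
        if not _is_integer_coordinate(values):
            raise ValueError("continuous coordinate needs an explicit grid")
        iv = np.round(values).astype(int)
        lo, hi = int(iv.min()), int(iv.max())
        centers = np.arange(lo, hi + 1, dtype=float)
        return iv - lo, centers, len(centers)
    idx = grid.assign(values.astype(float))
    return idx, grid.centers, grid.n_bins


def _check_weights(weights, n):
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError("one weight per sample required")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if not np.isclose(total, 1.0, rtol=1e-6):
        raise ValueError("weights must be normalized to sum 1")
    return weights


def pmf_along(
    coordinate,
    weights,
    grid: HistogramGrid | None = None,
    temperature: float = 300.0,
    name: str = "R2",
    unit: str = "bp",
) -> FreeEnergyProfile:
    """Free-energy profile along a per-sample coordinate.

    P per bin is the summed sample weight; F = -kBT ln P, min-anchored.
    Integer coordinates (counts) get unit-width bins spanning their range;
    empty bins are reported missing.
    """
    coordinate = np.asarray(coordinate)
    weights = _check_weights(weights, len(coordinate))
    idx, centers, nbin = _bin_coordinate(coordinate, grid)
    p = np.zeros(nbin)
    np.add.at(p, idx, weights)
    if p.sum() <= 0:
        raise ValueError("empty support")
    return FreeEnergyProfile.from_probability(
        (centers,), p, names=(name,), units=(unit,), temperature=temperature
    )


def weighted_mean(coordinate, weights, observable, grid=None) -> pd.DataFrame:
    """Per-bin weighted mean of an observable A along the coordinate.

    Returns a table (bin center, mean, weight); bins with no samples are
    omitted (undefined, not zero).
    """
    coordinate = np.asarray(coordinate)
    observable = np.asarray(observable, dtype=float)
    weights = _check_weights(weights, len(coordinate))
    if observable.shape != coordinate.shape:
        raise ValueError("observable must align with the coordinate series")
    if not np.all(np.isfinite(observable)):
        raise ValueError("observable contains non-finite values")
    idx, centers, nbin = _bin_coordinate(coordinate, grid)
    wsum = np.zeros(nbin)
    awsum = np.zeros(nbin)
    np.add.at(wsum, idx, weights)
    np.add.at(awsum, idx, weights * observable)
    mask = wsum > 0
    return pd.DataFrame(
        {"bin": centers[mask], "mean": awsum[mask] / wsum[mask], "weight": wsum[mask]}
    )


def weighted_spread(coordinate, weights, observable, grid=None) -> pd.DataFrame:
    """Per-bin weighted spread sigma = sqrt(<A^2> - <A>^2) (clipped at 0)."""
    coordinate = np.asarray(coordinate)
    observable = np.asarray(observable, dtype=float)
    weights = _check_weights(weights, len(coordinate))
    idx, centers, nbin = _bin_coordinate(coordinate, grid)
    wsum = np.zeros(nbin)
    awsum = np.zeros(nbin)
    a2wsum = np.zeros(nbin)
    np.add.at(wsum, idx, weights)
    np.add.at(awsum, idx, weights * observable)
    np.add.at(a2wsum, idx, weights * observable**2)
    mask = wsum > 0
    mean = awsum[mask] / wsum[mask]
    second = a2wsum[mask] / wsum[mask]
    sigma = np.sqrt(np.maximum(second - mean**2, 0.0))
    return pd.DataFrame({"bin": centers[mask], "sigma": sigma, "mean": mean,
                         "weight": wsum[mask]})


def fes_2d(
    coord1,
    coord2,
    weights,
    grid1: HistogramGrid | None = None,
    grid2: HistogramGrid | None = None,
    temperature: float = 300.0,
    names=("R1", "R2"),
    units=("A", "bp"),
) -> FreeEnergyProfile:
    """2-D free-energy landscape over a coordinate pair.

    The joint weighted histogram is converted to F = -kBT ln P with the
    global minimum anchored at 0; marginalizing over either axis
    reproduces the corresponding 1-D profile.
    """
    coord1 = np.asarray(coord1)
    coord2 = np.asarray(coord2)
    if coord1.shape != coord2.shape:
        raise ValueError("coordinates must align")
    weights = _check_weights(weights, len(coord1))
    i1, c1, n1 = _bin_coordinate(coord1, grid1)
    i2, c2, n2 = _bin_coordinate(coord2, grid2)
    p = np.zeros((n1, n2))
    np.add.at(p, (i1, i2), weights)
    return FreeEnergyProfile.from_probability(
        (c1, c2), p, names=tuple(names), units=tuple(units), temperature=temperature
    )


def marginal(profile: FreeEnergyProfile, axis: int) -> FreeEnergyProfile:
    """1-D profile obtained by summing the 2-D P over the given axis."""
    if profile.ndim != 2:
        raise ValueError("marginal needs a 2-D profile")
    keep = 1 - axis
    p = profile.p.sum(axis=axis)
    return FreeEnergyProfile.from_probability(
        (profile.coords[keep],),
        p,
        names=(profile.names[keep],),
        units=(profile.units[keep],),
        temperature=profile.temperature,
    )
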