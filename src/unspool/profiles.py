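"""Free-energy profile container shared by the estimation modules.

A profile couples a probability distribution P on a (1-D or 2-D) bin grid
with the corresponding free energy F = -kBT ln P, anchored so that
min F = 0 on the populated bins.  Unpopulated bins are reported as missing
(NaN), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import kbt


@dataclass
class FreeEnergyProfile:
    """Free energy F (kcal/mol) over a coordinate grid.

    Parameters
    ----------
    coords
        Bin centers.  One array for a 1-D profile; a tuple of two arrays
        (meshgrid-compatible, ``F.shape == (len(c0), len(c1))``) for 2-D.
    f
        Free energy per bin, min-anchored to 0 on the support; NaN off
        support.
    p
        Probability mass per bin (sums to 1 over the support).
    names
        Coordinate name(s), e.g. ``("d",)`` or ``("d", "n_unwrapped")``.
    units
        Coordinate unit(s), same length as ``names``.
    temperature
        Temperature (K) used for the F <-> P conversion.
    """

    coords: tuple[np.ndarray, ...]
    f: np.ndarray
    p: np.ndarray
    names: tuple[str, ...] = ("d",)
    units: tuple[str, ...] = ("A",)
    temperature: float = 300.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = tuple(np.asarray(c, dtype=float) for c in self.coords)
        self.f = np.asarray(self.f, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.ndim not in (1, 2):
            raise ValueError("only 1-D and 2-D profiles are supported")

    @property
    def ndim(self) -> int:
        return len(self.coords)

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of populated bins."""
        return np.isfinite(self.f)

    @classmethod
    def from_probability(
        cls,
        coords,
        p,
        *,
        names=("d",),
        units=("A",),
        temperature: float = 300.0,
        meta: dict | None = None,
    ) -> "FreeEnergyProfile":
        """Build F = -kBT ln P from a (possibly unnormalized) bin mass array."""
        if isinstance(coords, np.ndarray):
            coords = (coords,)
        coords = tuple(coords)
        p = np.asarray(p, dtype=float)
        if np.any(p < 0):
            raise ValueError("probability mass must be nonnegative")
        total = p.sum()
        if total <= 0:
            raise ValueError("probability mass is identically zero")
        p = p / total
        with np.errstate(divide="ignore"):
            f = np.where(p > 0, -kbt(temperature) * np.log(np.where(p > 0, p, 1.0)), np.nan)
        f = f - np.nanmin(f)
        return cls(coords, f, p, tuple(names), tuple(units), temperature, meta or {})

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per bin)."""
        if self.ndim == 1:
            return pd.DataFrame(
                {self.names[0]: self.coords[0], "F_kcal_mol": self.f, "P": self.p}
            )
        c0, c1 = np.meshgrid(self.coords[0], self.coords[1], indexing="ij")
        return pd.DataFrame(
            {
                self.names[0]: c0.ravel(),
                self.names[1]: c1.ravel(),
                "F_kcal_mol": self.f.ravel(),
                "P": self.p.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def delta(self, lo_value: float, hi_value: float, axis: int = 0) -> float:
        """F(hi_value) - F(lo_value) read off the profile (nearest bins)."""
        if self.ndim != 1:
            raise ValueError("delta is defined for 1-D profiles")
        c = self.coords[0]
        i = int(np.argmin(np.abs(c - lo_value)))
        j = int(np.argmin(np.abs(c - hi_value)))
        return float(self.f[j] - self.f[i])

    def plot(self, ax=None, **kwargs):
        """Quick matplotlib rendering (line for 1-D, pcolormesh for 2-D)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.ndim == 1:
            ax.plot(self.coords[0], self.f, **kwargs)
            ax.set_xlabel(f"{self.names[0]} ({self.units[0]})")
            ax.set_ylabel("F (kcal/mol)")
        else:
            mesh = ax.pcolormesh(
                self.coords[0], self.coords[1], self.f.T, shading="nearest", **kwargs
            )
            ax.set_xlabel(f"{self.names[0]} ({self.units[0]})")
            ax.set_ylabel(f"{self.names[1]} ({self.units[1]})")
            ax.figure.colorbar(mesh, ax=ax, label="F (kcal/mol)")
        return ax
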