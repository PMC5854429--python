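"""Structural observables of unwrapping: per-end unwrapped counts,
residue-wise contact probabilities, and end-asymmetry distributions.

Definitions follow the conventions used for nucleosomal DNA: a unit (base
pair or bead) counts as unwrapped when its center has moved MORE THAN the
threshold (strict inequality, default 4 A) away from its position in the
fully wrapped reference structure, with a positive radial component
relative to the core center ("shifted outward").  A residue is in contact
with the partner group in a frame when at least one atom pair is WITHIN
the cutoff (inclusive, default 4 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceStructure",
    "UnwrapCounts",
    "ContactTable",
    "AsymmetryMatrix",
    "StitchResult",
    "count_unwrapped",
    "contact_ratio",
    "asymmetry_distribution",
    "stitch_stage_profiles",
]


@dataclass
class ReferenceStructure:
    """Fully wrapped reference: per-unit centers, core center, end ordering.

    ``end1_ids`` / ``end2_ids`` list unit ids outermost-first; the two
    lists must be disjoint and the ids unique.
    """

    positions: dict  # unit id -> (3,) reference center, A
    core_center: np.ndarray
    end1_ids: tuple
    end2_ids: tuple

    def __post_init__(self):
        self.core_center = np.asarray(self.core_center, dtype=float)
        ids = list(self.end1_ids) + list(self.end2_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("end unit lists must be disjoint with unique ids")
        missing = [i for i in ids if i not in self.positions]
        if missing:
            raise ValueError(f"reference is missing positions for units {missing}")

    @classmethod
    def from_mimic(cls, mimic) -> "ReferenceStructure":
        """Reference at the mimic's wrapped anchor geometry."""
        anchors, _ = mimic.anchor_geometry()
        nb = mimic.spec.n_beads
        positions = {}
        end1, end2 = [], []
        for j in range(nb):
            positions[("end1", j)] = anchors[0, j]
            positions[("end2", j)] = anchors[1, j]
            end1.append(("end1", j))
            end2.append(("end2", j))
        return cls(positions, np.zeros(3), tuple(end1), tuple(end2))

    @classmethod
    def from_pdb(cls, path, end1_chain: str, end2_chain: str) -> "ReferenceStructure":
        """Per-residue centers of mass from a PDB file, one unit per residue.

        Units are (chain, residue number) ids ordered by residue number
        (ascending for end1, descending for end2: outermost first is the
        caller's responsibility via chain orientation).
        """
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
        positions = {}
        ends = {end1_chain: [], end2_chain: []}
        for chain in (end1_chain, end2_chain):
            sel = structure[structure.chain_id == chain]
            for res_id in np.unique(sel.res_id):
                coords = sel.coord[sel.res_id == res_id]
                positions[(chain, int(res_id))] = coords.mean(axis=0)
                ends[chain].append((chain, int(res_id)))
        core = structure.coord.mean(axis=0)
        return cls(positions, core, tuple(ends[end1_chain]), tuple(ends[end2_chain]))


@dataclass(frozen=True)
class UnwrapCounts:
    """Per-end unwrapped-unit counts for one frame.

    ``end1`` / ``end2`` count contiguously from the free end inward (a
    unit counts only if every unit outward of it is also unwrapped);
    ``end1_any`` / ``end2_any`` count every displaced unit.
    """

    end1: int
    end2: int
    end1_any: int
    end2_any: int

    @property
    def total(self) -> int:
        return self.end1 + self.end2

    @property
    def total_any(self) -> int:
        return self.end1_any + self.end2_any


def _unwrapped_mask(frame, reference: ReferenceStructure, ids, threshold: float, mode: str):
    ref = np.stack([reference.positions[i] for i in ids])
    try:
        pos = np.stack([frame[i] for i in ids])
    except KeyError:
        missing = [i for i in ids if i not in frame]
        raise KeyError(f"frame is missing units {missing}") from None
    disp = pos - ref
    dist = np.linalg.norm(disp, axis=1)
    if mode == "radial_outward":
        radial = np.einsum("ij,ij->i", disp, ref - reference.core_center)
        return (dist > threshold) & (radial > 0)
    if mode == "displacement":
        return dist > threshold
    if mode == "radial_distance":
        r_ref = np.linalg.norm(ref - reference.core_center, axis=1)
        r_now = np.linalg.norm(pos - reference.core_center, axis=1)
        return (r_now - r_ref) > threshold
    raise ValueError(f"unknown unwrapping mode {mode!r}")


def count_unwrapped(
    frame,
    reference: ReferenceStructure,
    threshold: float = 4.0,
    mode: str = "radial_outward",
) -> UnwrapCounts:
    """Per-end unwrapped counts of one frame (dict unit id -> center).

    ``mode`` selects the displacement definition: ``radial_outward``
    (default: displacement beyond the threshold AND pointing away from the
    core), ``displacement`` (any direction) or ``radial_distance`` (change
    of distance from the core center).
    """
    out = []
    for ids in (reference.end1_ids, reference.end2_ids):
        if not ids:
            out.append((0, 0))
            continue
        mask = _unwrapped_mask(frame, reference, ids, threshold, mode)
        contiguous = int(np.argmin(mask)) if not mask.all() else len(mask)
        out.append((contiguous, int(mask.sum())))
    return UnwrapCounts(out[0][0], out[1][0], out[0][1], out[1][1])


@dataclass
class ContactTable:
    """Residue x stratum contact probabilities in [0, 1]."""

    table: pd.DataFrame  # columns: residue_id, stratum, probability
    cutoff: float

    def __post_init__(self):
        p = self.table["probability"].to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("contact probabilities must lie in [0, 1]")

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(index="residue_id", columns="stratum", values="probability")


def contact_ratio(
    frames_a,
    frames_b,
    weights,
    strata,
    cutoff: float = 4.0,
) -> ContactTable:
    """Weighted residue-wise contact probabilities, stratified.

    Parameters
    ----------
    frames_a
        Per-frame dict residue_id -> (m, 3) atom coordinates of group A
        (e.g. histone residues).
    frames_b
        Per-frame (n, 3) atom coordinates of group B (e.g. DNA).
    weights
        Per-frame weights; renormalized within each stratum.
    strata
        Per-frame stratification label (e.g. unwrapped count).
    cutoff
        A residue is in contact when its minimal atom-pair distance to
        group B is <= cutoff (inclusive).
    """
    weights = np.asarray(weights, dtype=float)
    strata = np.asarray(strata)
    if not (len(frames_a) == len(frames_b) == len(weights) == len(strata)):
        raise ValueError("frames, weights and strata must align")
    if len(frames_a) == 0:
        raise ValueError("no frames")
    residues = list(frames_a[0].keys())
    if not residues:
        raise ValueError("empty residue group")
    contact = np.zeros((len(frames_a), len(residues)), dtype=bool)
    for fi, (fa, fb) in enumerate(zip(frames_a, frames_b)):
        b = np.asarray(fb, dtype=float)
        if b.size == 0:
            raise ValueError("empty partner group")
        for ri, rid in enumerate(residues):
            a = np.asarray(fa[rid], dtype=float)
            d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
            contact[fi, ri] = np.sqrt(d2.min()) <= cutoff
    rows = []
    for stratum in np.unique(strata):
        idx = np.flatnonzero(strata == stratum)
        # frame-ordered accumulation keeps results independent of any
        # vectorization or spatial-index acceleration of the distance scan
        wsum = 0.0
        acc = np.zeros(len(residues))
        for i in idx:
            wsum += weights[i]
            acc += weights[i] * contact[i]
        if wsum <= 0:
            continue
        probs = acc / wsum
        for rid, p in zip(residues, probs):
            rows.append({"residue_id": rid, "stratum": stratum, "probability": float(p)})
    return ContactTable(pd.DataFrame(rows), cutoff)


@dataclass
class AsymmetryMatrix:
    """P(end difference | total unwrapped count).

    Rows are end1 - end2 differences, columns total counts; each populated
    column sums to 1.
    """

    totals: np.ndarray
    differences: np.ndarray
    probability: np.ndarray  # (n_differences, n_totals)

    def to_frame(self) -> pd.DataFrame:
        t, d = np.meshgrid(self.totals, self.differences, indexing="xy")
        df = pd.DataFrame(
            {"total": t.ravel(), "difference": d.ravel(),
             "probability": self.probability.ravel()}
        )
        return df[np.isfinite(df["probability"])]

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def column(self, total: int) -> pd.Series:
        j = int(np.flatnonzero(self.totals == total)[0])
        return pd.Series(self.probability[:, j], index=self.differences)


def asymmetry_distribution(counts, weights=None) -> AsymmetryMatrix:
    """Distribution of the end1 - end2 count difference per total count.

    ``counts`` is an (n, 2) array of per-frame (end1, end2) unwrapped
    counts; each total-count column of the joint weighted tally is
    renormalized to 1 over the differences (columns with no support are
    NaN).
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("counts must be (n, 2)")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = len(counts)
    weights = np.ones(n) / n if weights is None else np.asarray(weights, dtype=float)
    totals_per_frame = counts.sum(axis=1)
    diff_per_frame = counts[:, 0] - counts[:, 1]
    tmax = int(totals_per_frame.max()) if n else 0
    totals = np.arange(tmax + 1)
    differences = np.arange(-tmax, tmax + 1)
    mat = np.zeros((len(differences), len(totals)))
    np.add.at(mat, (diff_per_frame + tmax, totals_per_frame), weights)
    colsum = mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(colsum > 0, mat / colsum, np.nan)
    return AsymmetryMatrix(totals, differences, prob)


@dataclass
class StitchResult:
    """Total free-energy change stitched from sequential stages."""

    total: float
    stage_deltas: tuple
    metadata: dict = field(default_factory=dict)


def stitch_stage_profiles(stage_deltas, boundaries=None) -> StitchResult:
    """Sum per-stage free-energy changes into a total (kcal/mol).

    ``boundaries`` optionally records the matched end states between
    consecutive stages in the result metadata.
    """
    deltas = [float(d) for d in stage_deltas]
    if not deltas:
        raise ValueError("need at least one stage")
    meta = {"n_stages": len(deltas)}
    if boundaries is not None:
        meta["boundaries"] = list(boundaries)
    return StitchResult(float(sum(deltas)), tuple(deltas), meta)
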