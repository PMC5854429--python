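"""Unwrapped-unit counting, contact probabilities, end asymmetry, stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_contact_table, brute_min_distance

from unspool.structure_metrics import (
    ReferenceStructure,
    asymmetry_distribution,
    contact_ratio,
    count_unwrapped,
    stitch_stage_profiles,
)
from unspool.toy_systems import SpoolMimic, SpoolMimicSpec, simulate_trajectory


@pytest.fixture(scope="module")
def linear_reference():
    """Ten units per end on a line through the core at the origin."""
    positions = {}
    end1, end2 = [], []
    for j in range(10):
        positions[("e1", j)] = np.array([10.0 + j, 0.0, 0.0])   # outermost first
        positions[("e2", j)] = np.array([-10.0 - j, 0.0, 0.0])
        end1.append(("e1", j))
        end2.append(("e2", j))
    # outermost first means largest radius first
    end1 = end1[::-1]
    end2 = end2[::-1]
    return ReferenceStructure(positions, np.zeros(3), tuple(end1), tuple(end2))


class TestCountUnwrapped:
    def test_reference_frame_has_no_unwrapping(self, linear_reference):
        frame = dict(linear_reference.positions)
        counts = count_unwrapped(frame, linear_reference)
        assert (counts.end1, counts.end2, counts.total) == (0, 0, 0)

    def test_strict_threshold_boundary(self, linear_reference):
        frame = dict(linear_reference.positions)
        outer = linear_reference.end1_ids[0]
        frame[outer] = frame[outer] + np.array([4.0, 0, 0])  # exactly 4: wrapped
        assert count_unwrapped(frame, linear_reference).end1 == 0
        frame[outer] = linear_reference.positions[outer] + np.array([4.0 + 1e-9, 0, 0])
        counts = count_unwrapped(frame, linear_reference)
        assert (counts.end1, counts.end2, counts.total) == (1, 0, 1)

    def test_inward_displacement_is_not_unwrapping(self, linear_reference):
        frame = dict(linear_reference.positions)
        outer = linear_reference.end1_ids[0]
        frame[outer] = frame[outer] - np.array([4.1, 0, 0])
        assert count_unwrapped(frame, linear_reference).end1 == 0
        # but the direction-agnostic mode counts it
        assert count_unwrapped(frame, linear_reference, mode="displacement").end1 == 1

    def test_contiguous_vs_any_counting(self, linear_reference):
        frame = dict(linear_reference.positions)
        inner = linear_reference.end1_ids[2]  # third unit from the end
        frame[inner] = frame[inner] + np.array([5.0, 0, 0])
        counts = count_unwrapped(frame, linear_reference)
        assert counts.end1 == 0 and counts.end1_any == 1

    def test_missing_unit_reported(self, linear_reference):
        frame = dict(linear_reference.positions)
        frame.pop(("e1", 3))
        with pytest.raises(KeyError, match="e1"):
            count_unwrapped(frame, linear_reference)

    @given(st.floats(1.0, 8.0), st.floats(0.1, 3.9))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_counts_monotone_in_threshold(self, linear_reference, displacement, delta):
        frame = dict(linear_reference.positions)
        for uid in linear_reference.end1_ids[:4]:
            frame[uid] = frame[uid] + np.array([displacement, 0, 0])
        loose = count_unwrapped(frame, linear_reference, threshold=4.0)
        tight = count_unwrapped(frame, linear_reference, threshold=4.0 - delta)
        assert tight.end1_any >= loose.end1_any

    def test_mimic_embedding_reproduces_internal_counts(self, rng):
        mimic = SpoolMimic(SpoolMimicSpec())
        ref = ReferenceStructure.from_mimic(mimic)
        x = rng.uniform(0.0, 8.0, size=(2, 10))
        pos = mimic.embed(x)
        frame = {("end1", j): pos[0, j] for j in range(10)}
        frame.update({("end2", j): pos[1, j] for j in range(10)})
        counts = count_unwrapped(frame, ref)
        assert counts.end1_any == mimic.counts_any(x)[0]
        assert counts.end2_any == mimic.counts_any(x)[1]
        assert counts.end1 == mimic.counts_contiguous(x)[0]
        assert counts.end2 == mimic.counts_contiguous(x)[1]


class TestContactRatio:
    def _frames(self, rng, n_frames=20, n_res=4, n_atoms=3):
        frames_a, frames_b = [], []
        for _ in range(n_frames):
            frames_a.append(
                {r: rng.uniform(-6, 6, size=(n_atoms, 3)) for r in range(n_res)}
            )
            frames_b.append(rng.uniform(-6, 6, size=(8, 3)))
        return frames_a, frames_b

    def test_cutoff_is_inclusive(self):
        frames_a = [{"r1": np.array([[0.0, 0.0, 0.0]])}]
        frames_b = [np.array([[3.99, 0.0, 0.0]])]
        table = contact_ratio(frames_a, frames_b, np.array([1.0]), np.array([0]))
        assert table.table["probability"].iloc[0] == 1.0
        frames_b = [np.array([[4.01, 0.0, 0.0]])]
        table = contact_ratio(frames_a, frames_b, np.array([1.0]), np.array([0]))
        assert table.table["probability"].iloc[0] == 0.0

    def test_exact_cutoff_counts_as_contact(self):
        frames_a = [{"r1": np.array([[0.0, 0.0, 0.0]])}]
        frames_b = [np.array([[4.0, 0.0, 0.0]])]
        table = contact_ratio(frames_a, frames_b, np.array([1.0]), np.array([0]))
        assert table.table["probability"].iloc[0] == 1.0

    def test_matches_brute_force_scan(self, rng):
        frames_a, frames_b = self._frames(rng)
        weights = rng.random(20)
        weights /= weights.sum()
        strata = rng.integers(0, 3, 20)
        table = contact_ratio(frames_a, frames_b, weights, strata)
        expected = brute_contact_table(frames_a, frames_b, weights, strata, 4.0)
        for _, row in table.table.iterrows():
            assert row["probability"] == pytest.approx(
                expected[(row["residue_id"], row["stratum"])], rel=1e-12
            )

    def test_probabilities_bounded_and_deterministic(self, rng):
        frames_a, frames_b = self._frames(rng)
        weights = np.full(20, 1 / 20)
        strata = np.zeros(20, dtype=int)
        t1 = contact_ratio(frames_a, frames_b, weights, strata)
        t2 = contact_ratio(frames_a, frames_b, weights, strata)
        p = t1.table["probability"]
        assert ((p >= 0) & (p <= 1)).all()
        assert t1.table.equals(t2.table)

    def test_empty_stratum_omitted(self):
        frames_a = [{"r1": np.zeros((1, 3))}]
        frames_b = [np.zeros((1, 3))]
        table = contact_ratio(frames_a, frames_b, np.array([1.0]), np.array([2]))
        assert set(table.table["stratum"]) == {2}


class TestAsymmetry:
    def test_symmetric_frames_concentrate_at_zero(self):
        counts = np.array([[2, 2], [5, 5], [0, 0]])
        mat = asymmetry_distribution(counts)
        for total in (0, 4, 10):
            col = mat.column(total)
            assert col.loc[0] == pytest.approx(1.0)

    def test_mirror_pair_splits_evenly(self):
        counts = np.array([[5, 0], [0, 5]])
        mat = asymmetry_distribution(counts)
        col = mat.column(5)
        assert col.loc[5] == pytest.approx(0.5)
        assert col.loc[-5] == pytest.approx(0.5)

    def test_populated_columns_sum_to_one(self, rng):
        counts = rng.integers(0, 10, size=(500, 2))
        w = rng.random(500)
        w /= w.sum()
        mat = asymmetry_distribution(counts, w)
        colsum = np.nansum(mat.probability, axis=0)
        populated = ~np.isnan(mat.probability).all(axis=0)
        np.testing.assert_allclose(colsum[populated], 1.0, atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_distribution(np.array([[-1, 0]]))

    def test_pinned_arm_mass_sits_on_the_diagonal(self):
        # one arm held wrapped: the difference always equals the total
        spec = SpoolMimicSpec(pinned_arms=(1,), site_energies=(0.3, 0.3, 0.3, 0.3))
        mimic = SpoolMimic(spec)
        pull = lambda d: (-0.25 * d, np.full_like(np.asarray(d), -0.25))
        traj = simulate_trajectory(mimic, bias=pull, n_steps=60000,
                                   record_interval=30, seed=17, gamma=0.5)
        counts = np.stack(
            [traj.aux["unwrapped_end1"], traj.aux["unwrapped_end2"]], axis=1
        ).astype(int)
        assert counts[:, 0].max() >= 3  # the free arm does unwrap
        mat = asymmetry_distribution(counts)
        for total in range(1, counts[:, 0].max() + 1):
            col = mat.column(total)
            if np.isfinite(col).any():
                assert col.loc[total] == pytest.approx(1.0)


class TestStitching:
    def test_reported_stage_values_sum(self):
        assert stitch_stage_profiles([5.5, 6.0]).total == pytest.approx(11.5)

    def test_identity_and_commutativity(self):
        assert stitch_stage_profiles([4.2]).total == pytest.approx(4.2)
        assert stitch_stage_profiles([1.0, 2.5]).total == pytest.approx(
            stitch_stage_profiles([2.5, 1.0]).total
        )

    def test_boundaries_recorded(self):
        res = stitch_stage_profiles([1.0, 2.0], boundaries=["s1", "s2"])
        assert res.metadata["boundaries"] == ["s1", "s2"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stitch_stage_profiles([])


class TestReferenceStructure:
    def test_duplicate_ids_rejected(self):
        pos = {"a": np.zeros(3), "b": np.ones(3)}
        with pytest.raises(ValueError, match="disjoint"):
            ReferenceStructure(pos, np.zeros(3), ("a",), ("a",))

    def test_missing_position_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ReferenceStructure({"a": np.zeros(3)}, np.zeros(3), ("a",), ("b",))
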