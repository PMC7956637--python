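"""Contact detection and occupancy-statistics tests.

The grid-accelerated contact engine is compared with an all-pairs oracle; the
simultaneous/bridging classifier with exhaustive enumeration of molecule
configurations; occupancy statistics with hand-computed and generator ground
truth.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

import memtraj as mt
from memtraj.contacts import ContactSeries, bound_events, occupancy_report

from conftest import make_system


def _series(occupancy, regions=("A", "B"), cutoff=5.0):
    occupancy = np.asarray(occupancy, dtype=bool)
    return ContactSeries(
        region_names=list(regions),
        molecules=list(range(occupancy.shape[1])),
        occupancy=occupancy,
        cutoff=cutoff,
        times=np.arange(occupancy.shape[0], dtype=float),
    )


class TestFrameContacts:
    def test_boundary_inclusive(self):
        a = np.zeros((1, 3))
        assert mt.frame_contacts(a, np.array([[4.9, 0, 0]]), 5.0) is True
        assert mt.frame_contacts(a, np.array([[5.1, 0, 0]]), 5.0) is False
        assert mt.frame_contacts(a, np.array([[5.0, 0, 0]]), 5.0) is True

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError, match="cutoff"):
            mt.frame_contacts(np.zeros((1, 3)), np.ones((1, 3)), 0.0)

    def test_grid_equals_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            a = rng.uniform(0, 30, size=(200, 3))
            b = rng.uniform(0, 30, size=(200, 3))
            cutoff = rng.uniform(1.0, 6.0)
            assert mt.frame_contacts(a, b, cutoff) == (cdist(a, b).min() <= cutoff)

    def test_grid_equals_minimum_image_oracle_with_box(self):
        rng = np.random.default_rng(29)
        box = np.array([20.0, 24.0, 28.0])
        for _ in range(20):
            a = rng.uniform(0, 40, size=(60, 3))
            b = rng.uniform(0, 40, size=(60, 3))
            diff = a[:, None, :] - b[None, :, :]
            diff -= box * np.round(diff / box)
            dmin = np.linalg.norm(diff, axis=-1).min()
            cutoff = rng.uniform(1.0, 8.0)
            assert mt.frame_contacts(a, b, cutoff, box=box) == (dmin <= cutoff)


class TestOccupancyStatistics:
    def test_percent_arithmetic(self):
        occ = np.zeros((1000, 1, 1), dtype=bool)
        occ[:320, 0, 0] = True
        assert mt.occupancy_percent(_series(occ, ("TM I",)), "TM I") == 32.0
        assert mt.occupancy_percent(_series(np.ones((10, 2, 1)), ("r",)), "r") == 100.0
        assert mt.occupancy_percent(_series(np.zeros((10, 2, 1)), ("r",)), "r") == 0.0

    def test_mean_bound_per_frame(self):
        assert mt.mean_bound_per_frame(_series(np.ones((50, 1, 1)), ("r",)), "r") == 1.0
        occ = np.zeros((100, 2, 1), dtype=bool)
        occ[:50, :, 0] = True  # two molecules for half the frames
        occ[50:, 0, 0] = True  # one for the other half
        assert mt.mean_bound_per_frame(_series(occ, ("r",)), "r") == 1.5

    def test_zero_occupancy_iff_zero_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            occ = rng.random((40, 3, 2)) < rng.uniform(0, 0.3)
            s = _series(occ)
            for region in s.region_names:
                assert (mt.occupancy_percent(s, region) == 0) == (
                    mt.mean_bound_per_frame(s, region) == 0
                )

    def test_unknown_region_raises(self):
        with pytest.raises(KeyError):
            mt.occupancy_percent(_series(np.zeros((2, 1, 1)), ("A",)), "Z")


def _oracle_class(statuses):
    """Exhaustive distinct-representatives classification of one frame."""
    on_a = [i for i, s in enumerate(statuses) if s in ("A", "AB")]
    on_b = [i for i, s in enumerate(statuses) if s in ("B", "AB")]
    if not on_a and not on_b:
        return "none"
    if on_a and not on_b:
        return "only_a"
    if on_b and not on_a:
        return "only_b"
    if any(i != j for i in on_a for j in on_b):
        return "simultaneous"
    return "bridged_only"


class TestMotifOccupancyClasses:
    def test_three_canonical_cases(self):
        # distinct pair / lone bridger / bridger plus partner
        occ = np.array(
            [
                [[1, 0], [0, 1]],  # mol0 on A, mol1 on B -> simultaneous
                [[1, 1], [0, 0]],  # mol0 bridging alone -> excluded
                [[1, 1], [0, 1]],  # bridger + partner on B -> distinct pair exists
            ],
            dtype=bool,
        )
        labels, totals = mt.motif_occupancy_classes(_series(occ), "A", "B")
        assert list(labels) == ["simultaneous", "bridged_only", "simultaneous"]
        assert totals["simultaneous"] == 2 and totals["bridged_only"] == 1

    def test_exhaustive_enumeration_up_to_three_molecules(self):
        """Classifier agrees with brute force on every <=3-molecule configuration."""
        for n in range(0, 4):
            for statuses in itertools.product(("none", "A", "B", "AB"), repeat=n):
                occ = np.zeros((1, n, 2), dtype=bool)
                for i, s in enumerate(statuses):
                    occ[0, i, 0] = s in ("A", "AB")
                    occ[0, i, 1] = s in ("B", "AB")
                labels, _ = mt.motif_occupancy_classes(_series(occ), "A", "B")
                assert labels[0] == _oracle_class(statuses), statuses

    def test_class_counts_partition_frames(self):
        rng = np.random.default_rng(31)
        occ = rng.random((200, 4, 2)) < 0.35
        _, totals = mt.motif_occupancy_classes(_series(occ), "A", "B")
        assert sum(totals[c] for c in
                   ("none", "only_a", "only_b", "simultaneous", "bridged_only")) == 200

    @given(
        st.integers(0, 4).flatmap(
            lambda m: st.lists(
                st.lists(st.tuples(st.booleans(), st.booleans()),
                         min_size=m, max_size=m),
                min_size=1, max_size=25,
            )
        )
    )
    def test_partition_property_any_occupancy(self, frames):
        n_frames, n_mol = len(frames), len(frames[0])
        occ = np.array(frames, dtype=bool).reshape(n_frames, n_mol, 2)
        _, totals = mt.motif_occupancy_classes(_series(occ), "A", "B")
        assert sum(totals[c] for c in
                   ("none", "only_a", "only_b", "simultaneous", "bridged_only")) == n_frames

    def test_same_motif_rejected(self):
        with pytest.raises(ValueError):
            mt.motif_occupancy_classes(_series(np.zeros((1, 1, 2))), "A", "A")


class TestTotalBoundRatio:
    def test_identical_series(self):
        occ = np.random.default_rng(0).random((50, 2, 2)) < 0.4
        s = _series(occ)
        assert mt.total_bound_ratio(s, s) == 1.0

    def test_constructed_three_to_two(self):
        apo = np.zeros((3000, 1, 1), dtype=bool)
        apo[:, 0, 0] = True
        holo = np.zeros((3000, 1, 1), dtype=bool)
        holo[:2000, 0, 0] = True
        assert mt.total_bound_ratio(_series(apo, ("r",)), _series(holo, ("r",))) == 1.5

    def test_event_counting_one_per_molecule_frame(self):
        # a molecule touching both regions in one frame is a single event
        occ = np.ones((10, 2, 2), dtype=bool)
        assert bound_events(_series(occ)) == 20

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            mt.total_bound_ratio(_series(np.ones((2, 1, 1)), ("r",)),
                                 _series(np.zeros((2, 1, 1)), ("r",)))


class TestAssignLeaflets:
    def test_two_cholesterols_split(self):
        names = ["O3", "C1"] * 2
        elements = ["O", "C"] * 2
        resnames = ["CHL"] * 4
        resids = [1, 1, 2, 2]
        coords = np.array([[0, 0, 10], [0, 0, 9], [0, 0, -10], [0, 0, -9]], dtype=float)
        system = make_system(coords, names=names, elements=elements,
                             resnames=resnames, resids=resids)
        leaf = mt.assign_leaflets(system)
        assert list(leaf.values()) == ["upper", "lower"]

    def test_all_above_reference(self):
        names = ["O3"] * 3
        coords = np.array([[0, 0, 5], [0, 0, 6], [0, 0, 7]], dtype=float)
        system = make_system(coords, names=names, elements=["O"] * 3,
                             resnames=["CHL"] * 3, resids=[1, 2, 3])
        # the molecule exactly at the midplane counts as upper (>= convention)
        assert sorted(mt.assign_leaflets(system).values()) == ["lower", "upper", "upper"]

    def test_no_lipids_errors(self):
        system = make_system(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="no lipid"):
            mt.assign_leaflets(system)

    def test_generator_leaflets_recovered(self):
        spec = mt.SyntheticSpec(n_frames=2, sigma=0.1)  # everything parked
        system, truth = mt.synthesize_trajectory(spec, seed=9)
        leaf = mt.assign_leaflets(system, frame=0)
        assert all(leaf[m] == lf for m, lf in truth.parked_leaflets.items())


class TestRegionContactSeries:
    def test_deterministic_schedule_recovered(self):
        spec = mt.SyntheticSpec(
            n_frames=40, n_chol=1, n_popc=0, n_pope=0, sigma=0.12,
            chol_schedule=(mt.ScheduleEntry(0, "TM V", frames=range(0, 20)),),
        )
        system, truth = mt.synthesize_trajectory(spec, seed=13)
        regions = [mt.RegionDefinition.default_htspo()[n] for n in truth.region_names]
        series = mt.region_contact_series(system, regions, cutoff=5.0)
        assert np.array_equal(series.occupancy, truth.contact_table)
        assert mt.occupancy_percent(series, "TM V") == 50.0

    def test_no_cholesterol_is_valid_empty_axis(self):
        spec = mt.SyntheticSpec(n_frames=3, n_chol=0, n_popc=0, n_pope=0, sigma=0.0)
        system, _ = mt.synthesize_trajectory(spec, seed=0)
        regions = [mt.RegionDefinition.default_htspo()["TM V"]]
        series = mt.region_contact_series(system, regions, cutoff=5.0)
        assert series.occupancy.shape == (3, 0, 1)
        assert mt.occupancy_percent(series, "TM V") == 0.0

    def test_empty_region_errors(self):
        spec = mt.SyntheticSpec(n_frames=1, n_chol=1, n_popc=0, n_pope=0, sigma=0.0)
        system, _ = mt.synthesize_trajectory(spec, seed=0)
        with pytest.raises(ValueError, match="no atoms"):
            mt.region_contact_series(system, [mt.Region("LP I", 26, 46)], cutoff=5.0)

    def test_occupancy_monotone_in_cutoff(self):
        spec = mt.SyntheticSpec(
            n_frames=30, n_chol=2, n_popc=0, n_pope=0, sigma=0.1,
            chol_schedule=(
                mt.ScheduleEntry(0, "CRAC", k_on=0.3, k_off=0.3),
                mt.ScheduleEntry(1, "CARC", k_on=0.2, k_off=0.4),
            ),
        )
        system, truth = mt.synthesize_trajectory(spec, seed=21)
        regions = [mt.RegionDefinition.default_htspo()[n] for n in truth.region_names]
        prev = None
        for cutoff in (3.0, 4.0, 5.0, 6.5, 9.0):
            series = mt.region_contact_series(system, regions, cutoff=cutoff)
            pct = np.array([mt.occupancy_percent(series, n) for n in truth.region_names])
            if prev is not None:
                assert np.all(pct >= prev - 1e-12)
            prev = pct


class TestOccupancyReport:
    def test_report_consistency(self):
        occ = np.zeros((10, 2, 2), dtype=bool)
        occ[:5, 0, 0] = True
        rep = occupancy_report(_series(occ), "sys", motif_pair=("A", "B"))
        assert rep.percent["A"] == 50.0 and rep.percent["B"] == 0.0
        assert rep.events == 5
        assert sum(rep.motif_classes.values()) == 10
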