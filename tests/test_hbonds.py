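"""Amide-hydrogen placement, H-bond series, transitions, beta scaffold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnswitch.hbonds import (
    HBondPair,
    add_amide_hydrogens,
    beta_scaffold_report,
    detect_transitions,
    hbond_distance_series,
)
from tnswitch.metrics import MetricSeries
from tnswitch.structure_io import AtomRecord, Structure, Trajectory
from tnswitch.synthetic import build_beta_hairpin, displacement_event_trajectory


def _dipeptide(second_name="ALA"):
    # idealized two-residue backbone; residue 2 is eligible for an HN
    atoms = [
        AtomRecord(1, "N", "GLY", "A", 1, "N", (0.0, 0.0, 0.0)),
        AtomRecord(2, "CA", "GLY", "A", 1, "C", (1.45, 0.0, 0.0)),
        AtomRecord(3, "C", "GLY", "A", 1, "C", (2.0, 1.4, 0.0)),
        AtomRecord(4, "O", "GLY", "A", 1, "O", (1.4, 2.45, 0.0)),
        AtomRecord(5, "N", second_name, "A", 2, "N", (3.33, 1.5, 0.0)),
        AtomRecord(6, "CA", second_name, "A", 2, "C", (4.2, 2.7, 0.0)),
        AtomRecord(7, "C", second_name, "A", 2, "C", (5.6, 2.3, 0.4)),
        AtomRecord(8, "O", second_name, "A", 2, "O", (6.0, 1.2, 0.1)),
    ]
    return Structure(atoms)


class TestAmideHydrogens:
    def test_placement_geometry(self):
        out = add_amide_hydrogens(_dipeptide())
        h = out.atoms[-1]
        assert h.atom_name == "HN" and h.residue_number == 2
        n = out.atoms[4].position
        ca = out.atoms[5].position
        c_prev = out.atoms[2].position
        assert np.linalg.norm(h.position - n) == pytest.approx(1.01, abs=1e-9)
        # coplanar with C_prev, N, CA
        normal = np.cross(c_prev - n, ca - n)
        normal /= np.linalg.norm(normal)
        assert abs(np.dot(h.position - n, normal)) < 1e-6

    def test_proline_and_n_terminus_skipped(self):
        out = add_amide_hydrogens(_dipeptide(second_name="PRO"))
        assert len(out) == 8  # no H anywhere: res1 is N-terminal, res2 is PRO

    def test_idempotent_and_heavy_atoms_untouched(self):
        once = add_amide_hydrogens(_dipeptide())
        twice = add_amide_hydrogens(once)
        assert len(twice) == len(once)
        for a, b in zip(_dipeptide().atoms, once.atoms):
            np.testing.assert_array_equal(a.position, b.position)

    def test_missing_anchor_counts_skip(self):
        atoms = [a for a in _dipeptide().atoms if a.atom_name != "C" or a.residue_number != 1]
        with pytest.warns(UserWarning, match="skipped 1"):
            out = add_amide_hydrogens(Structure(atoms))
        assert out.hydrogens_skipped == 1


class TestHBondSeries:
    def test_heavy_mode_known_distance(self):
        atoms = [
            AtomRecord(1, "N", "ALA", "A", 1, "N", (0.0, 0.0, 0.0)),
            AtomRecord(2, "O", "ALA", "A", 5, "O", (0.0, 0.0, 2.9)),
        ]
        traj = Trajectory(Structure(atoms), Structure(atoms).coords[None])
        pair = HBondPair(("A", 1, "N"), ("A", 5, "O"))
        assert hbond_distance_series(traj, pair).values[0] == pytest.approx(2.9)

    def test_scheduled_break_separates_cleanly(self, hairpin):
        o_idx = [hairpin.index_of("A", 36, "O")]
        traj = displacement_event_trajectory(
            hairpin, o_idx, (0.0, -6.0, 0.0), event_frame=50, n_frames=100
        )
        pair = HBondPair(("A", 72, "HN"), ("A", 36, "O"), "ILE72HN-ILE36O")
        d = hbond_distance_series(traj, pair, mode="hydrogen").values
        assert np.all(d[:50] < 3.5) and np.all(d[50:] > 4.5)

    def test_hydrogen_mode_within_bond_length_of_heavy_mode(self, hairpin):
        traj = Trajectory(hairpin, hairpin.coords[None])
        for donor, acceptor in ((72, 36), (36, 72), (74, 34), (38, 70)):
            heavy = hbond_distance_series(
                traj, HBondPair(("A", donor, "N"), ("A", acceptor, "O"))
            ).values[0]
            hyd = hbond_distance_series(
                traj, HBondPair(("A", donor, "HN"), ("A", acceptor, "O")), mode="hydrogen"
            ).values[0]
            assert heavy - 1.01 - 1e-9 <= hyd <= heavy + 1.01 + 1e-9


class TestDetectTransitions:
    def test_single_step_breakage(self):
        s = MetricSeries("x", [2.8] * 50 + [5.0] * 50)
        events = detect_transitions(s, threshold=3.5, min_dwell=5)
        assert len(events) == 1
        assert events[0].kind == "breakage" and events[0].frame == 50

    def test_constant_series_has_no_events(self):
        assert detect_transitions(MetricSeries("x", [2.0] * 30), 3.5, 5) == []

    def test_short_blip_filtered_by_dwell(self):
        vals = [2.8] * 50 + [5.0] + [2.8] * 49
        assert detect_transitions(MetricSeries("x", vals), 3.5, min_dwell=5) == []

    def test_blip_counts_with_dwell_one(self):
        vals = [2.8] * 50 + [5.0] + [2.8] * 49
        events = detect_transitions(MetricSeries("x", vals), 3.5, min_dwell=1)
        assert [e.kind for e in events] == ["breakage", "reformation"]

    def test_prepending_noncrossing_frames_preserves_events(self):
        tail = [2.8] * 20 + [5.0] * 20 + [2.8] * 20
        base = detect_transitions(MetricSeries("x", tail), 3.5, 5)
        padded = detect_transitions(MetricSeries("x", [2.0] * 15 + tail), 3.5, 5)
        assert [e.kind for e in padded] == [e.kind for e in base]
        assert [e.frame - 15 for e in padded] == [e.frame for e in base]

    @settings(deadline=None, max_examples=50, derandomize=True, database=None)
    @given(
        st.lists(st.floats(min_value=1.0, max_value=8.0), min_size=2, max_size=120),
        st.integers(min_value=1, max_value=6),
    )
    def test_events_alternate_and_counts_balance(self, values, dwell):
        events = detect_transitions(MetricSeries("x", values), 3.5, dwell)
        kinds = [e.kind for e in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        n_break = kinds.count("breakage")
        n_reform = kinds.count("reformation")
        assert abs(n_break - n_reform) <= 1
        assert all(e.dwell_after >= dwell for e in events)

    def test_invalid_parameters(self):
        s = MetricSeries("x", [1.0, 2.0])
        with pytest.raises(ValueError):
            detect_transitions(s, threshold=0.0)
        with pytest.raises(ValueError):
            detect_transitions(s, threshold=3.5, min_dwell=0)


class TestBetaScaffold:
    def test_fully_bonded_hairpin_all_formed(self, hairpin):
        traj = Trajectory(hairpin, hairpin.coords[None])
        rep = beta_scaffold_report(traj, "A")
        assert set(rep) == {
            "ILE72HN-ILE36O",
            "ILE36HN-ILE72O",
            "PHE74HN-GLY34O",
            "THR38HN-GLY70O",
        }
        for entry in rep.values():
            assert entry["formed_fraction"] == 1.0

    def test_splayed_strands_break_flanking_pairs_only(self):
        splayed = build_beta_hairpin(splay=5.0)
        traj = Trajectory(splayed, splayed.coords[None])
        rep = beta_scaffold_report(traj, "A")
        assert rep["ILE72HN-ILE36O"]["formed_fraction"] == 1.0
        assert rep["ILE36HN-ILE72O"]["formed_fraction"] == 1.0
        assert rep["PHE74HN-GLY34O"]["formed_fraction"] == 0.0
        assert rep["THR38HN-GLY70O"]["formed_fraction"] == 0.0

    def test_missing_scaffold_residue_is_explicit(self, hairpin):
        partial = hairpin.subset(
            [i for i, a in enumerate(hairpin.atoms) if a.residue_number != 70]
        )
        traj = Trajectory(partial, partial.coords[None])
        with pytest.raises(KeyError, match="70"):
            beta_scaffold_report(traj, "A")
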