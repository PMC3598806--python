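"""Contacts and SASA.  The brute-force two-sphere oracle was written and
evaluated before the spiral-point implementation it checks."""

import numpy as np
import pytest

from tnswitch.geometry import rotate_about_axis
from tnswitch.packing import (
    ContactDef,
    contact_persistence,
    default_contact_panel,
    min_heavy_distance_series,
    residue_exposure_series,
    sasa_shrake_rupley,
)
from tnswitch.structure_io import AtomRecord, Structure, Trajectory
from tnswitch.synthetic import displacement_event_trajectory


def _atom(serial, name, res, resnum, element, pos, chain="A"):
    return AtomRecord(serial, name, res, chain, resnum, element, pos)


def brute_force_two_sphere_area(r1, r2, sep, probe, n=100_000, seed=1234):
    """Independent Monte-Carlo-free oracle: dense deterministic lattice of
    directions per sphere; area = expanded-sphere area times the fraction
    of surface points outside the other expanded sphere."""
    # dense spherical Fibonacci lattice (independent of the implementation's
    # point count but same closed-form construction idea; n is 100x denser)
    k = np.arange(n)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * k / golden
    z = 1 - 2 * (k + 0.5) / n
    r = np.sqrt(1 - z * z)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    centers = [np.zeros(3), np.array([sep, 0.0, 0.0])]
    radii = [r1 + probe, r2 + probe]
    total = 0.0
    for i in (0, 1):
        pts = centers[i] + radii[i] * dirs
        other = 1 - i
        outside = np.linalg.norm(pts - centers[other], axis=1) >= radii[other]
        total += 4 * np.pi * radii[i] ** 2 * outside.mean()
    return total


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = Structure([_atom(1, "C", "UNK", 1, "C", (0, 0, 0))])
        area = sasa_shrake_rupley(s, probe=1.4, n_points=960)[0]
        analytic = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_distant_atoms_do_not_occlude(self):
        s = Structure(
            [
                _atom(1, "C", "UNK", 1, "C", (0, 0, 0)),
                _atom(2, "O", "UNK", 2, "O", (50, 0, 0)),
            ]
        )
        areas = sasa_shrake_rupley(s)
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)
        assert areas[1] == pytest.approx(4 * np.pi * (1.52 + 1.4) ** 2, rel=0.01)

    @pytest.mark.parametrize("sep", [2.0, 3.5, 5.0])
    def test_overlapping_spheres_match_brute_force_oracle(self, sep):
        s = Structure(
            [
                _atom(1, "C", "UNK", 1, "C", (0, 0, 0)),
                _atom(2, "N", "UNK", 2, "N", (sep, 0, 0)),
            ]
        )
        total = sasa_shrake_rupley(s, n_points=960).sum()
        oracle = brute_force_two_sphere_area(1.70, 1.55, sep, probe=1.4)
        assert total == pytest.approx(oracle, rel=0.02)

    def test_rigid_transform_invariance(self, open_lobe):
        sub = open_lobe.subset(range(40))
        a = sasa_shrake_rupley(sub, n_points=960)
        moved = sub.with_coords(
            rotate_about_axis(sub.coords, [1, 2, 3], [3, 1, -2], 47.0) + 11.0
        )
        b = sasa_shrake_rupley(moved, n_points=960)
        assert b.sum() == pytest.approx(a.sum(), rel=0.005)

    def test_adding_an_atom_never_increases_existing_area(self, open_lobe):
        sub = open_lobe.subset(range(30))
        base = sasa_shrake_rupley(sub, n_points=240)
        grown = open_lobe.subset(range(31))
        after = sasa_shrake_rupley(grown, n_points=240)[:30]
        assert np.all(after <= base + 1e-9)

    def test_unknown_element_is_an_error(self):
        s = Structure([_atom(1, "XX", "UNK", 1, "Xx", (0, 0, 0))])
        with pytest.raises(KeyError, match="Xx"):
            sasa_shrake_rupley(s)


class TestContacts:
    def test_single_atom_residues_known_distance(self):
        s = Structure(
            [
                _atom(1, "CB", "ALA", 1, "C", (0, 0, 0)),
                _atom(2, "CB", "ALA", 5, "C", (4.0, 0, 0)),
            ]
        )
        traj = Trajectory(s, s.coords[None])
        pair = ContactDef(("A", 1), ("A", 5))
        assert min_heavy_distance_series(traj, pair).values[0] == pytest.approx(4.0)

    def test_symmetric_in_the_pair(self, open_lobe):
        traj = Trajectory(open_lobe, open_lobe.coords[None])
        ab = min_heavy_distance_series(traj, ContactDef(("A", 25), ("A", 77)))
        ba = min_heavy_distance_series(traj, ContactDef(("A", 77), ("A", 25)))
        assert ab.values[0] == pytest.approx(ba.values[0])

    def test_side_chain_scope_excludes_backbone(self):
        # backbone atoms nearest; side-chain scope must report a larger distance
        s = Structure(
            [
                _atom(1, "CA", "ALA", 1, "C", (0, 0, 0)),
                _atom(2, "CB", "ALA", 1, "C", (0, 0, 2.0)),
                _atom(3, "CA", "ALA", 5, "C", (3.0, 0, 0)),
                _atom(4, "CB", "ALA", 5, "C", (3.0, 0, 4.0)),
            ]
        )
        traj = Trajectory(s, s.coords[None])
        heavy = min_heavy_distance_series(traj, ContactDef(("A", 1), ("A", 5), "heavy"))
        side = min_heavy_distance_series(
            traj, ContactDef(("A", 1), ("A", 5), "side-chain-heavy")
        )
        assert side.values[0] > heavy.values[0]

    def test_glycine_side_chain_scope_is_error(self, open_lobe):
        traj = Trajectory(open_lobe, open_lobe.coords[None])
        pair = ContactDef(("A", 34), ("A", 74), "side-chain-heavy")  # 34 is GLY
        with pytest.raises(ValueError, match="no atoms in scope"):
            min_heavy_distance_series(traj, pair)

    def test_insertion_event_drops_distance_at_event_frame(self, open_lobe):
        # VAL44 analogue moved 3 A toward PHE77 at frame 30
        i44 = [
            i for i, a in enumerate(open_lobe.atoms)
            if a.residue_number == 44 and a.atom_name in ("CB", "CG")
        ]
        p44 = open_lobe.atoms[open_lobe.index_of("A", 44, "CB")].position
        p77 = open_lobe.atoms[open_lobe.index_of("A", 77, "CB")].position
        step = 3.0 * (p77 - p44) / np.linalg.norm(p77 - p44)
        traj = displacement_event_trajectory(open_lobe, i44, step, 30, 60)
        d = min_heavy_distance_series(
            traj, ContactDef(("A", 44), ("A", 77), "side-chain-heavy")
        ).values
        assert d[29] - d[30] == pytest.approx(np.ptp(d), abs=1e-9)
        assert np.all(d[:30] > d[30:].max())

    def test_persistence_fractions(self):
        s = Structure(
            [
                _atom(1, "CB", "ALA", 1, "C", (0, 0, 0)),
                _atom(2, "CB", "ALA", 5, "C", (4.0, 0, 0)),
            ]
        )
        frames = s.coords[None].repeat(10, axis=0)
        frames[5:, 1, 0] = 9.0  # move apart for half the frames
        traj = Trajectory(s, frames)
        close = ContactDef(("A", 1), ("A", 5), cutoff=4.5, label="half")
        assert contact_persistence(traj, [close])["half"] == 0.5
        always = Trajectory(s, s.coords[None].repeat(4, axis=0))
        assert contact_persistence(always, [close])["half"] == 1.0
        apart = Trajectory(s, frames[5:])
        assert contact_persistence(apart, [close])["half"] == 0.0

    def test_default_panel_resolves_on_toy_lobe(self, open_lobe):
        traj = Trajectory(open_lobe, open_lobe.coords[None])
        panel = default_contact_panel("A")
        fractions = contact_persistence(traj, panel)
        assert len(fractions) == len(panel)
        assert all(0.0 <= v <= 1.0 for v in fractions.values())


class TestExposure:
    def test_residue_alone_is_fully_exposed(self):
        s = Structure(
            [
                _atom(1, "CA", "ALA", 1, "C", (0, 0, 0)),
                _atom(2, "CB", "ALA", 1, "C", (1.5, 0, 0)),
            ]
        )
        traj = Trajectory(s, s.coords[None])
        vals = residue_exposure_series(traj, ("A", 1)).values
        assert vals[0] == pytest.approx(1.0, abs=1e-12)

    def test_enclosing_shell_buries_side_chain(self):
        atoms = [
            _atom(1, "CA", "ALA", 1, "C", (0, 0, 0)),
            _atom(2, "CB", "ALA", 1, "C", (1.5, 0, 0)),
        ]
        # cage of carbons on a sphere around the residue
        k = np.arange(60)
        phi = np.pi * (3 - 5**0.5) * k
        z = 1 - 2 * (k + 0.5) / 60
        r = np.sqrt(1 - z * z)
        for j, (x, y, zz) in enumerate(zip(r * np.cos(phi), r * np.sin(phi), z)):
            atoms.append(
                _atom(10 + j, "C", "CAG", 100 + j, "C",
                      (0.75 + 4.4 * x, 4.4 * y, 4.4 * zz))
            )
        s = Structure(atoms)
        traj = Trajectory(s, s.coords[None])
        vals = residue_exposure_series(traj, ("A", 1), n_points=960).values
        assert vals[0] < 0.05

    def test_expulsion_event_raises_exposure(self, open_lobe):
        idx = [
            i for i, a in enumerate(open_lobe.atoms)
            if a.residue_number == 28 and a.atom_name in ("CB", "CG")
        ]
        cb = open_lobe.atoms[open_lobe.index_of("A", 28, "CB")].position
        centre = open_lobe.coords.mean(axis=0)
        out = 18.0 * (cb - centre) / np.linalg.norm(cb - centre)
        traj = displacement_event_trajectory(open_lobe, idx, out, 2, 4)
        vals = residue_exposure_series(traj, ("A", 28), n_points=240).values
        assert vals[2:].min() > vals[:2].max()

    def test_glycine_rejected(self, open_lobe):
        traj = Trajectory(open_lobe, open_lobe.coords[None])
        with pytest.raises(ValueError, match="glycine"):
            residue_exposure_series(traj, ("A", 34))
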