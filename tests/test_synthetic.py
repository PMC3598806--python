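"""Generator contracts: prescribed geometry, determinism, stationary laws."""

import numpy as np
import pytest

from tnswitch.metrics import pocket_openness_series
from tnswitch.structure_io import read_trajectory, write_trajectory
from tnswitch.synthetic import (
    ConstructionError,
    SyntheticParams,
    ToyLobeSpec,
    build_toy_two_state_lobe,
    displacement_event_trajectory,
    morph_trajectory,
    noisy_static_trajectory,
    ou_two_probe_trajectory,
    rigid_rotation_trajectory,
)


class TestToyLobe:
    def test_conformer_pocket_targets(self, open_lobe, closed_lobe, semi_closed_lobe):
        def d(s):
            a = s.atoms[s.index_of("A", 16, "CA")].position
            b = s.atoms[s.index_of("A", 48, "CA")].position
            return float(np.linalg.norm(a - b))

        assert d(open_lobe) == pytest.approx(23.9, abs=0.2)
        assert d(closed_lobe) == pytest.approx(13.4, abs=0.2)
        assert d(semi_closed_lobe) == pytest.approx(15.7, abs=0.2)

    def test_conformers_share_identical_topology(self, open_lobe, closed_lobe):
        assert [a.key for a in open_lobe.atoms] == [a.key for a in closed_lobe.atoms]

    def test_loops_and_anchors_present(self, open_lobe):
        for r in list(range(29, 41)) + list(range(65, 77)) + [15, 16, 48, 54, 73, 104, 131]:
            assert open_lobe.has_atom("A", r, "CA")

    def test_deterministic(self):
        a = build_toy_two_state_lobe(ToyLobeSpec("open"))
        b = build_toy_two_state_lobe(ToyLobeSpec("open"))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_unreachable_target_raises_construction_error(self):
        with pytest.raises(ConstructionError):
            build_toy_two_state_lobe(ToyLobeSpec("open", target_pocket_distance=2.0))

    def test_unknown_conformer_rejected(self):
        with pytest.raises(ValueError):
            ToyLobeSpec("ajar")


class TestMorph:
    def test_noise_free_endpoints_equal_inputs(self, open_lobe, closed_lobe):
        traj = morph_trajectory(open_lobe, closed_lobe, 7, noise_sd=0.0)
        np.testing.assert_array_equal(traj.frames[0], open_lobe.coords)
        np.testing.assert_array_equal(traj.frames[-1], closed_lobe.coords)

    def test_pocket_series_linear_without_noise(self, open_lobe, closed_lobe):
        traj = morph_trajectory(open_lobe, closed_lobe, 21, noise_sd=0.0)
        a16 = traj.topology.index_of("A", 16, "CA")
        a48 = traj.topology.index_of("A", 48, "CA")
        # the anchor separation vector interpolates linearly, so each
        # coordinate of the difference is linear in the frame index
        diff = traj.frames[:, a16] - traj.frames[:, a48]
        fitted = np.polyfit(np.arange(21), diff, 1)
        resid = diff - np.polyval(fitted, np.arange(21)[:, None])
        assert np.abs(resid).max() < 1e-9

    def test_same_seed_reproduces(self, open_lobe, closed_lobe):
        t1 = morph_trajectory(open_lobe, closed_lobe, 12, 0.4, seed=99)
        t2 = morph_trajectory(open_lobe, closed_lobe, 12, 0.4, seed=99)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_topology_mismatch_rejected(self, open_lobe):
        truncated = open_lobe.subset(range(len(open_lobe) - 1))
        with pytest.raises(ValueError, match="topology"):
            morph_trajectory(open_lobe, truncated, 5)


class TestNoisyStatic:
    def test_zero_sd_is_static(self, open_lobe):
        traj = noisy_static_trajectory(open_lobe, 0.0, 5, seed=1)
        for f in range(5):
            np.testing.assert_array_equal(traj.frames[f], open_lobe.coords)

    def test_negative_sd_rejected(self, open_lobe):
        sd = np.full(len(open_lobe), -0.1)
        with pytest.raises(ValueError):
            noisy_static_trajectory(open_lobe, sd, 5, seed=1)

    def test_sd_length_checked(self, open_lobe):
        with pytest.raises(ValueError):
            noisy_static_trajectory(open_lobe, np.ones(3), 5, seed=1)


class TestRigidRotation:
    def test_zero_schedule_is_static(self, open_lobe):
        sel = [i for i, a in enumerate(open_lobe.atoms) if a.residue_number <= 72]
        traj = rigid_rotation_trajectory(
            open_lobe, sel, (("A", 104, "CA"), ("A", 73, "CA")), [0.0, 0.0, 0.0]
        )
        for f in range(3):
            np.testing.assert_allclose(traj.frames[f], open_lobe.coords, atol=1e-12)

    def test_unselected_atoms_never_move(self, open_lobe):
        sel = [i for i, a in enumerate(open_lobe.atoms) if a.residue_number <= 72]
        fixed = sorted(set(range(len(open_lobe))) - set(sel))
        traj = rigid_rotation_trajectory(
            open_lobe, sel, (("A", 104, "CA"), ("A", 73, "CA")), [0.0, 25.0]
        )
        np.testing.assert_array_equal(
            traj.frames[1][fixed], open_lobe.coords[fixed]
        )

    def test_off_axis_anchor_inside_selection_warns(self, open_lobe):
        sel = list(range(len(open_lobe)))  # includes both anchors
        with pytest.warns(UserWarning, match="inside the rotating selection"):
            rigid_rotation_trajectory(
                open_lobe, sel, (("A", 104, "CA"), ("A", 73, "CA")), [0.0, 10.0]
            )


class TestDisplacementEvent:
    def test_step_applied_from_event_frame(self, open_lobe):
        traj = displacement_event_trajectory(open_lobe, [0], (1.0, 0, 0), 3, 6)
        assert traj.frames[2, 0, 0] == open_lobe.coords[0, 0]
        assert traj.frames[3, 0, 0] == open_lobe.coords[0, 0] + 1.0

    def test_event_frame_bounds(self, open_lobe):
        with pytest.raises(ValueError):
            displacement_event_trajectory(open_lobe, [0], (1, 0, 0), 0, 5)
        with pytest.raises(ValueError):
            displacement_event_trajectory(open_lobe, [0], (1, 0, 0), 5, 5)


class TestOuProbe:
    def test_zero_sigma_stays_at_mean(self):
        params = SyntheticParams(seed=1, n_frames=200,
                                 ou={"theta": 1.0, "mu": 4.0, "sigma": 0.0, "dt": 0.01})
        traj, mu, sd = ou_two_probe_trajectory(params)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        np.testing.assert_allclose(d, mu, atol=1e-12)
        assert sd == 0.0

    def test_stationary_sd_matches_analytic_law(self):
        params = SyntheticParams(seed=7, n_frames=200_000,
                                 ou={"theta": 1.0, "mu": 4.0, "sigma": 1.4, "dt": 0.01})
        traj, _, sd = ou_two_probe_trajectory(params)
        d = traj.frames[:, 1, 2]
        burn = 5000
        assert np.std(d[burn:]) == pytest.approx(sd, rel=0.05)
        assert sd == pytest.approx(1.4 / np.sqrt(2.0), rel=1e-12)

    def test_same_seed_identical(self):
        p = SyntheticParams(seed=5, n_frames=500)
        a, *_ = ou_two_probe_trajectory(p)
        b, *_ = ou_two_probe_trajectory(p)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_unstable_discretization_rejected(self):
        params = SyntheticParams(seed=1, n_frames=10,
                                 ou={"theta": 300.0, "mu": 4.0, "sigma": 1.0, "dt": 0.01})
        with pytest.raises(ValueError, match="unstable"):
            ou_two_probe_trajectory(params)


def test_generated_trajectory_roundtrips_through_pdb(tmp_path, open_lobe, closed_lobe):
    traj = morph_trajectory(open_lobe, closed_lobe, 4, 0.1, seed=21)
    path = tmp_path / "morph.pdb"
    write_trajectory(traj, str(path))
    back = read_trajectory(str(path))
    d0 = pocket_openness_series(traj).values
    d1 = pocket_openness_series(back).values
    np.testing.assert_allclose(d1, d0, atol=2e-3)
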