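"""Secondary structure, contacts, hydrogen bonds, density and hydration."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from memdyn.io_model import Topology, Trajectory, select
from memdyn.structure_env import (
    assign_secondary_structure,
    contact_map,
    density_profile,
    detect_bilayer_topology,
    hbonds,
    helix_counts,
    hydration_count,
)
from memdyn.synthetic import (
    MembraneBoxSpec,
    make_bundle_reference,
    make_chain,
    make_membrane_box,
)

from conftest import make_trajectory


def _static_traj(top, coords, n_frames=2):
    return make_trajectory(coords, np.zeros((n_frames, top.n_atoms, 3)), topology=top)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_alpha(self):
        top, coords = make_chain(20)
        ss = assign_secondary_structure(_static_traj(top, coords))
        # ends cannot complete i->i+4 turn pairs; the interior must be H
        assert np.all(ss.classes[:, 4:16] == "H")
        assert np.array_equal(ss.classes[0], ss.classes[1])

    def test_helix_count_matches_turn_pattern_rule(self):
        """Helix residues equal the hand-applied consecutive i→i+4 rule."""
        top, coords = make_chain(20)
        ss = assign_secondary_structure(_static_traj(top, coords, n_frames=1))
        # independent application of the dictionary rule on ideal geometry:
        # turns exist at every i with i+4 <= 19 => i in 0..15; consecutive
        # pairs (i-1, i) for i in 1..15 mark residues i..i+3 => 1..18
        expected = np.zeros(20, dtype=bool)
        for i in range(1, 16):
            expected[i: i + 4] = True
        assert np.array_equal(ss.classes[0] == "H", expected)

    def test_extended_chain_has_no_helix(self):
        top, coords = make_chain(20, phi=180.0, psi=180.0)
        ss = assign_secondary_structure(_static_traj(top, coords))
        assert not np.any(ss.classes == "H")

    def test_agrees_with_reference_dssp_on_ideal_helix(self, tmp_path):
        """Cross-check the α-helix calls against mdtraj's DSSP on the same PDB."""
        mdtraj = pytest.importorskip("mdtraj")
        from memdyn.io_model import write_topology

        top, coords = make_chain(20)
        p = tmp_path / "helix.pdb"
        write_topology(p, top, coords)
        t = mdtraj.load(str(p))
        ref = mdtraj.compute_dssp(t, simplified=True)[0]
        ss = assign_secondary_structure(_static_traj(top, coords, n_frames=1))
        ours = ss.classes[0] == "H"
        theirs = ref == "H"
        # identical calls except possibly one terminal residue convention
        assert np.sum(ours != theirs) <= 2

    def test_invariant_under_rigid_motion(self):
        top, coords = make_chain(15)
        rot = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([4.0, -8.0, 2.5])
        a = assign_secondary_structure(_static_traj(top, coords, n_frames=1))
        b = assign_secondary_structure(_static_traj(top, moved, n_frames=1))
        assert np.array_equal(a.classes, b.classes)

    def test_replica_sd_zero_for_identical_replicas(self, small_bundle):
        top, coords = small_bundle
        traj = _static_traj(top, coords)
        counts = helix_counts(
            [assign_secondary_structure(t) for t in (traj, traj)]
        )
        assert np.allclose(counts["sd"], 0.0)
        assert (counts["mean"] > 0).any()

    def test_missing_backbone_atoms_listed(self):
        top, coords = make_chain(4)
        keep = np.ones(top.n_atoms, dtype=bool)
        keep[2 * 4 + 3] = False  # drop O of residue 3
        sub = Topology(
            names=top.names[keep], elements=top.elements[keep],
            resids=top.resids[keep], resnames=top.resnames[keep],
            chains=top.chains[keep], segments=top.segments[keep],
        )
        traj = _static_traj(sub, coords[keep], n_frames=1)
        with pytest.raises(ValueError, match="missing backbone.*3"):
            assign_secondary_structure(traj)


def _pair_topology(d_perp):
    """Two 'residues' of generic side-chain-like atoms separated along x."""
    names = ["CB", "OD1", "CB", "OG"]
    top = Topology(
        names=names,
        elements=["C", "O", "C", "O"],
        resids=[1, 1, 2, 2],
        resnames=["ASP", "ASP", "SER", "SER"],
        chains=["A"] * 4,
        segments=["TM2", "TM2", "TM7", "TM7"],
    )
    coords = np.array(
        [[0.0, 0.0, 0.0], [1.4, 0.0, 0.0],
         [1.4 + d_perp, 0.0, 0.0], [2.8 + d_perp, 0.0, 0.0]]
    )
    return top, coords


class TestContactMap:
    def test_permanent_contact_occupancy_one(self):
        top, coords = _pair_topology(3.0)
        traj = _static_traj(top, coords, n_frames=5)
        cm = contact_map(traj, np.array([0, 1]), np.array([2, 3]), cutoff=4.5)
        assert cm.partner_resids.tolist() == [2]
        assert cm.occupancy[0] == 1.0

    def test_distant_pair_occupancy_zero(self):
        top, coords = _pair_topology(10.0)
        traj = _static_traj(top, coords, n_frames=5)
        cm = contact_map(traj, np.array([0, 1]), np.array([2, 3]), cutoff=4.5)
        assert cm.occupancy[0] == 0.0

    def test_intermittent_contact_matches_brute_force(self):
        top, base = _pair_topology(3.0)
        disp = np.zeros((20, 4, 3))
        disp[7:, 2:, 0] = 10.0  # contact in first 7 of 20 frames only
        traj = make_trajectory(base, disp, topology=top)
        focal, cand = np.array([0, 1]), np.array([2, 3])
        cm = contact_map(traj, focal, cand, cutoff=4.5)
        assert cm.occupancy[0] == pytest.approx(0.35)
        # brute-force all-pairs loop
        hits = 0
        for f in range(20):
            dmin = min(
                np.linalg.norm(traj.coordinates[f, i] - traj.coordinates[f, j])
                for i in focal for j in cand
            )
            hits += dmin <= 4.5
        assert cm.occupancy[0] == pytest.approx(hits / 20.0)

    def test_occupancy_monotone_in_cutoff(self):
        top, base = _pair_topology(4.0)
        rng = np.random.default_rng(0)
        disp = rng.normal(scale=1.0, size=(30, 4, 3))
        traj = make_trajectory(base, disp, topology=top)
        occ = [
            contact_map(traj, np.array([0, 1]), np.array([2, 3]), cutoff=c).occupancy[0]
            for c in (2.0, 4.0, 6.0, 8.0)
        ]
        assert all(a <= b for a, b in zip(occ, occ[1:]))

    def test_nonpositive_cutoff_rejected(self):
        top, coords = _pair_topology(3.0)
        traj = _static_traj(top, coords)
        with pytest.raises(ValueError, match="cutoff"):
            contact_map(traj, np.array([0, 1]), np.array([2, 3]), cutoff=0.0)


def _hbond_system(angle_deg, two_acceptors=False):
    """Donor O-H pointing at acceptor(s) with controllable D-H-A angle."""
    d = 2.8
    h_pos = np.array([0.96, 0.0, 0.0])
    theta = np.deg2rad(180.0 - angle_deg)
    acc = h_pos + (d - 0.96) * np.array([np.cos(theta), np.sin(theta), 0.0])
    names = ["OG", "HG", "OD1"] + (["OD2"] if two_acceptors else [])
    elements = ["O", "H", "O"] + (["O"] if two_acceptors else [])
    resids = [1, 1, 2] + ([2] if two_acceptors else [])
    coords = [np.zeros(3), h_pos, acc]
    if two_acceptors:
        coords.append(acc + np.array([0.0, 2.2, 0.0]))
    top = Topology(
        names=names, elements=elements, resids=resids,
        resnames=["SER"] * 2 + ["ASP"] * (len(names) - 2),
        chains=["A"] * len(names), segments=["TM2"] * 2 + ["TM7"] * (len(names) - 2),
    )
    return top, np.array(coords)


class TestHbonds:
    def test_near_linear_geometry_detected(self):
        top, coords = _hbond_system(170.0)
        traj = _static_traj(top, coords)
        out = hbonds(traj, np.array([0]), np.array([2]))
        assert len(out) == 1 and out[0].occupancy == 1.0

    def test_bent_geometry_rejected(self):
        top, coords = _hbond_system(90.0)
        traj = _static_traj(top, coords)
        assert hbonds(traj, np.array([0]), np.array([2])) == []

    def test_carboxylate_oxygens_tracked_separately(self):
        top, base = _hbond_system(170.0, two_acceptors=True)
        # alternate frames: OD1 close (bonded), then swap OD1/OD2 positions
        coords = np.stack([base, base.copy(), base, base.copy()])
        coords[1, [2, 3]] = coords[1, [3, 2]]
        coords[3, [2, 3]] = coords[3, [3, 2]]
        traj = Trajectory(coordinates=coords, times=np.arange(4.0), topology=top)
        out = hbonds(traj, np.array([0]), np.array([2, 3]))
        by_acceptor = {b.acceptor: b.occupancy for b in out}
        assert by_acceptor == {2: 0.5, 3: 0.5}

    def test_empty_selections_warn(self):
        top, coords = _hbond_system(170.0)
        traj = _static_traj(top, coords)
        with pytest.warns(UserWarning, match="donors"):
            assert hbonds(traj, np.array([], dtype=int), np.array([2])) == []


class TestDensityAndHydration:
    def _profile(self, spec=None):
        spec = spec or MembraneBoxSpec(seed=0)
        top, traj = make_membrane_box(spec)
        return density_profile(
            traj, {"water": "water", "phosphate": "name P", "methyl": "name CM"}
        )

    def test_group_integrals_equal_atom_counts(self):
        prof = self._profile()
        for group, count in prof.counts.items():
            integral = prof.densities[group].sum() * prof.bin_volume
            assert integral == pytest.approx(count, rel=1e-6)

    def test_planted_core_waters_integrate_to_50(self):
        spec = MembraneBoxSpec(
            n_water=50, n_phosphate=64, n_methyl=64,
            water_slabs=[(-10.0, 10.0)], seed=1,
        )
        prof = self._profile(spec)
        assert hydration_count(prof, (-10.0, 10.0)) == pytest.approx(50.0, rel=1e-6)
        # half interval of a symmetric plant
        assert hydration_count(prof, (0.0, 10.0)) == pytest.approx(25.0, abs=4.0)

    def test_water_density_zero_in_core_when_excluded(self):
        prof = self._profile()
        core = np.abs(prof.bin_centers) < 10.0
        assert np.all(prof.densities["water"][core] == 0.0)

    def test_uniform_box_is_flat_within_poisson_noise(self):
        spec = MembraneBoxSpec(
            box=(40.0, 40.0, 40.0), n_water=20000, n_phosphate=0, n_methyl=0,
            water_slabs=[(-20.0, 20.0)], n_frames=1, seed=2,
        )
        top, traj = make_membrane_box(spec)
        prof = density_profile(traj, {"water": "water"})
        counts = prof.densities["water"] * prof.bin_volume
        mean = counts.mean()
        assert np.all(np.abs(counts - mean) < 5.0 * np.sqrt(mean))

    def test_all_atoms_single_bin(self):
        spec = MembraneBoxSpec(
            n_water=100, n_phosphate=0, n_methyl=0,
            water_slabs=[(3.0, 3.5)], n_frames=1, seed=3,
        )
        top, traj = make_membrane_box(spec)
        prof = density_profile(traj, {"water": "water"})
        assert np.count_nonzero(prof.densities["water"]) == 1

    def test_missing_box_rejected(self):
        top, traj = make_membrane_box(MembraneBoxSpec(seed=4))
        boxless = Trajectory(
            coordinates=traj.coordinates, times=traj.times, topology=top
        )
        with pytest.raises(ValueError, match="box"):
            density_profile(boxless, {"water": "water"})

    def test_empty_interval_rejected(self):
        prof = self._profile()
        with pytest.raises(ValueError, match="empty"):
            hydration_count(prof, (0.0, 0.0))

    def test_full_range_integral_is_total_water(self):
        prof = self._profile()
        total = hydration_count(prof, (-40.0, 40.0))
        assert total == pytest.approx(prof.counts["water"], rel=1e-6)


class TestBilayerTopology:
    def test_planted_geometry_recovered_within_bin(self):
        top, traj = make_membrane_box(MembraneBoxSpec(seed=5))
        prof = density_profile(
            traj, {"water": "water", "phosphate": "name P", "methyl": "name CM"}
        )
        topo = detect_bilayer_topology(prof)
        assert abs(topo["core"][0] + 10.0) <= 1.0
        assert abs(topo["core"][1] - 10.0) <= 1.0
        assert abs(topo["interface_upper"][0] - 15.0) <= 1.0
        assert abs(topo["interface_upper"][1] - 25.0) <= 1.0
        assert abs(topo["interface_lower"][0] + 25.0) <= 1.0
        assert abs(topo["interface_lower"][1] + 15.0) <= 1.0

    def test_single_leaflet_rejected(self):
        spec = MembraneBoxSpec(phosphate_slabs=[(15.0, 25.0)], seed=6)
        top, traj = make_membrane_box(spec)
        prof = density_profile(
            traj, {"water": "water", "phosphate": "name P", "methyl": "name CM"}
        )
        with pytest.raises(ValueError, match="leaflet|unimodal"):
            detect_bilayer_topology(prof)

    def test_intervals_invariant_to_doubling_counts(self):
        a = MembraneBoxSpec(seed=7)
        b = MembraneBoxSpec(
            n_water=2 * a.n_water, n_phosphate=2 * a.n_phosphate,
            n_methyl=2 * a.n_methyl, seed=7,
        )
        topos = []
        for spec in (a, b):
            top, traj = make_membrane_box(spec)
            prof = density_profile(
                traj, {"water": "water", "phosphate": "name P", "methyl": "name CM"}
            )
            topos.append(detect_bilayer_topology(prof))
        for key in topos[0]:
            assert abs(topos[0][key][0] - topos[1][key][0]) <= 1.0
            assert abs(topos[0][key][1] - topos[1][key][1]) <= 1.0
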