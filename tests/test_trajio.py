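"""Trajectory data model, fixture I/O, alignment, and frame selection."""

import numpy as np
import pytest

from memscramble.errors import (
    AlignmentError,
    EmptyTrajectoryError,
    FormatError,
    SelectionError,
    TopologyError,
)
from memscramble.synthgen import BilayerSpec, add_protein_scaffold, make_bilayer
from memscramble.trajio import (
    LipidRecord,
    RoleMap,
    Topology,
    Trajectory,
    align_membrane_frame,
    align_subunit,
    discard_equilibration,
    parse_role_map,
    read_fixture,
    read_trajectory,
    write_fixture,
)


class TestInvariants:
    def test_bead_count_mismatch_rejected(self, small_bilayer):
        bad = small_bilayer.copy()
        bad.coords = np.concatenate(
            [bad.coords, np.zeros((bad.n_frames, 1, 3))], axis=1
        )
        with pytest.raises(FormatError, match="bead count"):
            bad.validate()

    def test_nonuniform_times_rejected(self, small_bilayer):
        bad = small_bilayer.copy()
        bad.times = bad.times.copy()
        bad.times[-1] += 0.5
        with pytest.raises(FormatError, match="uniform"):
            bad.validate()

    def test_nonfinite_coordinates_rejected(self, small_bilayer):
        bad = small_bilayer.copy()
        bad.coords[0, 0, 0] = np.nan
        with pytest.raises(FormatError, match="finite"):
            bad.validate()

    def test_duplicate_role_beads_rejected(self):
        beads = {r: 0 for r in ("NC3", "PO4", "GL1", "GL2", "C4A", "C4B")}
        with pytest.raises(TopologyError, match="distinct"):
            LipidRecord(0, beads).validate()

    def test_missing_role_rejected(self):
        with pytest.raises(TopologyError, match="missing"):
            LipidRecord(0, {"NC3": 0}).validate()


class TestFixtureRoundTrip:
    def test_exact_round_trip(self, tmp_path, scaffold_bilayer):
        path = tmp_path / "traj.mstrj"
        write_fixture(scaffold_bilayer, path)
        back = read_fixture(path)
        assert np.array_equal(back.coords, scaffold_bilayer.coords)
        assert np.array_equal(back.times, scaffold_bilayer.times)
        assert np.array_equal(back.box, scaffold_bilayer.box)
        assert back.topology.to_dict() == scaffold_bilayer.topology.to_dict()

    def test_round_trip_with_noise(self, tmp_path):
        spec = BilayerSpec(lipids_per_leaflet=4, box_xy=30.0,
                           noise_sigma=0.7, seed=9)
        traj = make_bilayer(spec, 7)
        path = tmp_path / "n.mstrj"
        write_fixture(traj, path)
        assert np.array_equal(read_fixture(path).coords, traj.coords)

    def test_read_trajectory_dispatches_fixture(self, tmp_path, small_bilayer):
        path = tmp_path / "traj.mstrj"
        write_fixture(small_bilayer, path)
        back = read_trajectory(path)
        assert back.n_frames == small_bilayer.n_frames

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "x.mstrj"
        p.write_text("nonsense\n")
        with pytest.raises(FormatError):
            read_fixture(p)


class TestStandardFormats:
    def _write_pdb(self, path, n_models=3):
        # two DOPC lipids (6 beads each) plus one 2-bead residue
        lines = []
        beads = ["NC3", "PO4", "GL1", "GL2", "C4A", "C4B"]
        for m in range(n_models):
            lines.append(f"MODEL     {m + 1}")
            serial = 1
            for res, resn in ((1, "DOPC"), (2, "DOPC")):
                for j, name in enumerate(beads):
                    x, y, z = 10.0 * res + m, 5.0, 20.0 - 3 * j
                    lines.append(
                        f"ATOM  {serial:5d} {name:<4s} {resn:<4s}A{res:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    )
                    serial += 1
            for j, name in enumerate(["BB", "SC1"]):
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {'ALA':<4s}A{330:4d}    "
                    f"{30.0 + j:8.3f}{5.0:8.3f}{0.0:8.3f}  1.00  0.00"
                )
                serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")

    def test_read_pdb_multimodel(self, tmp_path):
        p = tmp_path / "sys.pdb"
        self._write_pdb(p)
        traj = read_trajectory(p, role_map="tm TM4 327-339")
        assert traj.n_frames == 3
        assert len(traj.topology.lipids) == 2
        assert traj.topology.residues[0].tm == "TM4"
        assert traj.topology.residues[0].sidechain  # SC1 present
        nc3 = traj.topology.lipids[0].beads["NC3"]
        assert traj.coords[1, nc3, 0] == pytest.approx(11.0, abs=1e-3)

    def test_missing_role_raises_topology_error(self, tmp_path):
        p = tmp_path / "bad.pdb"
        lines = ["MODEL     1"]
        for j, name in enumerate(["NC3", "PO4", "GL1"]):  # tails missing
            lines.append(
                f"ATOM  {j + 1:5d} {name:<4s} {'DOPC':<4s}A{1:4d}    "
                f"{1.0:8.3f}{1.0:8.3f}{float(j):8.3f}  1.00  0.00"
            )
        lines += ["ENDMDL", "END"]
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(TopologyError):
            read_trajectory(p)

    def test_parse_role_map(self, tmp_path):
        p = tmp_path / "roles.txt"
        p.write_text(
            "lipid POPC\nrole NC3 NC0  # alias\nion K Na\ntm TM6 430-452\n"
        )
        rm = parse_role_map(p)
        assert "POPC" in rm.lipid_resnames
        assert rm.role_names["NC0"] == "NC3"
        assert rm.ion_names["K"] == "Na"
        assert rm.tm_ranges["TM6"] == (430, 452)


class TestAlignSubunit:
    def test_translation_recovery(self, scaffold_bilayer):
        drift = np.arange(scaffold_bilayer.n_frames)[:, None] * np.array(
            [3.0, 4.0, 5.0]
        )
        moved = scaffold_bilayer.copy()
        moved.coords += drift[:, None, :]
        aligned = align_subunit(moved, "A", 0)
        assert np.allclose(aligned.coords, scaffold_bilayer.coords, atol=1e-9)

    def test_identity_on_aligned(self, scaffold_bilayer):
        aligned = align_subunit(scaffold_bilayer, "A", 0)
        assert np.allclose(aligned.coords, scaffold_bilayer.coords, atol=1e-12)

    def test_random_walk_drift_removed(self, scaffold_bilayer):
        rng = np.random.default_rng(4)
        walk = np.cumsum(rng.normal(0, 2.0, (scaffold_bilayer.n_frames, 3)),
                         axis=0)
        moved = scaffold_bilayer.copy()
        moved.coords += walk[:, None, :]
        aligned = align_subunit(moved, "A", 0)
        recs = aligned.topology.select_residues(chain="A")
        bb = np.array([r.backbone for r in recs])
        cents = aligned.coords[:, bb, :].mean(axis=1)
        assert np.max(np.linalg.norm(cents - cents[0], axis=1)) < 1e-9

    def test_empty_chain_raises(self, scaffold_bilayer):
        with pytest.raises(SelectionError):
            align_subunit(scaffold_bilayer, "Z")


class TestAlignMembraneFrame:
    def _line_residues_traj(self, angle_deg):
        """One 20-residue backbone line at the given angle from +y."""
        spec = BilayerSpec(lipids_per_leaflet=4, box_xy=30.0,
                           noise_sigma=0.0, lateral_sigma=0.0, seed=0)
        traj = make_bilayer(spec, 3)
        from memscramble.trajio import ResidueRecord, Topology

        n0 = traj.n_beads
        a = np.radians(angle_deg)
        direction = np.array([np.sin(a), np.cos(a), 0.0])
        t = np.linspace(-8, 8, 20)
        pts = 15.0 + t[:, None] * direction
        extra = np.broadcast_to(pts, (3, 20, 3)).copy()
        coords = np.concatenate([traj.coords, extra], axis=1)
        top = traj.topology
        residues = [
            ResidueRecord(700 + i, "A", n0 + i, [], "TM7") for i in range(20)
        ]
        new_top = Topology(
            n_beads=n0 + 20,
            bead_names=top.bead_names + ["BB"] * 20,
            lipids=top.lipids, residues=residues,
        )
        return Trajectory(coords, traj.times, traj.box, new_top)

    @pytest.mark.parametrize("angle", [90.0, 0.0, 30.0])
    def test_principal_axis_lands_on_y(self, angle):
        traj = self._line_residues_traj(angle)
        out = align_membrane_frame(traj, tm_labels=("TM7",))
        bb = np.array([r.backbone for r in out.topology.residues])
        xy = out.coords[0][bb, :2]
        xy = xy - xy.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(xy.T))
        v = vecs[:, 1]
        residual = min(abs(np.arctan2(v[0], v[1])),
                       abs(np.arctan2(-v[0], -v[1])))
        assert residual < 1e-6

    def test_identity_when_already_along_y(self):
        traj = self._line_residues_traj(0.0)
        out = align_membrane_frame(traj, tm_labels=("TM7",))
        assert np.allclose(out.coords, traj.coords, atol=1e-9)

    def test_alignment_is_isometry(self):
        traj = self._line_residues_traj(30.0)
        out = align_membrane_frame(traj, tm_labels=("TM7",))
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, traj.n_beads, (200, 2))
        d0 = np.linalg.norm(
            traj.coords[0, pairs[:, 0]] - traj.coords[0, pairs[:, 1]], axis=1
        )
        d1 = np.linalg.norm(
            out.coords[0, pairs[:, 0]] - out.coords[0, pairs[:, 1]], axis=1
        )
        assert np.max(np.abs(d0 - d1)) < 1e-6

    def test_isotropic_selection_raises(self, small_bilayer):
        from memscramble.trajio import ResidueRecord, Topology

        n0 = small_bilayer.n_beads
        # four beads on a square: isotropic xy covariance
        pts = np.array([[10.0, 10, 0], [10, 20, 0], [20, 10, 0], [20, 20, 0]])
        coords = np.concatenate(
            [small_bilayer.coords,
             np.broadcast_to(pts, (small_bilayer.n_frames, 4, 3))], axis=1
        )
        top = small_bilayer.topology
        residues = [ResidueRecord(i, "A", n0 + i, [], "TM7") for i in range(4)]
        traj = Trajectory(
            coords, small_bilayer.times, small_bilayer.box,
            Topology(n_beads=n0 + 4, bead_names=top.bead_names + ["BB"] * 4,
                     lipids=top.lipids, residues=residues),
        )
        with pytest.raises(AlignmentError):
            align_membrane_frame(traj, tm_labels=("TM7",))


class TestDiscardEquilibration:
    def test_first_microsecond_dropped(self):
        spec = BilayerSpec(lipids_per_leaflet=2, box_xy=20.0, seed=0,
                           lateral_sigma=0.0)
        traj = make_bilayer(spec, 10000)
        out = discard_equilibration(traj, 1000.0)
        assert out.n_frames == 9000
        assert out.times[0] == 1000.0  # times preserved, not re-zeroed

    def test_zero_cutoff_is_identity(self, small_bilayer):
        out = discard_equilibration(small_bilayer, 0.0)
        assert out.n_frames == small_bilayer.n_frames

    def test_boundary_keeps_single_frame(self):
        spec = BilayerSpec(lipids_per_leaflet=2, box_xy=20.0, seed=0,
                           lateral_sigma=0.0)
        traj = make_bilayer(spec, 10000)
        assert discard_equilibration(traj, 9999.5).n_frames == 1

    def test_cutoff_beyond_end_raises(self, small_bilayer):
        with pytest.raises(EmptyTrajectoryError):
            discard_equilibration(small_bilayer, 1e6)

    def test_idempotent(self, small_bilayer):
        once = discard_equilibration(small_bilayer, 10.0)
        twice = discard_equilibration(once, 10.0)
        assert np.array_equal(once.times, twice.times)
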