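"""PDB round trips, coarse-grain construction, radii, charges, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgchannel import (
    CGBead, CGProtein, IndoleLigand, RadiiTable, SiteDefinition, ToyChannelSpec,
    assign_charges, build_cg_protein, default_radii_table, make_toy_channel,
    measure_sidechain_radius, read_cg_pdb, read_structure, site_center,
    superpose_and_place, write_cg_pdb,
)
from cgchannel.structure_io import AlignmentError, FormatError


def _atom_line(serial, name, resname, chain, resnum, xyz, occ=1.0, altloc=" ",
               element=None):
    x, y, z = xyz
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:<3s} {chain}{resnum:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}")


def _write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


def _synthetic_chain(path, n_res=10, resname="ALA", chain="A", spacing=3.8):
    lines = []
    serial = 1
    for i in range(1, n_res + 1):
        lines.append(_atom_line(serial, "CA", resname, chain, i,
                                (i * spacing, 0.0, 0.0), element="C"))
        serial += 1
    return _write_pdb(path, lines)


class TestReadStructure:
    def test_toy_round_trip_positions(self, tmp_path):
        protein = make_toy_channel(ToyChannelSpec())
        path = tmp_path / "toy.pdb"
        write_cg_pdb(protein, path)
        back = read_cg_pdb(path)
        assert len(back) == len(protein)
        assert np.allclose(back.positions, protein.positions, atol=1e-3)
        assert np.array_equal(back.radii, protein.radii)
        assert np.allclose(back.alpha_center, protein.alpha_center, atol=1e-3)

    def test_leak_variant_round_trip_preserves_count(self, tmp_path):
        protein = make_toy_channel(ToyChannelSpec(leak=(3.0, 8.0)))
        path = tmp_path / "leaky.pdb"
        write_cg_pdb(protein, path)
        assert len(read_cg_pdb(path)) == len(protein)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            _atom_line(1, "CA", "ALA", "A", 1, (1.0, 0.0, 0.0), occ=0.6, altloc="A"),
            _atom_line(2, "CA", "ALA", "A", 1, (9.0, 0.0, 0.0), occ=0.4, altloc="B"),
        ]
        model = read_structure(_write_pdb(tmp_path / "alt.pdb", lines))
        ca = model["A"][(" ", 1, " ")]["CA"]
        assert ca.get_coord()[0] == pytest.approx(1.0)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(FormatError):
            read_structure(p)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            CGProtein([], SiteDefinition([("A", 1)]), SiteDefinition([("A", 2)]))


class TestBuildCGProtein:
    def test_one_bead_per_residue(self, tmp_path):
        model = read_structure(_synthetic_chain(tmp_path / "c.pdb", n_res=10))
        protein = build_cg_protein(model)
        assert len(protein) == 10
        assert np.allclose(protein.positions[:, 0], 3.8 * np.arange(1, 11))

    def test_override_radius_wins(self, tmp_path):
        model = read_structure(_synthetic_chain(tmp_path / "c.pdb", n_res=3))
        table = default_radii_table()
        table.overrides[("A", 2)] = 3.1
        protein = build_cg_protein(model, radii=table)
        assert protein.beads[1].radius == 3.1
        assert protein.beads[0].radius == table.defaults["ALA"]

    def test_unknown_residue_strict_vs_default(self, tmp_path):
        lines = [_atom_line(1, "CA", "XYZ", "A", 1, (0.0, 0.0, 0.0), element="C"),
                 _atom_line(2, "CA", "ALA", "A", 2, (3.8, 0.0, 0.0), element="C")]
        model = read_structure(_write_pdb(tmp_path / "x.pdb", lines))
        with pytest.raises(KeyError):
            build_cg_protein(model, strict=True)
        with pytest.warns(UserWarning):
            protein = build_cg_protein(model, strict=False)
        assert protein.beads[0].radius == 3.0  # documented fallback

    def test_indole_bead_radii(self):
        indole = IndoleLigand()
        assert tuple(indole.radii) == (1.6, 1.9)

    def test_radii_table_bounds(self):
        with pytest.raises(ValueError):
            RadiiTable({"ALA": 9.5})


class TestCharges:
    def _peptide(self, tmp_path, names):
        lines = [_atom_line(i + 1, "CA", n, "A", i + 1, (3.8 * i, 0.0, 0.0), element="C")
                 for i, n in enumerate(names)]
        return build_cg_protein(read_structure(_write_pdb(tmp_path / "p.pdb", lines)),
                                charge_scheme="none")

    def test_formal_scheme(self, tmp_path):
        protein = self._peptide(tmp_path, ["ASP", "GLU", "LYS", "ARG", "HIS", "ALA"])
        q = assign_charges(protein, "formal").charges
        assert list(q) == [-1.0, -1.0, 1.0, 1.0, 0.0, 0.0]

    def test_total_charge_two_asp_one_lys(self, tmp_path):
        protein = self._peptide(tmp_path, ["ASP", "ASP", "LYS"])
        assert assign_charges(protein, "formal").charges.sum() == -1.0

    def test_none_scheme_and_unknown_scheme(self, tmp_path):
        protein = self._peptide(tmp_path, ["ASP", "LYS"])
        assert np.all(assign_charges(protein, "none").charges == 0.0)
        with pytest.raises(ValueError):
            assign_charges(protein, "partial")


class TestSidechainRadius:
    def test_single_sidechain_atom(self, tmp_path):
        lines = [_atom_line(1, "N", "CYS", "A", 1, (-1.5, 0.0, 0.0), element="N"),
                 _atom_line(2, "CA", "CYS", "A", 1, (0.0, 0.0, 0.0), element="C"),
                 _atom_line(3, "C", "CYS", "A", 1, (1.5, 0.0, 0.0), element="C"),
                 _atom_line(4, "SG", "CYS", "A", 1, (0.0, 3.0, 0.0), element="S")]
        model = read_structure(_write_pdb(tmp_path / "s.pdb", lines))
        assert measure_sidechain_radius(model, "A", 1) == pytest.approx(3.0, abs=1e-6)

    def test_glycine_uses_table_default(self, tmp_path):
        lines = [_atom_line(1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0), element="C")]
        model = read_structure(_write_pdb(tmp_path / "g.pdb", lines))
        with pytest.warns(UserWarning):
            assert measure_sidechain_radius(model, "A", 1, default=2.1) == 2.1
        with pytest.raises(ValueError):
            measure_sidechain_radius(model, "A", 1)

    def test_centroid_and_farthest_conventions(self, tmp_path):
        # Arg-like geometry: sidechain atoms at hand-picked coordinates
        side = [("CB", (0.0, 1.0, 0.0)), ("CG", (0.0, 2.0, 1.0)),
                ("CD", (0.0, 3.0, 0.0)), ("NE", (0.0, 4.0, -1.0))]
        lines = [_atom_line(1, "CA", "ARG", "A", 1, (0.0, 0.0, 0.0), element="C")]
        lines += [_atom_line(i + 2, n, "ARG", "A", 1, xyz, element=n[0])
                  for i, (n, xyz) in enumerate(side)]
        model = read_structure(_write_pdb(tmp_path / "r.pdb", lines))
        pts = np.array([xyz for _, xyz in side])
        centroid = np.linalg.norm(pts.mean(axis=0))
        farthest = np.linalg.norm(pts, axis=1).max()
        assert measure_sidechain_radius(model, "A", 1) == pytest.approx(centroid, abs=1e-6)
        assert measure_sidechain_radius(model, "A", 1, convention="farthest") == \
            pytest.approx(farthest, abs=1e-6)


class TestSuperposition:
    def _ref(self, tmp_path, n=12):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-10, 10, (n, 3))
        lines = [_atom_line(i + 1, "CA", "ALA", "A", i + 1, tuple(c), element="C")
                 for i, c in enumerate(coords)]
        return _write_pdb(tmp_path / "ref.pdb", lines), coords

    def _snapshot(self, tmp_path, coords, rot=None, tran=(0.0, 0.0, 0.0)):
        moved = coords @ (rot.T if rot is not None else np.eye(3)) + np.asarray(tran)
        lines = [_atom_line(i + 1, "CA", "ALA", "A", i + 1, tuple(c), element="C")
                 for i, c in enumerate(moved)]
        return _write_pdb(tmp_path / "snap.pdb", lines)

    def test_identity_superposition(self, tmp_path):
        ref_path, coords = self._ref(tmp_path)
        ref = read_structure(ref_path)
        target = coords[0]
        indole, rmsd = superpose_and_place(ref, ref, target)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(indole.midpoint, target, atol=1e-6)

    @staticmethod
    def _model_from_coords(coords):
        from Bio.PDB.StructureBuilder import StructureBuilder

        sb = StructureBuilder()
        sb.init_structure("m")
        sb.init_model(0)
        sb.init_chain("A")
        sb.init_seg(" ")
        for i, c in enumerate(coords, start=1):
            sb.init_residue("ALA", " ", i, " ")
            sb.init_atom("CA", np.asarray(c, dtype=float), 0.0, 1.0, " ", "CA", i, "C")
        return sb.get_structure()[0]

    def test_rigid_motion_removed_exact(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-10, 10, (12, 3))
        rot = Rotation.from_euler("xyz", [31.0, -12.0, 77.0], degrees=True).as_matrix()
        tran = np.array([5.0, -3.0, 2.0])
        ref = self._model_from_coords(coords)
        snap = self._model_from_coords(coords @ rot.T + tran)
        target = np.array([1.0, 2.0, 3.0])
        indole, rmsd = superpose_and_place(snap, ref, target)
        assert rmsd < 1e-6
        # oracle: scipy's Kabsch (align_vectors) on the centered point sets
        r_or, _ = Rotation.align_vectors(coords @ rot.T + tran - (coords @ rot.T + tran).mean(0),
                                         coords - coords.mean(0))
        expected = r_or.as_matrix() @ (target - coords.mean(0)) + (coords @ rot.T + tran).mean(0)
        assert np.allclose(indole.midpoint, expected, atol=1e-8)
        assert np.allclose(indole.midpoint, rot @ target + tran, atol=1e-8)
        # bond length preserved by placement
        assert np.linalg.norm(indole.positions[1] - indole.positions[0]) == \
            pytest.approx(indole.bond_length, abs=1e-9)

    def test_idempotence(self, tmp_path):
        ref_path, coords = self._ref(tmp_path)
        ref = read_structure(ref_path)
        rot = Rotation.from_euler("z", 40.0, degrees=True).as_matrix()
        snap = read_structure(self._snapshot(tmp_path, coords, rot=rot))
        _, r1 = superpose_and_place(snap, ref, np.zeros(3))
        _, r2 = superpose_and_place(snap, ref, np.zeros(3))
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_too_few_common_atoms(self, tmp_path):
        ref_path, coords = self._ref(tmp_path, n=2)
        ref = read_structure(ref_path)
        with pytest.raises(AlignmentError):
            superpose_and_place(ref, ref, np.zeros(3))


class TestSiteCenter:
    def _protein(self, positions, selectors):
        beads = [CGBead(p, 2.0, 0.0, "A", i + 1, "ALA")
                 for i, p in enumerate(positions)]
        return CGProtein(beads, SiteDefinition(selectors), SiteDefinition([("A", 1)]))

    def test_single_and_midpoint(self):
        protein = self._protein([(0, 0, 0), (2, 0, 0)], [("A", 1), ("A", 2)])
        assert np.allclose(site_center(protein, protein.alpha_site), (1, 0, 0))
        assert np.allclose(site_center(protein, protein.beta_site), (0, 0, 0))

    def test_five_bead_mean_hand_sum(self):
        pts = [(1, 2, 3), (4, 0, -2), (0, 0, 0), (-3, 5, 1), (2, 2, 2)]
        protein = self._protein(pts, [("A", i) for i in range(1, 6)])
        hand = (np.array([1, 4, 0, -3, 2]).sum() / 5,
                np.array([2, 0, 0, 5, 2]).sum() / 5,
                np.array([3, -2, 0, 1, 2]).sum() / 5)
        assert np.allclose(site_center(protein, protein.alpha_site), hand)
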