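"""Structure loading, role/radius assignment, fragment maps, pocket tables."""

import numpy as np
import pandas as pd
import pytest

from nanopockets.fingerprints import FingerprintKey
from nanopockets.model_io import (AtomRecord, FrameSeries, PocketTable,
                                  StructureError, load_structure,
                                  parse_fragment_map, read_pocket_table,
                                  write_pocket_table)

ROLE_CFG = {"roles": {"core": {"elements": ["Au"]},
                      "ligand": {"elements": ["C", "N", "O", "S", "H"]}}}


def _write_xyz(path, rows):
    lines = [str(len(rows)), "test"]
    lines += [f"{el} {x:.3f} {y:.3f} {z:.3f}" for el, x, y, z in rows]
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture()
def xyz5(tmp_path):
    p = tmp_path / "five.xyz"
    _write_xyz(p, [("C", 0, 0, 0), ("O", 1.5, 0, 0), ("N", 0, 1.5, 0),
                   ("S", 0, 0, 1.5), ("Au", 3, 3, 3)])
    return p


class TestLoadStructure:
    def test_xyz_single_frame(self, xyz5):
        fs = load_structure(xyz5, role_config=ROLE_CFG)
        assert fs.n_frames == 1 and fs.n_atoms == 5
        by_el = {a.element.upper(): a for a in fs.atoms}
        assert by_el["C"].radius == pytest.approx(1.70)   # Bondi
        assert by_el["AU"].role == "core"
        assert by_el["S"].role == "ligand"

    def test_gro_nm_converted_to_angstrom(self, tmp_path):
        gro = tmp_path / "one.gro"
        gro.write_text(
            "test\n    2\n"
            "    1LIG     C1    1   0.100   0.200   0.300\n"
            "    1LIG     C2    2   0.400   0.500   0.600\n"
            "   2.0   2.0   2.0\n")
        fs = load_structure(gro, role_config=ROLE_CFG)
        assert np.allclose(fs.frames[0][0], [1.0, 2.0, 3.0])
        assert np.allclose(fs.frames[0][1], [4.0, 5.0, 6.0])

    def test_multiframe_xyz_trajectory(self, tmp_path, xyz5):
        traj = tmp_path / "traj.xyz"
        rows = [("C", 0, 0, 0), ("O", 1.5, 0, 0), ("N", 0, 1.5, 0),
                ("S", 0, 0, 1.5), ("Au", 3, 3, 3)]
        text = ""
        for shift in (0.0, 0.5, 1.0):
            text += "5\nframe\n" + "\n".join(
                f"{el} {x + shift:.3f} {y:.3f} {z:.3f}" for el, x, y, z in rows) + "\n"
        traj.write_text(text)
        fs = load_structure(xyz5, traj, role_config=ROLE_CFG)
        assert fs.n_frames == 3
        assert np.allclose(fs.frames[2][:, 0] - fs.frames[0][:, 0], 1.0)

    def test_atom_count_mismatch_raises(self, tmp_path, xyz5):
        bad = tmp_path / "bad.xyz"
        _write_xyz(bad, [("C", 0, 0, 0), ("O", 1.5, 0, 0)])
        with pytest.raises(StructureError):
            load_structure(xyz5, bad, role_config=ROLE_CFG)

    def test_unassigned_atoms_listed(self, xyz5):
        cfg = {"roles": {"core": {"elements": ["Au"]}}}
        with pytest.raises(StructureError, match="not assigned"):
            load_structure(xyz5, role_config=cfg)

    def test_unknown_element_needs_override(self, tmp_path):
        p = tmp_path / "odd.xyz"
        _write_xyz(p, [("Xq", 0, 0, 0)])
        cfg = {"roles": {"ligand": {"names": ["*"]}}}
        with pytest.raises(StructureError, match="radius"):
            load_structure(p, role_config=cfg)
        cfg_ok = {"roles": {"ligand": {"names": ["*"]}},
                  "radii": {"elements": {"Xq": 2.0}}}
        fs = load_structure(p, role_config=cfg_ok)
        assert fs.atoms[0].radius == 2.0

    def test_idempotent(self, xyz5):
        a = load_structure(xyz5, role_config=ROLE_CFG)
        b = load_structure(xyz5, role_config=ROLE_CFG)
        assert [x.role for x in a.atoms] == [x.role for x in b.atoms]
        assert np.array_equal(a.frames[0], b.frames[0])


def _three_ligand_series():
    atoms, frames = [], []
    pos = []
    aid = 0
    for lig in range(3):
        for k in range(10):
            atoms.append(AtomRecord(
                atom_id=aid, element="C", position=np.array([lig * 10.0, k, 0.0]),
                radius=1.7, role="ligand", ligand_index=lig, name=f"C{k + 1}",
                resname="LIG", residue_index=lig))
            pos.append([lig * 10.0, k, 0.0])
            aid += 1
    return FrameSeries(atoms=atoms, frames=[np.array(pos)])


class TestFragmentMap:
    CFG = {"species": [{"resname": "LIG", "fragments": {
        "inner": {"names": ["C1", "C2", "C3", "C4"]},
        "central": {"names": ["C5", "C6"]},
        "outer": {"names": ["C7", "C8", "C9", "C10"]}}}]}

    def test_counts(self):
        fs = _three_ligand_series()
        fmap = parse_fragment_map(self.CFG, fs)
        assert len(fmap.entries) == 30 and fmap.n_ligands == 3
        classes = [fmap.entries[i][1] for i in range(10)]
        assert classes == ["Inner"] * 4 + ["Central"] * 2 + ["Outer"] * 4
        # applied back onto the atom records
        assert all(a.fragment_class is not None for a in fs.atoms)

    def test_index_ranges(self):
        cfg = {"species": [{"fragments": {
            "inner": {"indices": [[0, 3]]}, "central": {"indices": [[4, 5]]},
            "outer": {"indices": [[6, 9]]}}}]}
        fmap = parse_fragment_map(cfg, _three_ligand_series())
        assert len(fmap.entries) == 30

    def test_uncovered_atom_error(self):
        cfg = {"species": [{"fragments": {
            "inner": {"names": ["C1", "C2", "C3", "C4"]},
            "central": {"names": ["C5", "C6"]},
            "outer": {"names": ["C7", "C8", "C9"]}}}]}  # C10 missing
        with pytest.raises(StructureError, match="not covered"):
            parse_fragment_map(cfg, _three_ligand_series())

    def test_double_claim_error(self):
        cfg = {"species": [{"fragments": {
            "inner": {"names": ["C1", "C2", "C3", "C4", "C5"]},
            "central": {"names": ["C5", "C6"]},
            "outer": {"names": ["C7", "C8", "C9", "C10"]}}}]}
        with pytest.raises(StructureError, match="claimed by both"):
            parse_fragment_map(cfg, _three_ligand_series())

    def test_non_contiguous_blocks_error(self):
        cfg = {"species": [{"fragments": {
            "inner": {"names": ["C1", "C2", "C3", "C10"]},
            "central": {"names": ["C5", "C6"]},
            "outer": {"names": ["C4", "C7", "C8", "C9"]}}}]}
        with pytest.raises(StructureError, match="contiguous"):
            parse_fragment_map(cfg, _three_ligand_series())


def _sample_table():
    from nanopockets.pocket_detect import Pocket
    from nanopockets.ses_grid import GridSpec
    grid = GridSpec((0, 0, 0), 0.5, (4, 4, 4))
    pockets = [
        Pocket(frame=0, pocket_id=0, voxels=np.zeros((2, 3), int), grid=grid,
               volume=150.0, center=np.array([1.0, 2.0, 3.0]), depth=1.15,
               depth_class="deep", wall_atom_ids={3, 1, 2},
               fingerprint=FingerprintKey(3, 2, 4), n_ligands=5,
               occupied=True, analyte_ids={7}),
        Pocket(frame=1, pocket_id=0, voxels=np.zeros((2, 3), int), grid=grid,
               volume=120.5, center=np.array([0.0, -1.0, 2.5]), depth=1.45,
               depth_class="shallow", wall_atom_ids={9},
               fingerprint=FingerprintKey(1, 0, 1), n_ligands=1),
    ]
    return PocketTable.from_pockets(pockets, n_frames=2)


class TestPocketTable:
    def test_empty_table_header_only_csv(self, tmp_path):
        t = PocketTable.empty(n_frames=0)
        path = tmp_path / "empty.csv"
        write_pocket_table(t, path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("frame,")
        back = read_pocket_table(path)
        assert back.df.empty

    def test_fingerprint_serialization(self, tmp_path):
        t = _sample_table()
        path = tmp_path / "t.csv"
        write_pocket_table(t, path)
        df = pd.read_csv(path)
        assert df.loc[0, "fingerprint"] == "3:2:4"
        assert df.loc[0, "wall_atom_ids"] == "1;2;3"

    def test_json_roundtrip_identity(self, tmp_path):
        t = _sample_table()
        path = tmp_path / "t.json"
        write_pocket_table(t, path)
        back = read_pocket_table(path)
        assert back.n_frames == t.n_frames
        pd.testing.assert_frame_equal(back.df, t.df)

    def test_csv_and_json_record_equality(self, tmp_path):
        t = _sample_table()
        write_pocket_table(t, tmp_path / "t.csv")
        write_pocket_table(t, tmp_path / "t.json")
        a = read_pocket_table(tmp_path / "t.csv").df
        b = read_pocket_table(tmp_path / "t.json").df
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
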