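"""Aggregate monolayer statistics: counts, classes, dihedrals, H-bonds."""

import numpy as np
import pandas as pd
import pytest

from nanopockets.model_io import (TABLE_COLUMNS, AtomRecord, FrameSeries,
                                  FragmentMap, PocketTable, Structure)
from nanopockets.shell_analysis import (AnalysisError, classify_conformer,
                                        dihedral_angle, dihedral_series,
                                        frame_summary, gauche_fractions,
                                        hbond_fractions, volume_depth_classes)


def _table(volumes, depths, frames=None, n_frames=None):
    frames = frames or [0] * len(volumes)
    rows = [{"frame": f, "pocket_id": i, "volume_A3": v,
             "center_x_A": 0.0, "center_y_A": 0.0, "center_z_A": 0.0,
             "depth_nm": d, "depth_class": "", "n_ligands": 1,
             "n_inner": 1, "n_central": 0, "n_outer": 0, "fingerprint": "1:0:0",
             "wall_atom_ids": "", "occupied": False, "analyte_ids": ""}
            for i, (v, d, f) in enumerate(zip(volumes, depths, frames))]
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return PocketTable(df, n_frames if n_frames is not None else max(frames) + 1)


class TestFrameSummary:
    def test_mean_and_population_sd(self):
        t = _table([120] * 12, [1.0] * 12,
                   frames=[0] * 2 + [1] * 4 + [2] * 6, n_frames=3)
        s = frame_summary(t)
        assert np.array_equal(s["counts"], [2, 4, 6])
        assert s["mean"] == pytest.approx(4.0)
        assert s["sd"] == pytest.approx(np.std([2, 4, 6]))  # 1.633, ddof=0

    def test_single_frame_sd_zero(self):
        s = frame_summary(_table([120, 130], [1, 1], frames=[0, 0], n_frames=1))
        assert s["sd"] == 0.0

    def test_zero_pocket_frames_count_as_zero(self):
        t = _table([120], [1.0], frames=[2], n_frames=5)
        s = frame_summary(t)
        assert np.array_equal(s["counts"], [0, 0, 1, 0, 0])
        assert s["mean"] == pytest.approx(0.2)  # total pockets / total frames

    def test_mean_equals_total_over_frames(self, np_fixture):
        from nanopockets.pipeline import analyze_frames
        table = analyze_frames(np_fixture.frames, fmap=np_fixture.fragment_map)
        s = frame_summary(table)
        assert s["mean"] == pytest.approx(len(table.df) / table.n_frames)


class TestClasses:
    def test_volume_thirds(self):
        c = volume_depth_classes(_table([120, 160, 320], [1.0, 1.2, 1.5]))
        assert c["volume_fractions"] == {
            "small": pytest.approx(1 / 3), "medium": pytest.approx(1 / 3),
            "large": pytest.approx(1 / 3)}

    def test_depth_partition(self):
        c = volume_depth_classes(_table([120] * 4, [1.0, 1.1, 1.4, 1.6]))
        f = c["depth_fractions"]
        assert f["deep"] + f["shallow"] == pytest.approx(1.0)
        assert f["deep"] == pytest.approx(0.5)

    def test_bad_edges_rejected(self):
        with pytest.raises(AnalysisError):
            volume_depth_classes(_table([120], [1.0]), volume_edges=(300, 150))

    def test_empty(self):
        c = volume_depth_classes(PocketTable.empty())
        assert c["n_pockets"] == 0


def _chain_series(coords_list, names):
    """Single-ligand FrameSeries from explicit per-frame coordinates."""
    atoms = [AtomRecord(atom_id=i, element="C", position=np.asarray(c, float),
                        radius=1.7, role="ligand", ligand_index=0,
                        fragment_class="Inner", name=nm, resname="LIG",
                        residue_index=0)
             for i, (c, nm) in enumerate(zip(coords_list[0], names))]
    return FrameSeries(atoms=atoms,
                       frames=[np.asarray(c, float) for c in coords_list])


def _butane(phi_deg):
    """Four-atom chain with the given torsion angle about the central bond."""
    phi = np.radians(phi_deg)
    return [[1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 1.5],
            [np.cos(phi), -np.sin(phi), 2.5]]


class TestDihedrals:
    @pytest.mark.parametrize("phi,conf", [
        (180.0, "trans"), (60.0, "gauche"), (-60.0, "gauche"),
        (125.0, "trans"), (-125.0, "trans"), (119.0, "gauche")])
    def test_textbook_geometries(self, phi, conf):
        coords = _butane(phi)
        ang = dihedral_angle(*coords)
        assert ang == pytest.approx(phi, abs=1e-6)
        assert classify_conformer(ang) == conf

    def test_boundary_is_trans(self):
        assert classify_conformer(120.0) == "trans"
        assert classify_conformer(-120.0) == "trans"
        assert classify_conformer(119.999) == "gauche"

    def test_series_and_fractions(self):
        fs = _chain_series([_butane(180.0), _butane(60.0)],
                           names=["C1", "C2", "C3", "C4"])
        fmap = FragmentMap(entries={i: (0, "Inner") for i in range(4)}, n_ligands=1)
        df = dihedral_series(fs, fmap, ["C1", "C2", "C3", "C4"])
        assert len(df) == 2  # one dihedral x two frames
        assert gauche_fractions(df)[0] == pytest.approx(0.5)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        coords = np.asarray(_butane(67.3))
        base = dihedral_angle(*coords)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ R.T + np.array([5.0, -3.0, 9.0])
        assert dihedral_angle(*moved) == pytest.approx(base, abs=1e-6)

    def test_missing_atom_reports_ligand(self):
        fs = _chain_series([_butane(180.0)], names=["C1", "C2", "C3", "C4"])
        fmap = FragmentMap(entries={i: (0, "Inner") for i in range(4)}, n_ligands=1)
        with pytest.raises(AnalysisError, match="ligand 0"):
            dihedral_series(fs, fmap, ["C1", "C2", "C3", "CX"])

    def test_short_chain_rejected(self):
        fs = _chain_series([_butane(180.0)], names=["C1", "C2", "C3", "C4"])
        fmap = FragmentMap(entries={}, n_ligands=0)
        with pytest.raises(AnalysisError):
            dihedral_series(fs, fmap, ["C1", "C2", "C3"])


def _hbond_system(n_donors=10, n_bonded=3):
    """Donors along x with one H each; acceptors placed linearly for a subset."""
    ids, elements, pos = [], [], []
    donors, acceptors = [], []
    aid = 0
    for i in range(n_donors):
        base = np.array([i * 10.0, 0.0, 0.0])
        ids.append(aid); elements.append("N"); pos.append(base); donors.append(aid)
        aid += 1
        ids.append(aid); elements.append("H"); pos.append(base + [1.0, 0, 0])
        aid += 1
        if i < n_bonded:
            ids.append(aid); elements.append("O"); pos.append(base + [2.9, 0, 0])
            acceptors.append(aid)
            aid += 1
    st = Structure(ids=np.array(ids), elements=np.array(elements, object),
                   positions=np.array(pos), radii=np.full(len(ids), 1.5),
                   roles=np.array(["ligand"] * len(ids), object))
    return st, np.array(pos), donors, acceptors


class TestHBonds:
    def test_linear_bond_counts(self):
        st, pos, donors, acceptors = _hbond_system(1, 1)
        out = hbond_fractions(st, pos, donors, acceptors)
        assert out["count"] == 1 and out["percent"] == 100.0

    def test_distance_fail(self):
        st, pos, donors, acceptors = _hbond_system(1, 1)
        pos2 = pos.copy()
        pos2[2] = pos2[0] + [4.0, 0, 0]  # move the acceptor out of range
        out = hbond_fractions(st, pos2, donors, acceptors)
        assert out["count"] == 0

    def test_angle_fail(self):
        st, pos, donors, acceptors = _hbond_system(1, 1)
        pos2 = pos.copy()
        pos2[2] = pos2[0] + [0.0, 2.9, 0]  # ~45 deg D-H...A angle
        out = hbond_fractions(st, pos2, donors, acceptors)
        assert out["count"] == 0

    def test_percent_of_maximum(self):
        st, pos, donors, acceptors = _hbond_system(10, 3)
        out = hbond_fractions(st, pos, donors, acceptors)
        assert out["max_possible"] == 10
        assert out["count"] == 3
        assert out["percent"] == pytest.approx(30.0)

    def test_donor_without_hydrogen(self):
        st, pos, donors, acceptors = _hbond_system(1, 1)
        pos2 = pos.copy()
        pos2[1] = pos2[0] + [5.0, 0, 0]  # H too far to resolve
        with pytest.raises(AnalysisError):
            hbond_fractions(st, pos2, donors, acceptors)
        out = hbond_fractions(st, pos2, donors, acceptors, lenient=True)
        assert out["count"] == 0 and out["max_possible"] == 0
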