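"""Monolayer descriptors aggregated over frames.

Covers the statistics used to characterize a coated nanoparticle's ligand
shell: pockets-per-frame counts, volume and depth class fractions,
backbone dihedral conformer (gauche/trans) fractions, and geometric
hydrogen-bond fractions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import FragmentMap, FrameSeries, PocketTable, Structure


class AnalysisError(ValueError):
    pass


def frame_summary(records: PocketTable) -> dict:
    """Pockets per frame: counts (zero-pocket frames included), mean ± sd.

    The standard deviation is the population sd (ddof=0); the mean equals
    total pockets / total frames exactly.
    """
    n_frames = records.n_frames
    counts = np.zeros(max(n_frames, 1), dtype=int)
    if not records.df.empty:
        for f, c in records.df.groupby("frame").size().items():
            counts[int(f)] = int(c)
    if n_frames == 0:
        counts = np.zeros(0, dtype=int)
    return {
        "counts": counts,
        "n_frames": int(n_frames),
        "mean": float(counts.mean()) if counts.size else 0.0,
        "sd": float(counts.std(ddof=0)) if counts.size else 0.0,
        "min": int(counts.min()) if counts.size else 0,
        "max": int(counts.max()) if counts.size else 0,
    }


def volume_depth_classes(records: PocketTable,
                         volume_edges: Sequence[float] = (150.0, 300.0),
                         depth_threshold_nm: float = 1.3,
                         volume_bin_width: float = 25.0,
                         depth_bin_width_nm: float = 0.05) -> dict:
    """Volume-class and depth-class fractions, plus histograms.

    Volume classes: below the first edge ("small"), between the edges
    ("medium"), above the last edge ("large").  Depth classes: deep iff
    depth < ``depth_threshold_nm``.
    """
    lo, hi = volume_edges
    if not lo < hi:
        raise AnalysisError(f"volume edges must be strictly increasing, got {volume_edges}")
    df = records.df
    if df.empty:
        return {
            "volume_fractions": {"small": 0.0, "medium": 0.0, "large": 0.0},
            "depth_fractions": {"deep": 0.0, "shallow": 0.0},
            "volume_histogram": None, "depth_histogram": None, "n_pockets": 0,
        }
    v = df["volume_A3"].to_numpy(dtype=float)
    n = len(v)
    vol_fr = {
        "small": float((v < lo).sum()) / n,
        "medium": float(((v >= lo) & (v <= hi)).sum()) / n,
        "large": float((v > hi).sum()) / n,
    }
    d = df["depth_nm"].to_numpy(dtype=float)
    have_depth = np.isfinite(d)
    if have_depth.any():
        dd = d[have_depth]
        depth_fr = {
            "deep": float((dd < depth_threshold_nm).sum()) / len(dd),
            "shallow": float((dd >= depth_threshold_nm).sum()) / len(dd),
        }
        d_edges = np.arange(0.0, dd.max() + 2 * depth_bin_width_nm, depth_bin_width_nm)
        d_hist = np.histogram(dd, bins=d_edges)
    else:
        depth_fr = {"deep": 0.0, "shallow": 0.0}
        d_hist = None
    v_edges = np.arange(0.0, v.max() + 2 * volume_bin_width, volume_bin_width)
    return {
        "volume_fractions": vol_fr,
        "depth_fractions": depth_fr,
        "volume_histogram": np.histogram(v, bins=v_edges),
        "depth_histogram": d_hist,
        "n_pockets": n,
    }


# ---------------------------------------------------------------------------
# dihedrals

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Standard torsion angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def classify_conformer(angle_deg: float, trans_cut_deg: float = 120.0) -> str:
    """'trans' iff |angle| >= the cut (default 120°), else 'gauche'."""
    return "trans" if abs(angle_deg) >= trans_cut_deg else "gauche"


def dihedral_series(frames: FrameSeries, fmap: FragmentMap,
                    chain_spec: Sequence[str],
                    trans_cut_deg: float = 120.0) -> pd.DataFrame:
    """Backbone dihedrals for every ligand and frame.

    ``chain_spec`` is the ordered list of heavy-atom names defining the
    chain (>= 4 names); each consecutive 4-tuple yields one dihedral.
    Returns a tidy frame with columns frame, ligand, dihedral (0-based
    sliding index), angle_deg and conformer.
    """
    if len(chain_spec) < 4:
        raise AnalysisError("chain_spec must list at least 4 consecutive heavy atoms")
    # resolve names per ligand
    by_ligand: dict[int, dict[str, int]] = {}
    for i, a in enumerate(frames.atoms):
        if a.role == "ligand" and a.ligand_index is not None:
            by_ligand.setdefault(a.ligand_index, {})[a.name or ""] = i
    rows = []
    for lig in sorted(by_ligand):
        names = by_ligand[lig]
        missing = [nm for nm in chain_spec if nm not in names]
        if missing:
            raise AnalysisError(f"ligand {lig} is missing chain atoms {missing}")
        idx = [names[nm] for nm in chain_spec]
        for f in range(frames.n_frames):
            pos = frames.frames[f]
            for k in range(len(idx) - 3):
                ang = dihedral_angle(pos[idx[k]], pos[idx[k + 1]],
                                     pos[idx[k + 2]], pos[idx[k + 3]])
                rows.append({"frame": f, "ligand": lig, "dihedral": k,
                             "angle_deg": ang,
                             "conformer": classify_conformer(ang, trans_cut_deg)})
    return pd.DataFrame(rows, columns=["frame", "ligand", "dihedral",
                                       "angle_deg", "conformer"])


def gauche_fractions(dihedrals: pd.DataFrame) -> pd.Series:
    """Per-dihedral gauche fraction across ligands and frames."""
    if dihedrals.empty:
        return pd.Series(dtype=float)
    return (dihedrals.assign(g=dihedrals["conformer"] == "gauche")
            .groupby("dihedral")["g"].mean())


# ---------------------------------------------------------------------------
# hydrogen bonds

def hbond_fractions(structure: Structure, positions_all: np.ndarray,
                    donors: Sequence[int], acceptors: Sequence[int],
                    hydrogens: dict[int, Sequence[int]] | None = None,
                    d_max: float = 3.5, angle_min_deg: float = 135.0,
                    dh_cut: float = 1.25, lenient: bool = False) -> dict:
    """Geometric hydrogen-bond count and percent of the maximum possible.

    ``donors``/``acceptors`` are atom ids into ``positions_all`` (a full
    (n_atoms, 3) coordinate array in Å).  Donor hydrogens are taken from
    ``hydrogens`` (donor id -> H ids) or, when absent, inferred as H atoms
    within ``dh_cut`` Å of the donor heavy atom.  An H-bond is a
    (donor-H, acceptor) pair with donor–acceptor distance <= ``d_max`` and
    D-H···A angle >= ``angle_min_deg``.  The maximum possible is the number
    of donor hydrogens.
    """
    if len(donors) == 0 or len(acceptors) == 0:
        raise AnalysisError("donor and acceptor selections must be non-empty")
    pos = np.asarray(positions_all, dtype=float)
    id_to_row = {int(a): k for k, a in enumerate(structure.ids)}

    if hydrogens is None:
        h_ids = [int(a) for a, el in zip(structure.ids, structure.elements)
                 if str(el).upper() == "H"]
        h_pos = pos[h_ids] if h_ids else np.zeros((0, 3))
        tree = cKDTree(h_pos) if h_ids else None
        hydrogens = {}
        for dnr in donors:
            if tree is None:
                hydrogens[int(dnr)] = []
                continue
            near = tree.query_ball_point(pos[int(dnr)], dh_cut)
            hydrogens[int(dnr)] = [h_ids[j] for j in near]

    pairs = []  # (donor, H)
    for dnr in donors:
        hs = hydrogens.get(int(dnr), [])
        if not hs:
            if lenient:
                continue
            raise AnalysisError(
                f"donor atom {dnr} has no resolvable hydrogen within {dh_cut} Å")
        pairs.extend((int(dnr), int(h)) for h in hs)
    max_possible = len(pairs)
    if max_possible == 0:
        return {"count": 0, "max_possible": 0, "percent": 0.0}

    acc = np.asarray([int(a) for a in acceptors], dtype=int)
    acc_tree = cKDTree(pos[acc])
    count = 0
    for dnr, h in pairs:
        near = acc_tree.query_ball_point(pos[dnr], d_max)
        for j in near:
            a = int(acc[j])
            if a == dnr or a == h:
                continue
            v1 = pos[dnr] - pos[h]
            v2 = pos[a] - pos[h]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) >= angle_min_deg:
                count += 1
    return {"count": count, "max_possible": max_possible,
            "percent": 100.0 * count / max_possible}
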