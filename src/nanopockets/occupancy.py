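"""Analyte occupancy of pockets.

An analyte molecule sits in a pocket when at least half of its heavy atoms
lie within the pocket's voxel region dilated by the small probe radius (the
dilation admits guests seated against the wall, where voxels are excluded
by vdW overlap).  Each analyte is assigned to at most one pocket — the one
containing most of its heavy atoms, ties going to the lower pocket id — and
a pocket is occupied when at least one analyte is assigned to it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fingerprints import fragment_occurrence
from .model_io import PocketTable
from .pocket_detect import Pocket, PocketParams


class OccupancyError(ValueError):
    pass


def assign_analytes(pockets: list[Pocket],
                    analyte_molecules: Mapping[int, np.ndarray],
                    params: PocketParams | None = None,
                    min_fraction: float = 0.5) -> list[Pocket]:
    """Assign analyte molecules to pockets and set the occupied flags.

    ``analyte_molecules`` maps a molecule id to the (M, 3) heavy-atom
    coordinates (Å) of that molecule.  Pockets are updated in place and
    returned.
    """
    params = params or PocketParams()
    for mol_id, coords in analyte_molecules.items():
        if np.asarray(coords).size == 0:
            raise OccupancyError(f"analyte molecule {mol_id} has no heavy atoms")
    for p in pockets:
        p.occupied = False
        p.analyte_ids = set()
    if not pockets:
        return pockets

    by_id = sorted(pockets, key=lambda p: p.pocket_id)
    trees = [cKDTree(p.voxel_centers()) for p in by_id]
    for mol_id in sorted(analyte_molecules):
        coords = np.asarray(analyte_molecules[mol_id], dtype=float)
        n_heavy = len(coords)
        best = None  # most heavy atoms inside; ties -> lowest pocket id
        for p, tree in zip(by_id, trees):
            d, _ = tree.query(coords, k=1)
            n_in = int((d <= params.probe_small).sum())
            if n_in / n_heavy >= min_fraction:
                if best is None or n_in > best[0]:
                    best = (n_in, p)
        if best is not None:
            best[1].occupied = True
            best[1].analyte_ids.add(int(mol_id))
    return pockets


def occupancy_summary(records: PocketTable) -> dict:
    """Occupied fraction plus depth/volume/composition splits by occupancy."""
    df = records.df
    if df.empty:
        return {
            "n_pockets": 0, "n_occupied": 0, "percent_occupied": 0.0,
            "occupied": None, "empty": None,
        }

    def _subset_stats(sub: pd.DataFrame, table: PocketTable) -> dict | None:
        if sub.empty:
            return None
        sub_table = PocketTable(sub, table.n_frames, table.frame_stride_ps)
        return {
            "n": int(len(sub)),
            "depth_nm_mean": float(sub["depth_nm"].mean()),
            "depth_nm_median": float(sub["depth_nm"].median()),
            "volume_A3_mean": float(sub["volume_A3"].mean()),
            "volume_A3_median": float(sub["volume_A3"].median()),
            "fragment_occurrence": fragment_occurrence(sub_table),
        }

    occ = df[df["occupied"]]
    emp = df[~df["occupied"]]
    return {
        "n_pockets": int(len(df)),
        "n_occupied": int(len(occ)),
        "percent_occupied": 100.0 * len(occ) / len(df),
        "occupied": _subset_stats(occ, records),
        "empty": _subset_stats(emp, records),
    }
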