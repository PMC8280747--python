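"""End-to-end per-frame pocket analysis.

Ties the modules together: for each frame of a :class:`FrameSeries`, detect
pockets on the core+ligand surface, fingerprint them against a fragment
map, optionally assign analyte molecules, and collect everything into a
:class:`PocketTable`.
"""

from __future__ import annotations

import numpy as np

from .fingerprints import FingerprintError, pocket_fingerprint
from .model_io import FragmentMap, FrameSeries, PocketTable
from .occupancy import assign_analytes
from .pocket_detect import PocketParams, detect_pockets


def analyte_molecules_at_frame(frames: FrameSeries, frame: int) -> dict[int, np.ndarray]:
    """Group role=analyte heavy atoms by residue into molecule coordinate sets."""
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(frames.atoms):
        if a.role == "analyte" and a.element.upper() != "H":
            groups.setdefault(int(a.residue_index or 0), []).append(i)
    pos = frames.frames[frame]
    return {mol: pos[idx] for mol, idx in groups.items()}


def analyze_frames(frames: FrameSeries, params: PocketParams | None = None,
                   fmap: FragmentMap | None = None,
                   with_depth: bool = True,
                   with_analytes: bool = True,
                   include_hydrogens: bool = True) -> PocketTable:
    """Run detection (+ fingerprints, + occupancy) over every frame."""
    params = params or PocketParams()
    all_pockets = []
    has_analytes = any(a.role == "analyte" for a in frames.atoms)
    for f in range(frames.n_frames):
        structure = frames.structure(f, roles=("core", "ligand"),
                                     include_hydrogens=include_hydrogens)
        core_com = frames.core_com(f) if with_depth else None
        pockets = detect_pockets(structure, params, core_com=core_com, frame=f)
        if fmap is not None:
            for p in pockets:
                try:
                    p.fingerprint, p.n_ligands = pocket_fingerprint(p.wall_atom_ids, fmap)
                except FingerprintError:
                    p.fingerprint, p.n_ligands = None, None
        if with_analytes and has_analytes:
            assign_analytes(pockets, analyte_molecules_at_frame(frames, f), params)
        all_pockets.extend(pockets)
    return PocketTable.from_pockets(all_pockets, frames.n_frames,
                                    frames.frame_stride_ps)
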