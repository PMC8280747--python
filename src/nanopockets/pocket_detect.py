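"""Dual-probe pocket detection.

A pocket is a connected component of the volumetric difference between the
regions enclosed by two solvent-excluded surfaces of the same structure:
the large probe (default 3 Å) bridges over cavity mouths the small,
water-sized probe (default 1.4 Å) can still enter.  Components smaller than
the minimum-volume cutoff (default 100 Å³, roughly the molecular volume of
salicylate) are discarded.  Each surviving pocket is geolocalized (center,
distance from the metal-core center of mass) and its wall atoms are
collected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .model_io import Structure
from .ses_grid import GridSpec, compute_ses, make_grid

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class PocketError(ValueError):
    pass


@dataclass
class PocketParams:
    """Detection parameters (lengths in Å unless noted)."""

    probe_small: float = 1.4
    probe_big: float = 3.0
    min_volume: float = 100.0
    spacing: float = 0.5
    connectivity: int = 26
    wall_contact_margin: float | None = None   # defaults to probe_small
    depth_threshold_nm: float = 1.3
    grid_padding: float | None = None          # defaults to probe_big + 2 Å

    def __post_init__(self):
        if not self.probe_small < self.probe_big:
            raise PocketError(
                f"probe_small ({self.probe_small}) must be < probe_big ({self.probe_big})")
        if self.min_volume <= 0:
            raise PocketError(f"min_volume must be > 0, got {self.min_volume}")
        if self.spacing <= 0:
            raise PocketError(f"spacing must be > 0, got {self.spacing}")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise PocketError(f"connectivity must be one of 6/18/26, got {self.connectivity}")

    @property
    def margin(self) -> float:
        return self.probe_small if self.wall_contact_margin is None else self.wall_contact_margin

    @property
    def padding(self) -> float:
        return self.probe_big + 2.0 if self.grid_padding is None else self.grid_padding


@dataclass
class Pocket:
    """One detected cavity in one frame."""

    frame: int
    pocket_id: int
    voxels: np.ndarray            # (M, 3) voxel indices
    grid: GridSpec
    volume: float                 # Å³
    center: np.ndarray            # Å, unweighted mean of voxel centers
    depth: float | None           # nm, |center - core com|
    depth_class: str | None       # "deep" | "shallow"
    wall_atom_ids: set = field(default_factory=set)
    fingerprint: object = None
    n_ligands: int | None = None
    occupied: bool = False
    analyte_ids: set = field(default_factory=set)

    def voxel_centers(self) -> np.ndarray:
        return self.grid.voxel_centers(self.voxels)


def classify_depth(depth_nm: float, threshold_nm: float = 1.3) -> str:
    """'deep' iff the pocket center is closer than ``threshold_nm`` to the core com."""
    if depth_nm < 0:
        raise PocketError(f"depth must be >= 0, got {depth_nm}")
    return "deep" if depth_nm < threshold_nm else "shallow"


def wall_atoms(pocket_voxel_centers: np.ndarray, structure: Structure,
               params: PocketParams) -> set[int]:
    """Atoms forming the pocket walls.

    Atom i is a wall atom iff some pocket voxel center lies within
    ``radius_i + wall_contact_margin + spacing`` of its center.
    """
    pocket_voxel_centers = np.asarray(pocket_voxel_centers, dtype=float)
    if pocket_voxel_centers.size == 0:
        raise PocketError("wall_atoms needs a non-empty pocket voxel set")
    tree = cKDTree(pocket_voxel_centers)
    d, _ = tree.query(structure.positions, k=1)
    cut = structure.radii + params.margin + params.spacing
    return {int(i) for i in structure.ids[d <= cut]}


def detect_pockets(structure: Structure, params: PocketParams | None = None,
                   core_com: np.ndarray | None = None,
                   frame: int = 0) -> list[Pocket]:
    """Detect, filter and geolocalize the pockets of one frame.

    Returns pockets sorted by volume descending (ties broken by
    lexicographic center), with ``pocket_id`` assigned from 0 in that order.
    ``core_com`` (Å) enables depth and deep/shallow classification; without
    it both are left unset.
    """
    params = params or PocketParams()
    if structure.n_atoms == 0:
        raise PocketError("cannot detect pockets for an empty atom set")

    grid = make_grid(structure.positions, structure.radii,
                     spacing=params.spacing, padding=params.padding)
    small = compute_ses(structure.positions, structure.radii, params.probe_small, grid)
    big = compute_ses(structure.positions, structure.radii, params.probe_big, grid)
    candidate = big.inside & ~small.inside

    labels, n_labels = ndi.label(
        candidate, structure=ndi.generate_binary_structure(
            3, _CONNECTIVITY_RANK[params.connectivity]))
    if n_labels == 0:
        return []

    voxel_volume = grid.voxel_volume
    counts = np.bincount(labels.ravel())[1:]  # skip background
    keep = np.nonzero(counts * voxel_volume >= params.min_volume)[0] + 1

    pockets = []
    objects = ndi.find_objects(labels)
    for lab in keep:
        sl = objects[lab - 1]
        local = np.argwhere(labels[sl] == lab)
        offset = np.array([s.start for s in sl])
        voxels = local + offset
        centers = grid.voxel_centers(voxels)
        center = centers.mean(axis=0)
        volume = len(voxels) * voxel_volume
        if core_com is not None:
            depth = float(np.linalg.norm(center - np.asarray(core_com))) / 10.0
            depth_class = classify_depth(depth, params.depth_threshold_nm)
        else:
            depth, depth_class = None, None
        walls = wall_atoms(centers, structure, params)
        pockets.append(Pocket(
            frame=frame, pocket_id=-1, voxels=voxels, grid=grid,
            volume=volume, center=center, depth=depth, depth_class=depth_class,
            wall_atom_ids=walls))

    pockets.sort(key=lambda p: (-p.volume, p.center[0], p.center[1], p.center[2]))
    for i, p in enumerate(pockets):
        p.pocket_id = i
    return pockets


def max_pairwise_center_distance(pockets: list[Pocket]) -> float:
    """Largest pairwise distance between pocket centers, in nm (0 if < 2 pockets)."""
    if len(pockets) < 2:
        return 0.0
    centers = np.array([p.center for p in pockets])
    from scipy.spatial.distance import pdist
    return float(pdist(centers).max()) / 10.0
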