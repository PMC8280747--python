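"""Synthetic test systems with known cavity structure, plus a brute-force oracle.

Two generators build bead (united-atom) geometries whose pocket structure is
known by construction:

* a *cup* — beads on a spherical shell minus a polar cap, enclosing one
  concave cavity whose mouth admits the water-sized probe but not the large
  one;
* a *coated nanoparticle* — a bead-sphere core wrapped in a dense, sealed
  monolayer of bead layers; each ligand is the radial bundle of beads in
  one spherical-Voronoi sector, partitioned radially into
  Inner/Central/Outer blocks.  For each splay group, the beads of a few
  neighboring ligands are bent apart (displaced off a flask-shaped void)
  to open a wedge cavity bordered by exactly those ligands (the "flower
  opening" motif).

The oracle implements the rolling-probe definition of the solvent-excluded
surface directly: a point is outside the SES iff some probe center on a
dense candidate grid clears every inflated atom sphere and lies within the
probe radius of the point.  It shares no machinery with the grid engine
(exhaustive / KD-tree search here, distance-transform closing there) and is
the independent reference the engine is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .model_io import AtomRecord, FragmentMap, FrameSeries, Structure
from .pocket_detect import PocketParams

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class FixtureError(ValueError):
    pass


def _zone_points(n: int, z_min: float, z_max: float, phase: float = 0.0) -> np.ndarray:
    """n unit vectors evenly covering the spherical zone z in [z_min, z_max]."""
    k = np.arange(n)
    z = z_min + (k + 0.5) * (z_max - z_min) / n
    phi = k * _GOLDEN_ANGLE + phase
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def fibonacci_sphere(n: int, phase: float = 0.0) -> np.ndarray:
    """n approximately uniform unit vectors on the full sphere."""
    return _zone_points(n, -1.0 + 1.0 / n, 1.0 - 1.0 / n, phase)


def make_cup_fixture(inner_radius: float = 4.5, shell_radius: float | None = None,
                     bead_radius: float = 1.5, aperture_deg: float = 45.0,
                     n_beads: int = 140, seed: int = 0,
                     jitter: float = 0.03) -> Structure:
    """Hemispherical-shell 'cup' with a single probe-size-selective cavity.

    Beads sit on a sphere of radius ``shell_radius`` (default
    ``inner_radius + bead_radius``) minus a polar cap of half-angle
    ``aperture_deg`` about +z.  The mouth is sized so the 1.4 Å probe can
    enter the cavity while the 3 Å probe is bridged across it.  Deterministic
    for a fixed seed.
    """
    if shell_radius is None:
        shell_radius = inner_radius + bead_radius
    if n_beads < 12:
        raise FixtureError("n_beads too small for a sealed shell")
    rng = np.random.default_rng(seed)
    # zone below the polar cap: polar angle in [aperture, 180 deg]
    z_max = float(np.cos(np.radians(aperture_deg)))
    dirs = _zone_points(n_beads, -1.0, z_max, phase=rng.uniform(0, 2 * np.pi))
    pos = shell_radius * dirs
    if jitter > 0:
        pos = pos + rng.normal(scale=jitter, size=pos.shape)

    # leak check: neighboring beads must not leave gaps wider than 2 bead radii
    tree = cKDTree(pos)
    nn, _ = tree.query(pos, k=2)
    max_gap = float(nn[:, 1].max()) - 2 * bead_radius
    if max_gap > 2 * bead_radius:
        raise FixtureError(
            f"leaky shell: largest bead gap {max_gap:.2f} Å exceeds 2×bead_radius; "
            "increase n_beads or bead_radius")

    n = len(pos)
    return Structure(
        ids=np.arange(n, dtype=int),
        elements=np.array(["C"] * n, dtype=object),
        positions=pos.astype(float),
        radii=np.full(n, float(bead_radius)),
        roles=np.array(["ligand"] * n, dtype=object),
        masses=np.full(n, 12.011),
    )


def random_cluster(n_atoms: int = 40, seed: int = 0, extent: float = 7.0,
                   r_min: float = 1.3, r_max: float = 2.0,
                   min_separation: float = 1.6) -> Structure:
    """Seeded random bead cluster used for engine-vs-oracle cross-validation."""
    rng = np.random.default_rng(seed)
    pos: list[np.ndarray] = []
    while len(pos) < n_atoms:
        cand = rng.uniform(-extent, extent, size=3)
        if all(np.linalg.norm(cand - p) >= min_separation for p in pos):
            pos.append(cand)
    pos_arr = np.array(pos)
    radii = rng.uniform(r_min, r_max, size=n_atoms)
    return Structure(
        ids=np.arange(n_atoms, dtype=int),
        elements=np.array(["C"] * n_atoms, dtype=object),
        positions=pos_arr, radii=radii,
        roles=np.array(["ligand"] * n_atoms, dtype=object),
        masses=np.full(n_atoms, 12.011),
    )


# ---------------------------------------------------------------------------
# coated nanoparticle

@dataclass
class CoatedNPFixture:
    """Coated-nanoparticle fixture: frames, fragment map and the constructed
    splay groups (sets of ligand indices bordering each opened wedge)."""

    frames: FrameSeries
    fragment_map: FragmentMap
    splay_groups: list[set]
    wedge_centers: np.ndarray    # (n_groups, 3) unit vectors
    cavity_centers: np.ndarray   # (n_groups, 3) Å, center of each carved void


def make_coated_np_fixture(core_radius: float = 7.0, n_ligands: int = 20,
                           beads_per_fragment: tuple[int, int, int] = (2, 1, 1),
                           splay_groups: int = 2, group_size: int = 4,
                           cavity_radius: float = 5.2, neck_radius: float = 3.9,
                           layer_spacing: float = 1.8, bead_spacing: float = 2.0,
                           ligand_bead_radius: float = 2.2,
                           n_frames: int = 1, jitter: float = 0.05,
                           seed: int = 0) -> CoatedNPFixture:
    """Coated nanoparticle with known wedge cavities in a sealed monolayer.

    The monolayer is a dense crust of bead layers (one radial layer per
    entry of ``beads_per_fragment``, expanded: (2,1,1) means two Inner
    layers, one Central, one Outer).  Each ligand is the bundle of crust
    beads inside one spherical-Voronoi sector of ``n_ligands`` anchor
    directions; beads overlap enough that neither probe can enter the
    intact crust, so the unsplayed particle has no pockets.

    For each splay group, the ``group_size`` ligands nearest a chosen
    direction are bent apart: their beads are displaced off a flask-shaped
    void (a buried ball of ``cavity_radius`` plus a neck of
    ``neck_radius`` opening through the outer surface).  The neck admits
    the water-sized probe but not the large one, so each wedge is one
    pocket whose walls are, by construction, exactly the group's ligands
    (beads lining a void are owned by its group).  Frames beyond the
    first add seeded Gaussian jitter to emulate a short trajectory.
    """
    if n_ligands < 4:
        raise FixtureError("need at least 4 ligands")
    if any(b < 1 for b in beads_per_fragment):
        raise FixtureError("beads_per_fragment entries must be >= 1")
    if splay_groups * group_size > n_ligands:
        raise FixtureError("splay groups would exhaust the ligand set")
    rng = np.random.default_rng(seed)
    r_lig = float(ligand_bead_radius)

    n_layers = sum(beads_per_fragment)
    classes = (["Inner"] * beads_per_fragment[0]
               + ["Central"] * beads_per_fragment[1]
               + ["Outer"] * beads_per_fragment[2])
    layer_r = [core_radius + 0.6 + j * layer_spacing for j in range(n_layers)]
    if layer_r[0] < core_radius - r_lig:
        raise FixtureError("ligand beads buried inside the core beyond tolerance")

    # --- crust beads, Voronoi-assigned to ligand anchors
    anchors = fibonacci_sphere(n_ligands, phase=rng.uniform(0, 2 * np.pi))
    pos_list, lig_list, layer_list = [], [], []
    for j, r in enumerate(layer_r):
        n_j = max(12, int(round(4 * np.pi * r * r / bead_spacing ** 2)))
        for p in r * fibonacci_sphere(n_j, phase=rng.uniform(0, 2 * np.pi)):
            pos_list.append(p)
            lig_list.append(int(np.argmax(anchors @ (p / np.linalg.norm(p)))))
            layer_list.append(j)
    pos = np.array(pos_list)
    lig_of = np.array(lig_list)
    layer_of = np.array(layer_list)

    # --- splay groups around greedily spread wedge directions
    seeds_idx = [0]
    while len(seeds_idx) < max(splay_groups, 1):
        d2 = [min(np.linalg.norm(anchors[i] - anchors[j]) for j in seeds_idx)
              for i in range(n_ligands)]
        seeds_idx.append(int(np.argmax(d2)))
    taken: set[int] = set()
    groups: list[set] = []
    axes = []
    for s in seeds_idx[:splay_groups]:
        order = np.argsort([np.inf if i in taken else
                            float(np.linalg.norm(anchors[i] - anchors[s]))
                            for i in range(n_ligands)])
        grp = set(int(i) for i in order[:group_size])
        taken |= grp
        groups.append(grp)
        d = anchors[sorted(grp)].mean(axis=0)
        axes.append(d / np.linalg.norm(d))

    # --- carve each wedge: displace beads off the flask void, then assign
    #     the void-lining beads to the group (these are the bent ligands)
    r_cav = core_radius + 0.6 + (n_layers - 1) * layer_spacing / 2
    outer = layer_r[-1] + r_lig
    push = 0.25
    lining_reach = r_lig + 1.4 + 0.5 + 1.0  # bead radius + small probe + grid + slack
    cavity_centers = []
    for d, grp in zip(axes, groups):
        c = d * r_cav
        cavity_centers.append(c)
        radial = pos @ d
        lat = pos - radial[:, None] * d
        latd = np.linalg.norm(lat, axis=1)
        dist = np.linalg.norm(pos - c, axis=1)
        # beads above the cavity near the axis leave through the neck wall
        upper = (radial > r_cav) & (latd < neck_radius) & (dist < cavity_radius + 2.0)
        latdir = np.where(latd[:, None] > 1e-9, lat / np.maximum(latd, 1e-9)[:, None], 0.0)
        pos[upper] = radial[upper, None] * d + latdir[upper] * (neck_radius + push)
        # remaining beads inside the ball move radially out of it
        dc = pos - c
        dist = np.linalg.norm(dc, axis=1)
        inball = dist < cavity_radius
        pos[inball] = c + dc[inball] / dist[inball, None] * (cavity_radius + push)
        # ownership of the void lining
        radial = pos @ d
        lat = pos - radial[:, None] * d
        latd = np.linalg.norm(lat, axis=1)
        d_ball = np.linalg.norm(pos - c, axis=1) - cavity_radius
        d_neck = np.where((radial > r_cav) & (radial < outer + 2.0),
                          latd - neck_radius, np.inf)
        lining = np.minimum(d_ball, d_neck) <= lining_reach
        ganchors = np.array(sorted(grp))
        unit = pos[lining] / np.linalg.norm(pos[lining], axis=1)[:, None]
        lig_of[lining] = ganchors[np.argmax(unit @ anchors[ganchors].T, axis=1)]

    # --- core: center bead plus a sealed shell of surface beads
    r_c = 2.0
    shell_r = max(core_radius - r_c, r_c)
    core_pos = [np.zeros(3)]
    core_rad = [shell_r]
    n_core = max(12, int(np.ceil(4 * np.pi * shell_r ** 2 / (r_c * 0.9) ** 2)))
    for u in fibonacci_sphere(n_core, phase=rng.uniform(0, 2 * np.pi)):
        core_pos.append(shell_r * u)
        core_rad.append(r_c)

    # --- assemble atoms: core first, then ligands in (ligand, layer) order
    atoms: list[AtomRecord] = []
    aid = 0
    for p, r in zip(core_pos, core_rad):
        atoms.append(AtomRecord(atom_id=aid, element="Au", position=np.asarray(p, float),
                                radius=float(r), role="core", name="AU", resname="COR",
                                residue_index=0, mass=196.967))
        aid += 1
    entries: dict[int, tuple[int, str]] = {}
    order = np.lexsort((layer_of, lig_of))
    for k in order:
        i, j = int(lig_of[k]), int(layer_of[k])
        atoms.append(AtomRecord(
            atom_id=aid, element="C", position=pos[k], radius=r_lig,
            role="ligand", ligand_index=i, fragment_class=classes[j],
            name=f"B{j + 1}", resname="LIG", residue_index=1 + i, mass=12.011))
        entries[aid] = (i, classes[j])
        aid += 1

    base_coords = np.array([a.position for a in atoms], dtype=float)
    frames = [base_coords]
    for _f in range(1, n_frames):
        frames.append(base_coords + rng.normal(scale=jitter, size=base_coords.shape))

    series = FrameSeries(atoms=atoms, frames=frames, frame_stride_ps=50.0)
    fmap = FragmentMap(entries=entries, n_ligands=n_ligands)
    return CoatedNPFixture(frames=series, fragment_map=fmap, splay_groups=groups,
                           wedge_centers=np.array(axes),
                           cavity_centers=np.array(cavity_centers))


def make_analyte_blob(center, n_atoms: int = 7, spread: float = 1.1,
                      seed: int = 0) -> np.ndarray:
    """Small seeded heavy-atom blob standing in for a guest molecule (Å coords)."""
    rng = np.random.default_rng(seed)
    return np.asarray(center, dtype=float) + rng.normal(scale=spread, size=(n_atoms, 3))


def add_analyte(frames: FrameSeries, center, n_atoms: int = 7,
                spread: float = 1.1, seed: int = 0,
                resname: str = "SAL") -> FrameSeries:
    """Return a new FrameSeries with one analyte blob appended at ``center``.

    The blob's coordinates are identical across frames; atom ids continue
    after the existing atoms and the molecule gets its own residue index.
    """
    coords = make_analyte_blob(center, n_atoms=n_atoms, spread=spread, seed=seed)
    next_id = max(a.atom_id for a in frames.atoms) + 1
    next_res = max((a.residue_index or 0) for a in frames.atoms) + 1
    atoms = list(frames.atoms)
    for k, p in enumerate(coords):
        atoms.append(AtomRecord(atom_id=next_id + k, element="C", position=p,
                                radius=1.70, role="analyte", name=f"A{k + 1}",
                                resname=resname, residue_index=next_res,
                                mass=12.011))
    new_frames = [np.vstack([fr, coords]) for fr in frames.frames]
    return FrameSeries(atoms=atoms, frames=new_frames,
                       frame_stride_ps=frames.frame_stride_ps)


# ---------------------------------------------------------------------------
# brute-force oracle

def oracle_point_in_ses(positions: np.ndarray, radii: np.ndarray, probe: float,
                        point: np.ndarray, resolution: float) -> bool:
    """Literal rolling-probe test for one point (True = inside the SES).

    The point is outside iff some candidate probe center c on a dense grid
    within the (2·probe)-box around the point satisfies |c - x_i| >= R_i +
    probe for every atom i and |c - point| <= probe.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    point = np.asarray(point, dtype=float)
    if probe == 0:
        return bool(np.any(np.linalg.norm(positions - point, axis=1) <= radii))
    span = np.arange(-probe - resolution, probe + resolution + 1e-9, resolution)
    gx, gy, gz = np.meshgrid(span, span, span, indexing="ij")
    cand = point + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    close = np.linalg.norm(cand - point, axis=1) <= probe
    cand = cand[close]
    # only atoms whose inflated sphere can reach the candidate box matter
    reach = np.linalg.norm(positions - point, axis=1) <= radii + 2 * probe + resolution
    ok = np.ones(len(cand), dtype=bool)
    for p, r in zip(positions[reach], radii[reach]):
        ok &= np.linalg.norm(cand - p, axis=1) >= r + probe - 1e-9
        if not ok.any():
            return True
    return not bool(ok.any())


def _accessible_probe_centers(positions: np.ndarray, radii: np.ndarray,
                              probe: float, lo: np.ndarray, hi: np.ndarray,
                              resolution: float) -> np.ndarray:
    """Dense candidate probe centers in [lo, hi] clearing every inflated sphere
    and reachable from the domain boundary (bulk solvent)."""
    axes = [np.arange(lo[d], hi[d] + resolution / 2, resolution) for d in range(3)]
    shape = tuple(len(ax) for ax in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cand = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(cand)
    blocked = np.zeros(len(cand), dtype=bool)
    for p, r in zip(positions, radii):
        idx = tree.query_ball_point(p, r + probe - 1e-9)
        blocked[idx] = True
    accessible = (~blocked).reshape(shape)
    # keep only probe positions connected to the box boundary (face adjacency)
    labels, n = ndi.label(accessible, structure=ndi.generate_binary_structure(3, 1))
    if n:
        keep = set()
        for axis in range(3):
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = face
                keep.update(np.unique(labels[tuple(sl)]))
        keep.discard(0)
        accessible = np.isin(labels, sorted(keep)) if keep else np.zeros_like(accessible)
    return cand[accessible.ravel()]


def oracle_ses_mask(positions: np.ndarray, radii: np.ndarray, probe: float,
                    query_points: np.ndarray, resolution: float) -> np.ndarray:
    """Vectorized oracle: inside-SES flags for many query points.

    Same rolling-probe definition as :func:`oracle_point_in_ses`, evaluated
    with a KD-tree over the accessible probe centers instead of a per-point
    exhaustive search.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    query_points = np.asarray(query_points, dtype=float)
    if probe == 0:
        tree = cKDTree(positions)
        out = np.zeros(len(query_points), dtype=bool)
        for i, q in enumerate(query_points):
            d = np.linalg.norm(positions - q, axis=1)
            out[i] = bool(np.any(d <= radii))
        return out
    lo = np.minimum((positions - radii[:, None]).min(0) - 2 * probe,
                    query_points.min(0) - probe) - 2 * resolution
    hi = np.maximum((positions + radii[:, None]).max(0) + 2 * probe,
                    query_points.max(0) + probe) + 2 * resolution
    accessible = _accessible_probe_centers(positions, radii, probe, lo, hi, resolution)
    if len(accessible) == 0:
        return np.ones(len(query_points), dtype=bool)
    tree = cKDTree(accessible)
    d, _ = tree.query(query_points, k=1)
    return d > probe + 1e-9  # outside iff an accessible center is within the probe


def oracle_pocket_volume(structure: Structure, params: PocketParams | None = None,
                         resolution: float = 0.25,
                         connectivity_rank: int = 3) -> list[float]:
    """Independent fine-grid integration of the dual-probe pocket volumes.

    Samples points on a grid of step ``resolution``, keeps those inside the
    big-probe SES and outside the small-probe SES per the oracle definition
    (candidate probe centers at half the sampling step), labels connected
    regions and returns their volumes in Å³, sorted descending.  No code is
    shared with the grid engine.
    """
    params = params or PocketParams()
    positions, radii = structure.positions, structure.radii
    pad = params.probe_big + 1.0
    lo = (positions - radii[:, None]).min(0) - pad
    hi = (positions + radii[:, None]).max(0) + pad
    axes = [np.arange(lo[d], hi[d] + resolution / 2, resolution) for d in range(3)]
    shape = tuple(len(ax) for ax in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    cand_res = resolution / 2
    in_small = oracle_ses_mask(positions, radii, params.probe_small, pts, cand_res)
    in_big = oracle_ses_mask(positions, radii, params.probe_big, pts, cand_res)
    pocket = (in_big & ~in_small).reshape(shape)

    labels, n = ndi.label(pocket, structure=ndi.generate_binary_structure(3, connectivity_rank))
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    vols = sorted((float(c) * resolution ** 3 for c in counts), reverse=True)
    return vols
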