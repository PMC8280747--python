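"""Voxel-grid solvent-excluded surfaces (Connolly–Richards).

The region enclosed by the SES for a probe of radius r is the set of points
no rolling spherical probe of radius r can reach while clearing every van
der Waals sphere.  On the grid this is evaluated through the *clearance
field*

    A(y) = min_i ( |y - c_i| - R_i )

(the radius of the largest atom-free ball centered at voxel center y,
computed exactly per atom).  A voxel x is **outside** the SES iff some
voxel center y with A(y) > r covers x with a free ball:

    |x - y| < g(y),    g(y) = min( floor_delta(A(y)), cap ) <= A(y),

because a probe of radius r then fits inside that free ball while covering
x.  Witnesses are further restricted to the connected component of the
accessible region {A > r} that touches the domain boundary: the probe must
be able to roll in from bulk solvent, so sealed interior voids large
enough to host the probe still count as enclosed.  The coverage radius g
is quantized to multiples of delta = spacing/2 and capped, and — crucially
— does not depend on the probe radius, so for r1 < r2 the witness set only
shrinks (accessible regions and their bulk-connected parts nest) and
SES(r1) ⊆ SES(r2) holds voxel-wise by construction.  The test is
conservative (sub-voxel fattening of the enclosed region at the surface,
like any center-sampled closing) but never marks a truly enclosed point as
outside, and the vdW voxelization is contained exactly for every r >= 0.

``r = 0`` returns the van der Waals voxelization itself.  Coverage is
evaluated with one binary Euclidean distance transform per occupied
radius bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

#: Largest free-ball coverage radius used when marking outside regions (Å).
#: Must be shared by every probe compared on one grid; 6 Å comfortably
#: exceeds the default large probe.
DEFAULT_COVERAGE_CAP = 6.0


class GridError(ValueError):
    """Raised when a grid cannot be built or violates the padding contract."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: centers at ``origin + index * spacing`` (Å)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise GridError(f"spacing must be > 0, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise GridError(f"grid dims must be >= 1, got {self.dims}")

    @property
    def end(self) -> np.ndarray:
        """Position of the last voxel center on each axis."""
        return np.asarray(self.origin) + (np.asarray(self.dims) - 1) * self.spacing

    def axes(self) -> list[np.ndarray]:
        return [self.origin[d] + self.spacing * np.arange(self.dims[d])
                for d in range(3)]

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centers (Å) for an (M, 3) array of voxel indices."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * self.spacing

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3


@dataclass
class SESVolume:
    """Boolean occupancy of the region enclosed by the SES for one probe."""

    grid: GridSpec
    inside: np.ndarray
    probe_radius: float


def make_grid(positions: np.ndarray, radii: np.ndarray,
              spacing: float = 0.5, padding: float = 5.0) -> GridSpec:
    """Grid covering the atom spheres' bounding box expanded by ``padding`` (Å).

    ``padding`` must be at least the largest probe radius that will be used
    on this grid (the SES computation re-checks this contract).
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if positions.size == 0:
        raise GridError("cannot build a grid for an empty atom set")
    if spacing <= 0:
        raise GridError(f"spacing must be > 0, got {spacing}")
    if padding < 0:
        raise GridError(f"padding must be >= 0, got {padding}")
    lo = (positions - radii[:, None]).min(axis=0) - padding
    hi = (positions + radii[:, None]).max(axis=0) + padding
    dims = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return GridSpec(origin=tuple(lo), spacing=spacing, dims=dims)


def _mark_spheres(grid: GridSpec, positions: np.ndarray,
                  radii: np.ndarray) -> np.ndarray:
    """Boolean mask of voxels whose center lies inside any of the spheres."""
    mask = np.zeros(grid.dims, dtype=bool)
    axes = grid.axes()
    origin = np.asarray(grid.origin)
    h = grid.spacing
    for p, r in zip(positions, radii):
        lo_idx = np.maximum(np.ceil((p - r - origin) / h).astype(int), 0)
        hi_idx = np.minimum(np.floor((p + r - origin) / h).astype(int),
                            np.asarray(grid.dims) - 1)
        if np.any(lo_idx > hi_idx):
            continue
        sl = tuple(slice(lo_idx[d], hi_idx[d] + 1) for d in range(3))
        dx2 = (axes[0][sl[0]] - p[0]) ** 2
        dy2 = (axes[1][sl[1]] - p[1]) ** 2
        dz2 = (axes[2][sl[2]] - p[2]) ** 2
        sub = (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) <= r * r
        mask[sl] |= sub
    return mask


def clearance_field(grid: GridSpec, positions: np.ndarray, radii: np.ndarray,
                    cap: float = DEFAULT_COVERAGE_CAP) -> np.ndarray:
    """A(y) = min_i(|y - c_i| - R_i) at every voxel center, clipped to ``cap``.

    Values above ``cap`` are reported as ``cap`` (they are only used as
    free-ball radii, which are capped anyway).  Negative values mean the
    voxel center lies inside an atom sphere.
    """
    field = np.full(grid.dims, cap, dtype=np.float32)
    axes = grid.axes()
    origin = np.asarray(grid.origin)
    h = grid.spacing
    for p, r in zip(positions, radii):
        reach = r + cap + h
        lo_idx = np.maximum(np.ceil((p - reach - origin) / h).astype(int), 0)
        hi_idx = np.minimum(np.floor((p + reach - origin) / h).astype(int),
                            np.asarray(grid.dims) - 1)
        if np.any(lo_idx > hi_idx):
            continue
        sl = tuple(slice(lo_idx[d], hi_idx[d] + 1) for d in range(3))
        dx2 = (axes[0][sl[0]] - p[0]) ** 2
        dy2 = (axes[1][sl[1]] - p[1]) ** 2
        dz2 = (axes[2][sl[2]] - p[2]) ** 2
        d = np.sqrt(dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :])
        np.minimum(field[sl], (d - r).astype(np.float32), out=field[sl])
    return np.minimum(field, cap)


def _bulk_connected(accessible: np.ndarray) -> np.ndarray:
    """Part of an accessible-region mask reachable from the domain boundary.

    6-connectivity: adjacent centers are one spacing apart, so a chain of
    accessible centers approximates a continuous probe path.
    """
    labels, n = ndi.label(accessible, structure=ndi.generate_binary_structure(3, 1))
    if n == 0:
        return accessible
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels.update(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)
    if not boundary_labels:
        return np.zeros_like(accessible)
    return np.isin(labels, sorted(boundary_labels))


def compute_ses(positions: np.ndarray, radii: np.ndarray,
                probe_radius: float, grid: GridSpec,
                coverage_cap: float = DEFAULT_COVERAGE_CAP) -> SESVolume:
    """Region enclosed by the SES for one probe radius, on ``grid``."""
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if positions.size == 0:
        raise GridError("cannot compute an SES for an empty atom set")
    if probe_radius < 0:
        raise GridError(f"probe radius must be >= 0, got {probe_radius}")
    if probe_radius >= coverage_cap:
        raise GridError(
            f"probe radius {probe_radius} exceeds the coverage cap {coverage_cap}; "
            "raise coverage_cap")
    lo_req = (positions - (radii + probe_radius)[:, None]).min(axis=0)
    hi_req = (positions + (radii + probe_radius)[:, None]).max(axis=0)
    if np.any(np.asarray(grid.origin) > lo_req) or np.any(grid.end < hi_req):
        raise GridError(
            "padding contract violated: grid does not contain every atom sphere "
            f"inflated by the probe radius {probe_radius} Å")

    if probe_radius == 0:
        return SESVolume(grid, _mark_spheres(grid, positions, radii), 0.0)

    h = grid.spacing
    delta = h / 2.0
    clearance = clearance_field(grid, positions, radii, cap=coverage_cap)
    # probe-independent quantized coverage radii (multiples of delta)
    n_bins = int(round(coverage_cap / delta))
    bins = np.clip((clearance / delta).astype(np.int32), a_min=None, a_max=n_bins)
    witness = _bulk_connected(clearance > probe_radius + 1e-9)

    outside = np.zeros(grid.dims, dtype=bool)
    lo_bin = max(int(np.floor((probe_radius - 1e-9) / delta)), 1)
    for b in range(lo_bin, n_bins + 1):
        members = witness & (bins == b)
        if not members.any():
            continue
        dist = ndi.distance_transform_edt(~members, sampling=h)
        outside |= dist <= b * delta - 1e-9
    return SESVolume(grid, ~outside, probe_radius)


def enclosed_volume(ses: SESVolume) -> float:
    """Volume (Å³) enclosed by the SES: inside-voxel count × spacing³."""
    return float(ses.inside.sum()) * ses.grid.voxel_volume
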