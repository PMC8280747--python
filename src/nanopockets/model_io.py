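"""Structure and trajectory I/O for coated-nanoparticle systems.

Reads a topology (PDB/GRO/XYZ) and optional trajectory (XTC/DCD/multi-model
files) through MDAnalysis, assigns van der Waals radii and roles
(core | ligand | analyte | solvent | ion), parses the fragment-map
configuration that splits every coating ligand into its Inner / Central /
Outer chemical blocks, and reads/writes the tidy per-frame, per-pocket
result tables.

All coordinates are handled in Å internally (MDAnalysis converts nm-based
formats such as GRO on read).  Trajectories are assumed pre-imaged: no
periodic-boundary unwrapping is performed.
"""

from __future__ import annotations

import fnmatch
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ROLES = ("core", "ligand", "analyte", "solvent", "ion")
FRAGMENT_CLASSES = ("Inner", "Central", "Outer")

#: Bondi van der Waals radii (Å), with the common metal extensions.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "AU": 1.66, "AG": 1.72, "HE": 1.40,
    "B": 1.92, "SI": 2.10, "SE": 1.90, "ZN": 1.39, "CU": 1.40,
}

#: Standard atomic masses (u) for the elements we expect in these systems.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "AU": 196.967, "AG": 107.868,
    "B": 10.81, "SI": 28.085, "SE": 78.971, "ZN": 65.38, "CU": 63.546,
}


class StructureError(ValueError):
    """Raised for malformed inputs or contract violations during loading."""


@dataclass
class AtomRecord:
    """One atom of the (frame-constant) topology.

    ``ligand_index`` and ``fragment_class`` are populated for role=ligand
    atoms only; ``fragment_class`` is filled when a fragment map is applied.
    """

    atom_id: int
    element: str
    position: np.ndarray
    radius: float
    role: str
    ligand_index: int | None = None
    fragment_class: str | None = None
    name: str | None = None
    resname: str | None = None
    residue_index: int | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise StructureError(f"atom {self.atom_id}: unknown role {self.role!r}")
        if self.role in ("core", "ligand", "analyte") and not self.radius > 0:
            raise StructureError(f"atom {self.atom_id}: radius must be > 0, got {self.radius}")
        if self.fragment_class is not None and self.fragment_class not in FRAGMENT_CLASSES:
            raise StructureError(
                f"atom {self.atom_id}: fragment class {self.fragment_class!r} "
                f"not in {FRAGMENT_CLASSES}")


@dataclass
class Structure:
    """Array view of a subset of atoms at one frame, used by the geometry engine."""

    ids: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    roles: np.ndarray
    masses: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.ids)


@dataclass
class FrameSeries:
    """Per-frame coordinates over a constant atom list.

    ``frames[i]`` is an (n_atoms, 3) float array in Å.  ``frame_stride_ps``
    is metadata only (the sampling interval of the source trajectory).
    """

    atoms: list[AtomRecord]
    frames: list[np.ndarray]
    frame_stride_ps: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not self.frames:
            raise StructureError("FrameSeries needs at least one frame")
        for k, fr in enumerate(self.frames):
            fr = np.asarray(fr, dtype=float)
            if fr.shape != (n, 3):
                raise StructureError(
                    f"frame {k}: expected {(n, 3)} coordinates, got {fr.shape}")
            self.frames[k] = fr

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def indices(self, roles: Sequence[str] | None = None,
                include_hydrogens: bool = True) -> np.ndarray:
        sel = []
        for i, a in enumerate(self.atoms):
            if roles is not None and a.role not in roles:
                continue
            if not include_hydrogens and a.element.upper() == "H":
                continue
            sel.append(i)
        return np.asarray(sel, dtype=int)

    def structure(self, frame: int = 0, roles: Sequence[str] | None = ("core", "ligand"),
                  include_hydrogens: bool = True) -> Structure:
        """Array view of one frame restricted to the given roles.

        The default (core + ligand, hydrogens included) is the atom set the
        solvent-excluded surfaces are computed on: solvent and free ions are
        excluded, and analytes are guests, not part of the host surface.
        """
        idx = self.indices(roles, include_hydrogens)
        if idx.size == 0:
            raise StructureError(f"no atoms with roles {roles}")
        atoms = [self.atoms[i] for i in idx]
        pos = self.frames[frame][idx]
        return Structure(
            ids=np.array([a.atom_id for a in atoms], dtype=int),
            elements=np.array([a.element for a in atoms], dtype=object),
            positions=np.asarray(pos, dtype=float),
            radii=np.array([a.radius for a in atoms], dtype=float),
            roles=np.array([a.role for a in atoms], dtype=object),
            masses=np.array([a.mass if a.mass is not None
                             else ATOMIC_MASSES.get(a.element.upper(), 12.0)
                             for a in atoms], dtype=float),
        )

    def core_com(self, frame: int = 0) -> np.ndarray:
        """Mass-weighted center of mass of the metal core at one frame (Å)."""
        idx = self.indices(roles=("core",))
        if idx.size == 0:
            raise StructureError("depth analysis requested but no role=core atoms present")
        masses = np.array([self.atoms[i].mass if self.atoms[i].mass is not None
                           else ATOMIC_MASSES.get(self.atoms[i].element.upper(), 12.0)
                           for i in idx])
        pos = self.frames[frame][idx]
        return (pos * masses[:, None]).sum(axis=0) / masses.sum()


@dataclass
class FragmentMap:
    """atom_id -> (ligand_index, fragment_class) for every coating-ligand atom."""

    entries: dict[int, tuple[int, str]]
    n_ligands: int

    def ligand_of(self, atom_id: int) -> int | None:
        e = self.entries.get(atom_id)
        return None if e is None else e[0]

    def fragment_of(self, atom_id: int) -> tuple[int, str] | None:
        return self.entries.get(atom_id)


# ---------------------------------------------------------------------------
# element / radius assignment

def _element_from_name(name: str) -> str:
    """Guess a chemical element from an atom name (e.g. 'C12' -> 'C', 'AU' -> 'AU')."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        raise StructureError(f"cannot infer an element from atom name {name!r}")
    two = stripped[:2].upper()
    if two in BONDI_RADII:
        return two.capitalize() if len(two) == 2 else two
    return stripped[0].upper()


def assign_radius(element: str, atom_id: int | None = None,
                  overrides: Mapping | None = None) -> float:
    """Bondi radius for ``element``, honouring per-element and per-atom overrides."""
    overrides = overrides or {}
    per_atom = overrides.get("atoms", {})
    if atom_id is not None:
        for key in (atom_id, str(atom_id)):
            if key in per_atom:
                return float(per_atom[key])
    per_elem = {str(k).upper(): float(v)
                for k, v in overrides.get("elements", {}).items()}
    if element.upper() in per_elem:
        return per_elem[element.upper()]
    try:
        return BONDI_RADII[element.upper()]
    except KeyError:
        raise StructureError(
            f"no van der Waals radius for element {element!r}"
            + (f" (atom {atom_id})" if atom_id is not None else "")
            + "; add an override under radii.elements") from None


# ---------------------------------------------------------------------------
# role config matching

def _matches(rule: Mapping, name: str, resname: str, element: str,
             resid: int, index: int) -> bool:
    def _pat_any(patterns, value):
        value = (value or "").upper()
        return any(fnmatch.fnmatchcase(value, str(p).upper()) for p in patterns)

    if "elements" in rule and str(element).upper() in {str(e).upper() for e in rule["elements"]}:
        return True
    if "names" in rule and _pat_any(rule["names"], name):
        return True
    if "resnames" in rule and _pat_any(rule["resnames"], resname):
        return True
    if "resids" in rule and int(resid) in {int(r) for r in rule["resids"]}:
        return True
    if "indices" in rule and int(index) in {int(i) for i in rule["indices"]}:
        return True
    return False


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith(".json"):
            return json.loads(text)
        return yaml.safe_load(text)
    return dict(config)


def load_structure(topology_path, trajectory_path=None, role_config=None,
                   frame_stride_ps: float = 0.0) -> FrameSeries:
    """Read a structure and optional trajectory into a :class:`FrameSeries`.

    ``role_config`` is a mapping (or YAML/JSON path) with a ``roles`` section
    assigning every atom to exactly one role by element / atom-name /
    residue-name / resid / index selection, and an optional ``radii`` section
    of overrides.  Roles are matched in the fixed precedence order
    core > ligand > analyte > solvent > ion.
    """
    import MDAnalysis as mda

    if role_config is None:
        raise StructureError("role_config is required: every atom must be assigned a role")
    cfg = _load_config(role_config)
    role_rules = cfg.get("roles", {})
    radii_overrides = cfg.get("radii", {})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is not None:
            try:
                u = mda.Universe(str(topology_path), str(trajectory_path))
            except (ValueError, OSError, IOError) as exc:
                raise StructureError(
                    f"topology/trajectory mismatch or unreadable trajectory: {exc}") from exc
            if u.trajectory.n_atoms != len(u.atoms):
                raise StructureError(
                    f"atom-count mismatch: topology has {len(u.atoms)} atoms, "
                    f"trajectory frames have {u.trajectory.n_atoms}")
        else:
            u = mda.Universe(str(topology_path))

    names, resnames, resids, elements = [], [], [], []
    for at in u.atoms:
        name = getattr(at, "name", "") or ""
        names.append(name)
        resnames.append(getattr(at, "resname", "") or "")
        resids.append(int(getattr(at, "resid", 0) or 0))
        elem = getattr(at, "element", "") or ""
        if not elem.strip():
            elem = _element_from_name(name)
        elements.append(elem.strip().capitalize() if len(elem.strip()) > 1
                        else elem.strip().upper())

    roles, unassigned = [], []
    for i in range(len(u.atoms)):
        assigned = None
        for role in ROLES:
            rule = role_rules.get(role)
            if rule and _matches(rule, names[i], resnames[i], elements[i], resids[i], i):
                assigned = role
                break
        if assigned is None:
            unassigned.append(i)
        roles.append(assigned)
    if unassigned:
        shown = ", ".join(f"{i}:{names[i]}/{resnames[i]}" for i in unassigned[:20])
        raise StructureError(
            f"{len(unassigned)} atoms not assigned a role by role_config "
            f"(first shown as index:name/resname): {shown}")

    # ligand_index: enumeration of ligand residues in order of appearance
    lig_index_of_residue: dict[int, int] = {}
    residue_index = {at.index: int(at.residue.resindex) for at in u.atoms}
    for i in range(len(u.atoms)):
        if roles[i] == "ligand":
            r = residue_index[i]
            if r not in lig_index_of_residue:
                lig_index_of_residue[r] = len(lig_index_of_residue)

    atoms = []
    first_frame = u.atoms.positions.copy().astype(float)
    for i in range(len(u.atoms)):
        role = roles[i]
        if role in ("core", "ligand", "analyte"):
            radius = assign_radius(elements[i], i, radii_overrides)
        else:
            radius = float(BONDI_RADII.get(elements[i].upper(), 1.5))
        atoms.append(AtomRecord(
            atom_id=i, element=elements[i], position=first_frame[i],
            radius=radius, role=role,
            ligand_index=(lig_index_of_residue[residue_index[i]]
                          if role == "ligand" else None),
            name=names[i] or None, resname=resnames[i] or None,
            residue_index=residue_index[i],
            mass=ATOMIC_MASSES.get(elements[i].upper()),
        ))

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ts in u.trajectory:
            frames.append(u.atoms.positions.copy().astype(float))
    return FrameSeries(atoms=atoms, frames=frames, frame_stride_ps=frame_stride_ps)


# ---------------------------------------------------------------------------
# fragment map

def parse_fragment_map(config, frames: FrameSeries) -> FragmentMap:
    """Parse a fragment-map config and resolve it against the loaded ligands.

    The config declares, per ligand species (matched by residue name, or
    applying to all ligand residues when no ``resname`` is given), which atom
    names or within-residue index ranges belong to the Inner, Central and
    Outer fragments.  Every ligand atom must be claimed by exactly one
    fragment, and the three blocks must be contiguous along the ligand's
    declared atom order.  The parsed classes are written back onto the
    ``FrameSeries`` atom records.
    """
    cfg = _load_config(config)
    species = cfg.get("species")
    if not species:
        raise StructureError("fragment-map config needs a non-empty 'species' list")

    # group ligand atoms by residue, in atom order
    ligands: dict[int, list[AtomRecord]] = {}
    for a in frames.atoms:
        if a.role == "ligand":
            ligands.setdefault(a.residue_index, []).append(a)
    if not ligands:
        raise StructureError("no role=ligand atoms in the structure")

    entries: dict[int, tuple[int, str]] = {}
    lig_order = sorted(ligands, key=lambda r: min(a.atom_id for a in ligands[r]))
    for lig_idx, res in enumerate(lig_order):
        lig_atoms = ligands[res]
        resname = lig_atoms[0].resname or ""
        spec = None
        for sp in species:
            want = sp.get("resname")
            if want is None or str(want).upper() == resname.upper():
                spec = sp
                break
        if spec is None:
            raise StructureError(
                f"ligand residue {res} (resname {resname!r}) matches no species entry")

        frag_cfg = spec.get("fragments", {})
        classes_here: list[str | None] = [None] * len(lig_atoms)
        for cls in FRAGMENT_CLASSES:
            decl = frag_cfg.get(cls) or frag_cfg.get(cls.lower())
            if decl is None:
                continue
            member = [False] * len(lig_atoms)
            if "names" in decl:
                pats = [str(p).upper() for p in decl["names"]]
                for k, a in enumerate(lig_atoms):
                    if any(fnmatch.fnmatchcase((a.name or "").upper(), p) for p in pats):
                        member[k] = True
            if "indices" in decl:
                for item in decl["indices"]:
                    if isinstance(item, (list, tuple)):
                        lo, hi = int(item[0]), int(item[1])
                        for k in range(lo, hi + 1):
                            if 0 <= k < len(lig_atoms):
                                member[k] = True
                    else:
                        member[int(item)] = True
            for k, m in enumerate(member):
                if not m:
                    continue
                if classes_here[k] is not None:
                    raise StructureError(
                        f"atom {lig_atoms[k].atom_id} (ligand {lig_idx}) claimed by "
                        f"both {classes_here[k]} and {cls}")
                classes_here[k] = cls
        missing = [lig_atoms[k].atom_id for k, c in enumerate(classes_here) if c is None]
        if missing:
            raise StructureError(
                f"ligand {lig_idx}: atoms not covered by any fragment declaration: "
                f"{missing[:20]}")
        # contiguity of class blocks along the declared atom order
        runs = [classes_here[0]]
        for c in classes_here[1:]:
            if c != runs[-1]:
                runs.append(c)
        if len(runs) != len(set(runs)):
            raise StructureError(
                f"ligand {lig_idx}: fragment classes are not contiguous along the "
                f"ligand's atom order ({runs})")
        for k, a in enumerate(lig_atoms):
            entries[a.atom_id] = (lig_idx, classes_here[k])
            a.ligand_index = lig_idx
            a.fragment_class = classes_here[k]

    return FragmentMap(entries=entries, n_ligands=len(lig_order))


# ---------------------------------------------------------------------------
# pocket tables

TABLE_COLUMNS = [
    "frame", "pocket_id", "volume_A3",
    "center_x_A", "center_y_A", "center_z_A",
    "depth_nm", "depth_class", "n_ligands",
    "n_inner", "n_central", "n_outer", "fingerprint",
    "wall_atom_ids", "occupied", "analyte_ids",
]


@dataclass
class PocketTable:
    """Tidy per-(frame, pocket) records feeding all aggregate statistics."""

    df: pd.DataFrame
    n_frames: int
    frame_stride_ps: float = 0.0

    @classmethod
    def empty(cls, n_frames: int = 0, frame_stride_ps: float = 0.0) -> "PocketTable":
        return cls(pd.DataFrame(columns=TABLE_COLUMNS), n_frames, frame_stride_ps)

    @classmethod
    def from_pockets(cls, pockets: Iterable, n_frames: int,
                     frame_stride_ps: float = 0.0) -> "PocketTable":
        rows = []
        for p in pockets:
            fp = p.fingerprint
            rows.append({
                "frame": int(p.frame), "pocket_id": int(p.pocket_id),
                "volume_A3": float(p.volume),
                "center_x_A": float(p.center[0]), "center_y_A": float(p.center[1]),
                "center_z_A": float(p.center[2]),
                "depth_nm": (float(p.depth) if p.depth is not None else float("nan")),
                "depth_class": p.depth_class if p.depth_class is not None else "",
                "n_ligands": (int(p.n_ligands) if p.n_ligands is not None else -1),
                "n_inner": (int(fp.n_inner) if fp is not None else -1),
                "n_central": (int(fp.n_central) if fp is not None else -1),
                "n_outer": (int(fp.n_outer) if fp is not None else -1),
                "fingerprint": (f"{fp.n_inner}:{fp.n_central}:{fp.n_outer}"
                                if fp is not None else ""),
                "wall_atom_ids": ";".join(str(i) for i in sorted(p.wall_atom_ids)),
                "occupied": bool(p.occupied),
                "analyte_ids": ";".join(str(i) for i in sorted(p.analyte_ids)),
            })
        df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
        return cls(df, n_frames, frame_stride_ps)


def write_pocket_table(table: PocketTable, path, format: str | None = None) -> None:
    """Write a pocket table as CSV or JSON (lossless round-trip via JSON)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        table.df.to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "n_frames": int(table.n_frames),
            "frame_stride_ps": float(table.frame_stride_ps),
            "records": table.df.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1, default=_json_scalar))
    else:
        raise StructureError(f"unknown pocket-table format {fmt!r} (use csv or json)")


def _json_scalar(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def read_pocket_table(path, format: str | None = None) -> PocketTable:
    """Read a pocket table written by :func:`write_pocket_table`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path, keep_default_na=False,
                         dtype={"wall_atom_ids": str, "analyte_ids": str,
                                "fingerprint": str, "depth_class": str})
        if df.empty:
            df = pd.DataFrame(columns=TABLE_COLUMNS)
        else:
            df["occupied"] = df["occupied"].astype(str).str.lower().isin(("true", "1"))
            df["depth_nm"] = pd.to_numeric(df["depth_nm"], errors="coerce")
        n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        return PocketTable(df[TABLE_COLUMNS], n_frames)
    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        df = pd.DataFrame(payload["records"], columns=TABLE_COLUMNS)
        return PocketTable(df, int(payload["n_frames"]),
                           float(payload.get("frame_stride_ps", 0.0)))
    raise StructureError(f"unknown pocket-table format {fmt!r} (use csv or json)")
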