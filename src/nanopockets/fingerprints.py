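"""Pocket fingerprints: fragment composition of pocket walls.

A pocket's fingerprint is the triple (n_inner, n_central, n_outer) counting
the fragment *instances* — one per (ligand, fragment class) pair — that
contribute at least one atom to the pocket walls.  Pockets sharing a triple
are degenerate members of the same fingerprint class.  Metal-core wall
atoms are kept in the wall set but do not enter fingerprints.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .model_io import FragmentMap, PocketTable


class FingerprintError(ValueError):
    pass


class FingerprintKey(NamedTuple):
    n_inner: int
    n_central: int
    n_outer: int

    def __str__(self) -> str:
        return f"{self.n_inner}:{self.n_central}:{self.n_outer}"


def pocket_fingerprint(wall_atom_ids: Iterable[int],
                       fmap: FragmentMap) -> tuple[FingerprintKey, int]:
    """Fingerprint and distinct-ligand count for one pocket's wall atoms.

    A fragment instance (ligand_index, class) is counted once if any of its
    atoms is a wall atom.  Non-ligand wall atoms (e.g. core gold) are
    ignored; a wall set with no ligand atoms at all flags a core-only
    pocket, which is an error.
    """
    instances = set()
    for atom_id in wall_atom_ids:
        entry = fmap.fragment_of(int(atom_id))
        if entry is not None:
            instances.add(entry)
    if not instances:
        raise FingerprintError(
            "pocket walls contain no ligand atoms (core-only pocket?)")
    counts = {"Inner": 0, "Central": 0, "Outer": 0}
    for _lig, cls in instances:
        counts[cls] += 1
    n_ligands = len({lig for lig, _cls in instances})
    return FingerprintKey(counts["Inner"], counts["Central"], counts["Outer"]), n_ligands


def aggregate_fingerprints(records: PocketTable, top_k: int = 14) -> pd.DataFrame:
    """Rank fingerprints by abundance.

    Returns the ``top_k`` most populated fingerprint classes with their
    pocket count, percentage of all pockets, and cumulative percentage
    (ties broken by lexicographic key).  The default top_k of 14 matches the
    conventional report depth for these monolayers.
    """
    if top_k < 1:
        raise FingerprintError(f"top_k must be >= 1, got {top_k}")
    df = records.df
    cols = ["fingerprint", "count", "percent", "cumulative_percent"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    valid = df[df["fingerprint"] != ""]
    if valid.empty:
        return pd.DataFrame(columns=cols)
    keys = valid["fingerprint"].map(lambda s: tuple(int(x) for x in s.split(":")))
    counted = keys.value_counts().reset_index()
    counted.columns = ["key", "count"]
    counted = counted.sort_values(
        by=["count", "key"], ascending=[False, True], kind="mergesort")
    total = len(valid)
    counted["percent"] = 100.0 * counted["count"] / total
    counted["cumulative_percent"] = counted["percent"].cumsum()
    counted["fingerprint"] = counted["key"].map(lambda k: f"{k[0]}:{k[1]}:{k[2]}")
    return counted.head(top_k)[cols].reset_index(drop=True)


def fragment_occurrence(records: PocketTable) -> dict[str, float]:
    """Percent occurrence of each fragment class over all pocket walls.

    For each class: 100 × (sum of that class's fingerprint counts over all
    pockets) / (sum of all counts).  The three percentages sum to 100 up to
    rounding; an empty table yields zeros with ``empty=True`` flagged.
    """
    df = records.df
    valid = df[df["fingerprint"] != ""] if not df.empty else df
    if valid.empty:
        return {"Inner": 0.0, "Central": 0.0, "Outer": 0.0, "empty": True}
    sums = np.array([valid["n_inner"].sum(), valid["n_central"].sum(),
                     valid["n_outer"].sum()], dtype=float)
    total = sums.sum()
    pct = 100.0 * sums / total if total > 0 else np.zeros(3)
    return {"Inner": float(pct[0]), "Central": float(pct[1]),
            "Outer": float(pct[2]), "empty": False}


def mean_fragments_per_pocket(records: PocketTable) -> float:
    """Mean of (n_inner + n_central + n_outer) over all fingerprinted pockets."""
    df = records.df
    valid = df[df["fingerprint"] != ""] if not df.empty else df
    if valid.empty:
        return 0.0
    return float((valid["n_inner"] + valid["n_central"] + valid["n_outer"]).mean())
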