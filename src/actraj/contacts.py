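"""Interface contact maps, conserved-contact fractions, persistence, monitors.

A contact is defined at the residue level: two residues across the interface
partition are in contact when any pair of their heavy atoms is within the
cutoff (5 Å by default). Interface sides can be chain-id sets or arbitrary
pseudo-chain selections, so the same machinery serves both inter-molecular
(G-protein / cyclase) and inter-domain (C1 / C2) interfaces. Contact searches
run through a KD-tree; results are identical to brute-force enumeration.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import SelectionSpec, Structure, Trajectory, resolve_selection

__all__ = [
    "ContactMap",
    "PersistenceTable",
    "AtomSpec",
    "DistanceMonitor",
    "contact_map",
    "conserved_contact_series",
    "persistence_table",
    "distance_series",
    "MonitorResolutionError",
    "UndefinedReferenceError",
]

ResidueKey = tuple[str, int]
ContactPair = tuple[ResidueKey, ResidueKey]


class MonitorResolutionError(ValueError):
    """A distance-monitor atom spec resolved to zero or several atoms."""


class UndefinedReferenceError(ValueError):
    """Conserved-contact reference frame has no contacts."""


@dataclasses.dataclass(frozen=True)
class ContactMap:
    """Set of interface residue pairs, A-side first in each pair."""

    pairs: frozenset[ContactPair]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)

    def residues_a(self) -> set[ResidueKey]:
        return {p[0] for p in self.pairs}

    def residues_b(self) -> set[ResidueKey]:
        return {p[1] for p in self.pairs}


@dataclasses.dataclass
class PersistenceTable:
    """Per-pair and per-residue presence fractions across a trajectory."""

    pair_fraction: dict[ContactPair, float]
    residue_fraction: dict[ResidueKey, float]
    persistent_residues: tuple[ResidueKey, ...]
    threshold: float

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_a": a[0],
                "residue_a": a[1],
                "chain_b": b[0],
                "residue_b": b[1],
                "frame_fraction": f,
            }
            for (a, b), f in sorted(self.pair_fraction.items())
        ]
        return pd.DataFrame(
            rows, columns=["chain_a", "residue_a", "chain_b", "residue_b", "frame_fraction"]
        )

    def residues_frame(self) -> pd.DataFrame:
        persistent = set(self.persistent_residues)
        rows = [
            {
                "chain": k[0],
                "residue": k[1],
                "frame_fraction": f,
                "persistent": k in persistent,
            }
            for k, f in sorted(self.residue_fraction.items())
        ]
        return pd.DataFrame(rows, columns=["chain", "residue", "frame_fraction", "persistent"])


def _heavy_side_indices(structure: Structure, side) -> np.ndarray:
    if isinstance(side, SelectionSpec):
        idx = resolve_selection(structure, side)
    else:
        chains = {side} if isinstance(side, str) else set(side)
        if not chains:
            raise ValueError("empty chain set")
        idx = np.array(
            [i for i, a in enumerate(structure.atoms) if a.chain_id in chains], dtype=int
        )
    idx = np.array([i for i in idx if structure.atoms[i].is_heavy], dtype=int)
    if idx.size == 0:
        raise ValueError("interface side resolves to zero heavy atoms")
    return idx


def _pairs_from_coords(
    structure: Structure,
    coords: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    cutoff: float,
    atom_level: bool = False,
) -> frozenset:
    tree_a = cKDTree(coords[ia])
    tree_b = cKDTree(coords[ib])
    hits = tree_a.query_ball_tree(tree_b, cutoff)
    pairs = set()
    for k, neighbours in enumerate(hits):
        if not neighbours:
            continue
        atom_a = structure.atoms[ia[k]]
        for m in neighbours:
            atom_b = structure.atoms[ib[m]]
            if atom_level:
                pairs.add(
                    (
                        (atom_a.chain_id, atom_a.residue_number, atom_a.name),
                        (atom_b.chain_id, atom_b.residue_number, atom_b.name),
                    )
                )
            else:
                pairs.add((atom_a.residue_key, atom_b.residue_key))
    return frozenset(pairs)


def contact_map(
    structure: Structure,
    chains_A,
    chains_B,
    cutoff: float = 5.0,
    atom_level: bool = False,
) -> ContactMap:
    """Residue-level (or atom-level) cross-interface contact map.

    A pair is included when any heavy-atom pair across the A/B partition is at
    distance <= cutoff.
    """
    ia = _heavy_side_indices(structure, chains_A)
    ib = _heavy_side_indices(structure, chains_B)
    if np.intersect1d(ia, ib).size:
        raise ValueError("interface sides overlap")
    pairs = _pairs_from_coords(structure, structure.coords, ia, ib, cutoff, atom_level)
    return ContactMap(pairs=pairs, cutoff=cutoff)


def _trajectory_maps(
    trajectory: Trajectory,
    chains_A,
    chains_B,
    cutoff: float,
) -> list[frozenset]:
    topo = trajectory.topology
    ia = _heavy_side_indices(topo, chains_A)
    ib = _heavy_side_indices(topo, chains_B)
    if np.intersect1d(ia, ib).size:
        raise ValueError("interface sides overlap")
    return [
        _pairs_from_coords(topo, trajectory.frames[f], ia, ib, cutoff)
        for f in range(trajectory.n_frames)
    ]


def conserved_contact_series(
    trajectory: Trajectory,
    chains_A,
    chains_B,
    cutoff: float = 5.0,
    reference_frame: int = 0,
) -> pd.DataFrame:
    """Fraction of reference-frame contacts retained per frame, plus totals.

    The reference defaults to the first frame (the docked pose after
    equilibration). Columns: frame, time_ns, fraction, n_contacts.
    """
    if not 0 <= reference_frame < trajectory.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    maps = _trajectory_maps(trajectory, chains_A, chains_B, cutoff)
    ref = maps[reference_frame]
    if not ref:
        raise UndefinedReferenceError(
            f"reference frame {reference_frame} has no interface contacts"
        )
    fraction = np.array([len(m & ref) / len(ref) for m in maps])
    totals = np.array([len(m) for m in maps])
    return pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ns": trajectory.times_ns,
            "fraction": fraction,
            "n_contacts": totals,
        }
    )


def persistence_table(
    trajectory: Trajectory,
    chains_A,
    chains_B,
    cutoff: float = 5.0,
    threshold: float = 0.8,
) -> PersistenceTable:
    """Presence fractions of interface pairs and residues over a trajectory.

    A residue counts as present in a frame when it takes part in at least one
    interface pair; the persistent-residue list uses a strict ``> threshold``
    comparison (fractions exactly at the threshold are excluded).
    """
    maps = _trajectory_maps(trajectory, chains_A, chains_B, cutoff)
    n = len(maps)
    pair_counts: dict[ContactPair, int] = {}
    residue_counts: dict[ResidueKey, int] = {}
    for m in maps:
        seen: set[ResidueKey] = set()
        for pair in m:
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
            seen.update(pair)
        for key in seen:
            residue_counts[key] = residue_counts.get(key, 0) + 1
    pair_fraction = {p: c / n for p, c in pair_counts.items()}
    residue_fraction = {k: c / n for k, c in residue_counts.items()}
    persistent = tuple(sorted(k for k, f in residue_fraction.items() if f > threshold))
    return PersistenceTable(
        pair_fraction=pair_fraction,
        residue_fraction=residue_fraction,
        persistent_residues=persistent,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Distance monitors
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AtomSpec:
    """One named atom: chain, residue name (optional), residue number, atom name."""

    chain_id: str
    residue_number: int
    atom_name: str
    residue_name: str | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomSpec":
        """Parse ``A:LYS:1065:NZ`` (or ``A:1065:NZ`` without a residue name)."""
        parts = [p.strip() for p in text.strip().split(":")]
        if len(parts) == 4:
            chain, resname, resnum, name = parts
        elif len(parts) == 3:
            chain, resnum, name = parts
            resname = None
        else:
            raise ValueError(f"cannot parse atom spec {text!r}")
        return cls(
            chain_id=chain,
            residue_number=int(resnum),
            atom_name=name.upper(),
            residue_name=resname.upper() if resname else None,
        )

    def describe(self) -> str:
        resname = self.residue_name or "*"
        return f"{self.chain_id}:{resname}:{self.residue_number}:{self.atom_name}"

    def resolve(self, structure: Structure) -> int:
        hits = [
            i
            for i, a in enumerate(structure.atoms)
            if a.chain_id == self.chain_id
            and a.residue_number == self.residue_number
            and a.name == self.atom_name
            and (self.residue_name is None or a.residue_name == self.residue_name)
        ]
        if len(hits) != 1:
            raise MonitorResolutionError(
                f"atom spec {self.describe()} resolved to {len(hits)} atoms"
            )
        return hits[0]


@dataclasses.dataclass
class DistanceMonitor:
    """Labelled atom-pair distance monitor (e.g. active-site key contacts)."""

    label: str
    spec_a: AtomSpec
    spec_b: AtomSpec
    series: np.ndarray | None = None

    @classmethod
    def parse(cls, text: str) -> "DistanceMonitor":
        """Parse ``label: A:LYS:1065:NZ -- B:ATP:1:O2G``."""
        m = re.fullmatch(r"\s*([^:]+?)\s*:\s*(.+?)\s*--\s*(.+?)\s*", text)
        if not m:
            raise ValueError(f"cannot parse monitor {text!r}")
        return cls(
            label=m.group(1),
            spec_a=AtomSpec.parse(m.group(2)),
            spec_b=AtomSpec.parse(m.group(3)),
        )


def distance_series(
    trajectory: Trajectory,
    monitors: Sequence[DistanceMonitor],
) -> pd.DataFrame:
    """Per-frame Euclidean distances for each monitor.

    Returns a table with ``time_ns`` plus one column per monitor label; the
    monitors' ``series`` fields are filled in place.
    """
    data: dict[str, np.ndarray] = {"time_ns": trajectory.times_ns}
    for mon in monitors:
        i = mon.spec_a.resolve(trajectory.topology)
        j = mon.spec_b.resolve(trajectory.topology)
        d = np.linalg.norm(trajectory.frames[:, i, :] - trajectory.frames[:, j, :], axis=1)
        mon.series = d
        data[mon.label] = d
    return pd.DataFrame(data)
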