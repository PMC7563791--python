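"""Rigid-body superposition and RMSD/RMSF/average-structure machinery.

All fits are plain (unweighted) least-squares rigid superpositions computed
with the Kabsch algorithm; reflections are corrected so the result is always a
proper rotation. Fit and measure selections are independent, so the RMSD of a
domain can be evaluated after fitting on that same domain (the default) or any
other subset.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .model_io import (
    BACKBONE_ATOMS,
    SelectionSpec,
    Structure,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "SuperpositionResult",
    "PerResidueProfile",
    "kabsch",
    "rmsd_series",
    "average_structure",
    "rmsf_profile",
    "rmsf_per_atom",
    "profile_difference",
    "displacement_map",
    "DegenerateGeometryError",
    "InsufficientFramesError",
    "ProfileKeyMismatchError",
]


class DegenerateGeometryError(ValueError):
    """Point set too small or rank-deficient for a unique superposition."""


class InsufficientFramesError(ValueError):
    """Operation needs more trajectory frames than were provided."""


class ProfileKeyMismatchError(ValueError):
    """Two per-residue profiles do not share identical residue keys."""


@dataclasses.dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclasses.dataclass
class PerResidueProfile:
    """Ordered per-residue values keyed by (chain_id, residue_number)."""

    keys: tuple[tuple[str, int], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.keys) != self.values.size:
            raise ValueError("keys and values differ in length")

    def __getitem__(self, key: tuple[str, int]) -> float:
        return float(self.values[self.keys.index(key)])

    def __len__(self) -> int:
        return len(self.keys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [k[0] for k in self.keys],
                "residue": [k[1] for k in self.keys],
                "value": self.values,
            }
        )


def _check_rank(coords: np.ndarray, what: str) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size < 2 or s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError(f"{what}: points are collinear/degenerate")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Returns the proper rotation and translation minimizing the coordinate RMSD
    over all rigid transforms, together with the minimized RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"incompatible shapes {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    _check_rank(mobile, "mobile")
    _check_rank(reference, "reference")

    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.array([1.0, 1.0, d])
    rotation = (vt.T * flip) @ u.T
    # evaluate the RMSD on the transformed coordinates rather than through the
    # singular-value identity: the identity cancels catastrophically near zero
    rmsd = float(np.sqrt(np.mean(np.sum((p @ rotation.T - q) ** 2, axis=1))))
    translation = cr - rotation @ cm
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _resolve_pair(
    trajectory: Trajectory,
    reference: Structure,
    sel: SelectionSpec,
) -> tuple[np.ndarray, np.ndarray]:
    idx_t = resolve_selection(trajectory.topology, sel)
    idx_r = resolve_selection(reference, sel)
    if idx_t.size != idx_r.size:
        raise ValueError(
            f"selection {sel.describe()!r} resolves to {idx_t.size} atoms on the "
            f"trajectory but {idx_r.size} on the reference"
        )
    return idx_t, idx_r


def rmsd_series(
    trajectory: Trajectory,
    fit_sel: SelectionSpec,
    reference: Structure | None = None,
    measure_sel: SelectionSpec | None = None,
) -> pd.DataFrame:
    """Per-frame RMSD after least-squares fitting.

    Each frame is fitted on *fit_sel* and the RMSD evaluated on *measure_sel*
    (defaulting to the fit selection). The reference defaults to the iterative
    average structure, the convention used for time-averaged comparisons.
    Returns a table with columns ``time_ns`` and ``rmsd``.
    """
    if measure_sel is None:
        measure_sel = fit_sel
    if reference is None:
        reference = average_structure(trajectory, fit_sel)
    fit_t, fit_r = _resolve_pair(trajectory, reference, fit_sel)
    mea_t, mea_r = _resolve_pair(trajectory, reference, measure_sel)
    ref_fit = reference.coords[fit_r]
    ref_mea = reference.coords[mea_r]
    out = np.empty(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        sup = kabsch(trajectory.frames[i][fit_t], ref_fit)
        moved = sup.transform(trajectory.frames[i][mea_t])
        out[i] = np.sqrt(np.mean(np.sum((moved - ref_mea) ** 2, axis=1)))
    return pd.DataFrame({"time_ns": trajectory.times_ns, "rmsd": out})


def average_structure(
    trajectory: Trajectory,
    fit_sel: SelectionSpec,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> Structure:
    """Iterative average: fit all frames to the running mean until converged.

    Convergence is declared when the RMS displacement of the mean between
    iterations drops below *tol* Å (default well below PDB coordinate
    precision). On non-convergence a warning is issued and the last mean
    returned.
    """
    idx = resolve_selection(trajectory.topology, fit_sel)
    mean = trajectory.frames[0].copy()
    for _ in range(max_iter):
        fitted = np.empty_like(trajectory.frames)
        for i in range(trajectory.n_frames):
            sup = kabsch(trajectory.frames[i][idx], mean[idx])
            fitted[i] = sup.transform(trajectory.frames[i])
        new_mean = fitted.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    else:
        warnings.warn(
            f"average_structure did not converge below {tol} Å in {max_iter} iterations",
            RuntimeWarning,
        )
    return trajectory.topology.with_coords(mean)


def _fitted_frames(trajectory: Trajectory, target: np.ndarray, idx: np.ndarray) -> np.ndarray:
    fitted = np.empty_like(trajectory.frames)
    for i in range(trajectory.n_frames):
        sup = kabsch(trajectory.frames[i][idx], target[idx])
        fitted[i] = sup.transform(trajectory.frames[i])
    return fitted


def rmsf_per_atom(trajectory: Trajectory, fit_sel: SelectionSpec) -> np.ndarray:
    """Per-atom RMS fluctuation about the average structure after fitting."""
    if trajectory.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    idx = resolve_selection(trajectory.topology, fit_sel)
    avg = average_structure(trajectory, fit_sel)
    fitted = _fitted_frames(trajectory, avg.coords, idx)
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def _group_to_residues(structure: Structure, per_atom: np.ndarray) -> PerResidueProfile:
    """Residue-level profile: mean over backbone atoms, all atoms as fallback."""
    keys = structure.residue_keys()
    values = np.empty(len(keys))
    by_res: dict[tuple[str, int], list[int]] = {k: [] for k in keys}
    bb_by_res: dict[tuple[str, int], list[int]] = {k: [] for k in keys}
    for i, atom in enumerate(structure.atoms):
        by_res[atom.residue_key].append(i)
        if atom.name in BACKBONE_ATOMS:
            bb_by_res[atom.residue_key].append(i)
    for j, key in enumerate(keys):
        idx = bb_by_res[key] or by_res[key]
        values[j] = float(np.mean(per_atom[idx]))
    return PerResidueProfile(keys=tuple(keys), values=values)


def rmsf_profile(trajectory: Trajectory, fit_sel: SelectionSpec) -> PerResidueProfile:
    """Per-residue flexibility map: backbone-averaged atomic RMSF."""
    per_atom = rmsf_per_atom(trajectory, fit_sel)
    return _group_to_residues(trajectory.topology, per_atom)


def profile_difference(a: PerResidueProfile, b: PerResidueProfile) -> PerResidueProfile:
    """Elementwise a - b; values may be negative (flexibility changes)."""
    if a.keys != b.keys:
        only_a = set(a.keys) - set(b.keys)
        only_b = set(b.keys) - set(a.keys)
        raise ProfileKeyMismatchError(
            f"residue keys differ: only in a: {sorted(only_a)}; only in b: {sorted(only_b)}"
        )
    return PerResidueProfile(keys=a.keys, values=a.values - b.values)


def displacement_map(
    a: Structure,
    b: Structure,
    fit_sel: SelectionSpec,
) -> PerResidueProfile:
    """Per-residue displacement of *b* relative to *a* after fitting on *fit_sel*.

    Structures are matched on (chain, residue_number, atom name); *b* is
    rigidly fitted onto *a* using the atoms of *fit_sel* common to both, then
    each common residue reports the mean backbone-atom displacement.
    """
    index_a = {atom.key: i for i, atom in enumerate(a.atoms)}
    common = [(index_a[atom.key], j) for j, atom in enumerate(b.atoms) if atom.key in index_a]
    if not common:
        raise ValueError("structures share no common residues/atoms")
    ia = np.array([c[0] for c in common])
    ib = np.array([c[1] for c in common])

    fit_ia = set(resolve_selection(a, fit_sel))
    pair_fit = [(x, y) for x, y in common if x in fit_ia]
    if len(pair_fit) < 3:
        raise DegenerateGeometryError("fewer than 3 common atoms in the fit selection")
    fa = a.coords[[p[0] for p in pair_fit]]
    fb = b.coords[[p[1] for p in pair_fit]]
    sup = kabsch(fb, fa)
    moved_b = sup.transform(b.coords)

    disp = np.zeros(len(a))
    disp[ia] = np.sqrt(np.sum((moved_b[ib] - a.coords[ia]) ** 2, axis=1))
    common_res = {a.atoms[i].residue_key for i in ia}
    sub = a.subset([i for i in range(len(a)) if a.atoms[i].residue_key in common_res])
    disp_sub = disp[[i for i in range(len(a)) if a.atoms[i].residue_key in common_res]]
    return _group_to_residues(sub, disp_sub)
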