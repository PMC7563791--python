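"""Solvent-accessible surface area and interface-complementarity measures.

The SASA implementation is the slice-based Lee-Richards construction: each
atom's solvent-expanded sphere (van der Waals radius + probe) is cut into thin
z-slices; at each slice the fraction of the circle not covered by neighbouring
expanded circles is accumulated. By Archimedes' hat-box theorem a zone of a
sphere of radius R between two planes a height h apart has area 2*pi*R*h, so
the accessible contribution of a slice is R * h * (accessible angle), exact in
the angular direction -- the only discretization error is in z.

Interface complementarity follows the buried-surface convention: the change in
accessible surface area on complexation is dASA = ASA(A) + ASA(B) - ASA(AB),
the interface area is dASA/2 (single-sided), and the gap index is the
inter-chain gap volume divided by the interface area. Low gap indices mean
tight shape complementarity. The gap volume is a union of "gap spheres" grown
between surface atoms of the two chains, shrunk until they touch no atom, in
the style of the classic grid-based gap-analysis tools.

Hydrogens are excluded from all surface computation (united-atom radii).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .model_io import SelectionSpec, Structure, resolve_selection

__all__ = [
    "SasaResult",
    "GapParams",
    "InterfaceReport",
    "lee_richards_sasa",
    "gap_spheres",
    "union_volume_grid",
    "gap_volume",
    "interface_report",
]


@dataclasses.dataclass(frozen=True)
class SasaResult:
    """Per-atom and total solvent-accessible area in square Å."""

    per_atom: np.ndarray  # aligned with the structure's atoms; 0 for excluded atoms
    total: float
    probe_radius: float


@dataclasses.dataclass(frozen=True)
class GapParams:
    """Gap-sphere construction parameters (Å).

    Spheres starting above ``r_max`` are skipped, spheres shrinking below
    ``r_min`` are discarded, and the union volume is integrated on a cubic
    grid of spacing ``grid``.
    """

    r_min: float = 1.0
    r_max: float = 5.0
    grid: float = 0.5
    shrink_step: float = 0.1
    max_iter: int = 50

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be < r_max")
        if not self.grid > 0:
            raise ValueError("grid spacing must be > 0")


@dataclasses.dataclass(frozen=True)
class InterfaceReport:
    """Complementarity summary for a two-chain-set interface.

    ``gap_index`` is None when the chains make no contact (interface area is
    zero, so the ratio is undefined).
    """

    asa_A: float
    asa_B: float
    asa_AB: float
    delta_asa: float
    interface_area: float
    gap_volume: float
    gap_index: float | None


def _arc_union_length(starts: np.ndarray, widths: np.ndarray) -> float:
    """Total length of the union of arcs [start, start+width] on a circle."""
    if starts.size == 0:
        return 0.0
    if widths.sum() >= 2.0 * np.pi:
        # may still be < 2*pi after union, but do the exact merge below
        pass
    two_pi = 2.0 * np.pi
    s = np.mod(starts, two_pi)
    e = s + widths
    segs: list[tuple[float, float]] = []
    for a, b in zip(s, e):
        if b <= two_pi:
            segs.append((a, b))
        else:  # wraps around
            segs.append((a, two_pi))
            segs.append((0.0, b - two_pi))
    segs.sort()
    total = 0.0
    cur_a, cur_b = segs[0]
    for a, b in segs[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    total += cur_b - cur_a
    return min(total, two_pi)


def _dedupe_coords(coords: np.ndarray) -> np.ndarray:
    """Indices of unique atom positions; warns when exact duplicates exist."""
    _, first = np.unique(np.round(coords, 6), axis=0, return_index=True)
    if first.size < coords.shape[0]:
        warnings.warn(
            f"{coords.shape[0] - first.size} duplicate atom position(s) detected; "
            "treating each duplicate group as one atom",
            RuntimeWarning,
        )
    return np.sort(first)


def lee_richards_sasa(
    structure: Structure,
    probe: float = 1.4,
    slice_dz: float = 0.1,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Lee-Richards slice-integrated solvent-accessible surface area.

    Heavy atoms only by default (united-atom radii include the hydrogens).
    Atoms at exactly duplicated coordinates are counted once with a warning.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if not slice_dz > 0:
        raise ValueError("slice_dz must be > 0")
    keep = np.array(
        [include_hydrogens or a.is_heavy for a in structure.atoms], dtype=bool
    )
    idx = np.nonzero(keep)[0]
    coords = structure.coords[idx]
    radii = structure.vdw_radii[idx] + probe
    uniq = _dedupe_coords(coords)
    coords = coords[uniq]
    radii = radii[uniq]
    idx = idx[uniq]

    n = coords.shape[0]
    per_atom_kept = np.zeros(n)
    if n:
        tree = cKDTree(coords)
        rmax = radii.max()
        for i in range(n):
            per_atom_kept[i] = _atom_sasa(i, coords, radii, tree, rmax, slice_dz)
    per_atom = np.zeros(len(structure))
    per_atom[idx] = per_atom_kept
    return SasaResult(per_atom=per_atom, total=float(per_atom.sum()), probe_radius=probe)


def _atom_sasa(
    i: int,
    coords: np.ndarray,
    radii: np.ndarray,
    tree: cKDTree,
    rmax: float,
    dz: float,
) -> float:
    ri = radii[i]
    ci = coords[i]
    neigh = np.array(tree.query_ball_point(ci, ri + rmax), dtype=int)
    neigh = neigh[neigh != i]
    if neigh.size:
        d = np.linalg.norm(coords[neigh] - ci, axis=1)
        neigh = neigh[d < ri + radii[neigh]]
    ncoords = coords[neigh]
    nradii = radii[neigh]
    dxy = np.hypot(ncoords[:, 0] - ci[0], ncoords[:, 1] - ci[1]) if neigh.size else np.empty(0)
    theta = (
        np.arctan2(ncoords[:, 1] - ci[1], ncoords[:, 0] - ci[0]) if neigh.size else np.empty(0)
    )

    # slice edges across [zi - ri, zi + ri], last slice clamped
    edges = np.arange(ci[2] - ri, ci[2] + ri, dz)
    uppers = np.minimum(edges + dz, ci[2] + ri)
    heights = uppers - edges
    mids = 0.5 * (edges + uppers)

    area = 0.0
    for zc, h in zip(mids, heights):
        rc2 = ri * ri - (zc - ci[2]) ** 2
        if rc2 <= 0.0:
            continue
        rc = np.sqrt(rc2)
        if neigh.size:
            dzj = zc - ncoords[:, 2]
            active = np.abs(dzj) < nradii
            if active.any():
                rj = np.sqrt(nradii[active] ** 2 - dzj[active] ** 2)
                d = dxy[active]
                if np.any(d <= rj - rc):  # circle fully buried at this slice
                    continue
                ov = (d < rc + rj) & (d > np.abs(rc - rj))
                if ov.any():
                    cosa = (d[ov] ** 2 + rc2 - rj[ov] ** 2) / (2.0 * d[ov] * rc)
                    alpha = np.arccos(np.clip(cosa, -1.0, 1.0))
                    covered = _arc_union_length(theta[active][ov] - alpha, 2.0 * alpha)
                    area += ri * h * (2.0 * np.pi - covered)
                    continue
        area += ri * h * 2.0 * np.pi
    return area


# ---------------------------------------------------------------------------
# Gap volume
# ---------------------------------------------------------------------------


def _side_indices(structure: Structure, side) -> np.ndarray:
    """Heavy-atom indices of a chain set or a pseudo-chain SelectionSpec."""
    if isinstance(side, SelectionSpec):
        idx = resolve_selection(structure, side)
    else:
        chains = {side} if isinstance(side, str) else set(side)
        idx = np.array(
            [i for i, a in enumerate(structure.atoms) if a.chain_id in chains], dtype=int
        )
    idx = np.array([i for i in idx if structure.atoms[i].is_heavy], dtype=int)
    if idx.size == 0:
        raise ValueError("side selection resolves to zero heavy atoms")
    return idx


def gap_spheres(
    structure: Structure,
    chains_A,
    chains_B,
    params: GapParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Construct the retained inter-chain gap spheres (centres, radii).

    For every cross-interface atom pair a gap sphere is seeded midway between
    the van der Waals surfaces with radius (d - r_a - r_b)/2; pairs whose seed
    radius exceeds ``r_max`` (or is non-positive) are skipped. Each sphere is
    then shrunk in ``shrink_step`` decrements, recentred half a step away from
    the most-penetrating atom, until no atom of either chain penetrates it;
    spheres falling below ``r_min`` are discarded.
    """
    params = params or GapParams()
    ia = _side_indices(structure, chains_A)
    ib = _side_indices(structure, chains_B)
    if np.intersect1d(ia, ib).size:
        raise ValueError("chain sets A and B overlap")
    coords = structure.coords
    radii = structure.vdw_radii
    all_idx = np.concatenate([ia, ib])
    all_coords = coords[all_idx]
    all_radii = radii[all_idx]
    tree = cKDTree(all_coords)
    max_vdw = all_radii.max()

    pa = coords[ia]
    pb = coords[ib]
    ra = radii[ia]
    rb = radii[ib]
    diff = pb[None, :, :] - pa[:, None, :]
    dist = np.linalg.norm(diff, axis=2)
    seed_r = 0.5 * (dist - ra[:, None] - rb[None, :])
    cand = np.argwhere((seed_r > 0.0) & (seed_r <= params.r_max))

    centers: list[np.ndarray] = []
    out_radii: list[float] = []
    for i, j in cand:
        d = dist[i, j]
        u = diff[i, j] / d
        rg = seed_r[i, j]
        center = pa[i] + u * (ra[i] + rg)
        ok = False
        for _ in range(params.max_iter):
            near = tree.query_ball_point(center, rg + max_vdw)
            if near:
                dd = np.linalg.norm(all_coords[near] - center, axis=1)
                pen = all_radii[near] + rg - dd
                worst = int(np.argmax(pen))
                if pen[worst] <= 1e-9:
                    ok = True
                    break
                away = center - all_coords[near][worst]
                norm = np.linalg.norm(away)
                if norm > 1e-12:
                    center = center + (away / norm) * (0.5 * params.shrink_step)
                rg -= params.shrink_step
                if rg < params.r_min:
                    break
            else:
                ok = True
                break
        if ok and rg >= params.r_min:
            centers.append(center)
            out_radii.append(float(rg))
    if not centers:
        return np.zeros((0, 3)), np.zeros(0)
    return np.array(centers), np.array(out_radii)


def union_volume_grid(centers: np.ndarray, radii: np.ndarray, grid: float) -> float:
    """Volume of a union of spheres by counting cubic-grid cell centres."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if centers.shape[0] == 0:
        return 0.0
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    axes = [np.arange(lo[k] + 0.5 * grid, hi[k], grid) for k in range(3)]
    shape = tuple(ax.size for ax in axes)
    if 0 in shape:
        return 0.0
    occupied = np.zeros(shape, dtype=bool)
    for c, r in zip(centers, radii):
        # index window of cells this sphere can reach
        win = []
        for k in range(3):
            i0 = int(np.searchsorted(axes[k], c[k] - r))
            i1 = int(np.searchsorted(axes[k], c[k] + r, side="right"))
            if i0 >= i1:
                break
            win.append((i0, i1))
        if len(win) < 3:
            continue
        ax = [axes[k][w[0] : w[1]] - c[k] for k, w in enumerate(win)]
        local = (
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        ) <= r * r
        region = occupied[win[0][0] : win[0][1], win[1][0] : win[1][1], win[2][0] : win[2][1]]
        region |= local
    return int(occupied.sum()) * grid**3


def gap_volume(
    structure: Structure,
    chains_A,
    chains_B,
    params: GapParams | None = None,
) -> float:
    """Inter-chain gap volume in cubic Å (union of retained gap spheres)."""
    params = params or GapParams()
    centers, radii = gap_spheres(structure, chains_A, chains_B, params)
    return union_volume_grid(centers, radii, params.grid)


def interface_report(
    complex_structure: Structure,
    chains_A,
    chains_B,
    probe: float = 1.4,
    gap_params: GapParams | None = None,
    slice_dz: float = 0.1,
    min_interface_area: float = 1e-6,
) -> InterfaceReport:
    """ASA-based interface statistics plus gap volume / gap index.

    ASA of each chain set is computed in isolation, ASA of the complex on all
    atoms of both sets together; dASA = ASA_A + ASA_B - ASA_AB and the
    single-sided interface area is dASA/2. When the interface area is zero
    (chains out of contact) the gap index is reported as None.
    """
    ia = _side_indices(complex_structure, chains_A)
    ib = _side_indices(complex_structure, chains_B)
    if np.intersect1d(ia, ib).size:
        raise ValueError("chain sets A and B overlap")
    sub_a = complex_structure.subset(ia)
    sub_b = complex_structure.subset(ib)
    sub_ab = complex_structure.subset(np.concatenate([ia, ib]))
    asa_a = lee_richards_sasa(sub_a, probe=probe, slice_dz=slice_dz).total
    asa_b = lee_richards_sasa(sub_b, probe=probe, slice_dz=slice_dz).total
    asa_ab = lee_richards_sasa(sub_ab, probe=probe, slice_dz=slice_dz).total
    delta = asa_a + asa_b - asa_ab
    interface_area = 0.5 * delta
    vol = gap_volume(complex_structure, chains_A, chains_B, gap_params)
    index = vol / interface_area if interface_area > min_interface_area else None
    return InterfaceReport(
        asa_A=asa_a,
        asa_B=asa_b,
        asa_AB=asa_ab,
        delta_asa=delta,
        interface_area=interface_area,
        gap_volume=vol,
        gap_index=index,
    )
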