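"""Independent oracles used to cross-check the implementation modules.

Each oracle deliberately takes a different computational route from the code
under test: numerical quadrature instead of slice integration for surface
area, Monte-Carlo instead of grid counting for sphere-union volume, naive
re-scanning for greedy clustering, a hierarchical rotation grid search instead
of the closed-form superposition, and all-pairs enumeration instead of
KD-tree contact searches.
"""

from __future__ import annotations

import numpy as np


def fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (deterministic Fibonacci lattice)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    vdw_radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Point-counting SASA: fraction of test points on each expanded sphere
    not inside any other expanded sphere, times the sphere area."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(vdw_radii, dtype=float) + probe
    sphere = fibonacci_sphere(n_points)
    n = coords.shape[0]
    per_atom = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        free = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            free &= d2 > radii[j] ** 2
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * free.mean()
    return per_atom, float(per_atom.sum())


def mc_union_volume(
    centers: np.ndarray,
    radii: np.ndarray,
    n_points: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo volume of a union of spheres (uniform over the bounding box)."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if centers.shape[0] == 0:
        return 0.0
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    inside = np.zeros(n_points, dtype=bool)
    for c, r in zip(centers, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) <= r * r
    box = float(np.prod(hi - lo))
    return box * inside.mean()


def gromos_brute(matrix: np.ndarray, cutoff: float) -> list[list[int]]:
    """Naive greedy clustering: full neighbour re-scan every iteration.

    Neighbourhood rule rmsd <= cutoff, ties to the lowest frame index, the
    same stated contract as the implementation but executed with explicit
    python loops over an explicit remaining-set.
    """
    n = matrix.shape[0]
    remaining = list(range(n))
    clusters: list[list[int]] = []
    while remaining:
        best, best_count = None, -1
        for i in remaining:
            count = sum(1 for j in remaining if matrix[i, j] <= cutoff)
            if count > best_count:  # strict: first (lowest) index wins ties
                best, best_count = i, count
        members = [j for j in remaining if matrix[best, j] <= cutoff]
        clusters.append(members)
        remaining = [j for j in remaining if j not in members]
    return clusters


def _rotation_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def _rmsd_after(rot: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    # optimal translation for a fixed rotation aligns the centroids
    moved = p @ rot.T
    return float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rigid transforms via hierarchical rotation-grid search.

    Axes from a Fibonacci lattice x angles on a grid, refined locally over
    several levels down to ~0.05 deg; translation handled in closed form
    (centroid alignment). Independent of the SVD route.
    """
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)

    best_rmsd = np.inf
    best_axis = np.array([0.0, 0.0, 1.0])
    best_angle = 0.0
    axes = fibonacci_sphere(200)
    for axis in axes:
        for angle in np.deg2rad(np.arange(0.0, 181.0, 10.0)):
            r = _rmsd_after(_rotation_axis_angle(axis, angle), p, q)
            if r < best_rmsd:
                best_rmsd, best_axis, best_angle = r, axis, angle

    # local refinement: shrink the axis cone and the angle window
    axis_step = 0.3  # radians of axis perturbation
    angle_step = np.deg2rad(10.0)
    for _ in range(8):
        for da in np.linspace(-axis_step, axis_step, 5):
            for db in np.linspace(-axis_step, axis_step, 5):
                # perturb the axis in its tangent plane
                t1 = np.cross(best_axis, [1.0, 0.3, 0.7])
                t1 /= np.linalg.norm(t1)
                t2 = np.cross(best_axis, t1)
                axis = best_axis + da * t1 + db * t2
                axis /= np.linalg.norm(axis)
                for dang in np.linspace(-angle_step, angle_step, 7):
                    angle = best_angle + dang
                    r = _rmsd_after(_rotation_axis_angle(axis, angle), p, q)
                    if r < best_rmsd:
                        best_rmsd, best_axis, best_angle = r, axis, angle
        axis_step *= 0.4
        angle_step *= 0.4
    return best_rmsd


def brute_contact_pairs(structure, ia, ib, cutoff: float) -> frozenset:
    """All-pairs residue contact enumeration (no spatial acceleration)."""
    pairs = set()
    coords = structure.coords
    for i in ia:
        ai = structure.atoms[i]
        for j in ib:
            aj = structure.atoms[j]
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.add((ai.residue_key, aj.residue_key))
    return frozenset(pairs)
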