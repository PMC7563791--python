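"""Synthetic structures and trajectories with planted, recoverable properties.

The microsecond MD trajectories these analyses were designed for are not
publicly deposited, so every generator here plants a known ground truth --
helix crossing angles, interface gaps, conformational substates, noise levels
-- that the analysis modules must recover within stated tolerances. The
generators emulate the relevant geometry of a two-domain cyclase catalytic
core with a bound G-protein chain; they make no attempt at force-field realism
(side chains are omitted, noise is isotropic Gaussian, substates are rigid
displacements).

All randomness is drawn from ``numpy.random.default_rng(seed)``; a fixed seed
reproduces outputs exactly, including written PDB files.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .model_io import (
    DEFAULT_RADII,
    DEFAULT_RADIUS,
    Atom,
    SelectionSpec,
    Structure,
    Trajectory,
    resolve_selection,
)
from .superpose import kabsch

__all__ = [
    "make_ideal_helix",
    "make_helix_pair",
    "make_two_chain_complex",
    "make_multistate_trajectory",
    "make_random_structure",
    "make_perturbed_state",
    "make_analysis_fixture",
    "PackingError",
]


class PackingError(RuntimeError):
    """Random placement could not satisfy the minimum-separation constraint."""


def _radius(element: str) -> float:
    return DEFAULT_RADII.get(element.upper(), DEFAULT_RADIUS)


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to *direction* (Rodrigues construction)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# Backbone stub placement on helical sub-lattices: (radius Å, phase offset deg,
# z offset Å) per atom name, approximating ideal alpha-helix internal geometry.
_BACKBONE_LATTICE = {
    "N": (1.55, -28.0, -0.57),
    "CA": (None, 0.0, 0.0),  # radius taken from the helix parameter
    "C": (1.52, 26.0, 0.51),
    "O": (2.00, 38.0, 1.40),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def make_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    chain_id: str = "A",
    start_res: int = 1,
    residue_name: str = "ALA",
    serial_start: int = 1,
) -> Structure:
    """Ideal alpha-helical backbone (N, CA, C, O stubs) along *direction*.

    C-alpha atoms sit exactly on a helix of the stated rise, twist and radius;
    the other backbone atoms sit on companion helical lattices at canonical
    offsets. The helix starts at *origin* (position of the first residue's
    C-alpha projection onto the axis).
    """
    if n_res < 4:
        raise ValueError(f"need n_res >= 4, got {n_res}")
    rot = _rotation_to(direction)
    origin = np.asarray(origin, dtype=float)
    atoms: list[Atom] = []
    serial = serial_start
    for k in range(n_res):
        theta0 = math.radians(twist * k)
        z0 = rise * k
        for name in ("N", "CA", "C", "O"):
            r_off, phase, dz = _BACKBONE_LATTICE[name]
            r = radius if r_off is None else r_off
            theta = theta0 + math.radians(phase)
            local = np.array([r * math.cos(theta), r * math.sin(theta), z0 + dz])
            pos = rot @ local + origin
            element = _BACKBONE_ELEMENTS[name]
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name=residue_name,
                    residue_number=start_res + k,
                    chain_id=chain_id,
                    position=tuple(float(x) for x in pos),
                    vdw_radius=_radius(element),
                )
            )
            serial += 1
    return Structure(atoms, metadata={"generator": "ideal_helix", "n_res": n_res})


def _recentre_calpha(structure: Structure, target: np.ndarray) -> Structure:
    ca = resolve_selection(structure, SelectionSpec(atom_class="calpha"))
    shift = np.asarray(target, dtype=float) - structure.coords[ca].mean(axis=0)
    return structure.with_coords(structure.coords + shift)


def make_helix_pair(
    angle: float,
    center_separation: float,
    n_res: int = 18,
    seed: int = 0,
) -> Structure:
    """Two ideal helices at an exact planted crossing angle and separation.

    Chain A runs along +z with its C-alpha centroid at the origin; chain B's
    axis is rotated by *angle* degrees about x and its centroid placed at
    (*center_separation*, 0, 0). A separation below 4 Å raises a clash
    warning.
    """
    if not 0.0 <= angle <= 180.0:
        raise ValueError("angle must be in [0, 180] degrees")
    if center_separation < 4.0:
        import warnings

        warnings.warn(
            f"centre separation {center_separation} Å risks steric clash", RuntimeWarning
        )
    a = make_ideal_helix(n_res, chain_id="A")
    a = _recentre_calpha(a, np.zeros(3))
    ang = math.radians(angle)
    direction_b = (0.0, math.sin(ang), math.cos(ang))
    b = make_ideal_helix(n_res, chain_id="B", direction=direction_b, serial_start=len(a.atoms) + 1)
    b = _recentre_calpha(b, np.array([center_separation, 0.0, 0.0]))
    return Structure(
        a.atoms + b.atoms,
        metadata={"generator": "helix_pair", "angle": angle, "separation": center_separation},
    )


def make_two_chain_complex(
    n_atoms_per_chain: int,
    surface_gap: float,
    seed: int = 0,
    spacing: float = 4.0,
    xy_jitter: float = 0.5,
) -> Structure:
    """Two parallel atom slabs with an exact nearest-surface separation.

    Carbon pseudo-atoms (one residue each) are laid out on a jittered square
    grid; chain B sits directly above chain A so the nearest van der Waals
    surface separation equals *surface_gap* exactly. Contacts, buried surface
    and gap volume all vary monotonically with the gap.
    """
    if surface_gap < 0:
        raise ValueError("surface_gap must be >= 0")
    rng = np.random.default_rng(seed)
    r = _radius("C")
    side = math.ceil(math.sqrt(n_atoms_per_chain))
    xs, ys = np.meshgrid(np.arange(side) * spacing, np.arange(side) * spacing, indexing="ij")
    grid = np.column_stack([xs.ravel(), ys.ravel()])[:n_atoms_per_chain]
    jitter = rng.uniform(-xy_jitter, xy_jitter, size=grid.shape)
    xy = grid + jitter  # shared between chains: nearest pair is exactly vertical
    z_b = 2.0 * r + surface_gap
    atoms: list[Atom] = []
    serial = 1
    for chain_id, z in (("A", 0.0), ("B", z_b)):
        for i, (x, y) in enumerate(xy):
            atoms.append(
                Atom(
                    serial=serial,
                    name="CA",
                    element="C",
                    residue_name="GLY",
                    residue_number=i + 1,
                    chain_id=chain_id,
                    position=(float(x), float(y), float(z)),
                    vdw_radius=r,
                )
            )
            serial += 1
    return Structure(
        atoms,
        metadata={"generator": "two_chain_complex", "surface_gap": surface_gap, "seed": seed},
    )


def make_perturbed_state(
    structure: Structure,
    target_rmsd: float,
    seed: int = 0,
    sel: SelectionSpec | None = None,
) -> Structure:
    """A conformational substate at a planted fitted RMSD from *structure*.

    A random Gaussian displacement field is applied to the selected atoms and
    rescaled (a few fixed-point iterations) until the least-squares-fitted
    RMSD on the selection matches *target_rmsd*.
    """
    rng = np.random.default_rng(seed)
    sel = sel or SelectionSpec()
    idx = resolve_selection(structure, sel)
    disp = np.zeros_like(structure.coords)
    disp[idx] = rng.normal(0.0, 1.0, size=(idx.size, 3))
    scale = target_rmsd / max(np.sqrt(np.mean(np.sum(disp[idx] ** 2, axis=1))), 1e-12)
    coords = structure.coords
    for _ in range(6):
        moved = coords + scale * disp
        rmsd = kabsch(moved[idx], coords[idx]).rmsd
        if abs(rmsd - target_rmsd) < 1e-6:
            break
        scale *= target_rmsd / max(rmsd, 1e-12)
    return structure.with_coords(coords + scale * disp)


def _block_lengths_from_occupancies(occupancies: Sequence[float], n_frames: int) -> list[int]:
    occ = np.asarray(occupancies, dtype=float)
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancies sum to {occ.sum()}, expected 1")
    base = np.floor(occ * n_frames).astype(int)
    remainder = n_frames - base.sum()
    # largest-remainder apportionment, ties to the lowest state index
    frac = occ * n_frames - base
    order = np.argsort(-frac, kind="stable")
    for k in range(remainder):
        base[order[k]] += 1
    return base.tolist()


def make_multistate_trajectory(
    states: Sequence[Structure],
    occupancies: Sequence[float] | None = None,
    n_frames: int | None = None,
    noise_sigma: float = 0.0,
    dt_ns: float = 1.0,
    seed: int = 0,
    block_lengths: Sequence[tuple[int, int]] | None = None,
    t0_ns: float = 0.0,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory visiting planted states in contiguous blocks, plus labels.

    Either *occupancies* with *n_frames* (one contiguous block per state, in
    the given order) or explicit *block_lengths* as (state_index, n_frames)
    pairs. Isotropic Gaussian noise of *noise_sigma* Å is added independently
    to every coordinate. Returns the trajectory and the per-frame state
    labels for recovery scoring.
    """
    if not states:
        raise ValueError("need at least one state")
    n_atoms = len(states[0])
    keys0 = [a.key for a in states[0].atoms]
    for s in states[1:]:
        if len(s) != n_atoms or [a.key for a in s.atoms] != keys0:
            raise ValueError("states do not share a common topology")
    if block_lengths is None:
        if occupancies is None or n_frames is None:
            raise ValueError("provide either block_lengths or occupancies with n_frames")
        lengths = _block_lengths_from_occupancies(occupancies, n_frames)
        block_lengths = [(i, n) for i, n in enumerate(lengths) if n > 0]
    rng = np.random.default_rng(seed)
    labels: list[int] = []
    frames: list[np.ndarray] = []
    for state_idx, count in block_lengths:
        base = states[state_idx].coords
        for _ in range(count):
            noise = rng.normal(0.0, noise_sigma, size=base.shape) if noise_sigma > 0 else 0.0
            frames.append(base + noise)
            labels.append(state_idx)
    traj = Trajectory(states[0], np.array(frames), dt_ns=dt_ns, t0_ns=t0_ns)
    return traj, np.array(labels)


def make_random_structure(
    n_atoms: int,
    box: float,
    min_separation: float,
    seed: int = 0,
    element: str = "C",
    chain_id: str = "A",
) -> Structure:
    """Uniform random atoms in a cubic box with a minimum pairwise separation."""
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    max_tries = 10_000 * max(n_atoms, 1)
    tries = 0
    while len(coords) < n_atoms:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"could not place {n_atoms} atoms with separation {min_separation} in a "
                f"{box} Å box after {max_tries} attempts"
            )
        p = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(p - q) >= min_separation for q in coords):
            coords.append(p)
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element=element,
            residue_name="GLY",
            residue_number=i + 1,
            chain_id=chain_id,
            position=tuple(float(x) for x in p),
            vdw_radius=_radius(element),
        )
        for i, p in enumerate(coords)
    ]
    return Structure(atoms, metadata={"generator": "random_structure", "seed": seed})


# ---------------------------------------------------------------------------
# Composite fixture for the end-to-end pipeline
# ---------------------------------------------------------------------------


def _renumber_chain(structure: Structure, chain_id: str, serial_start: int) -> list[Atom]:
    import dataclasses as _dc

    out = []
    serial = serial_start
    for a in structure.atoms:
        out.append(_dc.replace(a, chain_id=chain_id, serial=serial))
        serial += 1
    return out


def make_analysis_fixture(
    seed: int = 0,
    n_frames: int = 40,
    dt_ns: float = 50.0,
    noise_sigma: float = 0.1,
    equilibration_ns: float = 400.0,
) -> tuple[Trajectory, np.ndarray, dict]:
    """A small two-domain/G-protein system with planted substate structure.

    Layout: chain A (domain "C1") and chain B (domain "C2") are each a pair of
    ideal helices (residues 1-18 and 30-47) in contact across a narrow
    interface; chain G is a flat pseudo-G-protein slab touching chain A. The
    trajectory spends its equilibration segment in a displaced conformation
    (so equilibration skipping is observable), then alternates between two
    production substates differing by a ~3 Å backbone displacement of domain
    C2, with isotropic Gaussian coordinate noise on top.

    Returns (trajectory, planted labels, analysis-config dict); the config is
    ready for the pipeline once its ``trajectory`` key is pointed at a written
    multi-model PDB.
    """
    # domain C1: helix pair, chain A
    a1 = make_ideal_helix(18, chain_id="A", start_res=1)
    a1 = _recentre_calpha(a1, np.zeros(3))
    a2 = make_ideal_helix(
        18, chain_id="A", start_res=30, direction=(0.0, math.sin(0.5), math.cos(0.5))
    )
    a2 = _recentre_calpha(a2, np.array([11.0, 0.0, 0.0]))
    chain_a = Structure(a1.atoms + _renumber_chain(a2, "A", len(a1.atoms) + 1))

    # domain C2: same pair translated into contact along +y
    chain_b_atoms = _renumber_chain(
        chain_a.with_coords(chain_a.coords + np.array([0.0, 10.0, 0.0])),
        "B",
        len(chain_a.atoms) + 1,
    )

    # pseudo-G-protein: slab below chain A
    slab = make_two_chain_complex(36, 0.5, seed=seed)
    g_idx = [i for i, at in enumerate(slab.atoms) if at.chain_id == "A"]
    g_sub = slab.subset(g_idx)
    g_coords = g_sub.coords.copy()
    # rotate the slab plane normal from z to y, put it at y = -6.5
    g_coords = g_coords[:, [0, 2, 1]] * np.array([1.0, 1.0, -1.0])
    g_coords += np.array([-6.0, -6.5, -12.0])
    g_atoms = _renumber_chain(
        g_sub.with_coords(g_coords), "G", len(chain_a.atoms) + len(chain_b_atoms) + 1
    )

    base = Structure(chain_a.atoms + chain_b_atoms + g_atoms)

    # substate 1: domain C2 displaced by ~3 Å fitted backbone RMSD
    state1 = make_perturbed_state(
        base, 3.0, seed=seed + 1, sel=SelectionSpec(chains=frozenset("B"), atom_class="backbone")
    )
    # equilibration conformation: a third, clearly distinct placement
    state2 = make_perturbed_state(
        base, 4.5, seed=seed + 2, sel=SelectionSpec(chains=frozenset("B"), atom_class="backbone")
    )

    n_equil = int(equilibration_ns // dt_ns)
    n_prod = n_frames - n_equil
    if n_prod < 4:
        raise ValueError("n_frames leaves too few production frames after equilibration")
    n0 = int(round(0.6 * n_prod))
    blocks = [(2, n_equil), (0, n0), (1, n_prod - n0)]
    traj, labels = make_multistate_trajectory(
        [base, state1, state2],
        block_lengths=blocks,
        noise_sigma=noise_sigma,
        dt_ns=dt_ns,
        seed=seed,
    )
    config = {
        "dt_ns": dt_ns,
        "equilibration_ns": equilibration_ns,
        "seed": seed,
        "domains": {"c1": "chain=A", "c2": "chain=B", "gprotein": "chain=G"},
        "helices": {
            "c1_a": "chain=A; resid=1-18; atoms=calpha",
            "c1_b": "chain=A; resid=30-47; atoms=calpha",
            "c2_a": "chain=B; resid=1-18; atoms=calpha",
            "c2_b": "chain=B; resid=30-47; atoms=calpha",
        },
        "cluster": {"selection": "chain=B; atoms=backbone", "cutoff": 1.5, "min_dwell_ns": 100.0},
        "contacts": {"side_a": "chain=G", "side_b": "chain=A", "cutoff": 5.0, "persistence_threshold": 0.8},
        "interface": {
            "side_a": "chain=A",
            "side_b": "chain=B",
            "probe": 1.4,
            "stride": 10,
            "gap": {"r_min": 1.0, "r_max": 5.0, "grid": 0.5},
        },
        "monitors": [
            "groove_gap: A:ALA:5:CA -- B:ALA:5:CA",
            "gprot_anchor: G:GLY:1:CA -- A:ALA:1:CA",
        ],
    }
    return traj, labels, config
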