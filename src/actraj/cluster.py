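"""GROMOS conformational clustering with dwell-time filtering.

The algorithm is the classic greedy scheme: the frame with the most neighbours
within an RMSD cutoff becomes a cluster centre, the centre and its neighbours
are removed, and the process repeats on the remaining frames. Cluster dwell
time is member count times the frame interval; clusters whose dwell time is
strictly below the threshold are marked discarded (a dwell exactly at the
threshold is retained). The representative member is the medoid by default,
i.e. the member minimizing summed RMSD to its co-members; the greedy centre is
also stored for the alternative "most neighbours" reading of a cluster centre.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model_io import SelectionSpec, Structure, Trajectory, resolve_selection

__all__ = [
    "Cluster",
    "ClusterSet",
    "pairwise_rmsd",
    "gromos_cluster",
    "representative_structure",
    "MatrixTooLargeError",
]

MAX_FRAMES = 20_000


class MatrixTooLargeError(ValueError):
    """Pairwise matrix would exceed the supported in-memory frame count."""


@dataclasses.dataclass(frozen=True)
class Cluster:
    id: int
    members: tuple[int, ...]  # frame indices, ascending
    dwell_ns: float
    representative: int  # medoid frame index
    center: int  # greedy centre (most-neighbours frame)
    retained: bool

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class ClusterSet:
    """Partition of trajectory frames into conformational clusters."""

    clusters: tuple[Cluster, ...]  # ordered by size descending
    assignments: np.ndarray  # frame index -> cluster id
    cutoff: float
    dt_ns: float
    min_dwell_ns: float
    selection: SelectionSpec | None = None

    @property
    def retained_clusters(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.retained)

    @property
    def n_frames(self) -> int:
        return int(self.assignments.size)

    def labels(self, discarded: int = -1) -> np.ndarray:
        """Per-frame cluster ids with discarded clusters mapped to *discarded*."""
        keep = {c.id for c in self.retained_clusters}
        return np.array([a if a in keep else discarded for a in self.assignments])

    def cluster(self, cluster_id: int) -> Cluster:
        for c in self.clusters:
            if c.id == cluster_id:
                return c
        raise KeyError(f"unknown cluster id {cluster_id}")

    def summary(self) -> pd.DataFrame:
        n = self.n_frames
        return pd.DataFrame(
            {
                "cluster_id": [c.id for c in self.clusters],
                "size": [c.size for c in self.clusters],
                "percent": [100.0 * c.size / n for c in self.clusters],
                "dwell_ns": [c.dwell_ns for c in self.clusters],
                "retained": [c.retained for c in self.clusters],
                "representative_frame": [c.representative for c in self.clusters],
                "center_frame": [c.center for c in self.clusters],
            }
        )

    def to_frame(self, t0_ns: float = 0.0) -> pd.DataFrame:
        reps = {c.representative for c in self.clusters}
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_ns": t0_ns + self.dt_ns * np.arange(self.n_frames),
                "cluster_id": self.labels(),
                "is_representative": [i in reps for i in range(self.n_frames)],
            }
        )


def pairwise_rmsd(trajectory: Trajectory, sel: SelectionSpec) -> np.ndarray:
    """Symmetric matrix of least-squares-fitted RMSDs between all frame pairs."""
    n = trajectory.n_frames
    if n < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    if n > MAX_FRAMES:
        raise MatrixTooLargeError(f"{n} frames exceed the supported maximum of {MAX_FRAMES}")
    idx = resolve_selection(trajectory.topology, sel)
    coords = trajectory.frames[:, idx, :]
    centered = coords - coords.mean(axis=1, keepdims=True)
    ssq = np.einsum("fij,fij->f", centered, centered)
    m = idx.size
    matrix = np.zeros((n, n))
    for i in range(n - 1):
        # cross-covariances of frame i against all later frames at once
        h = np.einsum("ai,faj->fij", centered[i], centered[i + 1 :])
        s = np.linalg.svd(h, compute_uv=False)
        det = np.linalg.det(h)
        s[:, 2] = np.where(det < 0, -s[:, 2], s[:, 2])
        msd = (ssq[i] + ssq[i + 1 :] - 2.0 * s.sum(axis=1)) / m
        matrix[i, i + 1 :] = matrix[i + 1 :, i] = np.sqrt(np.clip(msd, 0.0, None))
    return matrix


def gromos_cluster(
    matrix: np.ndarray,
    cutoff: float,
    dt_ns: float,
    min_dwell_ns: float = 100.0,
    selection: SelectionSpec | None = None,
) -> ClusterSet:
    """Greedy GROMOS clustering of a pairwise RMSD matrix.

    Neighbourhood is inclusive (``rmsd <= cutoff``); ties in neighbour count
    are broken toward the lowest frame index so results are deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1] or matrix.shape[0] == 0:
        raise ValueError(f"need a non-empty square matrix, got shape {matrix.shape}")
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    n = matrix.shape[0]
    adjacency = matrix <= cutoff
    np.fill_diagonal(adjacency, True)

    remaining = np.ones(n, dtype=bool)
    raw: list[tuple[int, np.ndarray]] = []  # (centre, member frame indices)
    while remaining.any():
        counts = (adjacency & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(adjacency[center] & remaining)[0]
        raw.append((center, members))
        remaining[members] = False

    order = sorted(range(len(raw)), key=lambda k: (-raw[k][1].size, k))
    clusters: list[Cluster] = []
    assignments = np.empty(n, dtype=int)
    for new_id, k in enumerate(order, start=1):
        center, members = raw[k]
        sub = matrix[np.ix_(members, members)]
        medoid = int(members[np.argmin(sub.sum(axis=1))])
        dwell = members.size * dt_ns
        clusters.append(
            Cluster(
                id=new_id,
                members=tuple(int(m) for m in members),
                dwell_ns=float(dwell),
                representative=medoid,
                center=center,
                retained=bool(dwell >= min_dwell_ns),
            )
        )
        assignments[members] = new_id
    return ClusterSet(
        clusters=tuple(clusters),
        assignments=assignments,
        cutoff=cutoff,
        dt_ns=dt_ns,
        min_dwell_ns=min_dwell_ns,
        selection=selection,
    )


def representative_structure(
    trajectory: Trajectory,
    clusters: ClusterSet,
    cluster_id: int,
    method: str = "medoid",
) -> Structure:
    """Representative frame of a retained cluster as a Structure.

    ``method='medoid'`` (default) returns the member minimizing summed RMSD to
    its co-members; ``method='center'`` returns the greedy most-neighbours
    centre.
    """
    cluster = clusters.cluster(cluster_id)
    if not cluster.retained:
        raise ValueError(f"cluster {cluster_id} was discarded by the dwell-time filter")
    if method == "medoid":
        frame = cluster.representative
    elif method == "center":
        frame = cluster.center
    else:
        raise ValueError(f"unknown method {method!r}; use 'medoid' or 'center'")
    return trajectory.frame_structure(frame)
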