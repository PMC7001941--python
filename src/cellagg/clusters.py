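"""Aggregate identification from cell positions.

An aggregate is a connected component of the contact graph: two disk-cells
are in contact when their center distance (through the nearest periodic
image) does not exceed the cell diameter, i.e. the disks touch or overlap.
Singletons are size-1 clusters, so the cluster count at time zero equals
the number of seeded cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree

from .space import BoxSpec

__all__ = ["ClusterLabeling", "contact_pairs", "connected_components", "neighbor_count"]

#: tolerance added to the contact distance so that exactly-touching disks
#: (the state truncated moves end in) register as neighbors despite roundoff
CONTACT_TOL = 1e-6


@dataclass(frozen=True)
class ClusterLabeling:
    """Partition of cells into aggregates for one frame.

    ``labels[i]`` is the cluster id of cell index ``i``; ``sizes`` and
    ``coms`` are indexed by cluster id (0..n_clusters-1).
    """

    labels: np.ndarray
    sizes: np.ndarray
    coms: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def contact_pairs(positions, contact_dist: float, box: BoxSpec) -> np.ndarray:
    """All unordered index pairs at periodic distance <= contact_dist.

    Accelerated with a periodic k-d tree; contract-equivalent to the
    all-pairs scan.  Returns an (m, 2) int array with pair[0] < pair[1].
    """
    if contact_dist <= 0:
        raise ValueError(f"contact_dist must be positive, got {contact_dist}")
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(pos, boxsize=box.side_length)
    pairs = tree.query_pairs(contact_dist + CONTACT_TOL, output_type="ndarray")
    return pairs


def connected_components(pairs, n_cells: int, positions=None, box: BoxSpec | None = None) -> ClusterLabeling:
    """Connected components of the contact graph.

    ``pairs`` indexes cells 0..n_cells-1.  Centers of mass are computed
    (periodically) when ``positions`` and ``box`` are given, else set to NaN.
    """
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    if pairs.size and (pairs.min() < 0 or pairs.max() >= n_cells):
        raise ValueError("pair references an unknown cell index")
    if pairs.size:
        data = np.ones(len(pairs), dtype=np.int8)
        graph = sparse.coo_matrix(
            (data, (pairs[:, 0], pairs[:, 1])), shape=(n_cells, n_cells)
        )
        n_comp, labels = _cc(graph, directed=False)
    else:
        n_comp, labels = n_cells, np.arange(n_cells, dtype=np.intp)
    labels = np.asarray(labels, dtype=np.intp)
    sizes = np.bincount(labels, minlength=n_comp)
    coms = np.full((n_comp, 2), np.nan)
    if positions is not None and box is not None:
        # vectorized per-axis circular mean over all clusters at once
        pos = np.asarray(positions, dtype=float)
        L = box.side_length
        theta = pos * (2.0 * np.pi / L)
        for ax in (0, 1):
            s = np.bincount(labels, weights=np.sin(theta[:, ax]), minlength=n_comp)
            c = np.bincount(labels, weights=np.cos(theta[:, ax]), minlength=n_comp)
            coms[:, ax] = np.mod(np.arctan2(s, c) * (L / (2.0 * np.pi)), L)
    return ClusterLabeling(labels=labels, sizes=sizes, coms=coms)


def neighbor_count(pairs, n_cells: int) -> np.ndarray:
    """Contact-graph degree of every cell (vector of length n_cells)."""
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    if pairs.size and (pairs.min() < 0 or pairs.max() >= n_cells):
        raise ValueError("pair references an unknown cell index")
    deg = np.zeros(n_cells, dtype=np.intp)
    if pairs.size:
        np.add.at(deg, pairs[:, 0], 1)
        np.add.at(deg, pairs[:, 1], 1)
    return deg
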