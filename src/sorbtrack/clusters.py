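"""Periodic single-linkage clustering of water molecules.

Two waters are linked when their oxygen–oxygen minimum-image distance is
at most the cutoff (default 3.5 Å, the first minimum of the bulk-water
O–O pair correlation); clusters are the connected components of that
graph, found by union–find over a periodic k-d tree's neighbour pairs.
Per-cluster statistics include the mass-weighted radius of gyration,
computed after unwrapping the cluster into a single periodic image by a
breadth-first traversal of the linkage graph.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import Box, Topology, Trajectory, wrap_coords

__all__ = ["ClusterSet", "ClusterSeries", "cluster_frame", "cluster_series", "cluster_rg"]


@dataclass
class ClusterSet:
    """Partition of the water molecules of one frame into linkage clusters,
    ordered by descending size (ties: smallest member molecule id)."""

    frame: int
    clusters: list[np.ndarray]  # water molecule ids per cluster
    sizes: np.ndarray
    rg: np.ndarray  # mass-weighted radius of gyration, Å

    @property
    def largest_size(self) -> int:
        return int(self.sizes[0]) if len(self.sizes) else 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class ClusterSeries:
    """Per-frame largest-cluster statistics over a trajectory."""

    table: pd.DataFrame  # frame, time_ps, largest_size, n_clusters, largest_rg_A

    def summary(self) -> dict:
        s = self.table["largest_size"]
        return {
            "largest_size_max": int(s.max()),
            "largest_size_mean": float(s.mean()),
            "largest_size_sd": float(s.std(ddof=0)),
            "n_clusters_mean": float(self.table["n_clusters"].mean()),
        }


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _linkage_pairs(opos: np.ndarray, lengths: np.ndarray, cutoff: float) -> np.ndarray:
    """Index pairs with minimum-image distance <= cutoff (inclusive)."""
    pts = np.minimum(wrap_coords(opos, lengths), np.nextafter(lengths, 0.0))
    tree = cKDTree(pts, boxsize=lengths)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = opos[pairs[:, 1]] - opos[pairs[:, 0]]
    d -= lengths * np.floor(d / lengths + 0.5)
    keep = np.einsum("ij,ij->i", d, d) <= cutoff**2 * (1 + 1e-12)
    return pairs[keep]


def cluster_frame(
    coords: np.ndarray,
    topology: Topology,
    box: Box,
    cutoff: float = 3.5,
    frame: int = 0,
) -> ClusterSet:
    """Single-linkage water clusters of one frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mol_ids, oxy = topology.water_oxygens()
    if len(mol_ids) == 0:
        raise ValueError("no water molecules in the topology")
    pos = np.asarray(coords, float)
    pairs = _linkage_pairs(pos[oxy], box.lengths, cutoff)
    uf = _UnionFind(len(mol_ids))
    for i, j in pairs:
        uf.union(int(i), int(j))
    roots = np.array([uf.find(i) for i in range(len(mol_ids))])
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        groups.setdefault(int(r), []).append(i)
    clusters = [np.asarray(sorted(g), int) for g in groups.values()]
    clusters.sort(key=lambda c: (-len(c), int(mol_ids[c[0]])))
    sizes = np.array([len(c) for c in clusters], int)
    rgs = np.array(
        [cluster_rg(mol_ids[c], pos, topology, box, cutoff=cutoff) for c in clusters]
    )
    return ClusterSet(
        frame=frame,
        clusters=[mol_ids[c] for c in clusters],
        sizes=sizes,
        rg=rgs,
    )


def cluster_rg(
    member_molecule_ids: np.ndarray,
    coords: np.ndarray,
    topology: Topology,
    box: Box,
    cutoff: float = 3.5,
) -> float:
    """Mass-weighted radius of gyration of one cluster (all atoms of the
    member molecules), after unwrapping the cluster into one periodic
    image by breadth-first traversal over the linkage graph."""
    members = np.asarray(member_molecule_ids, int)
    if members.size == 0:
        raise ValueError("empty cluster")
    lengths = box.lengths
    all_ids, oxy = topology.water_oxygens()
    id_to_row = {int(m): k for k, m in enumerate(all_ids)}
    rows = np.array([id_to_row[int(m)] for m in members])
    opos = np.asarray(coords, float)[oxy[rows]]

    # BFS-unwrap the member oxygens into a connected image
    n = len(rows)
    unwrapped = np.empty((n, 3))
    visited = np.zeros(n, bool)
    local_pairs = _linkage_pairs(opos, lengths, cutoff)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in local_pairs:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    for start in range(n):
        if visited[start]:
            continue
        unwrapped[start] = opos[start]
        visited[start] = True
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in adj[i]:
                if not visited[j]:
                    d = opos[j] - opos[i]
                    d -= lengths * np.floor(d / lengths + 0.5)
                    unwrapped[j] = unwrapped[i] + d
                    visited[j] = True
                    queue.append(j)

    # gather all atoms of each member molecule around its unwrapped oxygen
    positions = []
    masses = []
    for k, m in enumerate(members):
        atoms = np.flatnonzero(topology.molecule_ids == m)
        o_atom = oxy[rows[k]]
        rel = np.asarray(coords, float)[atoms] - np.asarray(coords, float)[o_atom]
        rel -= lengths * np.floor(rel / lengths + 0.5)
        positions.append(unwrapped[k] + rel)
        masses.append(topology.masses[atoms])
    pos = np.concatenate(positions)
    mass = np.concatenate(masses)
    extent = pos.max(axis=0) - pos.min(axis=0)
    if np.any(extent >= lengths / 2):
        warnings.warn(
            "cluster diameter >= L/2 after unwrapping; radius of gyration is "
            "periodically ambiguous",
            RuntimeWarning,
            stacklevel=2,
        )
    com = (mass[:, None] * pos).sum(axis=0) / mass.sum()
    return float(np.sqrt((mass * ((pos - com) ** 2).sum(axis=1)).sum() / mass.sum()))


def cluster_series(
    traj: Trajectory,
    topology: Topology,
    cutoff: float = 3.5,
    stride: int = 1,
) -> ClusterSeries:
    """Largest-cluster size, cluster count and largest-cluster radius of
    gyration per frame (at the given stride)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = []
    for f in range(0, traj.n_frames, stride):
        cs = cluster_frame(traj.coords[f], topology, traj.box(f), cutoff, frame=f)
        rows.append(
            {
                "frame": f,
                "time_ps": traj.times[f],
                "largest_size": cs.largest_size,
                "n_clusters": cs.n_clusters,
                "largest_rg_A": float(cs.rg[0]) if len(cs.rg) else np.nan,
            }
        )
    return ClusterSeries(pd.DataFrame(rows))
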