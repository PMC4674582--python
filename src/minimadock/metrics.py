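"""Pose-quality metrics for a minima set against the native (crystal) pose.

Two rank indices summarise how well a target function positions a ligand:

* **IN** ("index of native") — the rank the locally *optimized* native
  pose's energy would take inside the energy-sorted minima list.  IN = 1
  means no stored minimum beats the native; infinity means every stored
  minimum lies below it (the true rank is unknowable from a truncated set).
* **INN** ("index of near native") — the rank of the lowest-energy stored
  minimum within 2 Å heavy-atom RMSD of the *non-optimized* native pose;
  infinity if no stored minimum is that close.

RMSD is always over heavy atoms, identity atom mapping, no superposition
and no chemical-symmetry correction: the receptor frame is fixed, so poses
are comparable in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .constants import CONSTANTS
from .structures import Conformation

__all__ = [
    "NativeReference",
    "IndexReport",
    "ClusterReport",
    "heavy_atom_rmsd",
    "index_of_native",
    "index_of_near_native",
    "cluster_minima",
    "window_count",
    "rmsd_profile",
]


@dataclass
class NativeReference:
    """Crystal pose plus its locally optimized counterpart and energy."""

    native_conf: Conformation
    optimized_native_conf: Conformation | None = None
    optimized_native_energy: float = math.nan


@dataclass(frozen=True)
class IndexReport:
    IN: float
    INN: float
    inn_rmsd_threshold: float = 2.0


@dataclass
class ClusterReport:
    labels: np.ndarray  # member -> 1-based cluster id
    n_clusters: int
    cluster_link_rmsd: float
    native_cluster_index: float  # 1-based, or inf


def heavy_atom_rmsd(a: Conformation, b: Conformation, heavy_indices=None) -> float:
    """RMSD over heavy atoms, identity mapping, no superposition."""
    if len(a) != len(b):
        raise ValueError(f"conformations have {len(a)} vs {len(b)} atoms")
    if heavy_indices is None:
        xa, xb = a.coords, b.coords
    else:
        idx = np.asarray(heavy_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("no heavy atoms to compare")
        xa, xb = a.coords[idx], b.coords[idx]
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def index_of_native(mset, ref: NativeReference) -> float:
    """Rank of the optimized-native energy inside the sorted minima list.

    Members tied exactly with the native energy rank after it, so IN = 1
    exactly when no stored minimum strictly beats the native.  If *every*
    stored member lies below the native the index is reported as infinity:
    the set is truncated, so the true rank is a lower bound only.
    """
    if math.isnan(ref.optimized_native_energy):
        raise ValueError("optimized_native_energy is required for IN")
    energies = mset.energies
    if len(energies) == 0:
        return 1.0
    below = int(np.sum(energies < ref.optimized_native_energy))
    if below == len(energies):
        return math.inf
    return float(1 + below)


def index_of_near_native(mset, ref: NativeReference, threshold: float = 2.0) -> float:
    """Rank of the first (lowest-energy) member within *threshold* Å of the
    non-optimized native pose; infinity if none qualifies."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for rank, m in enumerate(mset.members, start=1):
        if heavy_atom_rmsd(m.conf, ref.native_conf, mset.heavy_indices) < threshold:
            return float(rank)
    return math.inf


def _pairwise_rmsd(mset) -> np.ndarray:
    n = len(mset.members)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = heavy_atom_rmsd(
                mset.members[i].conf, mset.members[j].conf, mset.heavy_indices
            )
    return D


def cluster_minima(
    mset,
    link_rmsd: float = 1.4,
    native_conf: Conformation | None = None,
    linkage: str = "single",
) -> ClusterReport:
    """Group minima into clusters by pairwise RMSD.

    The stated pairwise rule — two conformations belong together when
    their RMSD is below ``link_rmsd`` — is not transitive; by default its
    minimal closure is used: single-linkage connected components of the
    graph with edges RMSD < link_rmsd.  ``linkage="complete"`` instead
    requires *every* pair within a cluster to satisfy the rule.  Clusters
    are numbered 1..n by ascending lowest member energy; the native pose
    is assigned to the lowest-numbered cluster holding a member within
    ``link_rmsd`` of it, or infinity if none does.
    """
    if link_rmsd <= 0:
        raise ValueError("link_rmsd must be positive")
    n = len(mset.members)
    if n == 0:
        return ClusterReport(np.array([], dtype=int), 0, link_rmsd, math.inf)
    D = _pairwise_rmsd(mset)
    if linkage == "single":
        adj = csr_matrix((D < link_rmsd) & ~np.eye(n, dtype=bool))
        _, raw = connected_components(adj, directed=False)
    elif linkage == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage as _linkage
        from scipy.spatial.distance import squareform

        if n == 1:
            raw = np.array([0])
        else:
            Z = _linkage(squareform(D, checks=False), method="complete")
            raw = fcluster(Z, t=link_rmsd * (1 - 1e-12), criterion="distance") - 1
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    # renumber by ascending lowest member energy (members are sorted)
    energies = mset.energies
    order: dict[int, int] = {}
    labels = np.zeros(n, dtype=int)
    for i in np.argsort(energies, kind="stable"):
        if raw[i] not in order:
            order[raw[i]] = len(order) + 1
    for i in range(n):
        labels[i] = order[raw[i]]
    native_idx: float = math.inf
    if native_conf is not None:
        for i in range(n):
            d = heavy_atom_rmsd(mset.members[i].conf, native_conf, mset.heavy_indices)
            if d < link_rmsd:
                native_idx = min(native_idx, float(labels[i]))
    return ClusterReport(labels, len(order), link_rmsd, native_idx)


def window_count(mset, width_kT: float = 5.0, T: float = 310.0) -> int:
    """Number of minima within ``width_kT * kT`` of the lowest energy —
    the members that contribute appreciably to the multiwell sum."""
    energies = mset.energies
    if len(energies) == 0:
        raise ValueError("window_count of an empty set")
    top = energies[0] + width_kT * CONSTANTS.kT(T)
    return int(np.sum(energies <= top))


def rmsd_profile(mset, native_conf: Conformation) -> np.ndarray:
    """Sorted (ascending) RMSDs of every member to the native pose; the
    first element is the 'lowest RMSD' summary statistic."""
    if len(mset.members) == 0:
        raise ValueError("rmsd_profile of an empty set")
    vals = [
        heavy_atom_rmsd(m.conf, native_conf, mset.heavy_indices) for m in mset.members
    ]
    return np.sort(np.array(vals))
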