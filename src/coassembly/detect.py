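"""Contact-graph construction and multicomponent cluster detection.

Two components interact when any inter-atom minimum-image distance is
strictly below the contact cutoff (3.5 A by default).  Clusters are the
connected components of the resulting contact graph with at least two
members; the analysis usually retains only large clusters (more than 30
members).  Periodic boundary conditions are honoured both in edge
detection and when a cluster is unwrapped into a contiguous set of
coordinates for geometric analysis.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Frame


@dataclass
class ContactGraph:
    """Component-level contact graph of one frame.

    ``edges`` maps each unordered component pair ``(i, j)`` (``i < j``) to
    the minimum inter-atom minimum-image distance of that pair (strictly
    below the cutoff by construction).
    """

    n_components: int
    edges: dict
    cutoff: float

    def neighbors(self) -> list:
        adj = [[] for _ in range(self.n_components)]
        for (i, j) in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass
class Cluster:
    """A connected set of >= 2 components; the unit of all statistics."""

    members: frozenset
    frame_index: int
    edge_subgraph: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def minimum_image_displacement(delta: np.ndarray, box: float) -> np.ndarray:
    """Nearest-periodic-image displacement vectors for a cubic box."""
    return delta - box * np.round(delta / box)


def contact_pairs(frame: Frame, cutoff: float) -> ContactGraph:
    """Build the contact graph under the any-atom minimum-image rule.

    Uses a periodic k-d tree for candidate atom pairs, then reduces to
    component pairs keeping exact strict ``< cutoff`` semantics.  The
    result is independent of the acceleration structure.

    Raises
    ------
    ValueError
        If ``cutoff >= box_length / 2`` (minimum image convention invalid).
    """
    L = frame.box_length
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= L / 2:
        raise ValueError(f"cutoff {cutoff} must be < half the box length {L / 2}")
    pos = frame.coords % L
    tree = cKDTree(pos, boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    edges: dict = {}
    if len(pairs):
        ci = frame.atom_component[pairs[:, 0]]
        cj = frame.atom_component[pairs[:, 1]]
        inter = ci != cj
        pairs = pairs[inter]
        ci, cj = ci[inter], cj[inter]
        if len(pairs):
            delta = minimum_image_displacement(pos[pairs[:, 0]] - pos[pairs[:, 1]], L)
            dist = np.linalg.norm(delta, axis=1)
            keep = dist < cutoff  # strict: ties at the cutoff are excluded
            lo = np.minimum(ci, cj)[keep]
            hi = np.maximum(ci, cj)[keep]
            for a, b, d in zip(lo, hi, dist[keep]):
                key = (int(a), int(b))
                if key not in edges or d < edges[key]:
                    edges[key] = float(d)
    return ContactGraph(n_components=frame.n_components, edges=edges, cutoff=cutoff)


def find_clusters(graph: ContactGraph, frame_index: int = 0) -> list:
    """Connected components with >= 2 members, as :class:`Cluster` objects.

    Isolated components are not clusters.  Every edge of the graph belongs
    to exactly one returned cluster.  Output ordered by descending size,
    ties by smallest member index.
    """
    parent = list(range(graph.n_components))

    def root(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in graph.edges:
        ri, rj = root(i), root(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict = {}
    for node in range(graph.n_components):
        groups.setdefault(root(node), []).append(node)
    clusters = []
    for members in groups.values():
        if len(members) < 2:
            continue
        mset = frozenset(members)
        sub = {e: d for e, d in graph.edges.items() if e[0] in mset}
        clusters.append(Cluster(members=mset, frame_index=frame_index, edge_subgraph=sub))
    clusters.sort(key=lambda c: (-c.size, min(c.members)))
    return clusters


def filter_clusters(clusters, min_size: int = 31) -> list:
    """Retain clusters with ``size >= min_size``.

    ``min_size=31`` keeps clusters of more than 30 peptides, drugs and
    ions.  Stable order: (frame_index, descending size, smallest member).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    kept = [c for c in clusters if c.size >= min_size]
    kept.sort(key=lambda c: (c.frame_index, -c.size, min(c.members)))
    return kept


def unwrap_cluster(frame: Frame, cluster: Cluster) -> np.ndarray:
    """Translate cluster members by lattice vectors into one contiguous copy.

    Breadth-first traversal over the cluster's contact edges: each newly
    visited component is shifted by the lattice vector that realizes the
    minimum-image displacement to its already-placed neighbor, so all edge
    contact distances are reproduced without the minimum image convention.

    Returns an ``(n_atoms, 3)`` array (same atom indexing as the frame;
    atoms outside the cluster keep their wrapped coordinates).

    Raises
    ------
    ValueError
        If the accumulated shifts are inconsistent, i.e. the cluster wraps
        around (percolates) the periodic box.
    """
    L = frame.box_length
    coords = frame.coords.copy()
    members = sorted(cluster.members)
    # make each member whole first: atoms of a boundary-straddling component
    # are wrapped individually, so rebuild them around the first atom
    for m in members:
        am = frame.component_atoms(m)
        ref = coords[am[0]]
        coords[am] = ref + minimum_image_displacement(coords[am] - ref, L)
    adj: dict = {m: [] for m in members}
    for (i, j) in cluster.edge_subgraph:
        adj[i].append(j)
        adj[j].append(i)
    shifts: dict = {members[0]: np.zeros(3)}
    queue = deque([members[0]])
    while queue:
        i = queue.popleft()
        ai = frame.component_atoms(i)
        for j in adj[i]:
            # lattice shift putting j's closest atom next to i's, given i's shift
            aj = frame.component_atoms(j)
            delta = coords[aj][:, None, :] - coords[ai][None, :, :]
            mic = minimum_image_displacement(delta, L)
            d2 = np.einsum("ijk,ijk->ij", mic, mic)
            fa, fb = np.unravel_index(np.argmin(d2), d2.shape)
            raw = coords[aj[fa]] - coords[ai[fb]]
            lattice = mic[fa, fb] - raw  # multiple of L per axis
            shift = shifts[i] + lattice
            if j in shifts:
                if not np.allclose(shifts[j], shift, atol=1e-6):
                    raise ValueError(
                        "cluster percolates the periodic box; no consistent unwrapping"
                    )
            else:
                shifts[j] = shift
                queue.append(j)
    for m in members:
        coords[frame.component_atoms(m)] += shifts[m]
    return coords


def brute_force_contact_pairs(frame: Frame, cutoff: float) -> ContactGraph:
    """O(N^2) all-pairs reference detector (oracle for tests and audits)."""
    L = frame.box_length
    if cutoff >= L / 2:
        raise ValueError("cutoff must be < half the box length")
    pos = frame.coords % L
    edges: dict = {}
    n = frame.n_components
    atom_lists = [frame.component_atoms(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            delta = pos[atom_lists[i]][:, None, :] - pos[atom_lists[j]][None, :, :]
            mic = minimum_image_displacement(delta, L)
            d = np.sqrt(np.einsum("ijk,ijk->ij", mic, mic)).min()
            if d < cutoff:
                edges[(i, j)] = float(d)
    return ContactGraph(n_components=n, edges=edges, cutoff=cutoff)
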