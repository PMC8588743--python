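"""Distance-based tree building: neighbor joining, bootstrap support, Newick.

Neighbor joining (Saitou & Nei 1987) agglomerates the pair minimizing
``Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` and is consistent on
additive matrices: it returns the unique tree realizing the matrix exactly.
Ties in Q are broken lexicographically on cluster names (a cluster is named by
its smallest leaf) so results are deterministic. Negative branch-length
estimates are clamped to zero with the deficit moved to the sister branch, the
common convention, and the clamp count is recorded on the tree.

Bootstrap support resamples alignment columns with replacement, rebuilds the
NJ tree per replicate, and scores each internal edge of the reference tree by
the percentage of replicate trees containing the same bipartition.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .distances import DistanceMatrix, build_distance_matrix
from .errors import SaturationError, UndefinedComparisonError
from .seq_io import Alignment

_TIE_TOL = 1e-10


@dataclass
class TreeNode:
    """A node in an (un)rooted tree; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())


class PhyloTree:
    """Unrooted tree stored with an arbitrary (trifurcating) root."""

    def __init__(self, root: TreeNode, clamped_branches: int = 0):
        self.root = root
        self.clamped_branches = clamped_branches
        self.dropped_replicates = 0

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each represented by the side *not* containing
        the lexicographically smallest leaf (a canonical orientation)."""
        all_leaves = self.leaf_names
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> None:
            for child in node.children:
                side = child.leaf_names()
                if anchor in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(side)
                visit(child)

        visit(self.root)
        return splits

    def internal_edges(self) -> list[tuple[frozenset[str], TreeNode]]:
        """(canonical split, child node) for every internal non-root edge."""
        all_leaves = self.leaf_names
        anchor = min(all_leaves)
        edges = []

        def visit(node: TreeNode) -> None:
            for child in node.children:
                if not child.is_leaf:
                    side = child.leaf_names()
                    if anchor in side:
                        side = all_leaves - side
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        edges.append((side, child))
                    visit(child)

        visit(self.root)
        return edges

    def leaf_distances(self) -> dict[frozenset[str], float]:
        """Patristic (path-length) distances between all leaf pairs."""
        # flatten to an adjacency list and BFS from every leaf
        adjacency: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def build(node: TreeNode) -> int:
            nid = id(node)
            adjacency.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for child in node.children:
                cid = build(child)
                adjacency[nid].append((cid, child.length))
                adjacency[cid].append((nid, child.length))
            return nid

        build(self.root)
        result: dict[frozenset[str], float] = {}
        for start, start_name in names.items():
            dist = {start: 0.0}
            queue = deque([start])
            while queue:
                here = queue.popleft()
                for neighbor, w in adjacency[here]:
                    if neighbor not in dist:
                        dist[neighbor] = dist[here] + w
                        queue.append(neighbor)
            for nid, name in names.items():
                if name != start_name:
                    result[frozenset((start_name, name))] = dist[nid]
        return result

    def newick(self, decimals: int = 9) -> str:
        """Newick with branch lengths; supports as internal-node labels (integer %)."""

        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.support is None else f"{node.support:.0f}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length + 0.0:.{decimals}g}"

        return fmt(self.root, top=True) + ";"


def to_newick(tree: PhyloTree) -> str:
    return tree.newick()


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Standard NJ over a distance-mode matrix; exact on additive inputs."""
    if matrix.is_similarity:
        raise ValueError("neighbor joining needs a distance matrix, not similarities")
    if not np.all(np.isfinite(matrix.values)):
        raise SaturationError(
            "distance matrix contains saturated (infinite) pairs: "
            f"{matrix.flagged_pairs or 'unknown'}"
        )
    labels = list(matrix.labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")

    clamped = 0

    def clamp(pair: list[float]) -> list[float]:
        nonlocal clamped
        la, lb = pair
        if la < 0:
            lb, la, = lb + la, 0.0
            clamped += 1
        if lb < 0:
            la, lb = la + lb, 0.0
            clamped += 1
        return [la, lb]

    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in labels}
    dist: dict[frozenset[str], float] = {
        frozenset((a, b)): matrix.value(a, b) for a, b in combinations(labels, 2)
    }
    active = sorted(labels)

    if len(active) == 2:
        a, b = active
        d = dist[frozenset((a, b))]
        nodes[a].length = nodes[b].length = d / 2
        return PhyloTree(TreeNode(children=[nodes[a], nodes[b]]), clamped)

    while len(active) > 3:
        r = len(active)
        totals = {
            a: sum(dist[frozenset((a, k))] for k in active if k != a) for a in active
        }
        best_q, best_pair = None, None
        for a, b in combinations(active, 2):  # active is sorted -> lexicographic scan
            q = (r - 2) * dist[frozenset((a, b))] - totals[a] - totals[b]
            if best_q is None or q < best_q - _TIE_TOL:
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        d_ab = dist[frozenset((a, b))]
        la = d_ab / 2 + (totals[a] - totals[b]) / (2 * (r - 2))
        la, lb = clamp([la, d_ab - la])
        nodes[a].length, nodes[b].length = la, lb
        merged = TreeNode(children=[nodes[a], nodes[b]])
        name = min(a, b)
        for k in active:
            if k not in (a, b):
                d_new = (dist[frozenset((a, k))] + dist[frozenset((b, k))] - d_ab) / 2
                dist[frozenset((name, k))] = d_new
        active = sorted(set(active) - {a, b} | {name})
        nodes[name] = merged

    x, y, z = active
    dxy, dxz, dyz = (dist[frozenset(p)] for p in ((x, y), (x, z), (y, z)))
    lx = (dxy + dxz - dyz) / 2
    ly = (dxy + dyz - dxz) / 2
    lz = (dxz + dyz - dxy) / 2
    for name, length in ((x, lx), (y, ly), (z, lz)):
        if length < 0:
            clamped += 1
            length = 0.0
        nodes[name].length = length
    return PhyloTree(TreeNode(children=[nodes[x], nodes[y], nodes[z]]), clamped)


def bootstrap_support(
    alignment: Alignment,
    model: str,
    replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree on the full alignment with column-resampling bootstrap supports.

    Per-replicate RNG seeds are derived from the root ``seed`` by a fixed
    increment of one, so runs are reproducible and individually replayable.
    Replicates whose resampled alignment leaves some pair with zero comparable
    sites (or a saturated corrected distance) are dropped and counted in
    ``tree.dropped_replicates``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    reference = neighbor_joining(build_distance_matrix(alignment, model))
    counts: dict[frozenset[str], int] = {split: 0 for split, _ in reference.internal_edges()}
    ncols = alignment.column_count
    dropped = 0
    for i in range(replicates):
        rng = np.random.default_rng(seed + i)
        resampled = alignment.take_columns(rng.integers(0, ncols, size=ncols))
        try:
            replicate_tree = neighbor_joining(build_distance_matrix(resampled, model))
        except (UndefinedComparisonError, SaturationError):
            dropped += 1
            continue
        splits = replicate_tree.bipartitions()
        for split in counts:
            if split in splits:
                counts[split] += 1
    effective = replicates - dropped
    for split, node in reference.internal_edges():
        node.support = 100.0 * counts[split] / effective if effective else float("nan")
    reference.dropped_replicates = dropped
    return reference
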