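import numpy as np
import pytest

from nemadelim.morphometrics import load_reference_tables
from nemadelim.seq_io import Alignment, SequenceRecord
from nemadelim.synthetic_data import SimulationConfig, simulate_locus_set


def record(isolate, residues, locus="COI", **kw):
    return SequenceRecord(isolate_id=isolate, locus=locus, residues=residues, **kw)


@pytest.fixture(scope="session")
def range_table():
    return load_reference_tables()


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset under the default study-like conditions."""
    config = SimulationConfig(seed=11)
    records, truth = simulate_locus_set(config)
    return config, records, truth


@pytest.fixture()
def coi_alignment(default_dataset):
    _, records, _ = default_dataset
    return Alignment(locus="COI", rows=records["COI"])


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree with positive branch lengths.

    Built by repeatedly splitting a random edge; returns (leaf labels,
    dict of pairwise path lengths, set of canonical non-trivial splits).
    Used as the independent oracle for neighbor-joining consistency.
    """
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    # adjacency: node -> {neighbor: length}; internal nodes are negative ints
    adjacency = {}
    nxt = [-1]

    def connect(a, b, w):
        adjacency.setdefault(a, {})[b] = w
        adjacency.setdefault(b, {})[a] = w

    def disconnect(a, b):
        del adjacency[a][b]
        del adjacency[b][a]

    def fresh():
        nxt[0] -= 1
        return nxt[0]

    center = fresh()
    for leaf in labels[:3]:
        connect(center, leaf, rng.uniform(0.5, 2.0))
    for leaf in labels[3:]:
        edges = [(a, b) for a in adjacency for b in adjacency[a] if str(a) < str(b)]
        a, b = edges[rng.integers(len(edges))]
        w = adjacency[a][b]
        mid = fresh()
        disconnect(a, b)
        split = rng.uniform(0.25, 0.75) * w
        connect(a, mid, split)
        connect(mid, b, w - split)
        connect(mid, leaf, rng.uniform(0.5, 2.0))

    # pairwise path lengths by BFS
    from collections import deque

    distances = {}
    for start in labels:
        seen = {start: 0.0}
        queue = deque([start])
        while queue:
            here = queue.popleft()
            for neighbor, w in adjacency[here].items():
                if neighbor not in seen:
                    seen[neighbor] = seen[here] + w
                    queue.append(neighbor)
        for other in labels:
            if other != start:
                distances[frozenset((start, other))] = seen[other]

    # canonical splits: for each internal edge, the side not holding min(labels)
    anchor = min(labels)
    splits = set()
    internal = [v for v in adjacency if isinstance(v, int)]
    for a in internal:
        for b in adjacency[a]:
            if isinstance(b, int) and a < b:
                # leaves on b's side of edge (a, b)
                side = set()
                stack, seen = [b], {a, b}
                while stack:
                    here = stack.pop()
                    if isinstance(here, str):
                        side.add(here)
                    for neighbor in adjacency[here]:
                        if neighbor not in seen:
                            seen.add(neighbor)
                            stack.append(neighbor)
                side = frozenset(side if anchor not in side else set(labels) - side)
                if 2 <= len(side) <= n_leaves - 2:
                    splits.add(side)
    return labels, distances, splits
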