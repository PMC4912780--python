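import numpy as np
import pytest

import splicevents as sv


@pytest.fixture(scope="session")
def cassette_gene():
    return sv.canonical_gene("cassette exon", "CASS", "chr1")


@pytest.fixture(scope="session")
def cassette_graph(cassette_gene):
    return sv.build_extended_graph(cassette_gene)


@pytest.fixture(scope="session")
def canonical_genes():
    """One fixture gene per category, keyed by category."""
    return {
        cat: sv.canonical_gene(cat, f"G{i}", f"chr{i}")
        for i, cat in enumerate(sv.CATEGORIES, start=1)
    }


@pytest.fixture(scope="session")
def random_genes():
    """A reproducible batch of random multi-isoform gene models."""
    rng = np.random.default_rng(20240917)
    return [
        sv.random_gene(rng, f"R{i:03d}", f"chr{i}") for i in range(500)
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small fully simulated two-group experiment."""
    config = sv.SimulationConfig(n_genes=8, seed=11,
                                 differential_fraction=0.5)
    return sv.simulate_dataset(config)


def per_base_subexon_oracle(gene):
    """Brute-force per-base membership labelling + run-length merge."""
    lo = min(t.span[0] for t in gene.transcripts)
    hi = max(t.span[1] for t in gene.transcripts)
    labels = []
    for pos in range(lo, hi + 1):
        members = frozenset(
            t.transcript_id for t in gene.transcripts
            if any(s <= pos <= e for s, e in t.exons)
        )
        labels.append((pos, members))
    runs = []
    for pos, members in labels:
        if not members:
            continue
        if runs and runs[-1][2] == members and runs[-1][1] == pos - 1:
            runs[-1][1] = pos
        else:
            runs.append([pos, pos, members])
    return [((s, e), m) for s, e, m in runs]


def transcript_edge_walk(graph):
    """Per-edge traversing-isoform sets recomputed from the stored walks."""
    edge_iso = {}
    for tid, path in graph.transcript_paths.items():
        for key in path:
            edge_iso.setdefault(key, set()).add(tid)
    return {k: frozenset(v) for k, v in edge_iso.items()}


def chain_endpoints(keys):
    """(u, v) if edge keys form one simple chain, else None (test-local)."""
    if not keys:
        return None
    nxt = {}
    targets = set()
    for u, v in keys:
        if u in nxt:
            return None
        nxt[u] = v
        if v in targets:
            return None
        targets.add(v)
    starts = [u for u in nxt if u not in targets]
    if len(starts) != 1:
        return None
    node, seen = starts[0], 0
    first = node
    while node in nxt:
        node = nxt[node]
        seen += 1
    return (first, node) if seen == len(keys) else None


def bipartition_event_oracle(graph):
    """Exhaustive isoform-bipartition oracle for event triplets.

    For every subset of isoforms and every bipartition (A, B) of it, the
    triplet is an event iff the edges traversed by exactly A form a simple
    chain, those by exactly B form a chain with the same endpoints, and at
    least one edge is traversed by exactly A | B.  Returns canonical
    (iso_A, iso_B, keys_R, keys_A, keys_B) tuples.
    """
    from itertools import combinations

    edge_iso = transcript_edge_walk(graph)
    isoforms = sorted(graph.transcript_paths)
    found = set()
    for r in range(2, len(isoforms) + 1):
        for subset in combinations(isoforms, r):
            sset = set(subset)
            for k in range(1, r // 2 + 1):
                for a in combinations(subset, k):
                    a = frozenset(a)
                    b = frozenset(sset - a)
                    if len(a) > len(b) or (len(a) == len(b)
                                           and sorted(a) > sorted(b)):
                        continue
                    keys_a = frozenset(
                        key for key, iso in edge_iso.items() if iso == a)
                    keys_b = frozenset(
                        key for key, iso in edge_iso.items() if iso == b)
                    keys_r = frozenset(
                        key for key, iso in edge_iso.items()
                        if iso == a | b)
                    if not (keys_a and keys_b and keys_r):
                        continue
                    ca = chain_endpoints(keys_a)
                    cb = chain_endpoints(keys_b)
                    if ca is None or cb is None or ca != cb:
                        continue
                    pair = tuple(sorted([a, b], key=sorted))
                    keys = {a: keys_a, b: keys_b}
                    found.add((pair[0], pair[1], keys_r,
                               keys[pair[0]], keys[pair[1]]))
    return found


def canonical_triplets(triplets):
    """Canonical form of enumerate_events output, comparable to the oracle."""
    out = set()
    for t in triplets:
        iso_a = t.path_a[0].isoform_set
        iso_b = t.path_b[0].isoform_set
        pair = tuple(sorted([iso_a, iso_b], key=sorted))
        keys = {
            iso_a: frozenset(e.key for e in t.path_a),
            iso_b: frozenset(e.key for e in t.path_b),
        }
        out.add((pair[0], pair[1],
                 frozenset(e.key for e in t.reference),
                 keys[pair[0]], keys[pair[1]]))
    return out
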