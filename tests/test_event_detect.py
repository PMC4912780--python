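"""Graph pruning, event enumeration, path assignment and classification."""

import networkx as nx
import numpy as np
import pytest

import splicevents as sv
from splicevents.event_detect import (
    ALT3, ALT5, ALT_FIRST, ALT_LAST, CASSETTE, COMPLEX, MUTUALLY_EXCLUSIVE,
    RETAINED_INTRON, enumerate_events, path_genomic_length,
)
from splicevents.transcript_graph import START, END

from conftest import bipartition_event_oracle, canonical_triplets


# ---------------------------------------------------------------------------
# pruning

def all_edge_keys(graph):
    return {e.key for e in graph.edges()}


def coherent(graph):
    g = graph.graph
    if g.number_of_edges() == 0:
        return True
    fwd = nx.descendants(g, START) | {START} if START in g else set()
    bwd = nx.ancestors(g, END) | {END} if END in g else set()
    return set(g.nodes()) <= (fwd & bwd)


def test_prune_all_probed_is_identity(cassette_graph):
    pruned = sv.prune_graph(cassette_graph, all_edge_keys(cassette_graph))
    assert all_edge_keys(pruned) == all_edge_keys(cassette_graph)


def eight_exon_gene():
    """Two isoforms over exons E1..E8 (E2 and E4 are skippable)."""
    exons = {i: (100 * i + 1, 100 * i + 60) for i in range(1, 9)}
    t1 = [exons[i] for i in range(1, 9)]
    t2 = [exons[i] for i in (1, 3, 5, 6, 7, 8)]
    return sv.GeneModel("G8", "chr1", "+", (
        sv.TranscriptModel("T1", tuple(t1)),
        sv.TranscriptModel("T2", tuple(t2))))


def test_prune_keeps_bridge_removes_dead_branch():
    """Probe-less interior branch goes; a probe-less terminal bridge stays.

    No probes sit on the E3-E4 / E4-E5 junctions or the E4 exon, so the E4
    detour can be removed (E3 still reaches E5 through the skip junction);
    no probe sits on E7-E8 either, but removing it would disconnect E7
    from the end node, so it must be kept.
    """
    gene = eight_exon_gene()
    graph = sv.build_extended_graph(gene)

    def node(i, ab):
        return f"G8:SE{i:03d}.{ab}"

    unprobed = {
        (node(3, "b"), node(4, "a")),  # E3-E4
        (node(4, "b"), node(5, "a")),  # E4-E5
        (node(4, "a"), node(4, "b")),  # E4 exon
        (node(7, "b"), node(8, "a")),  # E7-E8
    }
    probed = all_edge_keys(graph) - unprobed
    pruned = sv.prune_graph(graph, probed)
    keys = all_edge_keys(pruned)
    assert (node(3, "b"), node(4, "a")) not in keys
    assert (node(4, "b"), node(5, "a")) not in keys
    assert (node(4, "a"), node(4, "b")) not in keys
    assert (node(7, "b"), node(8, "a")) in keys
    assert probed <= keys
    assert coherent(pruned)


def random_probed_subset(graph, rng):
    keys = sorted(all_edge_keys(graph))
    return {k for k in keys if rng.random() < 0.7}


@pytest.mark.parametrize("seed", range(10))
def test_prune_matches_exhaustive_removal_oracle(random_genes, seed):
    """Fixed point: kept unprobed edges are exactly the irremovable ones."""
    rng = np.random.default_rng(seed)
    graph = sv.build_extended_graph(random_genes[seed])
    probed = random_probed_subset(graph, rng)
    pruned = sv.prune_graph(graph, probed)
    keys = all_edge_keys(pruned)
    assert (probed & all_edge_keys(graph)) <= keys
    assert coherent(pruned)
    # every retained unprobed edge is irremovable: taking it out (with the
    # cascade of newly incoherent nodes and their unprobed edges) must
    # break coherence or cost a probed edge
    for key in sorted(keys - probed):
        g2 = pruned.graph.copy()
        g2.remove_edge(*key)
        removable = True
        while True:
            fwd = nx.descendants(g2, START) | {START} if START in g2 else set()
            bwd = nx.ancestors(g2, END) | {END} if END in g2 else set()
            bad = set(g2.nodes()) - (fwd & bwd)
            if not bad:
                break
            doomed = [(u, v) for u, v in g2.edges() if u in bad or v in bad]
            if any(e in probed for e in doomed):
                removable = False
                break
            g2.remove_nodes_from(bad)
            if g2.number_of_edges() == 0:
                break
        assert not removable, f"edge {key} was removable but kept"


def test_prune_unprobed_gene_collapses():
    gene = eight_exon_gene()
    graph = sv.build_extended_graph(gene)
    pruned = sv.prune_graph(graph, set())
    assert all_edge_keys(pruned) == set()


# ---------------------------------------------------------------------------
# enumeration

def test_single_isoform_gene_has_no_events():
    gene = sv.GeneModel("G", "chr1", "+", (
        sv.TranscriptModel("T1", ((1, 100), (201, 300))),))
    graph = sv.build_extended_graph(gene)
    assert enumerate_events(graph) == []


def test_cassette_triplet_edges(cassette_graph):
    triplets = enumerate_events(cassette_graph)
    assert len(triplets) == 1
    t = triplets[0]
    ref_kinds = sorted(e.kind for e in t.reference)
    assert ref_kinds == ["end_link", "exon", "exon", "start_link"]
    chains = sorted(
        [sorted(e.kind for e in t.path_a), sorted(e.kind for e in t.path_b)]
    )
    assert chains == [["exon", "junction", "junction"], ["junction"]]


def test_enumeration_matches_bipartition_oracle(random_genes):
    for gene in random_genes[:60]:
        graph = sv.build_extended_graph(gene)
        got = canonical_triplets(enumerate_events(graph))
        assert got == bipartition_event_oracle(graph)


def test_flow_variant_enumerates_identical_triplets(random_genes):
    for i, gene in enumerate(random_genes[:100]):
        graph = sv.build_extended_graph(gene)
        a = canonical_triplets(enumerate_events(graph, "isoform_set"))
        b = canonical_triplets(enumerate_events(graph, "flow", seed=i))
        assert a == b


def test_disjoint_union_invariant(random_genes):
    for gene in random_genes[:100]:
        graph = sv.build_extended_graph(gene)
        for ev in sv.detect_events(graph):
            assert not ev.isoforms_path1 & ev.isoforms_path2
            assert ev.isoforms_reference == \
                (ev.isoforms_path1 | ev.isoforms_path2)
            for e in ev.path1:
                assert e.isoform_set == ev.isoforms_path1
            for e in ev.path2:
                assert e.isoform_set == ev.isoforms_path2
            # PCR designability: every member of the triplet is non-empty
            assert ev.reference_path and ev.path1 and ev.path2


# ---------------------------------------------------------------------------
# path assignment

def test_cassette_p1_contains_skipped_exon(cassette_graph):
    ev = sv.detect_events(cassette_graph)[0]
    assert any(e.kind == "exon" for e in ev.path1)
    assert [e.kind for e in ev.path2] == ["junction"]
    assert path_genomic_length(ev.path1) > path_genomic_length(ev.path2)


def test_equal_length_tie_broken_by_leftmost_coordinate():
    # alternative last exons of identical length
    gene = sv.GeneModel("G", "chr1", "+", (
        sv.TranscriptModel("T1", ((1, 100), (201, 300))),
        sv.TranscriptModel("T2", ((1, 100), (401, 500)))))
    ev = sv.detect_events(sv.build_extended_graph(gene))[0]
    assert path_genomic_length(ev.path1) == path_genomic_length(ev.path2)
    exon1 = [e.span for e in ev.path1 if e.kind == "exon"]
    exon2 = [e.span for e in ev.path2 if e.kind == "exon"]
    assert exon1 == [(201, 300)] and exon2 == [(401, 500)]


def test_alt_donor_path_metric_by_hand():
    """Transcriptomic path length recomputed by hand on an alt-donor gene."""
    gene = sv.canonical_gene(ALT5, "G", "chr1")
    ev = sv.detect_events(sv.build_extended_graph(gene))[0]
    # P1 = adjacency + 50 nt extension exon + junction (gap 150): exonic 50
    # P2 = single junction (gap 200): exonic 0
    assert path_genomic_length(ev.path1) == 50
    assert path_genomic_length(ev.path2) == 0
    assert sum(e.gap for e in ev.path1) == 150
    assert sum(e.gap for e in ev.path2) == 200


# ---------------------------------------------------------------------------
# classification

def test_canonical_fixtures_get_intended_labels(canonical_genes):
    for category, gene in canonical_genes.items():
        events = sv.detect_events(sv.build_extended_graph(gene))
        assert [e.category for e in events] == [category]


@pytest.mark.parametrize("category", sv.CANONICAL_CATEGORIES)
def test_perturbed_fixtures_become_complex(category):
    gene = sv.canonical_gene(category, "P", "chr1", perturbed=True)
    events = sv.detect_events(sv.build_extended_graph(gene))
    assert events, "perturbed gene still has a localized event"
    assert all(e.category == COMPLEX for e in events)


@pytest.mark.parametrize("category,flipped", [
    (ALT5, ALT3), (ALT3, ALT5), (ALT_FIRST, ALT_LAST), (ALT_LAST, ALT_FIRST),
    (CASSETTE, CASSETTE), (RETAINED_INTRON, RETAINED_INTRON),
    (MUTUALLY_EXCLUSIVE, MUTUALLY_EXCLUSIVE),
])
def test_minus_strand_flips_oriented_labels(category, flipped):
    gene = sv.canonical_gene(category, "G", "chr1", strand="-")
    events = sv.detect_events(sv.build_extended_graph(gene))
    assert [e.category for e in events] == [flipped]


def test_classification_total_and_deterministic(random_genes):
    for gene in random_genes[:100]:
        graph = sv.build_extended_graph(gene)
        a = [(e.event_id, e.category) for e in sv.detect_events(graph)]
        b = [(e.event_id, e.category) for e in sv.detect_events(graph)]
        assert a == b
        assert all(cat in sv.CATEGORIES for _, cat in a)


def test_event_ids_ordinal_by_window():
    gene = sv.GeneModel("G", "chr1", "+", (
        sv.TranscriptModel("T1", ((1, 100), (201, 260), (401, 500),
                                  (601, 660), (801, 900))),
        sv.TranscriptModel("T2", ((1, 100), (401, 500), (601, 660),
                                  (801, 900))),
        sv.TranscriptModel("T3", ((1, 100), (201, 260), (401, 500),
                                  (801, 900))),
        sv.TranscriptModel("T4", ((1, 100), (401, 500), (801, 900))),
    ))
    events = sv.detect_events(sv.build_extended_graph(gene))
    ids = [e.event_id for e in events]
    assert ids == [f"G_{i}" for i in range(1, len(ids) + 1)]
    windows = [e.genomic_window for e in events]
    assert windows == sorted(windows)
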