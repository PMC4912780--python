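"""Pruning, enumeration and classification of alternative-splicing events.

An event is a triplet {PR, P1, P2} of edge sets of the extended splicing
graph: P1 and P2 are the two alternative paths, each a chain of edges
carried by the same set of isoforms, diverging at a single node ``u`` and
reconverging at a single node ``v`` (possibly START/END); PR is the set of
reference edges carried by exactly the union of the two isoform sets.  Any
positive per-isoform flow then satisfies flow(PR) = flow(P1) + flow(P2) on
every edge of the triplet.

Edges are grouped canonically by their exact isoform set.  The equivalent
random-flow formulation (grouping by the per-edge sum of random per-isoform
weights, a probabilistic hash of the isoform set) is available as an
option; it uses random integer weights so sums are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .transcript_graph import (
    ADJACENCY, END, END_LINK, EXON, JUNCTION, START, START_LINK,
    ExtendedSplicingGraph, GraphEdge,
)

CASSETTE = "cassette exon"
ALT3 = "alternative 3'"
ALT5 = "alternative 5'"
RETAINED_INTRON = "retained intron"
ALT_FIRST = "alternative first exon"
ALT_LAST = "alternative last exon"
MUTUALLY_EXCLUSIVE = "mutually exclusive exons"
COMPLEX = "complex"

CANONICAL_CATEGORIES = (
    CASSETTE, ALT3, ALT5, RETAINED_INTRON, ALT_FIRST, ALT_LAST,
    MUTUALLY_EXCLUSIVE,
)
CATEGORIES = CANONICAL_CATEGORIES + (COMPLEX,)


@dataclass
class Event:
    """A detected splicing event (paths ordered: P1 genomically longer)."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    category: str
    reference_path: tuple[GraphEdge, ...]
    path1: tuple[GraphEdge, ...]
    path2: tuple[GraphEdge, ...]
    divergence: str
    convergence: str
    genomic_window: tuple[int, int]

    @property
    def isoforms_path1(self) -> frozenset[str]:
        return self.path1[0].isoform_set

    @property
    def isoforms_path2(self) -> frozenset[str]:
        return self.path2[0].isoform_set

    @property
    def isoforms_reference(self) -> frozenset[str]:
        return self.reference_path[0].isoform_set


@dataclass
class RawTriplet:
    """An unordered event candidate: reference group and two path chains."""

    reference: tuple[GraphEdge, ...]
    path_a: tuple[GraphEdge, ...]
    path_b: tuple[GraphEdge, ...]
    divergence: str
    convergence: str


# ---------------------------------------------------------------------------
# pruning

def prune_graph(
    graph: ExtendedSplicingGraph, probed_edges: set[tuple[str, str]]
) -> ExtendedSplicingGraph:
    """Remove probe-less edges that are not needed for graph coherence.

    Every probed edge is retained.  An unprobed edge is removed only when
    the graph stays coherent without it: after the removal (and the cascade
    removal of nodes left off every START -> END path, together with their
    unprobed incident edges) every remaining node still lies on a
    START -> END path and no probed edge is lost.  Removals are attempted
    in sorted edge order until a fixed point, which matches the
    per-edge exhaustive-removal characterization.
    """
    g = graph.graph.copy()
    changed = True
    while changed:
        changed = False
        for key in sorted(g.edges()):
            if key in probed_edges or not g.has_edge(*key):
                continue
            g2 = _try_remove(g, key, probed_edges)
            if g2 is not None:
                g = g2
                changed = True
    return graph.copy_with_edges(set(g.edges()))


def _coherent_nodes(g: nx.DiGraph) -> set[str]:
    """Nodes lying on some START -> END path."""
    if START not in g or END not in g:
        return set()
    fwd = nx.descendants(g, START) | {START}
    bwd = nx.ancestors(g, END) | {END}
    return fwd & bwd


def _try_remove(g: nx.DiGraph, key, probed_edges):
    """Graph after removing ``key`` if coherence survives, else ``None``."""
    g2 = g.copy()
    g2.remove_edge(*key)
    while True:
        ok = _coherent_nodes(g2)
        bad = set(g2.nodes()) - ok
        if not bad:
            return g2
        doomed = [
            (u, v) for u, v in g2.edges() if u in bad or v in bad
        ]
        if any(e in probed_edges for e in doomed):
            return None
        g2.remove_nodes_from(bad)
        if g2.number_of_edges() == 0:
            return g2


# ---------------------------------------------------------------------------
# enumeration

def _edge_sort_key(e: GraphEdge):
    return (e.span if e.span is not None else (-1, -1), e.source, e.target)


def _as_chain(edges: list[GraphEdge]) -> tuple[str, str] | None:
    """(u, v) if the edges form one simple directed chain, else None."""
    if not edges:
        return None
    out: dict[str, str] = {}
    indeg: dict[str, int] = {}
    for e in edges:
        if e.source in out:
            return None
        out[e.source] = e.target
        indeg[e.target] = indeg.get(e.target, 0) + 1
        indeg.setdefault(e.source, indeg.get(e.source, 0))
    if any(n > 1 for n in indeg.values()):
        return None
    sources = [s for s in out if indeg.get(s, 0) == 0]
    if len(sources) != 1:
        return None
    u = sources[0]
    node, steps = u, 0
    while node in out:
        node = out[node]
        steps += 1
    if steps != len(edges):
        return None
    return u, node


def _order_chain(edges: tuple[GraphEdge, ...]) -> tuple[GraphEdge, ...]:
    by_source = {e.source: e for e in edges}
    chain = _as_chain(list(edges))
    assert chain is not None
    node, ordered = chain[0], []
    while node in by_source:
        e = by_source[node]
        ordered.append(e)
        node = e.target
    return tuple(ordered)


def group_edges_by_isoform_set(
    graph: ExtendedSplicingGraph,
) -> dict[frozenset[str], list[GraphEdge]]:
    groups: dict[frozenset[str], list[GraphEdge]] = {}
    for e in graph.edges():
        groups.setdefault(e.isoform_set, []).append(e)
    for edges in groups.values():
        edges.sort(key=_edge_sort_key)
    return groups


def group_edges_by_flow(
    graph: ExtendedSplicingGraph, seed: int = 0
) -> dict[frozenset[str], list[GraphEdge]]:
    """Random-flow grouping: a probabilistic hash of the isoform set.

    Each isoform receives an independent random positive integer weight;
    the flow of an edge is the exact integer sum over its isoform set, so
    two edges share a flow value iff they share an isoform set (up to a
    vanishing collision probability).  Returned keyed by isoform set so the
    result is directly comparable with the canonical grouping.
    """
    rng = np.random.default_rng(seed)
    isoforms = sorted(graph.transcript_paths)
    weights = {
        t: int(w) for t, w in
        zip(isoforms, rng.integers(1, 2**62, size=len(isoforms)))
    }
    by_flow: dict[int, list[GraphEdge]] = {}
    for e in graph.edges():
        flow = sum(weights[t] for t in e.isoform_set)
        by_flow.setdefault(flow, []).append(e)
    groups: dict[frozenset[str], list[GraphEdge]] = {}
    for edges in by_flow.values():
        iso = frozenset().union(*(e.isoform_set for e in edges))
        groups[iso] = sorted(edges, key=_edge_sort_key)
    return groups


def enumerate_events(
    graph: ExtendedSplicingGraph,
    method: str = "isoform_set",
    seed: int = 0,
) -> list[RawTriplet]:
    """All localized triplets {PR, P1, P2} of the (pruned) graph.

    A pair of edge groups (A, B) with disjoint isoform sets forms an event
    when each group is a single directed chain, both chains share their
    endpoints (u, v), and a non-empty reference group carries exactly the
    union of the two isoform sets.  Nested and overlapping triplets are all
    emitted.
    """
    if method == "isoform_set":
        groups = group_edges_by_isoform_set(graph)
    elif method == "flow":
        groups = group_edges_by_flow(graph, seed=seed)
    else:
        raise ValueError(f"unknown grouping method {method!r}")

    iso_sets = sorted(groups, key=lambda s: tuple(sorted(s)))
    triplets: list[RawTriplet] = []
    for i, iso_a in enumerate(iso_sets):
        for iso_b in iso_sets[i + 1:]:
            if iso_a & iso_b:
                continue
            ref = groups.get(iso_a | iso_b)
            if not ref:
                continue
            chain_a = _as_chain(groups[iso_a])
            chain_b = _as_chain(groups[iso_b])
            if chain_a is None or chain_b is None or chain_a != chain_b:
                continue
            triplets.append(RawTriplet(
                reference=tuple(ref),
                path_a=_order_chain(tuple(groups[iso_a])),
                path_b=_order_chain(tuple(groups[iso_b])),
                divergence=chain_a[0],
                convergence=chain_a[1],
            ))
    return triplets


# ---------------------------------------------------------------------------
# path assignment and classification

def path_genomic_length(path: tuple[GraphEdge, ...]) -> int:
    """Transcriptomic (exonic) length of a path in nucleotides."""
    return sum(e.exonic_length for e in path)


def assign_paths(
    triplet: RawTriplet, graph: ExtendedSplicingGraph
) -> tuple[tuple[GraphEdge, ...], tuple[GraphEdge, ...]]:
    """Order the two alternative paths: P1 is the genomically longer one.

    Length is measured in the transcriptome (summed exonic nucleotides of
    the path; junction gaps are untranscribed and contribute nothing), so
    in a cassette event the exon-containing path is always P1.  Exact ties
    are broken deterministically: the path whose leftmost genomic
    coordinate is smaller becomes P1.
    """
    def spans(path):
        return tuple(sorted(e.span for e in path if e.span is not None))

    a, b = triplet.path_a, triplet.path_b
    if path_genomic_length(a) != path_genomic_length(b):
        return (a, b) if path_genomic_length(a) > path_genomic_length(b) \
            else (b, a)
    return (a, b) if spans(a) <= spans(b) else (b, a)


def _is_real_junction(e: GraphEdge) -> bool:
    return e.kind == JUNCTION and e.gap > 0


def _interior_is_exonic(path) -> bool:
    return all(e.kind in (EXON, ADJACENCY) for e in path[1:-1])


def _junction_positions(path) -> list[int]:
    return [i for i, e in enumerate(path) if _is_real_junction(e)]


def classify_event(
    path1: tuple[GraphEdge, ...],
    path2: tuple[GraphEdge, ...],
    divergence: str,
    convergence: str,
    strand: str,
) -> str:
    """Label an event with one of the 7 canonical categories or complex.

    The decision uses only the structure of the two alternative subpaths
    (edge kinds and their order) plus the strand, which flips the
    donor/acceptor and first/last interpretations for minus-strand genes.
    """
    minus = strand == "-"
    if divergence == START and convergence == END:
        return COMPLEX
    if divergence == START:
        if all(_is_terminal_exon_path(p, at_start=True) for p in (path1, path2)):
            return ALT_LAST if minus else ALT_FIRST
        return COMPLEX
    if convergence == END:
        if all(_is_terminal_exon_path(p, at_start=False) for p in (path1, path2)):
            return ALT_FIRST if minus else ALT_LAST
        return COMPLEX

    # internal divergence and convergence
    for short, other in ((path2, path1), (path1, path2)):
        if len(short) == 1 and _is_real_junction(short[0]):
            jpos = _junction_positions(other)
            exonic_rest = all(
                e.kind in (EXON, ADJACENCY)
                for i, e in enumerate(other) if i not in jpos
            )
            if not exonic_rest:
                return COMPLEX
            if len(jpos) == 0:
                return RETAINED_INTRON
            if len(jpos) == 2 and jpos == [0, len(other) - 1] and len(other) >= 3:
                return CASSETTE
            if len(jpos) == 1 and jpos[0] in (0, len(other) - 1) and len(other) >= 2:
                # one shared splice site; the exon extension sits on the
                # other side of the single junction
                if jpos[0] == len(other) - 1:
                    # extension at the divergence side (genomic left)
                    return ALT3 if minus else ALT5
                return ALT5 if minus else ALT3
            return COMPLEX

    def _me_path(p) -> bool:
        return (
            len(p) >= 3
            and _is_real_junction(p[0])
            and _is_real_junction(p[-1])
            and _interior_is_exonic(p)
        )

    if _me_path(path1) and _me_path(path2):
        return MUTUALLY_EXCLUSIVE
    return COMPLEX


def _is_terminal_exon_path(path, at_start: bool) -> bool:
    """start_link.exon(s).junction (or its mirror at the END side)."""
    if len(path) < 3:
        return False
    first, last, interior = path[0], path[-1], path[1:-1]
    if at_start:
        ok_ends = first.kind == START_LINK and _is_real_junction(last)
    else:
        ok_ends = _is_real_junction(first) and last.kind == END_LINK
    return ok_ends and all(e.kind in (EXON, ADJACENCY) for e in interior)


def _event_window(
    triplet: RawTriplet, graph: ExtendedSplicingGraph
) -> tuple[int, int]:
    """Genomic window of an event, including the flanking boundary subexons."""
    spans = [
        e.span for e in triplet.path_a + triplet.path_b if e.span is not None
    ]
    lo = min(s[0] for s in spans)
    hi = max(s[1] for s in spans)
    u_se = graph.subexon_of_node(triplet.divergence)
    v_se = graph.subexon_of_node(triplet.convergence)
    if u_se is not None:
        lo = min(lo, u_se.start)
    if v_se is not None:
        hi = max(hi, v_se.end)
    return lo, hi


def detect_events(
    graph: ExtendedSplicingGraph,
    method: str = "isoform_set",
    seed: int = 0,
) -> list[Event]:
    """Enumerate, orient, classify and deterministically number the events."""
    triplets = enumerate_events(graph, method=method, seed=seed)
    drafts = []
    for t in triplets:
        p1, p2 = assign_paths(t, graph)
        category = classify_event(p1, p2, t.divergence, t.convergence,
                                  graph.strand)
        window = _event_window(t, graph)
        drafts.append((window, category, t, p1, p2))
    drafts.sort(key=lambda d: (d[0], d[1], d[3][0].source, d[3][-1].target))
    events = []
    for i, (window, category, t, p1, p2) in enumerate(drafts, start=1):
        iso1 = p1[0].isoform_set
        iso2 = p2[0].isoform_set
        iso_ref = t.reference[0].isoform_set
        assert not (iso1 & iso2) and iso_ref == (iso1 | iso2)
        events.append(Event(
            event_id=f"{graph.gene_id}_{i}",
            gene_id=graph.gene_id,
            chrom=graph.chrom,
            strand=graph.strand,
            category=category,
            reference_path=t.reference,
            path1=p1,
            path2=p2,
            divergence=t.divergence,
            convergence=t.convergence,
            genomic_window=window,
        ))
    return events
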