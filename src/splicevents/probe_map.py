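"""Placement of probes on splicing-graph edges and probeset construction.

Probes are short oligos measured on the array.  A probe whose sequence lies
wholly inside one subexon measures that subexon's exon edge; a probe
straddling the boundary between two consecutive subexons of an isoform
measures the junction (or adjacency) edge joining them.  Probes are matched
by exact (mismatch-free) substring search against the spliced transcript
sequences; alternatively a pre-computed genomic placement can be supplied.

Probes hitting more than 3 genes are discarded as non-informative; probes
spanning three or more subexons are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .transcript_graph import ExtendedSplicingGraph, find_subexon

logger = logging.getLogger(__name__)

MIN_PROBE_LENGTH = 16

#: probe_id -> set of (gene_id, (source, target)) edge hits
ProbeHits = dict[str, set[tuple[str, tuple[str, str]]]]


@dataclass(frozen=True)
class ProbeRecord:
    """A probe given either by sequence or by genomic placement blocks."""

    probe_id: str
    sequence: str | None = None
    chrom: str | None = None
    blocks: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.sequence is not None and len(self.sequence) < MIN_PROBE_LENGTH:
            raise ValueError(
                f"{self.probe_id}: probe sequence shorter than "
                f"{MIN_PROBE_LENGTH} nt"
            )
        if self.sequence is None and not self.blocks:
            raise ValueError(f"{self.probe_id}: needs a sequence or blocks")


def spliced_sequence(
    graph: ExtendedSplicingGraph, transcript_id: str, genome: dict[str, str]
) -> tuple[str, list[int]]:
    """Spliced (mature) sequence of an isoform plus its genomic position map.

    ``genome`` maps chromosome name to its full forward-strand sequence
    (1-based positions; index 0 of the string is position 1).  Returns the
    concatenated exonic sequence and, per transcript position, the genomic
    coordinate it came from.
    """
    chrom_seq = genome[graph.chrom]
    seq_parts: list[str] = []
    pos_map: list[int] = []
    for u, v in graph.transcript_paths[transcript_id]:
        e = graph.edge(u, v)
        if e.kind == "exon":
            s, t = e.span
            seq_parts.append(chrom_seq[s - 1 : t])
            pos_map.extend(range(s, t + 1))
    return "".join(seq_parts), pos_map


def _subexon_chain(graph: ExtendedSplicingGraph, transcript_id: str):
    chain = []
    for u, v in graph.transcript_paths[transcript_id]:
        if graph.edge(u, v).kind == "exon":
            chain.append(graph.subexon_of_node(u))
    return chain


def map_probes(
    probes: list[ProbeRecord],
    graphs: dict[str, ExtendedSplicingGraph],
    genome: dict[str, str] | None = None,
) -> ProbeHits:
    """Map every probe to the (gene, edge) pairs it measures.

    Sequence probes are searched exactly in every spliced transcript of
    every gene; placement probes are resolved directly against subexon
    coordinates.  Probes matching nothing are dropped with a log entry.
    """
    hits: ProbeHits = {}
    # pre-compute spliced sequences once
    spliced: list[tuple[str, str, str, list[int]]] = []  # gene, tid, seq, map
    if genome is not None:
        for gene_id, graph in graphs.items():
            for tid in graph.transcript_paths:
                seq, pos_map = spliced_sequence(graph, tid, genome)
                spliced.append((gene_id, tid, seq, pos_map))

    for probe in probes:
        probe_hits: set[tuple[str, tuple[str, str]]] = set()
        if probe.sequence is not None:
            for gene_id, tid, seq, pos_map in spliced:
                start = seq.find(probe.sequence)
                while start != -1:
                    key = _resolve_occurrence(
                        graphs[gene_id], tid, pos_map, start,
                        len(probe.sequence), probe.probe_id,
                    )
                    if key is not None:
                        probe_hits.add((gene_id, key))
                    start = seq.find(probe.sequence, start + 1)
        else:
            probe_hits = _resolve_placement(probe, graphs)
        if probe_hits:
            hits[probe.probe_id] = probe_hits
        else:
            logger.info("probe %s matched no transcript; dropped",
                        probe.probe_id)
    return hits


def _resolve_occurrence(graph, transcript_id, pos_map, start, length,
                        probe_id):
    """Edge key for one exact match of a probe in one transcript."""
    gpos_first = pos_map[start]
    gpos_last = pos_map[start + length - 1]
    chain = _subexon_chain(graph, transcript_id)
    touched = [
        se for se in chain
        if not (se.end < gpos_first or se.start > gpos_last)
    ]
    if len(touched) == 1:
        se = touched[0]
        return (f"{se.subexon_id}.a", f"{se.subexon_id}.b")
    if len(touched) == 2:
        u, v = touched
        return (f"{u.subexon_id}.b", f"{v.subexon_id}.a")
    logger.warning("probe %s spans %d subexons in %s; occurrence dropped",
                   probe_id, len(touched), transcript_id)
    return None


def _resolve_placement(probe: ProbeRecord, graphs) -> set:
    out = set()
    for gene_id, graph in graphs.items():
        if probe.chrom is not None and probe.chrom != graph.chrom:
            continue
        subexons = sorted(graph.subexons.values(), key=lambda s: s.interval)
        if len(probe.blocks) == 1:
            s, e = probe.blocks[0]
            se = find_subexon(subexons, s)
            if se is not None and se.start <= s and e <= se.end:
                key = (f"{se.subexon_id}.a", f"{se.subexon_id}.b")
                if graph.graph.has_edge(*key):
                    out.add((gene_id, key))
        elif len(probe.blocks) == 2:
            (s1, e1), (s2, e2) = sorted(probe.blocks)
            u = find_subexon(subexons, e1)
            v = find_subexon(subexons, s2)
            if u is not None and v is not None and u.end == e1 and v.start == s2:
                key = (f"{u.subexon_id}.b", f"{v.subexon_id}.a")
                if graph.graph.has_edge(*key):
                    out.add((gene_id, key))
        else:
            logger.warning("probe %s has %d blocks; only 1 or 2 supported",
                           probe.probe_id, len(probe.blocks))
    return out


def filter_multimapping(hits: ProbeHits, max_genes: int = 3) -> ProbeHits:
    """Drop probes hitting more than ``max_genes`` distinct genes."""
    kept: ProbeHits = {}
    removed = 0
    for probe_id, probe_hits in hits.items():
        n_genes = len({gene for gene, _ in probe_hits})
        if n_genes <= max_genes:
            kept[probe_id] = probe_hits
        else:
            removed += 1
    if removed:
        logger.info("multimap filter removed %d probes (> %d genes)",
                    removed, max_genes)
    return kept


def assign_probes_to_graph(graph: ExtendedSplicingGraph,
                           hits: ProbeHits) -> set[tuple[str, str]]:
    """Fill per-edge probe sets for one gene; returns the probed edge keys."""
    probed: set[tuple[str, str]] = set()
    for e in graph.edges():
        e.probe_ids = set()
    for probe_id, probe_hits in hits.items():
        for gene_id, key in probe_hits:
            if gene_id == graph.gene_id and graph.graph.has_edge(*key):
                graph.edge(*key).probe_ids.add(probe_id)
                probed.add(key)
    return probed


@dataclass
class ProbesetMap:
    """Grouping of probes into per-event path probesets (the CDF analogue)."""

    table: pd.DataFrame  # columns: event_id, path, probe_id
    unmeasurable: set[str]

    PATHS = ("Ref", "P1", "P2")

    def probes(self, event_id: str, path: str) -> list[str]:
        t = self.table
        return sorted(t[(t.event_id == event_id) & (t.path == path)].probe_id)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ProbesetMap":
        table = pd.read_csv(path, sep="\t", dtype=str)
        table = table[["event_id", "path", "probe_id"]]
        return cls(table=table.reset_index(drop=True), unmeasurable=set())


def build_probeset_map(events, hits: ProbeHits) -> ProbesetMap:
    """Pool probes per event path into probesets.

    Every edge of a path contributes its probes to the path's probeset, so
    e.g. a cassette inclusion probeset pools the exon and both flanking
    junctions.  Events with any empty path probeset are flagged
    unmeasurable and excluded from the statistics stage.
    """
    edge_probes: dict[tuple[str, tuple[str, str]], set[str]] = {}
    for probe_id, probe_hits in hits.items():
        for gene_edge in probe_hits:
            edge_probes.setdefault(gene_edge, set()).add(probe_id)

    rows = []
    unmeasurable: set[str] = set()
    for ev in events:
        path_sets = {}
        for label, path in (("Ref", ev.reference_path),
                            ("P1", ev.path1), ("P2", ev.path2)):
            pool: set[str] = set()
            for edge in path:
                pool |= edge_probes.get((ev.gene_id, edge.key), set())
            path_sets[label] = pool
        if any(not s for s in path_sets.values()):
            unmeasurable.add(ev.event_id)
            continue
        for label in ProbesetMap.PATHS:
            for probe_id in sorted(path_sets[label]):
                rows.append((ev.event_id, label, probe_id))
    table = pd.DataFrame(rows, columns=["event_id", "path", "probe_id"])
    if unmeasurable:
        logger.info("%d events unmeasurable (some path without probes)",
                    len(unmeasurable))
    return ProbesetMap(table=table, unmeasurable=unmeasurable)
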