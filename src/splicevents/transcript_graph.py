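"""Gene models, subexon decomposition and the extended splicing graph.

A gene is represented by its transcript isoforms, each an ordered list of
exon intervals (1-based, inclusive, GTF convention).  The gene is decomposed
into *subexons*: maximal contiguous genomic regions whose every base belongs
to the same set of transcripts.  Subexons become nodes of a directed acyclic
splicing graph; each node is then split into an entry node (``.a``) and an
exit node (``.b``) so that exon bodies (``.a -> .b``) and junctions
(``.b -> .a``) are both edges.  Probes can then live exclusively on edges:
exon probes on exon edges, junction probes on junction/adjacency edges.

Graphs are always laid out in genomic left-to-right orientation regardless
of strand; strand is consulted only when event categories are labelled.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
import pyranges

logger = logging.getLogger(__name__)

START = "START"
END = "END"


class GTFParseError(ValueError):
    """Raised when an annotation line cannot be parsed."""


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered list of disjoint exon intervals."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: chromosome, strand, and >=1 transcript isoforms."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene without transcripts")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.gene_id}: duplicate transcript ids")

    @property
    def transcript_ids(self) -> tuple[str, ...]:
        return tuple(t.transcript_id for t in self.transcripts)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class Subexon:
    """Maximal contiguous region whose bases share one transcript set."""

    subexon_id: str
    interval: tuple[int, int]
    transcript_set: frozenset[str]

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1


EXON = "exon"
JUNCTION = "junction"
ADJACENCY = "adjacency"
START_LINK = "start_link"
END_LINK = "end_link"


@dataclass
class GraphEdge:
    """One edge of the extended splicing graph.

    ``span`` is the genomic interval covered by the edge: the subexon body
    for exon edges, the (possibly empty) genomic gap for junction and
    adjacency edges, and ``None`` for start/end links.
    """

    source: str
    target: str
    kind: str
    span: tuple[int, int] | None
    isoform_set: frozenset[str]
    probe_ids: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)

    @property
    def gap(self) -> int:
        """Genomic gap bridged by a junction edge (0 for everything else)."""
        if self.kind not in (JUNCTION, ADJACENCY) or self.span is None:
            return 0
        return max(0, self.span[1] - self.span[0] + 1)

    @property
    def exonic_length(self) -> int:
        """Transcribed nucleotides carried by the edge."""
        if self.kind == EXON:
            return self.span[1] - self.span[0] + 1
        return 0


@dataclass
class ExtendedSplicingGraph:
    """a/b-duplicated splicing graph of a single gene.

    ``graph`` is a :class:`networkx.DiGraph` whose edges carry a
    :class:`GraphEdge` under the ``"edge"`` attribute.  ``transcript_paths``
    maps every isoform to its full START -> ... -> END edge-key sequence.
    """

    gene_id: str
    chrom: str
    strand: str
    graph: nx.DiGraph
    subexons: dict[str, Subexon]
    transcript_paths: dict[str, list[tuple[str, str]]]

    def edge(self, u: str, v: str) -> GraphEdge:
        return self.graph.edges[u, v]["edge"]

    def edges(self) -> list[GraphEdge]:
        return [d["edge"] for _, _, d in self.graph.edges(data=True)]

    def subexon_of_node(self, node: str) -> Subexon | None:
        if node in (START, END):
            return None
        return self.subexons[node.rsplit(".", 1)[0]]

    def copy_with_edges(self, keys: set[tuple[str, str]]) -> "ExtendedSplicingGraph":
        """New graph containing only the edges in ``keys`` (nodes implied)."""
        g = nx.DiGraph()
        for u, v in keys:
            g.add_edge(u, v, edge=self.graph.edges[u, v]["edge"])
        return ExtendedSplicingGraph(
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            graph=g,
            subexons=self.subexons,
            transcript_paths=self.transcript_paths,
        )


def _validate_gtf_lines(path: str) -> int:
    """Cheap syntactic pass so malformed lines are reported by number."""
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise GTFParseError(
                    f"{path}: line {lineno}: start {start} > end {end}"
                )
            n_features += 1
    return n_features


def load_gtf(path: str) -> list[GeneModel]:
    """Read gene models from a GTF file (ensembl attribute dialect).

    Only ``exon`` features are used; they must carry ``gene_id`` and
    ``transcript_id`` attributes.  Coordinates are kept 1-based inclusive.
    Genes whose transcripts span several chromosomes or strands, or whose
    exons overlap within one transcript, are rejected with a log entry.
    """
    if _validate_gtf_lines(path) == 0:
        return []
    df = pyranges.read_gtf(path).df
    df = df[df.Feature == "exon"]
    if df.empty:
        return []
    if "transcript_id" not in df.columns or "gene_id" not in df.columns:
        raise GTFParseError(f"{path}: exon features lack gene_id/transcript_id")
    # pyranges uses 0-based half-open coordinates internally
    df = df.assign(start1=df.Start + 1, end1=df.End)
    genes: list[GeneModel] = []
    for gene_id, gdf in df.groupby("gene_id", sort=True, observed=True):
        chroms = set(map(str, gdf.Chromosome))
        strands = set(map(str, gdf.Strand))
        if len(chroms) > 1 or len(strands) > 1:
            logger.warning(
                "gene %s rejected: spans chromosomes %s / strands %s",
                gene_id, sorted(chroms), sorted(strands),
            )
            continue
        try:
            transcripts = tuple(
                TranscriptModel(
                    transcript_id=str(tid),
                    exons=tuple(zip(tdf.start1, tdf.end1)),
                )
                for tid, tdf in gdf.groupby("transcript_id", sort=True,
                                            observed=True)
            )
            genes.append(
                GeneModel(str(gene_id), chroms.pop(), strands.pop(), transcripts)
            )
        except ValueError as exc:
            logger.warning("gene %s rejected: %s", gene_id, exc)
    return genes


def decompose_subexons(gene: GeneModel) -> list[Subexon]:
    """Cut a gene into subexons.

    Breakpoints are placed at every distinct exon start and end across all
    transcripts; runs of contiguous segments with identical transcript
    membership are merged back, so the result is the coarsest partition of
    the exonic bases into same-membership regions.
    """
    breaks: set[int] = set()
    for t in gene.transcripts:
        for s, e in t.exons:
            breaks.add(s)
            breaks.add(e + 1)
    points = sorted(breaks)
    raw: list[tuple[int, int, frozenset[str]]] = []
    for lo, hi in zip(points[:-1], points[1:]):
        members = frozenset(
            t.transcript_id
            for t in gene.transcripts
            if any(s <= lo and hi - 1 <= e for s, e in t.exons)
        )
        if members:
            raw.append((lo, hi - 1, members))
    # merge zero-gap neighbours with identical membership (maximality)
    merged: list[tuple[int, int, frozenset[str]]] = []
    for seg in raw:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] + 1 == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(list(seg))  # type: ignore[arg-type]
    return [
        Subexon(f"{gene.gene_id}:SE{i:03d}", (lo, hi), members)
        for i, (lo, hi, members) in enumerate(merged, start=1)
    ]


def build_extended_graph(
    gene: GeneModel, subexons: list[Subexon] | None = None
) -> ExtendedSplicingGraph:
    """Build the a/b-extended splicing graph of a gene.

    Every subexon ``v`` contributes an exon edge ``v.a -> v.b`` carrying the
    subexon's transcript set; consecutive subexons of an isoform are joined
    ``u.b -> v.a`` (an *adjacency* edge when the genomic gap is zero, a
    *junction* edge otherwise).  START links to the first subexon of every
    isoform and the last subexon of every isoform links to END, so each
    isoform traces a simple START -> END path.
    """
    if subexons is None:
        subexons = decompose_subexons(gene)
    subexons = sorted(subexons, key=lambda s: s.interval)
    g = nx.DiGraph()
    edges: dict[tuple[str, str], GraphEdge] = {}

    def add(u, v, kind, span, tid):
        if (u, v) in edges:
            edges[(u, v)].isoform_set = edges[(u, v)].isoform_set | {tid}
        else:
            edges[(u, v)] = GraphEdge(u, v, kind, span, frozenset({tid}))

    paths: dict[str, list[tuple[str, str]]] = {}
    for t in gene.transcripts:
        chain = [
            se for se in subexons if t.transcript_id in se.transcript_set
        ]
        # a transcript's subexons must tile its exons exactly
        assert sum(se.length for se in chain) == t.length
        path: list[tuple[str, str]] = []
        a0 = f"{chain[0].subexon_id}.a"
        add(START, a0, START_LINK, None, t.transcript_id)
        path.append((START, a0))
        for i, se in enumerate(chain):
            a, b = f"{se.subexon_id}.a", f"{se.subexon_id}.b"
            add(a, b, EXON, se.interval, t.transcript_id)
            path.append((a, b))
            if i + 1 < len(chain):
                nxt = chain[i + 1]
                gap_span = (se.end + 1, nxt.start - 1)
                kind = ADJACENCY if nxt.start == se.end + 1 else JUNCTION
                add(b, f"{nxt.subexon_id}.a", kind, gap_span, t.transcript_id)
                path.append((b, f"{nxt.subexon_id}.a"))
        bL = f"{chain[-1].subexon_id}.b"
        add(bL, END, END_LINK, None, t.transcript_id)
        path.append((bL, END))
        paths[t.transcript_id] = path

    for (u, v), e in edges.items():
        g.add_edge(u, v, edge=e)
    esg = ExtendedSplicingGraph(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        graph=g,
        subexons={s.subexon_id: s for s in subexons},
        transcript_paths=paths,
    )
    assert nx.is_directed_acyclic_graph(g)
    return esg


def find_subexon(subexons: list[Subexon], pos: int) -> Subexon | None:
    """Subexon containing genomic position ``pos`` (subexons sorted)."""
    starts = [s.start for s in subexons]
    i = bisect_right(starts, pos) - 1
    if i >= 0 and subexons[i].start <= pos <= subexons[i].end:
        return subexons[i]
    return None


def subexon_table(genes_subexons: dict[str, list[Subexon]],
                  genes: dict[str, GeneModel]) -> pd.DataFrame:
    """Flat TSV-ready table of subexons (one row per subexon)."""
    rows = []
    for gene_id, sxs in genes_subexons.items():
        gene = genes[gene_id]
        for s in sorted(sxs, key=lambda s: s.interval):
            rows.append({
                "gene_id": gene_id,
                "subexon_id": s.subexon_id,
                "chrom": gene.chrom,
                "start": s.start,
                "end": s.end,
                "transcripts": ",".join(sorted(s.transcript_set)),
            })
    return pd.DataFrame(
        rows, columns=["gene_id", "subexon_id", "chrom", "start", "end",
                       "transcripts"]
    )
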