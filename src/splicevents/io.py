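"""Readers and writers for the package's plain-text interchange formats.

Everything is TSV with a header (or GTF/BED/FASTA where a genome-browser
convention exists).  Genomic coordinates are 1-based inclusive everywhere
except BED output, which uses the 0-based half-open convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probe_map import ProbeRecord
from .transcript_graph import GeneModel

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# GTF / FASTA

def write_gtf(genes: list[GeneModel], path: str) -> None:
    """Write gene models as exon features (ensembl attribute dialect)."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                for s, e in t.exons:
                    attrs = (f'gene_id "{gene.gene_id}"; '
                             f'transcript_id "{t.transcript_id}";')
                    fh.write("\t".join([
                        gene.chrom, "splicevents", "exon", str(s), str(e),
                        ".", gene.strand, ".", attrs,
                    ]) + "\n")


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# probes / signals / matrices

def write_probe_table(probes: list[ProbeRecord], path: str) -> None:
    rows = []
    for p in probes:
        blocks = (",".join(f"{s}-{e}" for s, e in p.blocks)
                  if p.blocks else "")
        rows.append((p.probe_id, p.sequence or "", p.chrom or "", blocks))
    pd.DataFrame(rows, columns=["probe_id", "sequence", "chrom", "blocks"]) \
        .to_csv(path, sep="\t", index=False)


def read_probe_table(path: str) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    probes = []
    for rec in df.itertuples(index=False):
        blocks = None
        if rec.blocks:
            blocks = tuple(
                tuple(int(x) for x in b.split("-"))
                for b in rec.blocks.split(",")
            )
        probes.append(ProbeRecord(
            probe_id=rec.probe_id,
            sequence=rec.sequence or None,
            chrom=rec.chrom or None,
            blocks=blocks,
        ))
    return probes


def read_signal_matrix(path: str) -> pd.DataFrame:
    """Probe x sample signal TSV; first column is the probe id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError(f"{path}: signal matrix contains non-finite values")
    return df


def write_signal_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id",
              float_format=FLOAT_FORMAT)


def read_design_matrix(path: str) -> np.ndarray:
    """Numeric TSV with a header row of coefficient names."""
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_design_matrix(M: np.ndarray, path: str,
                        names: list[str] | None = None) -> None:
    M = np.atleast_2d(M)
    if names is None:
        names = [f"coef{i + 1}" for i in range(M.shape[1])]
    pd.DataFrame(M, columns=names).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# events

@dataclass
class EdgeRecord:
    source: str
    target: str
    kind: str
    span: tuple[int, int] | None


@dataclass
class EventRecord:
    """Deserialized event: enough structure for IGV export and domains."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    category: str
    genomic_window: tuple[int, int]
    reference_path: tuple[EdgeRecord, ...]
    path1: tuple[EdgeRecord, ...]
    path2: tuple[EdgeRecord, ...]
    isoforms_path1: frozenset[str]
    isoforms_path2: frozenset[str]


def _edge_token(e) -> str:
    span = f"{e.span[0]}-{e.span[1]}" if e.span is not None else "."
    return f"{e.source}>{e.target}|{e.kind}|{span}"


def _parse_edge_token(token: str) -> EdgeRecord:
    nodes, kind, span = token.split("|")
    source, target = nodes.split(">")
    parsed = None
    if span != ".":
        a, b = span.split("-")
        parsed = (int(a), int(b))
    return EdgeRecord(source, target, kind, parsed)


def write_events(events, path: str) -> None:
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "category": ev.category,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "start": ev.genomic_window[0],
            "end": ev.genomic_window[1],
            "path_ref": ",".join(_edge_token(e) for e in ev.reference_path),
            "path1": ",".join(_edge_token(e) for e in ev.path1),
            "path2": ",".join(_edge_token(e) for e in ev.path2),
            "isoforms_path1": ",".join(sorted(ev.isoforms_path1)),
            "isoforms_path2": ",".join(sorted(ev.isoforms_path2)),
        })
    pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "category", "chrom", "strand", "start", "end",
        "path_ref", "path1", "path2", "isoforms_path1", "isoforms_path2",
    ]).to_csv(path, sep="\t", index=False)


def read_events(path: str) -> list[EventRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    events = []
    for rec in df.itertuples(index=False):
        events.append(EventRecord(
            event_id=rec.event_id,
            gene_id=rec.gene_id,
            chrom=rec.chrom,
            strand=rec.strand,
            category=rec.category,
            genomic_window=(int(rec.start), int(rec.end)),
            reference_path=tuple(_parse_edge_token(t)
                                 for t in rec.path_ref.split(",")),
            path1=tuple(_parse_edge_token(t) for t in rec.path1.split(",")),
            path2=tuple(_parse_edge_token(t) for t in rec.path2.split(",")),
            isoforms_path1=frozenset(rec.isoforms_path1.split(",")),
            isoforms_path2=frozenset(rec.isoforms_path2.split(",")),
        ))
    return events


# ---------------------------------------------------------------------------
# IGV track export

def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def _path_blocks(path) -> list[tuple[int, int]]:
    """Displayable genomic blocks of a path (1-based inclusive).

    Exon edges contribute their intervals; a junction edge contributes two
    1-nt anchors flanking its gap so that probe-less skip paths are still
    visible as connected features.
    """
    blocks: list[tuple[int, int]] = []
    for e in path:
        if e.kind == "exon":
            blocks.append(e.span)
        elif e.kind == "junction" and e.span is not None:
            blocks.append((e.span[0] - 1, e.span[0] - 1))
            blocks.append((e.span[1] + 1, e.span[1] + 1))
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def write_igv_gtf(events, path: str, graphs=None) -> None:
    """Event track: per event three grouped features (Ref/P1/P2) + probes.

    When per-gene graphs (with probe assignments) are supplied, each probe
    is emitted as a sub-feature located on its edge's display blocks.
    """
    with open(path, "w") as fh:
        for ev in events:
            for label, p in (("Ref", ev.reference_path), ("P1", ev.path1),
                             ("P2", ev.path2)):
                tid = f"{ev.event_id}_{label}"
                for s, e in _path_blocks(p):
                    attrs = (f'gene_id "{ev.event_id}"; '
                             f'transcript_id "{tid}"; '
                             f'category "{ev.category}";')
                    fh.write("\t".join([
                        ev.chrom, "splicevents", "exon", str(s), str(e), ".",
                        ev.strand, ".", attrs,
                    ]) + "\n")
                if graphs is not None and ev.gene_id in graphs:
                    graph = graphs[ev.gene_id]
                    for edge in p:
                        if not graph.graph.has_edge(edge.source, edge.target):
                            continue
                        ge = graph.edge(edge.source, edge.target)
                        for pid in sorted(ge.probe_ids):
                            for s, e in _path_blocks((ge,)):
                                attrs = (f'gene_id "{ev.event_id}"; '
                                         f'transcript_id "{tid}_probes"; '
                                         f'probe_id "{pid}";')
                                fh.write("\t".join([
                                    ev.chrom, "splicevents", "exon", str(s),
                                    str(e), ".", ev.strand, ".", attrs,
                                ]) + "\n")


def write_igv_bed(events, path: str) -> None:
    """BED12 track: one line per event path with its display blocks."""
    with open(path, "w") as fh:
        for ev in events:
            for label, p in (("Ref", ev.reference_path), ("P1", ev.path1),
                             ("P2", ev.path2)):
                blocks = _path_blocks(p)
                if not blocks:
                    continue
                chrom_start = to_bed_interval(*blocks[0])[0]
                chrom_end = to_bed_interval(*blocks[-1])[1]
                sizes = ",".join(str(e - s + 1) for s, e in blocks)
                starts = ",".join(
                    str(to_bed_interval(s, e)[0] - chrom_start)
                    for s, e in blocks
                )
                fh.write("\t".join(map(str, [
                    ev.chrom, chrom_start, chrom_end,
                    f"{ev.event_id}_{label}", 0, ev.strand,
                    chrom_start, chrom_end, "0,0,0",
                    len(blocks), sizes, starts,
                ])) + "\n")


# ---------------------------------------------------------------------------
# results / domains

def write_results(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_domain_table(path: str) -> pd.DataFrame:
    """TSV: transcript_id, domain_id [, start, end] (transcript-relative)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "domain_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: domain table needs columns {required}")
    return df


def write_enrichment(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
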