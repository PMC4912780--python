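"""Protein-domain annotation of event paths and enrichment testing.

Each alternative path of an event is marked with the protein domains
carried by its isoforms inside the event's genomic window.  A domain that
marks exactly one path of an event is *informative* there: the event
contributes a pair (log FC of the domain-bearing path, log FC of the other
path) and a paired Wilcoxon signed-rank test asks whether domain-bearing
paths are systematically over- or under-used.  Domains present in both
paths of an event (constitutive regions) are non-informative for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .transcript_graph import GeneModel

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25  # exact signed-rank distribution up to here, normal beyond


@dataclass
class PathDomainMatrix:
    """Sparse boolean (event path) x domain incidence matrix.

    Rows come in (P1, P2) pairs per event; only the alternative paths are
    annotated (the reference is shared by construction).
    """

    event_ids: list[str]
    domains: list[str]
    matrix: sparse.csr_matrix  # shape (2 * n_events, n_domains)

    def row(self, event_index: int, path: str) -> int:
        return 2 * event_index + (0 if path == "P1" else 1)

    def marks(self, domain_index: int) -> np.ndarray:
        """(n_events, 2) boolean marks of one domain on P1/P2."""
        col = self.matrix.getcol(domain_index).toarray().ravel()
        return col.reshape(-1, 2).astype(bool)


@dataclass
class DomainEnrichmentResult:
    domain_id: str
    n_informative_events: int
    direction: str              # "over" or "under"
    p_value: float
    p_over: float
    p_under: float


def transcript_to_genomic(
    gene: GeneModel, transcript_id: str, interval: tuple[int, int]
) -> list[tuple[int, int]]:
    """Project a transcript-relative interval onto genomic blocks.

    Transcript coordinates are 1-based along the spliced (mature)
    transcript in 5'->3' order, so they run genomically right-to-left for
    minus-strand genes.
    """
    t = gene.transcript(transcript_id)
    positions: list[int] = []
    exons = t.exons if gene.strand == "+" else tuple(reversed(t.exons))
    for s, e in exons:
        rng = range(s, e + 1) if gene.strand == "+" else range(e, s - 1, -1)
        positions.extend(rng)
    lo, hi = interval
    chunk = positions[max(lo - 1, 0):hi]
    if not chunk:
        return []
    blocks: list[tuple[int, int]] = []
    run = [chunk[0], chunk[0]]
    for p in chunk[1:]:
        if abs(p - run[1]) == 1:
            run[1] = p
        else:
            blocks.append((min(run), max(run)))
            run = [p, p]
    blocks.append((min(run), max(run)))
    return blocks


def annotate_paths(
    events,
    domain_table: pd.DataFrame,
    genes: dict[str, GeneModel],
) -> PathDomainMatrix:
    """Mark each alternative path with the domains its isoforms carry.

    ``domain_table`` columns: transcript_id, domain_id and optionally
    start/end (transcript-relative, 1-based).  With coordinates, a domain
    marks a path only when its genomic projection on some isoform of the
    path overlaps the event window (flanking subexons included); without
    coordinates carriage by an isoform of the path suffices.  Unknown
    transcript ids are ignored with a warning.
    """
    domains = sorted(domain_table.domain_id.unique())
    dom_index = {d: i for i, d in enumerate(domains)}
    has_coords = {"start", "end"} <= set(domain_table.columns)

    by_transcript: dict[str, list[tuple[str, tuple[int, int] | None]]] = {}
    known = {
        t.transcript_id for g in genes.values() for t in g.transcripts
    }
    unknown = set()
    for rec in domain_table.itertuples(index=False):
        if rec.transcript_id not in known:
            unknown.add(rec.transcript_id)
            continue
        iv = None
        if has_coords and pd.notna(rec.start) and pd.notna(rec.end):
            iv = (int(rec.start), int(rec.end))
        by_transcript.setdefault(rec.transcript_id, []).append(
            (rec.domain_id, iv)
        )
    if unknown:
        logger.warning("%d transcript ids in the domain table are unknown "
                       "and were ignored", len(unknown))

    events = list(events)
    mat = sparse.lil_matrix((2 * len(events), len(domains)), dtype=bool)
    for ei, ev in enumerate(events):
        gene = genes[ev.gene_id]
        w0, w1 = ev.genomic_window
        for pi, iso_set in ((0, ev.isoforms_path1), (1, ev.isoforms_path2)):
            for tid in iso_set:
                for domain_id, iv in by_transcript.get(tid, []):
                    if iv is not None:
                        blocks = transcript_to_genomic(gene, tid, iv)
                        if not any(s <= w1 and e >= w0 for s, e in blocks):
                            continue
                    mat[2 * ei + pi, dom_index[domain_id]] = True
    return PathDomainMatrix(
        event_ids=[ev.event_id for ev in events],
        domains=domains,
        matrix=mat.tocsr(),
    )


@lru_cache(maxsize=64)
def _signed_rank_tail(n: int) -> np.ndarray:
    """Exact null upper-tail P(W+ >= w) for w = 0..n(n+1)/2 (no ties)."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    tail = counts[::-1].cumsum()[::-1] / 2.0 ** n
    return tail


def _signed_rank_pvalues(d: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank p's (greater, less), Pratt zeros.

    Exact null distribution for small samples (a cached tie-free
    distribution serves the common case; scipy handles zeros and tied
    magnitudes), normal approximation with continuity correction beyond.
    """
    if np.all(d == 0):
        return 1.0, 1.0
    n = len(d)
    clean = np.all(d != 0) and len(np.unique(np.abs(d))) == n
    if n <= EXACT_N_MAX and clean:
        ranks = stats.rankdata(np.abs(d))
        w_plus = int(round(ranks[d > 0].sum()))
        w_minus = n * (n + 1) // 2 - w_plus
        tail = _signed_rank_tail(n)
        return float(tail[w_plus]), float(tail[w_minus])
    method = "exact" if n <= EXACT_N_MAX else "approx"
    kwargs = dict(zero_method="pratt", method=method)
    if method == "approx":
        kwargs["correction"] = True
    p_over = stats.wilcoxon(d, alternative="greater", **kwargs).pvalue
    p_under = stats.wilcoxon(d, alternative="less", **kwargs).pvalue
    return float(p_over), float(p_under)


def _aligned_logfc(matrix: PathDomainMatrix, event_stats: pd.DataFrame):
    """Per-event logFC arrays aligned to the matrix row order."""
    lfc1 = np.zeros(len(matrix.event_ids))
    lfc2 = np.zeros(len(matrix.event_ids))
    valid = np.zeros(len(matrix.event_ids), dtype=bool)
    for ei, event_id in enumerate(matrix.event_ids):
        if event_id in event_stats.index:
            row = event_stats.loc[event_id]
            lfc1[ei] = float(row.logFC_path1)
            lfc2[ei] = float(row.logFC_path2)
            valid[ei] = True
    return lfc1, lfc2, valid


def _domain_diffs(domain_index, matrix, lfc1, lfc2, valid,
                  csc=None) -> np.ndarray:
    """Paired differences (marked path logFC - other path logFC)."""
    if csc is None:
        csc = matrix.matrix.tocsc()
    rows = csc.indices[csc.indptr[domain_index]:csc.indptr[domain_index + 1]]
    marked: dict[int, list[int]] = {}
    for r in rows:
        marked.setdefault(r // 2, []).append(r % 2)
    diffs = []
    for ei, paths in marked.items():
        if len(paths) != 1 or not valid[ei]:
            continue
        diffs.append(lfc1[ei] - lfc2[ei] if paths[0] == 0
                     else lfc2[ei] - lfc1[ei])
    return np.asarray(diffs)


def test_domain(
    domain_index: int,
    matrix: PathDomainMatrix,
    event_stats: pd.DataFrame,
) -> DomainEnrichmentResult | None:
    """Paired signed-rank test of one domain across its informative events.

    ``event_stats`` must carry one row per event (indexed by event_id)
    with logFC_path1 and logFC_path2 columns.  Informative events are
    those where the domain marks exactly one path; the paired difference
    is (log FC of the marked path) - (log FC of the other path).  Returns
    None when no event is informative.
    """
    lfc1, lfc2, valid = _aligned_logfc(matrix, event_stats)
    d = _domain_diffs(domain_index, matrix, lfc1, lfc2, valid)
    if d.size == 0:
        return None
    p_over, p_under = _signed_rank_pvalues(d)
    direction = "over" if p_over <= p_under else "under"
    return DomainEnrichmentResult(
        domain_id=matrix.domains[domain_index],
        n_informative_events=len(d),
        direction=direction,
        p_value=min(p_over, p_under),
        p_over=p_over,
        p_under=p_under,
    )


def enrich_domains(
    matrix: PathDomainMatrix,
    event_stats: pd.DataFrame,
    p_max: float | None = 1e-3,
    expressed_only: bool = True,
) -> pd.DataFrame:
    """Run every domain's paired test over the significant event list.

    Events are restricted to those passing the expression filter and the
    combined p-value threshold before testing, then the table of results
    is ranked (see :func:`rank_domains`).
    """
    st = event_stats
    if "event_id" in st.columns:
        st = st.set_index("event_id")
    # with several contrasts per event keep the most significant row
    st = st[~st.index.duplicated(keep="first")]
    if expressed_only and "expressed" in st.columns:
        st = st[st.expressed]
    if p_max is not None and "pvalue" in st.columns:
        st = st[st.pvalue < p_max]
    lfc1, lfc2, valid = _aligned_logfc(matrix, st)
    csc = matrix.matrix.tocsc()
    results = []
    for di in range(len(matrix.domains)):
        d = _domain_diffs(di, matrix, lfc1, lfc2, valid, csc=csc)
        if d.size == 0:
            continue
        p_over, p_under = _signed_rank_pvalues(d)
        results.append(DomainEnrichmentResult(
            domain_id=matrix.domains[di],
            n_informative_events=len(d),
            direction="over" if p_over <= p_under else "under",
            p_value=min(p_over, p_under),
            p_over=p_over,
            p_under=p_under,
        ))
    return rank_domains(results, matrix)


def rank_domains(
    results: list[DomainEnrichmentResult],
    matrix: PathDomainMatrix | None = None,
) -> pd.DataFrame:
    """Sort by significance: over-expressed block first, then under.

    Domains with identical incidence columns (hence identical tests) are
    merged into a single row with comma-joined ids when the matrix is
    provided.
    """
    if matrix is not None and results:
        csc = matrix.matrix.tocsc()
        index_of = {d: i for i, d in enumerate(matrix.domains)}
        sig_of = {}
        for res in results:
            di = index_of[res.domain_id]
            rows = csc.indices[csc.indptr[di]:csc.indptr[di + 1]]
            sig_of[res.domain_id] = tuple(rows)
        merged: dict[bytes, list[DomainEnrichmentResult]] = {}
        for res in results:
            merged.setdefault(sig_of[res.domain_id], []).append(res)
        results = [
            DomainEnrichmentResult(
                domain_id=",".join(sorted(r.domain_id for r in group)),
                n_informative_events=group[0].n_informative_events,
                direction=group[0].direction,
                p_value=group[0].p_value,
                p_over=group[0].p_over,
                p_under=group[0].p_under,
            )
            for group in merged.values()
        ]
    rows = [{
        "domain_id": r.domain_id,
        "n_informative_events": r.n_informative_events,
        "direction": r.direction,
        "p_value": r.p_value,
    } for r in results]
    df = pd.DataFrame(
        rows, columns=["domain_id", "n_informative_events", "direction",
                       "p_value"],
    )
    if df.empty:
        return df
    df["_dir"] = (df.direction != "over").astype(int)
    df = (df.sort_values(["_dir", "p_value", "domain_id"])
            .drop(columns="_dir").reset_index(drop=True))
    df["padj"] = np.nan
    for direction in ("over", "under"):
        mask = df.direction == direction
        if mask.any():
            from .splice_stats import adjust_fdr
            df.loc[mask, "padj"] = adjust_fdr(df.loc[mask, "p_value"])
    return df
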