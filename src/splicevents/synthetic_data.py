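"""Ground-truthed synthetic transcriptomes, probes and signal matrices.

The generator emulates a junction/exon probe array experiment: multi-isoform
gene models embodying the canonical alternative-splicing patterns, probes
with unknown multiplicative affinities (~10 per exon, ~4 per junction), and
signals following the measurement model

    y_ij = log2(Affy_i * tau_j) + eps_ij,    eps_ij ~ N(0, sigma^2)

where tau_j is the summed concentration of the isoforms the probe
interrogates in sample j.  Everything is seeded and emits exactly the
formats the rest of the package consumes, so each module is testable
without external annotation or array files.

Template convention: in every canonical two-isoform gene, transcript T1 is
the isoform of the genomically longer path (P1) and T2 of the shorter
(P2), so concentrations (t1, t2) line up with the fitted coefficient
interpretations (b3+b4 = log2 FC of isoform 1, b3+b4+b5 = of isoform 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_detect import (
    ALT3, ALT5, ALT_FIRST, ALT_LAST, CASSETTE, CATEGORIES, COMPLEX,
    MUTUALLY_EXCLUSIVE, RETAINED_INTRON,
)
from .probe_map import ProbeRecord, ProbeHits, map_probes
from .transcript_graph import (
    ExtendedSplicingGraph, GeneModel, TranscriptModel, build_extended_graph,
)

logger = logging.getLogger(__name__)

NUCLEOTIDES = np.array(list("ACGT"))

# exon layouts (1-based inclusive) for each canonical pattern; T1 is always
# the P1 (genomically longer path) isoform
CANONICAL_TEMPLATES: dict[str, list[tuple[str, list[tuple[int, int]]]]] = {
    CASSETTE: [
        ("T1", [(101, 200), (301, 400), (501, 600)]),
        ("T2", [(101, 200), (501, 600)]),
    ],
    RETAINED_INTRON: [
        ("T1", [(101, 400)]),
        ("T2", [(101, 200), (301, 400)]),
    ],
    ALT5: [
        ("T1", [(101, 250), (401, 500)]),
        ("T2", [(101, 200), (401, 500)]),
    ],
    ALT3: [
        ("T1", [(101, 200), (351, 500)]),
        ("T2", [(101, 200), (401, 500)]),
    ],
    ALT_FIRST: [
        ("T1", [(101, 200), (501, 600)]),
        ("T2", [(301, 350), (501, 600)]),
    ],
    ALT_LAST: [
        ("T1", [(101, 200), (301, 420)]),
        ("T2", [(101, 200), (501, 600)]),
    ],
    MUTUALLY_EXCLUSIVE: [
        ("T1", [(101, 200), (301, 420), (701, 800)]),
        ("T2", [(101, 200), (501, 600), (701, 800)]),
    ],
    COMPLEX: [
        ("T1", [(101, 200), (301, 400), (451, 470), (701, 800)]),
        ("T2", [(101, 200), (501, 600), (701, 800)]),
    ],
}

# each canonical pattern with one alternative path broken by an extra
# internal splice, which demotes the event to "complex"
PERTURBED_TEMPLATES: dict[str, list[tuple[str, list[tuple[int, int]]]]] = {
    CASSETTE: [
        ("T1", [(101, 200), (301, 340), (361, 400), (501, 600)]),
        ("T2", [(101, 200), (501, 600)]),
    ],
    RETAINED_INTRON: [
        ("T1", [(101, 250), (271, 400)]),
        ("T2", [(101, 200), (301, 400)]),
    ],
    ALT5: [
        ("T1", [(101, 250), (271, 290), (401, 500)]),
        ("T2", [(101, 200), (401, 500)]),
    ],
    ALT3: [
        ("T1", [(101, 200), (311, 330), (351, 500)]),
        ("T2", [(101, 200), (401, 500)]),
    ],
    ALT_FIRST: [
        ("T1", [(101, 200), (501, 600)]),
        ("T2", [(301, 350), (381, 400), (501, 600)]),
    ],
    ALT_LAST: [
        ("T1", [(101, 200), (301, 340), (361, 420)]),
        ("T2", [(101, 200), (501, 600)]),
    ],
    MUTUALLY_EXCLUSIVE: [
        ("T1", [(101, 200), (301, 340), (361, 420), (701, 800)]),
        ("T2", [(101, 200), (501, 600), (701, 800)]),
    ],
}


def canonical_gene(category: str, gene_id: str, chrom: str,
                   strand: str = "+", perturbed: bool = False) -> GeneModel:
    """One fixture gene embodying a canonical pattern (or its perturbation)."""
    templates = PERTURBED_TEMPLATES if perturbed else CANONICAL_TEMPLATES
    spec = templates[category]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=tuple(
            TranscriptModel(f"{gene_id}.{tid}", tuple(exons))
            for tid, exons in spec
        ),
    )


def canonical_fixture_set(prefix: str = "FIX") -> list[GeneModel]:
    """One gene per canonical category plus one complex gene."""
    return [
        canonical_gene(cat, f"{prefix}_{i:02d}", f"chr{i}")
        for i, cat in enumerate(CATEGORIES, start=1)
    ]


def random_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    max_isoforms: int = 6,
    boundary_jitter: bool = True,
) -> GeneModel:
    """A random multi-isoform gene (exon subsets + boundary variations)."""
    n_exons = int(rng.integers(3, 8))
    lengths = rng.integers(40, 200, size=n_exons)
    gaps = rng.integers(50, 300, size=n_exons)
    exons = []
    pos = 101
    for L, g in zip(lengths, gaps):
        exons.append((pos, pos + int(L) - 1))
        pos += int(L) + int(g)
    k = int(rng.integers(1, max_isoforms + 1))
    seen: set[tuple] = set()
    transcripts = []
    for t in range(k):
        keep = rng.random(n_exons) < 0.6
        if not keep.any():
            keep[rng.integers(n_exons)] = True
        iso = []
        for i in np.flatnonzero(keep):
            s, e = exons[i]
            if boundary_jitter and rng.random() < 0.15:
                delta = int(rng.integers(1, (e - s) // 2 + 1))
                if rng.random() < 0.5:
                    s += delta
                else:
                    e -= delta
            iso.append((s, e))
        key = tuple(iso)
        if key in seen:
            continue
        seen.add(key)
        transcripts.append(TranscriptModel(f"{gene_id}.T{t + 1}", tuple(iso)))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, chrom, strand, tuple(transcripts))


@dataclass
class SimulationConfig:
    """Study conditions for a full synthetic array experiment."""

    n_genes: int = 16
    #: sampling weights over the 8 event categories
    event_mix: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 / len(CATEGORIES) for c in CATEGORIES}
    )
    n_samples: int = 3            # per condition
    design: str = "two-group"     # two-group | paired
    #: (t1, t2) isoform concentrations, condition 1 (reference)
    t_normal: tuple[float, float] = (4.0, 4.0)
    #: (t1, t2) in condition 2 for differential genes; (4, 4) -> (8, 2) is an
    #: opposite-direction change of |log2 FC| = 1 on both isoforms
    t_tumor: tuple[float, float] = (8.0, 2.0)
    differential_fraction: float = 0.5
    #: sd of per-gene log2 expression scale (genes differ in overall level,
    #: which is what the reference-quantile expression filter acts on)
    gene_log2_expression_sd: float = 1.5
    affinity_log_sd: float = 0.25
    noise_sd: float = 0.25
    replicate_log_sd: float = 0.0
    probes_per_exon: int = 10
    probes_per_junction: int = 4
    probe_length: int = 25
    seed: int = 0

    def __post_init__(self):
        total = sum(self.event_mix.values())
        if not np.isclose(total, 1.0):
            self.event_mix = {k: v / total for k, v in self.event_mix.items()}
        if any(t <= 0 for t in self.t_normal + self.t_tumor):
            raise ValueError("isoform concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.design not in ("two-group", "paired"):
            raise ValueError(f"unsupported design {self.design!r}")


def random_genome(
    genes: list[GeneModel], rng: np.random.Generator, margin: int = 100
) -> dict[str, str]:
    """Random nucleotide sequence per chromosome, long enough for its genes."""
    lengths: dict[str, int] = {}
    for g in genes:
        hi = max(t.span[1] for t in g.transcripts) + margin
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), hi)
    return {
        chrom: "".join(rng.choice(NUCLEOTIDES, size=n))
        for chrom, n in sorted(lengths.items())
    }


# ---------------------------------------------------------------------------
# transcriptome + truth

def _true_betas(t_n, t_t):
    b3 = np.log2((t_t[0] + t_t[1]) / (t_n[0] + t_n[1]))
    b34 = np.log2(t_t[0] / t_n[0])
    b345 = np.log2(t_t[1] / t_n[1])
    return b3, b34 - b3, b345 - b34


def generate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Gene models, genome and per-gene ground truth under the config.

    Returns (genes, genome, truth) where truth is a DataFrame with one row
    per gene: its intended category, window, the true per-condition
    concentrations, the implied coefficient values and the differential
    flag/direction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cats = list(config.event_mix)
    weights = np.array([config.event_mix[c] for c in cats])
    genes, rows = [], []
    for i in range(config.n_genes):
        cat = cats[int(rng.choice(len(cats), p=weights))]
        gene_id = f"SYN{i + 1:04d}"
        gene = canonical_gene(cat, gene_id, f"chr{i + 1}")
        genes.append(gene)
        differential = rng.random() < config.differential_fraction
        scale = 2.0 ** rng.normal(0.0, config.gene_log2_expression_sd)
        t_n = tuple(scale * t for t in config.t_normal)
        t_t = tuple(
            scale * t
            for t in (config.t_tumor if differential else config.t_normal)
        )
        b3, b4, b5 = _true_betas(t_n, t_t)
        span = (
            min(t.span[0] for t in gene.transcripts),
            max(t.span[1] for t in gene.transcripts),
        )
        rows.append({
            "gene_id": gene_id,
            "category": cat,
            "chrom": gene.chrom,
            "window_start": span[0],
            "window_end": span[1],
            "t1_normal": t_n[0], "t2_normal": t_n[1],
            "t1_tumor": t_t[0], "t2_tumor": t_t[1],
            "beta3": b3, "beta4": b4, "beta5": b5,
            "differential": differential,
            "direction": (
                "path1_up" if differential and t_t[0] >= t_n[0] else
                "path1_down" if differential else "none"
            ),
        })
    truth = pd.DataFrame(rows)
    genome = random_genome(genes, rng)
    return genes, genome, truth


# ---------------------------------------------------------------------------
# probes

def generate_probes(
    graphs: dict[str, ExtendedSplicingGraph],
    genome: dict[str, str],
    rng: np.random.Generator,
    probes_per_exon: int = 10,
    probes_per_junction: int = 4,
    probe_length: int = 25,
    dropout_edges: set[tuple[str, tuple[str, str]]] | None = None,
    decoy_gene_sets: list[list[str]] | None = None,
) -> list[ProbeRecord]:
    """Cut probe sequences from the synthetic genome along graph edges.

    Exon probes lie wholly inside a subexon; junction probes straddle the
    boundary with at least 6 nt on each side.  ``dropout_edges`` names
    (gene_id, edge-key) pairs that get no probes (to exercise pruning and
    unmeasurable events).  Each entry of ``decoy_gene_sets`` plants one
    shared sequence into every listed gene and emits a probe for it, to
    exercise the multimapping filter.
    """
    dropout_edges = dropout_edges or set()
    probes: list[ProbeRecord] = []

    if decoy_gene_sets:
        for di, gene_ids in enumerate(decoy_gene_sets):
            seq = "".join(rng.choice(NUCLEOTIDES, size=probe_length))
            for gene_id in gene_ids:
                graph = graphs[gene_id]
                target = next(
                    s for s in sorted(graph.subexons.values(),
                                      key=lambda s: s.interval)
                    if s.length >= probe_length
                )
                chrom = graph.chrom
                s0 = target.start - 1
                genome[chrom] = (genome[chrom][:s0] + seq
                                 + genome[chrom][s0 + probe_length:])
            probes.append(ProbeRecord(f"DECOY{di + 1:03d}", sequence=seq))

    for gene_id in sorted(graphs):
        graph = graphs[gene_id]
        chrom_seq = genome[graph.chrom]
        counter = 0
        for e in sorted(graph.edges(), key=lambda e: (e.source, e.target)):
            if (gene_id, e.key) in dropout_edges:
                continue
            if e.kind == "exon":
                s, t = e.span
                L = t - s + 1
                n_pos = L - probe_length + 1
                if n_pos < 1:
                    logger.warning("subexon %s-%s shorter than probe; no "
                                   "probes", e.source, e.target)
                    continue
                n = min(probes_per_exon, n_pos)
                offsets = sorted(rng.choice(n_pos, size=n, replace=False))
                for off in offsets:
                    counter += 1
                    start = s + int(off)
                    probes.append(ProbeRecord(
                        f"{gene_id}_p{counter:04d}",
                        sequence=chrom_seq[start - 1:start - 1 + probe_length],
                    ))
            elif e.kind in ("junction", "adjacency"):
                tid = sorted(e.isoform_set)[0]
                seq, pos_map = _spliced(graph, tid, genome)
                boundary_pos = graph.subexon_of_node(e.source).end
                b = pos_map.index(boundary_pos)
                lo = max(0, b - (probe_length - 7))
                hi = min(len(seq) - probe_length, b - 5)
                if hi < lo:
                    logger.warning("junction %s-%s too close to transcript "
                                   "end; no probes", e.source, e.target)
                    continue
                n = min(probes_per_junction, hi - lo + 1)
                offsets = sorted(rng.choice(hi - lo + 1, size=n,
                                            replace=False))
                for off in offsets:
                    counter += 1
                    p = lo + int(off)
                    probes.append(ProbeRecord(
                        f"{gene_id}_p{counter:04d}",
                        sequence=seq[p:p + probe_length],
                    ))
    return probes


def _spliced(graph, tid, genome):
    from .probe_map import spliced_sequence
    return spliced_sequence(graph, tid, genome)


# ---------------------------------------------------------------------------
# signals

def simulate_signals(
    probes: list[ProbeRecord],
    graphs: dict[str, ExtendedSplicingGraph],
    hits: ProbeHits,
    concentrations: dict[str, dict[str, tuple[float, float]]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Probe x sample log2 signal matrix under the measurement model.

    ``concentrations`` maps gene -> transcript -> (condition-1, condition-2)
    concentration.  A probe's expected signal is log2 of its affinity times
    the summed concentration of every isoform it interrogates (across all
    genes it hits); Gaussian noise of sd ``noise_sd`` is added.  Optional
    per-sample log-normal jitter of the concentrations models biological
    replicate variability.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples
    sample_ids = [f"C1_{j + 1}" for j in range(n)] + \
                 [f"C2_{j + 1}" for j in range(n)]
    cond = np.array([0] * n + [1] * n)

    probe_ids = [p.probe_id for p in probes if p.probe_id in hits]
    log_affinity = rng.normal(0.0, config.affinity_log_sd,
                              size=len(probe_ids))
    jitter: dict[tuple[str, int], float] = {}

    values = np.empty((len(probe_ids), 2 * n))
    for i, pid in enumerate(probe_ids):
        iso: set[tuple[str, str]] = set()
        for gene_id, key in hits[pid]:
            for t in graphs[gene_id].edge(*key).isoform_set:
                iso.add((gene_id, t))
        for j, c in enumerate(cond):
            tau = 0.0
            for gene_id, t in iso:
                base = concentrations[gene_id][t][c]
                if config.replicate_log_sd > 0:
                    k = (f"{gene_id}.{t}", j)
                    if k not in jitter:
                        jitter[k] = rng.normal(0.0, config.replicate_log_sd)
                    base = base * 2.0 ** jitter[k]
                tau += base
            values[i, j] = log_affinity[i] + np.log2(tau)
    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    return pd.DataFrame(values, index=probe_ids, columns=sample_ids)


# ---------------------------------------------------------------------------
# designs

def two_group_design(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + condition-increment design and its single contrast."""
    D = np.column_stack([np.ones(n1 + n2),
                         np.r_[np.zeros(n1), np.ones(n2)]])
    C = np.array([[0.0, 1.0]])
    return D, C


def paired_design(n_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Condition effect with per-subject blocking columns."""
    n = 2 * n_pairs
    D = np.zeros((n, 1 + n_pairs))
    D[:, 0] = np.r_[np.zeros(n_pairs), np.ones(n_pairs)]  # condition
    for s in range(n_pairs):
        D[s, 1 + s] = 1.0
        D[n_pairs + s, 1 + s] = 1.0
    C = np.zeros((1, 1 + n_pairs))
    C[0, 0] = 1.0
    return D, C


# ---------------------------------------------------------------------------
# whole-dataset convenience and direct event-block simulation

@dataclass
class SyntheticDataset:
    """Everything one experiment needs, generated under one seed."""

    config: SimulationConfig
    genes: list[GeneModel]
    genome: dict[str, str]
    graphs: dict[str, ExtendedSplicingGraph]
    probes: list[ProbeRecord]
    hits: ProbeHits
    signals: pd.DataFrame
    design: np.ndarray
    contrast: np.ndarray
    truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full pipeline input set: transcriptome, probes, mapping and signals."""
    rng = np.random.default_rng(config.seed)
    genes, genome, truth = generate_transcriptome(config, rng)
    graphs = {g.gene_id: build_extended_graph(g) for g in genes}
    probes = generate_probes(
        graphs, genome, rng,
        probes_per_exon=config.probes_per_exon,
        probes_per_junction=config.probes_per_junction,
        probe_length=config.probe_length,
    )
    hits = map_probes(probes, graphs, genome)
    concentrations = {
        row.gene_id: {
            f"{row.gene_id}.T1": (row.t1_normal, row.t1_tumor),
            f"{row.gene_id}.T2": (row.t2_normal, row.t2_tumor),
        }
        for row in truth.itertuples(index=False)
    }
    signals = simulate_signals(probes, graphs, hits, concentrations, config,
                               rng)
    if config.design == "two-group":
        D, C = two_group_design(config.n_samples, config.n_samples)
    else:
        D, C = paired_design(config.n_samples)
    return SyntheticDataset(config, genes, genome, graphs, probes, hits,
                            signals, D, C, truth)


def simulate_event_blocks(
    n_events: int,
    rng: np.random.Generator,
    n_per_cond: tuple[int, int] = (3, 3),
    t_normal: tuple[float, float] = (4.0, 4.0),
    t_tumor: tuple[float, float] = (4.0, 4.0),
    probes_per_path: int = 4,
    noise_sd: float = 0.25,
    affinity_log_sd: float = 0.25,
):
    """Probe-level signal blocks for many events, without a transcriptome.

    Direct simulation of the measurement model at the event level: every
    event has three probesets (Ref measuring t1 + t2, P1 measuring t1, P2
    measuring t2), each with ``probes_per_path`` probes of log-normal
    affinity.  Used for large-scale calibration and power studies of the
    statistics stage.  Returns (signals, probeset map, design, contrast).
    """
    from .probe_map import ProbesetMap

    n1, n2 = n_per_cond
    n_samples = n1 + n2
    cond = np.r_[np.zeros(n1, dtype=int), np.ones(n2, dtype=int)]
    sample_ids = [f"C1_{j + 1}" for j in range(n1)] + \
                 [f"C2_{j + 1}" for j in range(n2)]
    conc = np.array([
        [t_normal[0] + t_normal[1], t_tumor[0] + t_tumor[1]],  # Ref
        [t_normal[0], t_tumor[0]],                             # P1
        [t_normal[1], t_tumor[1]],                             # P2
    ])
    n_probes = 3 * probes_per_path
    log_mu = np.log2(conc)[:, cond]                 # (3, n_samples)
    mu = np.repeat(log_mu, probes_per_path, axis=0)  # (n_probes, n_samples)
    affin = rng.normal(0.0, affinity_log_sd, size=(n_events, n_probes))
    noise = rng.normal(0.0, noise_sd,
                       size=(n_events, n_probes, n_samples))
    values = mu[None, :, :] + affin[:, :, None] + noise
    probe_ids, map_rows = [], []
    for ev in range(n_events):
        event_id = f"EV{ev + 1:06d}"
        for path in ("Ref", "P1", "P2"):
            for p in range(probes_per_path):
                pid = f"{event_id}_{path}_{p + 1}"
                probe_ids.append(pid)
                map_rows.append((event_id, path, pid))
    signals = pd.DataFrame(values.reshape(-1, n_samples), index=probe_ids,
                           columns=sample_ids)
    pmap = ProbesetMap(
        table=pd.DataFrame(map_rows,
                           columns=["event_id", "path", "probe_id"]),
        unmeasurable=set(),
    )
    D, C = two_group_design(n1, n2)
    return signals, pmap, D, C
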