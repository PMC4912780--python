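"""Annotate event paths with protein domains and test differential usage.

Five cassette-exon genes carry a domain on the skippable exon (so the
domain marks only the inclusion path) and a second domain on a
constitutive flanking exon (marking both paths, hence non-informative).
A paired signed-rank test asks whether domain-bearing paths are
systematically over- or under-used across the significant events.
"""

import pandas as pd

import splicevents as sv

genes, events = [], []
for i in range(1, 6):
    g = sv.canonical_gene("cassette exon", f"G{i}", f"chr{i}")
    genes.append(g)
    events.extend(sv.detect_events(sv.build_extended_graph(g)))

# transcript-relative coordinates: on T1 positions 101-200 are the
# cassette exon, 1-100 the shared upstream exon
rows = []
for i in range(1, 6):
    rows.append((f"G{i}.T1", "KINASE", 120, 180))     # on the cassette exon
    rows.append((f"G{i}.T1", "SCAFFOLD", 10, 90))     # constitutive
    rows.append((f"G{i}.T2", "SCAFFOLD", 10, 90))
domain_table = pd.DataFrame(rows, columns=["transcript_id", "domain_id",
                                           "start", "end"])

# per-event fitted isoform log fold changes (inclusion up, skip down)
stats = pd.DataFrame({
    "event_id": [e.event_id for e in events],
    "logFC_path1": [1.2, 0.9, 1.5, 0.8, 1.1],
    "logFC_path2": [-1.0, -0.7, -1.3, -0.9, -1.2],
})

matrix = sv.annotate_paths(events, domain_table,
                           {g.gene_id: g for g in genes})
enrichment = sv.enrich_domains(matrix, stats, p_max=None,
                               expressed_only=False)
print(enrichment.to_string(index=False))
print()
print("KINASE marks only the inclusion paths, all of which go up: it is")
print("over-used (one-sided signed-rank p = 1/2^5).  SCAFFOLD marks both")
print("paths of every event, is never informative, and is not reported.")
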