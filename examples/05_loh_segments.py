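"""LOH segmentation and cross-lineage sharing.

Two lineages evolved from the same parent: tracts that overlap between
lineages (same retained haplotype over the same region) surface as shared
segments, the pattern seen when independent lines converge on the same
chromosomal region.
"""

from alemut.classify import classify_strain
from alemut.loh import segment_loh, shared_segments, segments_to_frame
from alemut.simulate import SimulationConfig, evolve_lineage, make_parent, make_reference

cfg = SimulationConfig(n_contigs=1, contig_length=100_000, n_cds_per_contig=10,
                       n_loh_tracts=2, tract_length_mean=20_000, n_de_novo=3.0,
                       n_cnv_events_mean=0.0,
                       n_lineages=1, group_sizes=(1,), group_names=("A",))
ref, _ = make_reference(cfg, seed=14)
parent = make_parent(ref, cfg.het_density, seed=15)
lengths = {c: ref.length(c) for c in ref.contigs}

all_segments = []
for sid, seed in (("EV_a", 16), ("EV_b", 18)):
    evolved, truth = evolve_lineage(parent, ref, cfg, seed=seed, strain_id=sid)
    calls = classify_strain(parent, evolved, ref)
    segs = segment_loh(calls, sid, max_gap=25_000, min_sites=3,
                       contig_lengths=lengths)
    all_segments.extend(segs)

print(segments_to_frame(all_segments).to_string(index=False))

shared = shared_segments(all_segments, min_reciprocal_overlap=0.5)
print(f"\n{len(shared)} shared segment group(s):")
for s in shared:
    print(f"  {s.contig}:{s.start}-{s.end} shared by {', '.join(s.strains)}")
print("\nSegment bounds are the outermost supporting LOH calls; reversion "
      "calls count\nas support even though they left no record in the "
      "evolved VCFs.")
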