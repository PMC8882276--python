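"""Protein-level effect annotation: missense, nonsense, and frameshift.

Uses a 4-codon toy ORF (ATG CAT TGG TAA -> MHW*) and a longer random ORF to
show substitution notation, truncation calls, and the frameshift tail
description (novel residues until the new stop + wild-type residues lost).
"""

from alemut import CDSFeature, ReferenceGenome
from alemut.effects import GenomicEdit, annotate_effect
from alemut.simulate import SimulationConfig, make_reference

toy = ReferenceGenome(contigs={"chrA": "ATGCATTGGTAAACGTACGT"})
cds = CDSFeature("TOY1", "chrA", 1, 12, "+")

for label, edit in [
    ("CAT->CAA", GenomicEdit("chrA", 6, "T", "A")),
    ("TGG->TGA", GenomicEdit("chrA", 9, "G", "A")),
]:
    e = annotate_effect(cds, toy, [edit])
    print(f"{label}: {e.effect} {e.notation} (conservation: {e.conservation})")

# a 4-bp deletion early in a 100-codon ORF shifts the frame
cfg = SimulationConfig(n_contigs=1, contig_length=3_000, n_cds_per_contig=1,
                       cds_codon_min=100, cds_codon_max=100,
                       n_lineages=1, group_sizes=(1,), group_names=("A",))
genome, (orf,) = make_reference(cfg, seed=8)
anchor = orf.start + 2
ref = genome.slice(orf.contig, anchor, anchor + 4)
e = annotate_effect(orf, genome, [GenomicEdit(orf.contig, anchor, ref, ref[0])])
print(f"\n4-bp deletion in a 100-codon ORF: {e.effect} at residue "
      f"{e.protein_pos}; {e.n_altered_tail} novel residues to the new stop, "
      f"{e.n_truncated} wild-type residues truncated.")
print("\nNotation follows the compact clone-report convention: H2Q means "
      "His2->Gln;\nW3* a stop at Trp3; fs@N a frameshift starting at "
      "residue N.")
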