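"""Classify parent-vs-evolved differences as new variants or LOH.

Builds a five-site example by hand: an LOH to the alternate allele, an LOH
reversion (evolved record absent -> imputed hom-ref), a heterozygous de novo
SNV, a homozygous de novo at a parent-het site, and a 1-bp deletion.
"""

from alemut import DiploidGenotype, GenotypeTable, ReferenceGenome, SiteRecord
from alemut.classify import classify_strain, calls_to_frame

genome = ReferenceGenome(contigs={"chrI": "ACGTACGTACGTACGTACGTACGT" * 10})

parent = GenotypeTable("parent", [
    SiteRecord("chrI", 10, "G", DiploidGenotype.of("G", "A")),   # het
    SiteRecord("chrI", 50, "A", DiploidGenotype.of("A", "T")),   # het
    SiteRecord("chrI", 90, "C", DiploidGenotype.of("C", "G")),   # het
])
evolved = GenotypeTable("EV1", [
    SiteRecord("chrI", 10, "G", DiploidGenotype.hom("A")),       # LOH to alt
    # site 50 absent: homozygosed back to reference (reversion)
    SiteRecord("chrI", 90, "C", DiploidGenotype.of("C", "G")),   # unchanged
    SiteRecord("chrI", 130, "T", DiploidGenotype.of("T", "G")),  # de novo het
    SiteRecord("chrI", 170, "AC", DiploidGenotype.hom("A")),     # hom 1-bp del
])

calls = classify_strain(parent, evolved, genome)
print(calls_to_frame(calls).to_string(index=False))

n_loh = sum(c.category == "loh" for c in calls)
n_rev = sum(bool(c.is_reversion) for c in calls if c.category == "loh")
print(f"\n{len(calls)} differences: {n_loh} LOH ({n_rev} reversion), "
      f"{len(calls) - n_loh} new variants.")
print("The unchanged het site at chrI:90 is dropped; the reversion at "
      "chrI:50 is only\nfound because the parent table supplies the site "
      "universe.")
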