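# alemut

Mutation analysis for adaptively evolved diploid yeast cohorts.

When an industrial *Saccharomyces cerevisiae* strain — diploid and highly
heterozygous — is put through adaptive laboratory evolution, the genomes of
the evolved isolates differ from the parent in two fundamentally different
ways. A site can acquire a **new (de novo) variant**: an allele present in
neither parental haplotype. Or a parent-heterozygous site can undergo
**loss of heterozygosity (LOH)**: mitotic recombination homozygoses a whole
chromosomal tract onto one of the two parental haplotypes. When the retained
haplotype is the reference one, the event is a **reversion** — the evolved
genotype is indistinguishable from wild type at that site, so it leaves no
record in the evolved strain's own variant calls and is only recoverable by
a parent-aware comparison. In evolved diploid cohorts LOH sites typically
outnumber de novo variants by an order of magnitude, with roughly half of
the LOH sites reverting to the reference allele.

`alemut` turns per-strain diploid genotype tables (single-sample VCF), a
reference FASTA, CDS features (GFF3) and per-base depth tracks into:

- **classification** — every parent-vs-evolved difference labelled
  `new_variant` or `loh` with zygosity and reversion subtyping, over the
  *union* of both tables' sites (absent sites are imputed homozygous
  reference, which is what makes reversions visible);
- **effect annotation** — protein-level consequences of coding variants
  under the standard genetic code: missense (`H2Q`), nonsense (`W3*`),
  frameshift (`fs@2` with the count of novel tail residues and of wild-type
  residues truncated), in-frame indels, synonymous; conservative vs
  non-conservative substitutions by BLOSUM62 sign;
- **LOH segmentation** — clustering of LOH calls into chromosomal segments
  (linear scan, gap threshold), with cross-strain shared-segment detection
  and hitchhiker flagging of de novo variants inside segments;
- **copy number** — per-position adjusted copy number
  `c_i = 2 · d_i / median(d)` (the genome-wide median is pinned at exactly
  2), per-gene integer copies by median + round-half-up, and gene-run /
  whole-chromosome gain-loss events; WIG fixedStep export;
- **cohort accounting** — per-strain new-vs-LOH tallies, group rows as
  unions of member strains' mutation keys (site + resulting genotype), a
  shared-between-groups row, per-contig-class column blocks with
  all / amino-acid-changing / genes-with-AA-changes counts, Venn partitions
  and recurrently mutated genes;
- **a synthetic diploid-evolution generator** — heterozygous parent, evolved
  lineages with planted LOH tracts, de novo SNVs/indels, CNV events,
  Poisson depth tracks and machine-readable truth sets, so every stage is
  testable end to end without external data.

## Worked example

```python
from alemut import (DiploidGenotype, GenotypeTable, ReferenceGenome,
                    SiteRecord)
from alemut.classify import classify_strain

genome = ReferenceGenome(contigs={"chrI": "ACGTACGTACGTACGTACGTACGT" * 10})
parent = GenotypeTable("parent", [
    SiteRecord("chrI", 10, "G", DiploidGenotype.of("G", "A")),
    SiteRecord("chrI", 50, "A", DiploidGenotype.of("A", "T")),
])
evolved = GenotypeTable("EV1", [
    SiteRecord("chrI", 10, "G", DiploidGenotype.hom("A")),
    # site 50 is absent: homozygosed back to the reference allele
    SiteRecord("chrI", 130, "T", DiploidGenotype.of("T", "G")),
])
for c in classify_strain(parent, evolved, genome):
    print(c.pos, c.category, c.zygosity,
          "reversion" if c.is_reversion else "")
```

prints

```
10 loh hom
50 loh hom reversion
130 new_variant het
```

i.e. the het site at 10 was homozygosed to the alternate allele, the het
site at 50 reverted to wild type (found only because the parent supplies the
site universe), and 130 carries a de novo heterozygous variant. The
`examples/` directory has one narrative script per capability (simulation,
classification, effect annotation, copy number, LOH segmentation, cohort
summary); each prints the numbers it computes and a line on what they mean.

A full run over an on-disk cohort is one call (or `alemut run` from the
shell):

```python
from alemut import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig.from_cohort_dir("cohort/", "results/"))
print(res["summary"])       # cohort accounting table
print(res["per_strain"])    # new-vs-LOH tallies per strain
```

## Command-line interface

`alemut` exposes thin subcommands over the library: `simulate`, `classify`,
`annotate`, `loh`, `cnv`, `summarize`, `run`. Every subcommand exits
non-zero with a one-line diagnostic on malformed input. See
`alemut --help`.
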