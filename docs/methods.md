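# Methods

## The comparison model

The pipeline operates on unphased diploid genotype tables, one per strain,
anchored to a common reference: records are `(contig, pos, ref, {a1, a2})`
with VCF-style anchored indels. Parent and evolved tables are compared over
the **union** of their sites; a site absent from one table is imputed
homozygous-reference there. This imputation is not a convenience but the
core of the method: an LOH event that retains the reference haplotype (a
*reversion*) produces an evolved genotype identical to wild type, which no
variant caller will report for the evolved strain alone. Only the parent
table, acting as the site universe, makes reversions observable. Sites with
identical genotypes on both sides are dropped (and counted in the log).

Classification of each differing site is a two-rule decision applied in
order, total over all valid inputs:

1. if the evolved genotype contains any allele absent from the parent's two
   alleles, the site is a **new variant** (heterozygous if one copy is
   novel, homozygous if both);
2. otherwise the evolved alleles are a strict sub-multiset of the parent's,
   which forces a heterozygous parent homozygosed to one of its alleles:
   **LOH**, a reversion iff the retained allele equals the reference.

A parent-*homozygous* site that became homozygous for a different allele is
a homozygous new variant, never LOH — loss of heterozygosity presupposes
heterozygosity. Sites are the counting unit throughout (one SNP or indel =
one mutation); a per-allele count would differ only at multi-allelic sites.
Indel records are minimally left-normalized on read (shared suffix then
prefix trimming, keeping the anchor base) so equivalent spellings from
different callers compare equal; full reference-window left-shifting is not
performed because the readers deliberately do not require the reference
sequence.

## Effect annotation

For each CDS the strand-corrected wild-type and mutant coding sequences are
translated with the standard nuclear genetic code (translation stops at the
first stop codon) and the effect is read off the protein diff:

- equal proteins → synonymous; a single-residue substitution → missense,
  notated `H2Q` from the first differing residue;
- a premature stop with unchanged frame → nonsense, notated `W3*` with the
  truncation position;
- a net indel length not divisible by 3 → frameshift, notated `fs@p` with
  two counts: the novel residues from the first altered position to the new
  stop, and the wild-type residues lost off the end (clamped at zero when
  the shifted frame extends the protein); a frameshift whose new frame
  reaches the end of the CDS window without a stop is flagged
  `stop_not_found`;
- codon-multiple indels → in-frame indel; loss of the terminal stop →
  stop-lost.

Edits are applied jointly, right-to-left in genomic coordinates, so indels
do not shift the coordinates of edits upstream of them and two substitutions
in one codon produce the doubly-edited codon. Per-call annotation (each
variant applied alone) is the default for per-mutation accounting; joint
annotation of all of a strain's edits in one CDS is available where
co-occurring edits interact. Heterozygous variants are annotated on the
edited haplotype; zygosity is carried as metadata, not used to suppress
effects. LOH reversions carry no edit relative to the reference and
annotate as no protein change. Variants straddling a CDS boundary are
clipped to the CDS and flagged. Substitutions are called conservative iff
their BLOSUM62 score is positive — a repository convention chosen because it
reproduces the usual field judgements (H→Q scores 0 and P→T scores −1, both
non-conservative; I→V scores +3, conservative).

## LOH segmentation

A single linear scan per contig joins consecutive LOH calls separated by at
most `max_gap` (default 25 kb); clusters of at least `min_sites` (default 3)
calls become segments bounded by their outermost supporting calls. At the
default heterozygosity of one site per 300 bp these settings detect tracts
of a few kb and up; both knobs are exposed because real segment boundaries
in published figures are typically drawn manually. Bounds are *not*
extended to midpoints between flanking het sites — conservative and exactly
reproducible. Reversion calls support segments like any other LOH call.
Segments sharing a reciprocal overlap of at least `min_reciprocal_overlap`
(default 0.5) across strains are linked; connected components with two or
more strains are reported with their intersection interval. De novo calls
inside a strain's segments are flagged as potential hitchhikers (positional
flag only; no selection inference).

## Copy number

Per-position depth is converted to approximate copy number
`c_i = 2·d_i / m` with `m` the **genome-wide** median depth of the sample
(per-contig normalization would erase whole-chromosome aneuploidies). By
construction the genome-wide median of `c` is exactly 2, and the profile is
invariant to scaling all depths by a constant. Gene-level copy is the
median of `c` over the gene span, rounded half-up, with loss/gain calls
against a configurable baseline ploidy of 2. A whole-contig event is called
when ≥ 80% of a contig's genes (contigs with ≥ 5 genes) share the same
non-neutral call; otherwise maximal runs of ≥ 3 consecutive same-call genes
are reported as partial events. An optional non-overlapping window-median
smoothing (default window 1 kb) is available for WIG export and plotting;
it is off for all quantitative outputs so the median-2 identity and the
per-gene medians are computed on raw normalized values. The method assumes
a mostly-diploid genome: if the majority of positions are aneuploid the
median anchor itself shifts.

## The synthetic-data generator

The generator emulates the genomic structure of a small adaptively evolved
diploid industrial-yeast cohort; its defaults are the package's study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_contigs`, `contig_length` | 3 × 100 kb | genome size (down-scaled from the ~12 Mb yeast genome for desk-scale runs) |
| `n_cds_per_contig` | 40 (60–180 codons) | gene density (~14% coding; real yeast is denser, which only raises the coding fraction of calls) |
| `het_density` | 1/300 bp | parent heterozygosity, industrial-strain-like |
| `n_loh_tracts`, `tract_length_mean` | 6, 10 kb (geometric) | ~200 LOH sites per lineage |
| `p_retain_reference` | 0.5 | reversion probability per tract |
| `n_de_novo` | Poisson(18) | de novo load; with ~200 LOH sites this puts the expected new-variant fraction near 8% |
| `snv_indel_ratio`, `p_de_novo_hom` | 4:1, 0.2 | de novo composition |
| CNV events | Poisson(1)/lineage, half whole-chromosome, Δ ∈ {−1,+1,+2} | depth-only copy changes |
| `mean_depth` | 50× | per-position Poisson depth |
| `n_lineages`, groups | 11 = 5 + 6 | two media groups |

LOH is modelled as gene-conversion-like tract homozygosis without copy
change; each tract independently retains the reference homolog with
probability `p_retain_reference`, turning its covered parent-het sites
hom-ref (dropped from the evolved table, recorded in the truth set) or
hom-alt. Chromosome-loss LOH can be emulated by pairing a terminal tract
with a −1 CNV event. Parent heterozygous sites are SNVs; indels enter
through de novo events (short, ≤ 4 bp, placed at fresh non-overlapping
positions). The tract-length distribution is geometric — a modelling
choice, parameterized in the config, since real tract lengths are not well
characterized. Depth is per-base Poisson, independent across positions;
read-level artefacts (GC bias, mappability, overdispersion) are not
simulated. Consequently, passing recovery tests demonstrate correctness of
the classification/segmentation/normalization logic on clean genotypes and
Poisson depth — not robustness to caller noise, alignment artefacts or
repeat regions, which real data add on top. All outputs are pure functions
of `(config, seed)`; cohorts regenerate bit-identically (SHA-256 manifest).

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere (VCF/GFF/WIG); BED export is
  0-based half-open.
- Mutation identity for cross-strain set operations is site **plus**
  resulting evolved genotype, so "the same heterozygous SNP in seven
  strains" is distinguishable from different mutations at one site;
  gene-level sharing uses gene ids only. Group rows of the cohort table are
  unions of member strains' keys — required for the inclusion–exclusion
  identity |overall| = |A| + |B| − |A∩B| to hold.
- Contig provenance classes (species reference / integrated pathway
  sequence / strain-private ORFs) are metadata supplied by a side manifest,
  defaulting to `reference`; the three column blocks of the cohort table
  are disjoint.
- Printed percentages round half-away-from-zero at the requested precision
  (`188/2255 → "8.3%"`).
- Integer copies round half-up; `round()`-style banker's rounding would
  bias 2.5 downward.
- Sites inside CNV regions are still classified under the diploid genotype
  model; ploidy-aware genotype calling is out of scope.
- Acceptance-scale runs use the default 3 × 100 kb / 11-lineage cohort, a
  deliberate down-scaling that keeps every stage exercised end to end while
  the whole suite runs in seconds.

## Known limitations

- No statistical changepoint segmentation (HMM/CBS) for LOH or CNV; the
  gap-join and gene-run rules are simple and fully reproducible instead.
- No read-level simulation or re-calling: the pipeline starts from genotype
  tables and assumes upstream calling/filtering has been done.
- Breakpoints are resolved only to the outermost supporting sites (LOH) or
  gene spans (CNV).
- Effect annotation covers CDS consequences only — no splice, UTR or
  regulatory effects, and no protein-structure inference.
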