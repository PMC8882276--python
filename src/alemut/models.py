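"""Core data model for diploid parent-vs-evolved mutation analysis.

Coordinates are 1-based inclusive everywhere (VCF/GFF/WIG convention).
Indel alleles use the VCF anchored representation: the first base of both
the reference and alternate allele is the base at ``pos``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

VALID_BASES = frozenset("ACGTN")

#: The three provenance classes of a contig in an engineered industrial strain:
#: the species reference, plasmid sequence integrated during engineering, and
#: ORFs private to the industrial parent (absent from the species reference).
CONTIG_CLASSES = ("reference", "inserted_pathway", "strain_specific")


class GenomeIOError(ValueError):
    """Malformed on-disk input (FASTA/GFF/VCF/WIG/TSV)."""


# ---------------------------------------------------------------------------
# reference genome and gene models
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """Ordered contig sequences plus a provenance class per contig.

    Parameters
    ----------
    contigs:
        Ordered mapping contig id -> upper-case nucleotide sequence.
    contig_class:
        Mapping contig id -> one of :data:`CONTIG_CLASSES`. Missing entries
        default to ``"reference"``.
    """

    contigs: dict[str, str]
    contig_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise GenomeIOError("genome has no contigs")
        for cid, seq in self.contigs.items():
            if not seq:
                raise GenomeIOError(f"contig {cid!r} has an empty sequence")
        for cid in list(self.contig_class):
            cls = self.contig_class[cid]
            if cls not in CONTIG_CLASSES:
                raise GenomeIOError(f"unknown contig class {cls!r} for {cid!r}")
        for cid in self.contigs:
            self.contig_class.setdefault(cid, "reference")

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def base(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        return self.contigs[contig][start - 1 : end]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class CDSFeature:
    """A protein-coding interval on a contig (forward-strand coordinates).

    ``start``/``end`` are 1-based inclusive; ``strand`` is ``"+"`` or ``"-"``.
    The strand-corrected sequence is expected to begin with ATG and end with a
    stop codon; readers only warn when that fails (``length_ok`` records
    whether the span length is a codon multiple).
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    phase: int = 0
    length_ok: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.gene_id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiploidGenotype:
    """An unphased pair of alleles; stored sorted so {A,G} == {G,A}."""

    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("diploid genotype needs exactly two alleles")
        a, b = self.alleles
        for al in (a, b):
            if not al or not set(al) <= VALID_BASES:
                raise ValueError(f"bad allele {al!r}")
        if a > b:
            object.__setattr__(self, "alleles", (b, a))

    @classmethod
    def of(cls, a: str, b: str) -> "DiploidGenotype":
        return cls((a, b))

    @classmethod
    def hom(cls, allele: str) -> "DiploidGenotype":
        return cls((allele, allele))

    @property
    def is_hom(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    @property
    def is_het(self) -> bool:
        return not self.is_hom

    def __iter__(self) -> Iterator[str]:
        return iter(self.alleles)

    def __contains__(self, allele: str) -> bool:
        return allele in self.alleles


@dataclass(frozen=True)
class SiteRecord:
    """One variable site of a strain: anchored ref allele plus genotype."""

    contig: str
    pos: int
    ref: str
    genotype: DiploidGenotype

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based")
        if not self.ref or not set(self.ref) <= VALID_BASES:
            raise ValueError(f"bad ref allele {self.ref!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)


@dataclass
class GenotypeTable:
    """Per-strain diploid genotypes at variable sites, sorted and unique.

    Every allele of every genotype is either the site's ref allele or one of
    its alternates; records are sorted by (contig, pos) with at most one
    record per site.
    """

    strain_id: str
    records: list[SiteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.contig, r.pos))
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(
                    f"{self.strain_id}: duplicate record at {rec.contig}:{rec.pos}"
                )
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SiteRecord]:
        return iter(self.records)

    def sites(self) -> dict[tuple[str, int], SiteRecord]:
        return {rec.key: rec for rec in self.records}

    def with_records(self, records: Iterable[SiteRecord]) -> "GenotypeTable":
        return GenotypeTable(self.strain_id, list(records))


# ---------------------------------------------------------------------------
# depth and copy number
# ---------------------------------------------------------------------------


@dataclass
class DepthTrack:
    """Dense per-position integer sequencing depth, one array per contig.

    Arrays are 0-indexed internally; index ``i`` holds the depth of the
    1-based position ``i + 1``.
    """

    depths: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for cid, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"depth track for {cid!r} must be a non-empty vector")
            if np.any(arr < 0):
                raise ValueError(f"negative depth on {cid!r}")
            self.depths[cid] = arr.astype(np.int64)

    def validate_against(self, genome: ReferenceGenome) -> None:
        for cid, arr in self.depths.items():
            if len(arr) != genome.length(cid):
                raise ValueError(
                    f"depth track for {cid!r} has {len(arr)} positions, "
                    f"contig length is {genome.length(cid)}"
                )


@dataclass(frozen=True)
class GeneCopyNumber:
    """Per-gene copy-number summary: median adjusted copy over the gene span,
    its rounded integer, and a gain/loss/neutral call vs baseline ploidy."""

    gene_id: str
    contig: str
    start: int
    end: int
    median_copy: float
    integer_copy: int
    call: str  # loss | neutral | gain


@dataclass
class CopyNumberProfile:
    """Median-normalised per-position copy number c_i = 2 * d_i / median(d),
    where the median is taken genome-wide over all positions of the sample."""

    values: dict[str, np.ndarray]
    median_depth: float
    genes: list[GeneCopyNumber] = field(default_factory=list)

    def genome_wide_median(self) -> float:
        return float(np.median(np.concatenate(list(self.values.values()))))


# ---------------------------------------------------------------------------
# classified mutation calls
# ---------------------------------------------------------------------------

NEW_VARIANT = "new_variant"
LOH = "loh"


@dataclass(frozen=True)
class SiteComparison:
    """A site where parent and evolved genotypes differ (as allele multisets)."""

    contig: str
    pos: int
    ref: str
    parent: DiploidGenotype
    evolved: DiploidGenotype

    def __post_init__(self) -> None:
        if self.parent == self.evolved:
            raise ValueError(
                f"{self.contig}:{self.pos}: identical genotypes are filtered upstream"
            )


@dataclass(frozen=True)
class MutationCall:
    """A classified parent-vs-evolved difference at one site.

    ``category`` is ``new_variant`` when the evolved strain carries an allele
    absent from both parental haplotypes, else ``loh`` (a parent-heterozygous
    site homozygosed to one of its two alleles). ``is_reversion`` is defined
    for LOH only and marks the retained allele equalling the reference
    allele — the evolved genotype is then indistinguishable from wild type.
    """

    contig: str
    pos: int
    ref: str
    category: str
    zygosity: str  # het | hom
    parent: DiploidGenotype
    evolved: DiploidGenotype
    variant_kind: str  # snp | indel
    contig_class: str = "reference"
    is_reversion: bool | None = None
    novel_alleles: tuple[str, ...] = ()
    retained_allele: str | None = None

    def __post_init__(self) -> None:
        if self.category not in (NEW_VARIANT, LOH):
            raise ValueError(f"bad category {self.category!r}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")
        if self.category == NEW_VARIANT:
            if not self.novel_alleles:
                raise ValueError("new_variant call without novel alleles")
            if self.is_reversion is not None:
                raise ValueError("is_reversion is defined for LOH calls only")
        else:
            if self.novel_alleles:
                raise ValueError("LOH call cannot carry novel alleles")
            if self.is_reversion is None or self.retained_allele is None:
                raise ValueError("LOH call needs is_reversion and retained_allele")

    @property
    def key(self) -> "MutationKey":
        return MutationKey(self.contig, self.pos, self.ref, self.evolved.alleles)


@dataclass(frozen=True)
class MutationKey:
    """Identity of a mutation for cross-strain set operations: the site plus
    the resulting evolved genotype, so the 'same heterozygous SNP' in two
    strains compares equal while different outcomes at one site do not."""

    contig: str
    pos: int
    ref: str
    evolved_alleles: tuple[str, str]


# ---------------------------------------------------------------------------
# LOH segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LOHSegment:
    """A run of LOH calls on one contig; bounds are the outermost supporting
    calls. ``terminal`` marks segments reaching near a contig end, the pattern
    expected from break-induced replication toward a telomere."""

    strain_id: str
    contig: str
    start: int
    end: int
    n_sites: int
    reversion_fraction: float
    terminal: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.n_sites < 1:
            raise ValueError("segment without supporting sites")

    def reciprocal_overlap(self, other: "LOHSegment") -> float:
        if self.contig != other.contig:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start) + 1
        if inter <= 0:
            return 0.0
        return min(inter / len(self), inter / len(other))

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# effect annotation
# ---------------------------------------------------------------------------

AA_CHANGING_EFFECTS = frozenset(
    {"missense", "nonsense", "stop_lost", "frameshift", "inframe_indel"}
)

EFFECTS = ("intergenic", "synonymous") + tuple(sorted(AA_CHANGING_EFFECTS))


@dataclass(frozen=True)
class EffectAnnotation:
    """Protein-level consequence of variants applied to one CDS.

    ``notation`` follows the compact convention used when reporting evolved
    clones: ``H2Q`` (missense), ``W3*`` (nonsense), ``fs@2`` (frameshift
    starting at residue 2). For frameshifts, ``n_altered_tail`` counts the
    novel residues from the first changed position to the new stop and
    ``n_truncated`` the wild-type residues lost off the end.
    """

    gene_id: str
    effect: str
    notation: str = ""
    protein_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    conservation: str = "n/a"  # conservative | non_conservative | n/a
    n_altered_tail: int | None = None
    n_truncated: int | None = None
    stop_not_found: bool = False
    boundary_truncated: bool = False

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect == "missense":
            if self.aa_ref == self.aa_alt:
                raise ValueError("missense with identical residues")
        if self.effect == "nonsense" and self.aa_alt != "*":
            raise ValueError("nonsense must substitute a stop")

    @property
    def aa_changing(self) -> bool:
        return self.effect in AA_CHANGING_EFFECTS


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
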