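"""Protein-level effect annotation of mutation calls on CDS features.

The mutant coding sequence is built by applying a strain's edits jointly to
the forward-strand genomic window of the CDS (right-to-left, so indels do not
shift downstream coordinates), reverse-complementing for minus-strand genes,
and translating both wild-type and mutant sequences with the standard nuclear
genetic code. Effects are then read off the protein diff:

* substitution of one residue       -> missense (``H2Q``-style notation)
* premature stop                    -> nonsense (``W3*``, truncation site)
* net indel not a codon multiple    -> frameshift (``fs@p``), with the count
  of novel tail residues up to the new stop and of wild-type residues lost
* codon-multiple indel              -> inframe_indel
* protein unchanged                 -> synonymous
* variant outside every CDS         -> intergenic
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .models import (
    CDSFeature,
    EffectAnnotation,
    LOH,
    MutationCall,
    NEW_VARIANT,
    ReferenceGenome,
)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class GenomicEdit:
    """An anchored sequence edit: replace ``ref`` starting at ``pos`` with
    ``alt`` (both on the forward strand, VCF-style)."""

    contig: str
    pos: int
    ref: str
    alt: str

    @property
    def end(self) -> int:
        return self.pos + len(self.ref) - 1

    @property
    def net(self) -> int:
        return len(self.alt) - len(self.ref)


def edit_for_call(call: MutationCall) -> GenomicEdit | None:
    """The single edit a call applies relative to the *reference* sequence.

    New variants edit in their novel allele; LOH to the non-reference allele
    edits in the retained allele; LOH reversions restore the reference and
    carry no edit (``None``).
    """
    if call.category == NEW_VARIANT:
        return GenomicEdit(call.contig, call.pos, call.ref, call.novel_alleles[0])
    assert call.category == LOH
    if call.is_reversion:
        return None
    return GenomicEdit(call.contig, call.pos, call.ref, call.retained_allele)


# ---------------------------------------------------------------------------
# sequence editing and translation
# ---------------------------------------------------------------------------


def apply_variants_to_cds(
    cds: CDSFeature,
    genome: ReferenceGenome,
    edits: Sequence[GenomicEdit],
) -> tuple[str, bool]:
    """Jointly apply edits to a CDS and return its strand-corrected mutant
    coding sequence plus a flag marking edits truncated at a CDS boundary.

    Edits must not overlap each other; each edit's ref allele must match the
    reference sequence. Edits straddling the CDS boundary are clipped to the
    CDS span and flagged.
    """
    for e in edits:
        if e.contig != cds.contig:
            raise ValueError(f"edit on {e.contig} applied to CDS on {cds.contig}")
        observed = genome.slice(e.contig, e.pos, e.end)
        if observed != e.ref:
            raise ValueError(
                f"edit ref {e.ref!r} at {e.contig}:{e.pos} does not match "
                f"reference {observed!r}"
            )
    ordered = sorted(edits, key=lambda e: e.pos)
    for a, b in zip(ordered, ordered[1:]):
        if b.pos <= a.end:
            raise ValueError(
                f"overlapping edits at {cds.contig}:{a.pos} and {cds.contig}:{b.pos}"
            )
    seq = list(genome.slice(cds.contig, cds.start, cds.end))
    truncated = False
    for e in reversed(ordered):  # right-to-left keeps earlier offsets valid
        if e.end < cds.start or e.pos > cds.end:
            raise ValueError(f"edit at {e.contig}:{e.pos} does not overlap the CDS")
        lo = max(e.pos, cds.start)
        hi = min(e.end, cds.end)
        ref_part = e.ref[lo - e.pos : hi - e.pos + 1]
        if lo != e.pos or hi != e.end:
            # clip: keep only the replaced bases inside the CDS; inserted
            # sequence is attributed to the anchor base when it lies inside
            truncated = True
            alt_part = e.alt[lo - e.pos : hi - e.pos + 1] if e.pos < cds.start else e.alt
            if e.pos >= cds.start:
                alt_part = e.alt
        else:
            alt_part = e.alt
        seq[lo - cds.start : hi - cds.start + 1] = list(alt_part)
    mutant = "".join(seq)
    if cds.strand == "-":
        mutant = reverse_complement(mutant)
    return mutant, truncated


def wild_type_cds(cds: CDSFeature, genome: ReferenceGenome) -> str:
    seq = genome.slice(cds.contig, cds.start, cds.end)
    return reverse_complement(seq) if cds.strand == "-" else seq


def translate(seq: str) -> tuple[str, int | None, bool]:
    """Translate with the standard nuclear code, stopping at the first stop.

    Returns ``(protein, stop_codon_index_1based_or_None, incomplete_codon)``.
    An ambiguous base (N) raises ``ValueError`` naming its position.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    n_pos = seq.find("N")
    if n_pos != -1:
        raise ValueError(f"ambiguous base N at position {n_pos + 1}")
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            return "".join(protein), i // 3 + 1, False
        protein.append(_CODON_TABLE.forward_table[codon])
    return "".join(protein), None, len(seq) % 3 != 0


# ---------------------------------------------------------------------------
# effect calling
# ---------------------------------------------------------------------------


def annotate_effect(
    cds: CDSFeature,
    genome: ReferenceGenome,
    edits: Sequence[GenomicEdit],
) -> EffectAnnotation:
    """Compare wild-type and mutant translations of one CDS and describe the
    protein-level outcome of the (jointly applied) edits."""
    if not edits:
        return EffectAnnotation(gene_id=cds.gene_id, effect="synonymous")
    inside = [e for e in edits if e.end >= cds.start and e.pos <= cds.end]
    if not inside:
        return EffectAnnotation(gene_id=cds.gene_id, effect="intergenic")

    wt_seq = wild_type_cds(cds, genome)
    mut_seq, boundary = apply_variants_to_cds(cds, genome, inside)
    wt_prot, wt_stop, _ = translate(wt_seq)
    mut_prot, mut_stop, _ = translate(mut_seq)

    net = sum(e.net for e in inside)
    if net % 3 != 0:
        return _frameshift(cds, wt_prot, mut_prot, mut_stop, boundary)

    if mut_prot == wt_prot and mut_stop is not None:
        return EffectAnnotation(
            gene_id=cds.gene_id, effect="synonymous", boundary_truncated=boundary
        )

    if net != 0:
        pos = _first_diff(wt_prot, mut_prot) or min(len(wt_prot), len(mut_prot)) + 1
        return EffectAnnotation(
            gene_id=cds.gene_id, effect="inframe_indel",
            notation=f"inframe@{pos}", protein_pos=pos,
            boundary_truncated=boundary,
        )

    # equal-length nucleotide change
    if len(mut_prot) < len(wt_prot):
        # premature stop; the truncated codon position is one past the mutant
        # protein end
        stop_pos = len(mut_prot) + 1
        aa_ref = wt_prot[stop_pos - 1]
        return EffectAnnotation(
            gene_id=cds.gene_id, effect="nonsense",
            notation=f"{aa_ref}{stop_pos}*", protein_pos=stop_pos,
            aa_ref=aa_ref, aa_alt="*", boundary_truncated=boundary,
        )
    if mut_stop is None and wt_stop is not None:
        pos = wt_stop
        aa_alt = mut_prot[pos - 1] if pos <= len(mut_prot) else None
        return EffectAnnotation(
            gene_id=cds.gene_id, effect="stop_lost",
            notation=f"*{pos}{aa_alt or '?'}", protein_pos=pos,
            aa_ref="*", aa_alt=aa_alt, stop_not_found=mut_stop is None and aa_alt is None,
            boundary_truncated=boundary,
        )
    pos = _first_diff(wt_prot, mut_prot)
    assert pos is not None, "equal proteins handled above"
    aa_ref, aa_alt = wt_prot[pos - 1], mut_prot[pos - 1]
    return EffectAnnotation(
        gene_id=cds.gene_id, effect="missense",
        notation=f"{aa_ref}{pos}{aa_alt}", protein_pos=pos,
        aa_ref=aa_ref, aa_alt=aa_alt,
        conservation=classify_conservation(aa_ref, aa_alt),
        boundary_truncated=boundary,
    )


def _frameshift(cds, wt_prot: str, mut_prot: str, mut_stop, boundary) -> EffectAnnotation:
    pos = _first_diff(wt_prot, mut_prot)
    if pos is None:
        # mutant protein is a prefix/extension of wild type; first altered
        # residue is the one past the shorter protein
        pos = min(len(wt_prot), len(mut_prot)) + 1
    n_altered = max(len(mut_prot) - (pos - 1), 0)
    n_truncated = max(len(wt_prot) - len(mut_prot), 0)
    return EffectAnnotation(
        gene_id=cds.gene_id, effect="frameshift",
        notation=f"fs@{pos}", protein_pos=pos,
        n_altered_tail=n_altered, n_truncated=n_truncated,
        stop_not_found=mut_stop is None,
        boundary_truncated=boundary,
    )


def _first_diff(a: str, b: str) -> int | None:
    """1-based position of the first differing residue, None if one is a
    prefix of the other (or they are equal)."""
    for i, (x, y) in enumerate(zip(a, b), start=1):
        if x != y:
            return i
    return None


def classify_conservation(aa_ref: str, aa_alt: str, matrix=None) -> str:
    """Conservative iff the substitution scores > 0 in the similarity matrix
    (BLOSUM62 by default). H->Q scores 0 and P->T scores -1, both
    non-conservative; I->V scores 3, conservative."""
    if aa_ref == "*" or aa_alt == "*":
        raise ValueError("stop codons are handled as nonsense, not substitutions")
    m = matrix if matrix is not None else _BLOSUM62
    return "conservative" if m[aa_ref, aa_alt] > 0 else "non_conservative"


# ---------------------------------------------------------------------------
# per-strain annotation of classified calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatedCall:
    """A mutation call joined with its protein-level effect (gene_id empty
    for intergenic calls)."""

    call: MutationCall
    effect: EffectAnnotation

    @property
    def aa_changing(self) -> bool:
        return self.effect.aa_changing

    @property
    def gene_id(self) -> str:
        return self.effect.gene_id


_INTERGENIC = EffectAnnotation(gene_id="", effect="intergenic")


def annotate_strain(
    calls: Sequence[MutationCall],
    genome: ReferenceGenome,
    features: Sequence[CDSFeature],
    joint: bool = False,
) -> list[AnnotatedCall]:
    """Annotate every call of one strain against the CDS catalogue.

    By default each call is annotated on its own (one effect per mutation, as
    in per-mutation accounting); with ``joint=True`` all of a strain's edits
    within one CDS are applied together and every call in that CDS receives
    the joint annotation — appropriate when co-occurring edits interact
    (e.g. two substitutions in one codon).
    """
    by_contig: dict[str, list[CDSFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    for feats in by_contig.values():
        feats.sort(key=lambda f: f.start)

    def feature_for(call: MutationCall) -> CDSFeature | None:
        span_end = call.pos + len(call.ref) - 1
        for f in by_contig.get(call.contig, ()):
            if call.pos <= f.end and span_end >= f.start:
                return f
        return None

    out: list[AnnotatedCall] = []
    if not joint:
        for call in calls:
            f = feature_for(call)
            if f is None:
                out.append(AnnotatedCall(call, _INTERGENIC))
                continue
            edit = edit_for_call(call)
            eff = annotate_effect(f, genome, [edit] if edit else [])
            out.append(AnnotatedCall(call, eff))
        return out

    groups: dict[str, list[MutationCall]] = {}
    orphans: list[MutationCall] = []
    feat_by_gene = {}
    for call in calls:
        f = feature_for(call)
        if f is None:
            orphans.append(call)
        else:
            groups.setdefault(f.gene_id, []).append(call)
            feat_by_gene[f.gene_id] = f
    for call in orphans:
        out.append(AnnotatedCall(call, _INTERGENIC))
    for gene_id, gcalls in groups.items():
        edits = [e for c in gcalls if (e := edit_for_call(c)) is not None]
        eff = annotate_effect(feat_by_gene[gene_id], genome, edits)
        for call in gcalls:
            out.append(AnnotatedCall(call, eff))
    out.sort(key=lambda ac: (ac.call.contig, ac.call.pos))
    return out


EFFECT_COLUMNS = [
    "contig", "pos", "category", "gene_id", "effect", "notation",
    "protein_pos", "aa_ref", "aa_alt", "conservation",
    "n_altered_tail", "n_truncated", "aa_changing",
]


def effects_to_frame(annotated: Sequence[AnnotatedCall]):
    import pandas as pd

    rows = []
    for ac in annotated:
        e = ac.effect
        rows.append({
            "contig": ac.call.contig, "pos": ac.call.pos,
            "category": ac.call.category,
            "gene_id": e.gene_id, "effect": e.effect, "notation": e.notation,
            "protein_pos": "" if e.protein_pos is None else e.protein_pos,
            "aa_ref": e.aa_ref or "", "aa_alt": e.aa_alt or "",
            "conservation": e.conservation,
            "n_altered_tail": "" if e.n_altered_tail is None else e.n_altered_tail,
            "n_truncated": "" if e.n_truncated is None else e.n_truncated,
            "aa_changing": str(e.aa_changing).lower(),
        })
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)
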