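"""Effect annotation: genetic-code outcomes, strand handling, and agreement
with an independent rebuild-and-translate oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from alemut.effects import (
    GenomicEdit,
    annotate_effect,
    annotate_strain,
    apply_variants_to_cds,
    classify_conservation,
    edit_for_call,
    translate,
)
from alemut.classify import classify_site
from alemut.models import CDSFeature, DiploidGenotype, ReferenceGenome, SiteComparison
from alemut.simulate import make_reference, SimulationConfig


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


class TestTranslate:
    def test_stops_at_first_stop(self):
        assert translate("ATGCATTGGTAA") == ("MHW", 4, False)
        assert translate("ATGTAA") == ("M", 2, False)

    def test_incomplete_trailing_codon_flagged(self):
        assert translate("ATGGG") == ("M", None, True)

    def test_ambiguous_base_named(self):
        with pytest.raises(ValueError, match="position 5"):
            translate("ATGCNTTGG")


class TestApplyVariants:
    def test_single_snp(self, toy_genome, toy_cds):
        seq, flag = apply_variants_to_cds(toy_cds, toy_genome,
                                          [GenomicEdit("chrA", 6, "T", "A")])
        assert seq == "ATGCAATGGTAA" and not flag

    def test_minus_strand_equivalence(self, toy_genome, toy_cds):
        """Editing the mirrored gene in genome space yields the identical
        coding sequence after reverse-complementing."""
        plus_seq, _ = apply_variants_to_cds(toy_cds, toy_genome,
                                            [GenomicEdit("chrA", 6, "T", "A")])
        mirrored = ReferenceGenome(contigs={"chrA": _revcomp(toy_genome.contigs["chrA"])})
        clen = len(mirrored.contigs["chrA"])
        cds = CDSFeature("g1", "chrA", clen - 11, clen, "-")
        gpos = clen - 6 + 1  # genomic position of CDS base 6 on the mirror
        minus_seq, _ = apply_variants_to_cds(
            cds, mirrored, [GenomicEdit("chrA", gpos, "A", "T")]
        )
        assert minus_seq == plus_seq

    def test_two_snps_in_one_codon_applied_jointly(self, toy_genome, toy_cds):
        seq, _ = apply_variants_to_cds(toy_cds, toy_genome, [
            GenomicEdit("chrA", 4, "C", "G"),
            GenomicEdit("chrA", 6, "T", "A"),
        ])
        assert seq[3:6] == "GAA"

    def test_ref_mismatch_rejected(self, toy_genome, toy_cds):
        with pytest.raises(ValueError, match="does not match"):
            apply_variants_to_cds(toy_cds, toy_genome, [GenomicEdit("chrA", 6, "G", "A")])

    def test_overlapping_edits_rejected(self, toy_genome, toy_cds):
        with pytest.raises(ValueError, match="overlapping"):
            apply_variants_to_cds(toy_cds, toy_genome, [
                GenomicEdit("chrA", 4, "CAT", "C"),
                GenomicEdit("chrA", 5, "A", "G"),
            ])


class TestAnnotateEffect:
    def test_missense_notation(self, toy_genome, toy_cds):
        e = annotate_effect(toy_cds, toy_genome, [GenomicEdit("chrA", 6, "T", "A")])
        assert (e.effect, e.notation) == ("missense", "H2Q")
        assert e.conservation == "non_conservative"

    def test_nonsense_with_truncation_position(self, toy_genome, toy_cds):
        e = annotate_effect(toy_cds, toy_genome, [GenomicEdit("chrA", 9, "G", "A")])
        assert (e.effect, e.notation, e.protein_pos) == ("nonsense", "W3*", 3)

    def test_synonymous_third_base_wobble(self):
        # GGT -> GGC: both glycine (4-fold degenerate codon)
        g = ReferenceGenome(contigs={"c": "ATGGGTTGGTAAACGT"})
        cds = CDSFeature("g1", "c", 1, 12, "+")
        e = annotate_effect(cds, g, [GenomicEdit("c", 6, "T", "C")])
        assert e.effect == "synonymous"

    def test_intergenic_when_outside_cds(self, toy_genome, toy_cds):
        e = annotate_effect(toy_cds, toy_genome, [GenomicEdit("chrA", 20, "T", "A")])
        assert e.effect == "intergenic"

    def test_frameshift_tail_and_truncation_counts(self):
        """A 4-bp deletion early in a 60-codon ORF: the annotated altered-tail
        and truncated-residue counts must equal a brute-force re-translation
        of the edited sequence."""
        rng = np.random.default_rng(17)
        cfg = SimulationConfig(n_contigs=1, contig_length=4_000,
                               n_cds_per_contig=1, cds_codon_min=60,
                               cds_codon_max=60, n_lineages=1,
                               group_sizes=(1,), group_names=("A",))
        genome, (cds,) = make_reference(cfg, seed=17)
        anchor = cds.start + 2  # deletion of CDS bases 4-7
        ref_allele = genome.slice(cds.contig, anchor, anchor + 4)
        edit = GenomicEdit(cds.contig, anchor, ref_allele, ref_allele[0])
        e = annotate_effect(cds, genome, [edit])
        assert e.effect == "frameshift"
        wt_p, mut_p = _oracle_proteins(genome, cds, [edit])
        first = next(
            (i + 1 for i, (a, b) in enumerate(zip(wt_p, mut_p)) if a != b),
            min(len(wt_p), len(mut_p)) + 1,
        )
        assert e.protein_pos == first
        assert e.n_altered_tail == len(mut_p) - first + 1
        assert e.n_truncated == len(wt_p) - len(mut_p)

    def test_strand_invariance(self, toy_genome, toy_cds):
        e_plus = annotate_effect(toy_cds, toy_genome, [GenomicEdit("chrA", 6, "T", "A")])
        mirrored = ReferenceGenome(contigs={"chrA": _revcomp(toy_genome.contigs["chrA"])})
        clen = len(mirrored.contigs["chrA"])
        cds = CDSFeature("g1", "chrA", clen - 11, clen, "-")
        e_minus = annotate_effect(cds, mirrored,
                                  [GenomicEdit("chrA", clen - 5, "A", "T")])
        assert (e_minus.effect, e_minus.notation) == (e_plus.effect, e_plus.notation)


class TestConservation:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("H", "Q", "non_conservative"),  # BLOSUM62 score 0
        ("P", "T", "non_conservative"),  # score -1
        ("I", "V", "conservative"),      # score 3
    ])
    def test_blosum62_sign_rule(self, ref, alt, expected):
        assert classify_conservation(ref, alt) == expected

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            classify_conservation("W", "*")


class TestEditForCall:
    def _call(self, ref, parent, evolved):
        return classify_site(SiteComparison(
            "chrA", 6, ref, DiploidGenotype(parent), DiploidGenotype(evolved)
        ))

    def test_reversion_has_no_edit(self):
        assert edit_for_call(self._call("T", ("T", "A"), ("T", "T"))) is None

    def test_loh_to_alternate_edits_retained_allele(self):
        e = edit_for_call(self._call("T", ("T", "A"), ("A", "A")))
        assert (e.pos, e.ref, e.alt) == (6, "T", "A")

    def test_new_variant_edits_novel_allele(self):
        e = edit_for_call(self._call("T", ("T", "T"), ("T", "G")))
        assert (e.pos, e.ref, e.alt) == (6, "T", "G")


# ---------------------------------------------------------------------------
# independent oracle: rebuild the mutant contig, re-extract, translate with
# Biopython, and diff proteins
# ---------------------------------------------------------------------------


def _oracle_proteins(genome, cds, edits):
    contig = list(genome.contigs[cds.contig])
    for e in sorted(edits, key=lambda e: e.pos, reverse=True):
        contig[e.pos - 1 : e.end] = list(e.alt)
    net = sum(e.net for e in edits)
    mutant_window = "".join(contig[cds.start - 1 : cds.end + net])
    wt_window = genome.slice(cds.contig, cds.start, cds.end)
    if cds.strand == "-":
        mutant_window = str(Seq(mutant_window).reverse_complement())
        wt_window = str(Seq(wt_window).reverse_complement())
    def prot(seq):
        aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate(table=1))
        return aa.split("*")[0]
    return prot(wt_window), prot(mutant_window)


def oracle_effect(genome, cds, edits):
    """Naive independent effect call from whole-sequence rebuild."""
    wt_p, mut_p = _oracle_proteins(genome, cds, edits)
    net = sum(e.net for e in edits)
    first = next(
        (i + 1 for i, (a, b) in enumerate(zip(wt_p, mut_p)) if a != b), None
    )
    if net % 3 != 0:
        pos = first if first is not None else min(len(wt_p), len(mut_p)) + 1
        return ("frameshift", f"fs@{pos}", max(len(mut_p) - pos + 1, 0),
                max(len(wt_p) - len(mut_p), 0))
    if wt_p == mut_p:
        return ("synonymous", "", None, None)
    if net != 0:
        pos = first if first is not None else min(len(wt_p), len(mut_p)) + 1
        return ("inframe_indel", f"inframe@{pos}", None, None)
    if len(mut_p) < len(wt_p):
        pos = len(mut_p) + 1
        return ("nonsense", f"{wt_p[pos - 1]}{pos}*", None, None)
    if len(mut_p) > len(wt_p):
        pos = len(wt_p) + 1
        return ("stop_lost", f"*{pos}{mut_p[pos - 1]}", None, None)
    return ("missense", f"{wt_p[first - 1]}{first}{mut_p[first - 1]}", None, None)


def random_edits(rng, genome, cds, n):
    """n non-overlapping random edits strictly inside the CDS body."""
    edits = []
    taken = []
    for _ in range(n):
        for _attempt in range(50):
            kind = rng.integers(3)
            pos = int(rng.integers(cds.start + 1, cds.end - 6))
            if kind == 0:  # SNV
                span = (pos, pos)
                ref = genome.base(cds.contig, pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            elif kind == 1:  # deletion of 1-4 bases
                d = int(rng.integers(1, 5))
                span = (pos, pos + d)
                ref = genome.slice(cds.contig, pos, pos + d)
                alt = ref[0]
            else:  # insertion of 1-4 bases
                span = (pos, pos)
                ref = genome.base(cds.contig, pos)
                alt = ref + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 5))))
            if span[1] >= cds.end:
                continue
            if all(span[1] < s or span[0] > e for s, e in taken):
                taken.append(span)
                edits.append(GenomicEdit(cds.contig, pos, ref, alt))
                break
    return edits


class TestOracleEquivalence:
    def test_random_cds_variant_combinations_match_oracle(self):
        """(effect, notation, frameshift tail counts) agree with the
        rebuild-and-translate oracle across random CDS/variant draws."""
        cfg = SimulationConfig(n_contigs=1, contig_length=20_000,
                               n_cds_per_contig=12, n_lineages=1,
                               group_sizes=(1,), group_names=("A",))
        genome, feats = make_reference(cfg, seed=29)
        rng = np.random.default_rng(30)
        checked = 0
        for _ in range(100):
            cds = feats[int(rng.integers(len(feats)))]
            edits = random_edits(rng, genome, cds, int(rng.integers(1, 4)))
            if not edits:
                continue
            got = annotate_effect(cds, genome, edits)
            eff, notation, tail, trunc = oracle_effect(genome, cds, edits)
            assert got.effect == eff
            assert got.notation == notation
            if eff == "frameshift":
                assert (got.n_altered_tail, got.n_truncated) == (tail, trunc)
            checked += 1
        assert checked >= 90
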