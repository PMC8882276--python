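"""Parent-vs-evolved comparison and mutation classification.

Every site at which the evolved genotype differs from the parental one is
classified into exactly one of two categories:

* ``new_variant`` — the evolved strain carries at least one allele absent
  from both parental haplotypes (a de novo mutation);
* ``loh`` — a parent-heterozygous site became homozygous for one of the two
  parental alleles (loss of heterozygosity). When the retained allele equals
  the reference allele the event is a *reversion*: the evolved genotype is
  indistinguishable from wild type, so such sites are absent from the evolved
  strain's own variant table and are only recoverable because the parent
  table supplies the site universe.

A parent-homozygous site that became homozygous for a *different* allele is a
homozygous new variant, not LOH: loss of heterozygosity requires a
heterozygous parent.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Sequence

from .models import (
    LOH,
    NEW_VARIANT,
    DiploidGenotype,
    GenotypeTable,
    MutationCall,
    ReferenceGenome,
    SiteComparison,
)

log = logging.getLogger("alemut")


def diff_sites(
    parent: GenotypeTable,
    evolved: GenotypeTable,
    reference: ReferenceGenome | None = None,
) -> list[SiteComparison]:
    """Compare two genotype tables over the union of their sites.

    A site present in only one table is imputed homozygous-reference in the
    other — this is what makes reversions visible at parent-only sites.
    Sites with identical genotypes on both sides are dropped (count logged).
    Conflicting ref alleles at a shared site raise ``ValueError``.
    """
    psites = parent.sites()
    esites = evolved.sites()
    out: list[SiteComparison] = []
    identical = 0
    for key in sorted(set(psites) | set(esites)):
        prec, erec = psites.get(key), esites.get(key)
        if prec is not None and erec is not None and prec.ref != erec.ref:
            raise ValueError(
                f"conflicting ref alleles at {key[0]}:{key[1]}: "
                f"{prec.ref!r} (parent) vs {erec.ref!r} (evolved)"
            )
        ref = (prec or erec).ref
        pgt = prec.genotype if prec else DiploidGenotype.hom(ref)
        egt = erec.genotype if erec else DiploidGenotype.hom(ref)
        if pgt == egt:
            identical += 1
            continue
        out.append(SiteComparison(key[0], key[1], ref, pgt, egt))
    if identical:
        log.info(
            "%s vs %s: dropped %d sites with identical genotypes",
            parent.strain_id, evolved.strain_id, identical,
        )
    return out


def classify_site(cmp: SiteComparison, contig_class: str = "reference") -> MutationCall:
    """Classify one differing site. Total over all valid comparisons."""
    parent_alleles = set(cmp.parent)
    novel = sorted({a for a in cmp.evolved if a not in parent_alleles})
    zygosity = "hom" if cmp.evolved.is_hom else "het"
    kind = _variant_kind(cmp)
    if novel:
        return MutationCall(
            contig=cmp.contig, pos=cmp.pos, ref=cmp.ref,
            category=NEW_VARIANT, zygosity=zygosity,
            parent=cmp.parent, evolved=cmp.evolved,
            variant_kind=kind, contig_class=contig_class,
            novel_alleles=tuple(novel),
        )
    # evolved alleles are a subset of the parent's but the multisets differ:
    # the parent must have been het and the evolved strain hom.
    assert cmp.parent.is_het and cmp.evolved.is_hom, (
        "classification rules are total: non-novel difference implies "
        "het parent homozygosed"
    )
    retained = cmp.evolved.alleles[0]
    return MutationCall(
        contig=cmp.contig, pos=cmp.pos, ref=cmp.ref,
        category=LOH, zygosity="hom",
        parent=cmp.parent, evolved=cmp.evolved,
        variant_kind=kind, contig_class=contig_class,
        is_reversion=(retained == cmp.ref),
        retained_allele=retained,
    )


def _variant_kind(cmp: SiteComparison) -> str:
    involved = {cmp.ref, *cmp.parent, *cmp.evolved}
    return "indel" if any(len(a) != 1 for a in involved) else "snp"


def classify_strain(
    parent: GenotypeTable,
    evolved: GenotypeTable,
    reference: ReferenceGenome,
) -> list[MutationCall]:
    """Full per-strain classification: diff then classify, tagged with the
    contig's provenance class, sorted by position."""
    calls = [
        classify_site(cmp, reference.contig_class.get(cmp.contig, "reference"))
        for cmp in diff_sites(parent, evolved, reference)
    ]
    counts = Counter(c.category for c in calls)
    log.info(
        "%s: %d calls (%d new variants, %d LOH)",
        evolved.strain_id, len(calls), counts[NEW_VARIANT], counts[LOH],
    )
    return calls


# ---------------------------------------------------------------------------
# TSV serialization of call lists
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "contig", "pos", "ref", "category", "zygosity", "variant_kind",
    "contig_class", "is_reversion", "retained_allele", "novel_alleles",
    "parent_alleles", "evolved_alleles",
]


def calls_to_frame(calls: Sequence[MutationCall]):
    """Render calls as a pandas DataFrame with the fixed column layout."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "contig": c.contig, "pos": c.pos, "ref": c.ref,
            "category": c.category, "zygosity": c.zygosity,
            "variant_kind": c.variant_kind, "contig_class": c.contig_class,
            "is_reversion": "" if c.is_reversion is None else str(c.is_reversion).lower(),
            "retained_allele": c.retained_allele or "",
            "novel_alleles": ",".join(c.novel_alleles),
            "parent_alleles": "/".join(c.parent.alleles),
            "evolved_alleles": "/".join(c.evolved.alleles),
        })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(calls: Sequence[MutationCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[MutationCall]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for row in df.itertuples(index=False):
        parent = DiploidGenotype(tuple(row.parent_alleles.split("/")))
        evolved = DiploidGenotype(tuple(row.evolved_alleles.split("/")))
        calls.append(MutationCall(
            contig=row.contig, pos=int(row.pos), ref=row.ref,
            category=row.category, zygosity=row.zygosity,
            parent=parent, evolved=evolved,
            variant_kind=row.variant_kind, contig_class=row.contig_class,
            is_reversion=(row.is_reversion == "true") if row.is_reversion else None,
            retained_allele=row.retained_allele or None,
            novel_alleles=tuple(a for a in row.novel_alleles.split(",") if a),
        ))
    return calls
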