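"""Cohort-level mutation accounting.

Reproduces the accounting structure used when reporting evolved-strain
cohorts: per-strain new-variant vs LOH tallies, group-level counts as the
union of member strains' mutations, a Shared row for mutations present in
every group, per-contig-class column blocks with all / amino-acid-changing /
genes-with-AA-changes counts, Venn partitions between strain pairs, and
recurrently mutated genes across independent lines.

Mutation identity for all cross-strain set operations is the
:class:`~alemut.models.MutationKey`: site plus resulting evolved genotype.
Two strains share a mutation only when the same site ended in the same
genotype, so the "same heterozygous SNP in seven strains" is distinguishable
from seven different mutations in one gene.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd

from .effects import AnnotatedCall
from .models import LOH, NEW_VARIANT, MutationKey

CATEGORY_ROWS = (("all", None), ("new_variants", NEW_VARIANT), ("loh", LOH))


def _key_info(
    annotated_by_strain: Mapping[str, Sequence[AnnotatedCall]],
) -> tuple[dict[str, set[MutationKey]], dict[MutationKey, dict]]:
    """Per-strain key sets plus per-key metadata (category, class, effect)."""
    per_strain: dict[str, set[MutationKey]] = {}
    info: dict[MutationKey, dict] = {}
    for strain, acs in annotated_by_strain.items():
        keys = set()
        for ac in acs:
            k = ac.call.key
            keys.add(k)
            info.setdefault(k, {
                "category": ac.call.category,
                "contig_class": ac.call.contig_class,
                "aa_changing": ac.aa_changing,
                "gene_id": ac.gene_id,
            })
        per_strain[strain] = keys
    return per_strain, info


def _block_counts(keys: set[MutationKey], info, contig_classes) -> dict:
    row: dict[str, int] = {}
    for cls in contig_classes:
        cls_keys = [k for k in keys if info[k]["contig_class"] == cls]
        aa = [k for k in cls_keys if info[k]["aa_changing"]]
        genes = {info[k]["gene_id"] for k in aa if info[k]["gene_id"]}
        row[f"{cls}_all"] = len(cls_keys)
        row[f"{cls}_aa_changing"] = len(aa)
        row[f"{cls}_genes_with_aa_changes"] = len(genes)
    row["total"] = len(keys)
    return row


def tabulate(
    annotated_by_strain: Mapping[str, Sequence[AnnotatedCall]],
    groups: Mapping[str, str],
    contig_classes: Sequence[str] = ("reference", "inserted_pathway", "strain_specific"),
) -> pd.DataFrame:
    """Build the cohort accounting table.

    Rows are (category in {all, new_variants, loh}) x (scope in {overall,
    one row per group, shared}); group scopes count the union of member
    strains' mutation keys and ``shared`` counts keys present in at least one
    strain of *each* group. Because group rows are unions, the identity
    ``|overall| = |A| + |B| - |A and B|`` holds for two groups.

    Raises ``ValueError`` for a strain with calls but no group assignment.
    """
    missing = set(annotated_by_strain) - set(groups)
    if missing:
        raise ValueError(f"strains missing from the group manifest: {sorted(missing)}")
    per_strain, info = _key_info(annotated_by_strain)

    group_names = sorted({groups[s] for s in per_strain})
    group_keys: dict[str, set[MutationKey]] = {g: set() for g in group_names}
    for strain, keys in per_strain.items():
        group_keys[groups[strain]] |= keys
    all_keys = set().union(*group_keys.values()) if group_keys else set()
    shared_keys = (
        set.intersection(*group_keys.values()) if len(group_keys) > 1 else set()
    )

    scopes = [("overall", all_keys)]
    scopes += [(g, group_keys[g]) for g in group_names]
    scopes += [("shared", shared_keys)]

    rows = []
    index = []
    for cat_name, cat in CATEGORY_ROWS:
        for scope_name, keys in scopes:
            sel = keys if cat is None else {k for k in keys if info[k]["category"] == cat}
            rows.append(_block_counts(sel, info, contig_classes))
            index.append((cat_name, scope_name))
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["category", "scope"]))
    return df


def per_strain_counts(
    annotated_by_strain: Mapping[str, Sequence[AnnotatedCall]],
) -> pd.DataFrame:
    """Per-strain totals: all / new variants / LOH / reversions."""
    rows = []
    for strain, acs in sorted(annotated_by_strain.items()):
        n_new = sum(1 for a in acs if a.call.category == NEW_VARIANT)
        n_loh = sum(1 for a in acs if a.call.category == LOH)
        n_rev = sum(1 for a in acs if a.call.category == LOH and a.call.is_reversion)
        rows.append({
            "strain_id": strain, "total": len(acs),
            "new_variants": n_new, "loh": n_loh, "reversions": n_rev,
        })
    return pd.DataFrame(rows, columns=["strain_id", "total", "new_variants", "loh", "reversions"])


def venn(
    keys_a: set[MutationKey] | Sequence[AnnotatedCall],
    keys_b: set[MutationKey] | Sequence[AnnotatedCall],
) -> tuple[int, int, int]:
    """Two-strain overlap partition: (only A, shared, only B)."""
    a = keys_a if isinstance(keys_a, set) else {ac.call.key for ac in keys_a}
    b = keys_b if isinstance(keys_b, set) else {ac.call.key for ac in keys_b}
    return len(a - b), len(a & b), len(b - a)


def shared_mutated_genes(
    annotated_by_strain: Mapping[str, Sequence[AnnotatedCall]],
    category: str | None = None,
    aa_changing_only: bool = True,
    min_strains: int = 2,
) -> pd.DataFrame:
    """Genes mutated in at least ``min_strains`` strains, with per-strain
    notations, plus the count of strains sharing the identical mutation.

    ``identical_key_strains`` is the largest number of strains carrying the
    very same mutation key in the gene — the pattern behind "seven of eleven
    strains carry the same heterozygous SNP".
    """
    if min_strains < 2:
        raise ValueError("min_strains must be >= 2")
    gene_strains: dict[str, dict[str, list[str]]] = {}
    gene_keys: dict[str, dict[MutationKey, set[str]]] = {}
    for strain, acs in annotated_by_strain.items():
        for ac in acs:
            if not ac.gene_id:
                continue
            if category is not None and ac.call.category != category:
                continue
            if aa_changing_only and not ac.aa_changing:
                continue
            gene_strains.setdefault(ac.gene_id, {}).setdefault(strain, []).append(
                ac.effect.notation or ac.effect.effect
            )
            gene_keys.setdefault(ac.gene_id, {}).setdefault(ac.call.key, set()).add(strain)
    rows = []
    for gene_id, strains in sorted(gene_strains.items()):
        if len(strains) < min_strains:
            continue
        identical = max((len(s) for s in gene_keys[gene_id].values()), default=0)
        rows.append({
            "gene_id": gene_id,
            "n_strains": len(strains),
            "strains": ",".join(sorted(strains)),
            "notations": ";".join(
                f"{s}:{'|'.join(strains[s])}" for s in sorted(strains)
            ),
            "identical_key_strains": identical,
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "n_strains", "strains", "notations",
                       "identical_key_strains"],
    )


def percent_printed(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Render 100*num/den rounded half-away-from-zero, e.g. (188, 2255, 1)
    -> '8.3%'."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quant = Decimal(1).scaleb(-decimals)
    return f"{value.quantize(quant, rounding=ROUND_HALF_UP)}%"
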