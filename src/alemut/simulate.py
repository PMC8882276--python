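"""Synthetic diploid-evolution data generator.

Emulates the genomic structure of an adaptively evolved heterozygous diploid
industrial yeast cohort: a parent carrying heterozygous SNVs at roughly one
site per 300 bp, and evolved lineages dominated by loss-of-heterozygosity
tracts (gene-conversion-like homozygosis of contiguous regions, with the
reference homolog retained about half the time, i.e. ~50% reversions),
plus scattered de novo SNVs/indels at roughly an order of magnitude lower
count than LOH sites (~8% of all differences), and segmental or
whole-chromosome copy-number changes visible only through Poisson read
depth. Every lineage ships with a machine-readable truth set so downstream
stages can be scored exactly.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as gio
from .models import (
    CDSFeature,
    DepthTrack,
    DiploidGenotype,
    GenotypeTable,
    ReferenceGenome,
    SiteRecord,
)

_BASES = np.array(list("ACGT"))
_STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CNVEvent:
    """A planted copy-number change: the whole contig when ``span`` is None,
    else the 1-based inclusive interval. ``copy_delta`` in {-1, +1, +2}."""

    contig: str
    copy_delta: int
    span: tuple[int, int] | None = None


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults mirror an eleven-isolate diploid evolution cohort: three 100-kb
    contigs, heterozygous sites at density 1/300 bp, six LOH tracts of mean
    10 kb per lineage (about 200 LOH sites) against a Poisson-mean 18 de
    novo events, which puts the expected cohort-wide new-variant fraction
    near 8%; half of LOH tracts retain the reference homolog (reversions);
    mean sequencing depth 50x.
    """

    n_contigs: int = 3
    contig_length: int = 100_000
    gc_fraction: float = 0.38
    n_cds_per_contig: int = 40
    cds_codon_min: int = 60
    cds_codon_max: int = 180

    het_density: float = 1 / 300

    n_loh_tracts: int = 6
    tract_length_mean: float = 10_000.0
    p_terminal_tract: float = 0.2
    p_retain_reference: float = 0.5

    n_de_novo: float = 18.0
    snv_indel_ratio: float = 4.0
    p_de_novo_hom: float = 0.2
    max_indel_len: int = 4

    n_cnv_events_mean: float = 1.0
    p_whole_chromosome: float = 0.5
    cnv_span_mean: float = 20_000.0
    cnv_delta_choices: tuple[int, ...] = (-1, 1, 2)
    cnv_delta_probs: tuple[float, ...] = (0.25, 0.6, 0.15)

    mean_depth: float = 50.0

    n_lineages: int = 11
    n_groups: int = 2
    group_names: tuple[str, ...] = ("YE-SSL", "MM-SSL")
    group_sizes: tuple[int, ...] = (5, 6)

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "het_density", "p_terminal_tract",
                     "p_retain_reference", "p_de_novo_hom", "p_whole_chromosome"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contig_length <= 0 or self.n_contigs <= 0:
            raise ValueError("contig dimensions must be positive")
        if sum(self.group_sizes) != self.n_lineages:
            raise ValueError("group_sizes must sum to n_lineages")
        if len(self.group_sizes) != len(self.group_names):
            raise ValueError("one size per group name")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("group_names",):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("group_sizes", "cnv_delta_choices"):
            if key in data:
                data[key] = tuple(int(x) for x in data[key])
        if "cnv_delta_probs" in data:
            data["cnv_delta_probs"] = tuple(float(x) for x in data["cnv_delta_probs"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


# ---------------------------------------------------------------------------
# truth set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth label for one site where the lineage differs from (or,
    for reversions, silently matches) the parent."""

    contig: str
    pos: int
    ref: str
    category: str  # new_variant | loh
    zygosity: str  # het | hom
    is_reversion: bool | None
    evolved_alleles: tuple[str, str]
    variant_kind: str  # snp | indel


@dataclass
class TruthSet:
    """Planted ground truth for one lineage: per-site labels, LOH tract
    intervals, the true per-position copy profile, and the de novo list."""

    strain_id: str
    labels: list[TruthLabel] = field(default_factory=list)
    tracts: list[dict] = field(default_factory=list)
    copy_profile: dict[str, np.ndarray] = field(default_factory=dict)
    de_novo: list[dict] = field(default_factory=list)
    cnv_events: list[CNVEvent] = field(default_factory=list)

    def label_index(self) -> dict[tuple[str, int], TruthLabel]:
        return {(l.contig, l.pos): l for l in self.labels}

    def to_json(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "labels": [dataclasses.asdict(l) for l in self.labels],
            "tracts": self.tracts,
            "copy_profile": {c: arr.tolist() for c, arr in self.copy_profile.items()},
            "de_novo": self.de_novo,
            "cnv_events": [dataclasses.asdict(e) for e in self.cnv_events],
        }

    @classmethod
    def from_json(cls, data: dict) -> "TruthSet":
        labels = [
            TruthLabel(**{**l, "evolved_alleles": tuple(l["evolved_alleles"])})
            for l in data["labels"]
        ]
        return cls(
            strain_id=data["strain_id"],
            labels=labels,
            tracts=data["tracts"],
            copy_profile={c: np.asarray(v) for c, v in data["copy_profile"].items()},
            de_novo=data["de_novo"],
            cnv_events=[
                CNVEvent(e["contig"], e["copy_delta"],
                         tuple(e["span"]) if e["span"] else None)
                for e in data["cnv_events"]
            ],
        )


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------


def make_reference(
    config: SimulationConfig, seed: int
) -> tuple[ReferenceGenome, list[CDSFeature]]:
    """Random reference genome at the configured GC with embedded CDSs.

    Each CDS is ATG + internal-stop-free random codons + a stop codon,
    placed non-overlapping (both strands); minus-strand genes are embedded
    as the reverse complement so the strand-corrected sequence is a clean
    ORF.
    """
    rng = np.random.default_rng(seed)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    contigs: dict[str, str] = {}
    features: list[CDSFeature] = []
    sense_codons = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOP_CODONS
    ]
    for ci in range(config.n_contigs):
        cid = f"chr{_roman(ci + 1)}"
        seq = rng.choice(_BASES, size=config.contig_length, p=probs)
        placed: list[tuple[int, int]] = []  # 0-based half-open, with margin
        for gi in range(config.n_cds_per_contig):
            n_codons = int(rng.integers(config.cds_codon_min, config.cds_codon_max + 1))
            length = 3 * n_codons
            start0 = _place_interval(rng, config.contig_length, length, placed)
            if start0 is None:
                raise ValueError(
                    f"could not place {config.n_cds_per_contig} CDS of up to "
                    f"{3 * config.cds_codon_max} bp on a {config.contig_length} bp contig"
                )
            placed.append((start0, start0 + length))
            body = rng.choice(sense_codons, size=n_codons - 2)
            orf = "ATG" + "".join(body) + _STOP_CODONS[int(rng.integers(3))]
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = orf if strand == "+" else _revcomp(orf)
            seq[start0 : start0 + length] = list(embedded)
            features.append(CDSFeature(
                gene_id=f"g{ci + 1}_{gi + 1:03d}", contig=cid,
                start=start0 + 1, end=start0 + length, strand=strand,
            ))
        contigs[cid] = "".join(seq)
    features.sort(key=lambda f: (f.contig, f.start))
    return ReferenceGenome(contigs=contigs), features


def _place_interval(rng, contig_len, length, placed, margin=10, max_tries=200):
    for _ in range(max_tries):
        start0 = int(rng.integers(0, contig_len - length))
        if all(start0 + length + margin <= lo or start0 >= hi + margin
               for lo, hi in placed):
            return start0
    return None


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _roman(n: int) -> str:
    numerals = [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for v, s in numerals:
        while n >= v:
            out += s
            n -= v
    return out


# ---------------------------------------------------------------------------
# parent and lineages
# ---------------------------------------------------------------------------


def make_parent(
    reference: ReferenceGenome, het_density: float, seed: int,
    strain_id: str = "parent",
) -> GenotypeTable:
    """Heterozygous parent: SNV sites drawn uniformly at the given density,
    each ref/alt with a random non-reference alternate base."""
    if het_density < 0:
        raise ValueError("het_density must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[SiteRecord] = []
    for cid, seq in reference.contigs.items():
        n = rng.binomial(len(seq), het_density)
        positions = np.sort(rng.choice(len(seq), size=n, replace=False)) + 1
        for pos in positions:
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            records.append(SiteRecord(cid, int(pos), ref, DiploidGenotype.of(ref, alt)))
    return GenotypeTable(strain_id=strain_id, records=records)


def evolve_lineage(
    parent: GenotypeTable,
    reference: ReferenceGenome,
    config: SimulationConfig,
    seed: int,
    strain_id: str = "evolved",
    cnv_events: Sequence[CNVEvent] | None = None,
) -> tuple[GenotypeTable, TruthSet]:
    """Derive one evolved lineage from the parent.

    LOH tracts homozygose every parental heterozygous site they cover: a
    tract retaining the reference homolog turns its sites hom-ref, which
    removes them from the evolved table entirely (reversions are invisible
    in the evolved strain's own VCF — only the truth set and a parent-aware
    comparison can recover them); a tract retaining the alternate homolog
    leaves hom-alt records. De novo SNVs/indels land at fresh positions.
    CNV events change only the true copy profile, never the genotypes.
    """
    rng = np.random.default_rng(seed)
    truth = TruthSet(strain_id=strain_id)

    tracts = _draw_tracts(rng, reference, config)
    tract_choices = [bool(rng.random() < config.p_retain_reference) for _ in tracts]

    psites = parent.sites()
    evolved: dict[tuple[str, int], SiteRecord] = dict(psites)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for rec in parent:
        occupied.setdefault(rec.contig, []).append((rec.pos, rec.pos + len(rec.ref) - 1))

    for (contig, lo, hi, terminal), retain_ref in zip(tracts, tract_choices):
        covered = [r for r in parent if r.contig == contig and lo <= r.pos <= hi]
        for rec in covered:
            ref, alt = rec.ref, next(a for a in rec.genotype if a != rec.ref)
            if retain_ref:
                evolved.pop(rec.key)  # hom-ref: indistinguishable from wild type
                retained, zyg = ref, "hom"
            else:
                evolved[rec.key] = SiteRecord(
                    rec.contig, rec.pos, rec.ref, DiploidGenotype.hom(alt)
                )
                retained, zyg = alt, "hom"
            truth.labels.append(TruthLabel(
                contig=rec.contig, pos=rec.pos, ref=rec.ref,
                category="loh", zygosity=zyg,
                is_reversion=retain_ref,
                evolved_alleles=(retained, retained),
                variant_kind="snp",
            ))
        truth.tracts.append({
            "contig": contig, "start": lo, "end": hi,
            "retained_reference": retain_ref, "terminal": terminal,
            "n_het_sites": len(covered),
        })

    _plant_de_novo(rng, reference, config, evolved, occupied, truth)

    # true copy profile
    profile = {cid: np.full(len(seq), 2, dtype=np.int16)
               for cid, seq in reference.contigs.items()}
    events = list(cnv_events) if cnv_events is not None else _draw_cnv_events(rng, reference, config)
    for ev in events:
        arr = profile[ev.contig]
        if ev.span is None:
            arr += ev.copy_delta
        else:
            lo, hi = ev.span
            arr[lo - 1 : hi] += ev.copy_delta
        np.clip(arr, 0, None, out=arr)
    truth.copy_profile = profile
    truth.cnv_events = events

    table = GenotypeTable(strain_id=strain_id, records=list(evolved.values()))
    truth.labels.sort(key=lambda l: (l.contig, l.pos))
    return table, truth


def _draw_tracts(rng, reference, config, max_retries: int = 200):
    """Non-overlapping LOH tract intervals, length-weighted across contigs."""
    cids = list(reference.contigs)
    lengths = np.array([reference.length(c) for c in cids], dtype=float)
    weights = lengths / lengths.sum()
    tracts: list[tuple[str, int, int, bool]] = []
    for _ in range(config.n_loh_tracts):
        for attempt in range(max_retries):
            cid = str(rng.choice(cids, p=weights))
            clen = reference.length(cid)
            tlen = min(int(rng.geometric(1.0 / config.tract_length_mean)), clen)
            terminal = bool(rng.random() < config.p_terminal_tract)
            if terminal:
                lo, hi = (1, tlen) if rng.random() < 0.5 else (clen - tlen + 1, clen)
            else:
                lo = int(rng.integers(1, clen - tlen + 2))
                hi = lo + tlen - 1
            if all(c != cid or hi < s or lo > e for c, s, e, _ in tracts):
                tracts.append((cid, lo, hi, terminal))
                break
        else:
            raise RuntimeError(
                f"could not place {config.n_loh_tracts} non-overlapping LOH tracts"
            )
    return tracts


def _plant_de_novo(rng, reference, config, evolved, occupied, truth) -> None:
    n = rng.poisson(config.n_de_novo)
    cids = list(reference.contigs)
    lengths = np.array([reference.length(c) for c in cids], dtype=float)
    weights = lengths / lengths.sum()
    p_snv = config.snv_indel_ratio / (config.snv_indel_ratio + 1.0)
    for _ in range(n):
        for attempt in range(200):
            cid = str(rng.choice(cids, p=weights))
            seq = reference.contigs[cid]
            is_snv = rng.random() < p_snv
            if is_snv:
                pos = int(rng.integers(1, len(seq) + 1))
                span = (pos, pos)
                ref = seq[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            else:
                ilen = int(rng.integers(1, config.max_indel_len + 1))
                if rng.random() < 0.5:  # deletion
                    pos = int(rng.integers(1, len(seq) - ilen))
                    ref = seq[pos - 1 : pos + ilen]
                    alt = ref[0]
                    span = (pos, pos + ilen)
                else:  # insertion
                    pos = int(rng.integers(1, len(seq)))
                    ref = seq[pos - 1]
                    alt = ref + "".join(rng.choice(_BASES, size=ilen))
                    span = (pos, pos + 1)  # keep a guard base after the anchor
            spans = occupied.setdefault(cid, [])
            if any(span[0] <= e and span[1] >= s for s, e in spans):
                continue
            hom = rng.random() < config.p_de_novo_hom
            gt = DiploidGenotype.hom(alt) if hom else DiploidGenotype.of(ref, alt)
            evolved[(cid, pos)] = SiteRecord(cid, pos, ref, gt)
            spans.append(span)
            truth.labels.append(TruthLabel(
                contig=cid, pos=pos, ref=ref,
                category="new_variant", zygosity="hom" if hom else "het",
                is_reversion=None, evolved_alleles=gt.alleles,
                variant_kind="snp" if is_snv and len(ref) == 1 else
                             ("snp" if is_snv else "indel"),
            ))
            truth.de_novo.append({
                "contig": cid, "pos": pos, "ref": ref, "alt": alt,
                "zygosity": "hom" if hom else "het",
                "kind": "snv" if is_snv else "indel",
            })
            break
        # silently give up on an event that cannot be placed; the truth set
        # only records what was actually planted


def _draw_cnv_events(rng, reference, config) -> list[CNVEvent]:
    n = rng.poisson(config.n_cnv_events_mean)
    events: list[CNVEvent] = []
    cids = list(reference.contigs)
    for _ in range(n):
        cid = str(rng.choice(cids))
        delta = int(rng.choice(config.cnv_delta_choices, p=config.cnv_delta_probs))
        if rng.random() < config.p_whole_chromosome:
            events.append(CNVEvent(cid, delta, None))
        else:
            clen = reference.length(cid)
            span_len = max(5000, min(int(rng.geometric(1.0 / config.cnv_span_mean)), clen))
            lo = int(rng.integers(1, clen - span_len + 2))
            events.append(CNVEvent(cid, delta, (lo, lo + span_len - 1)))
    return events


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------


def simulate_depth(
    copy_profile: Mapping[str, np.ndarray], mean_depth: float, seed: int
) -> DepthTrack:
    """Per-position depth ~ Poisson(mean_depth * copy / 2), independent per
    position; copy-0 segments have depth identically zero."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    depths = {}
    for cid, copies in copy_profile.items():
        copies = np.asarray(copies)
        if np.any(copies < 0):
            raise ValueError(f"negative copy number on {cid!r}")
        depths[cid] = rng.poisson(mean_depth * copies / 2.0)
    return DepthTrack(depths)


# ---------------------------------------------------------------------------
# full cohort on disk
# ---------------------------------------------------------------------------


def lineage_ids(config: SimulationConfig) -> list[str]:
    return [f"EV{i + 1}" for i in range(config.n_lineages)]


def group_assignment(config: SimulationConfig) -> dict[str, str]:
    groups: dict[str, str] = {}
    ids = lineage_ids(config)
    i = 0
    for name, size in zip(config.group_names, config.group_sizes):
        for _ in range(size):
            groups[ids[i]] = name
            i += 1
    return groups


def generate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int,
    force: bool = False,
) -> dict:
    """Write a complete simulated cohort to ``out_dir`` and return its
    manifest (file list with SHA-256 checksums).

    Layout: ``reference.fa``, ``genes.gff3``, ``classes.tsv``,
    ``parent.vcf``, ``groups.tsv``, per lineage ``<id>.vcf``,
    ``<id>.depth.tsv``, ``<id>.wig`` (true copy numbers), and
    ``truth/<id>.json``; plus ``config.yaml`` and ``MANIFEST.json``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "truth").mkdir(parents=True, exist_ok=True)

    root = np.random.default_rng(seed)
    sub = lambda: int(root.integers(0, 2**31 - 1))  # noqa: E731

    reference, features = make_reference(config, sub())
    parent = make_parent(reference, config.het_density, sub())
    groups = group_assignment(config)

    gio.write_fasta(reference, out / "reference.fa")
    gio.write_gff_cds(features, out / "genes.gff3")
    gio.write_class_manifest(reference.contig_class, out / "classes.tsv")
    gio.write_diploid_vcf(parent, reference, out / "parent.vcf")
    gio.write_groups(groups, out / "groups.tsv")

    for sid in lineage_ids(config):
        table, truth = evolve_lineage(parent, reference, config, sub(), strain_id=sid)
        depth = simulate_depth(truth.copy_profile, config.mean_depth, sub())
        gio.write_diploid_vcf(table, reference, out / f"{sid}.vcf")
        gio.write_depth_tsv(depth, out / f"{sid}.depth.tsv")
        gio.write_wig(
            {c: a.astype(float) for c, a in truth.copy_profile.items()},
            out / f"{sid}.wig",
        )
        with open(out / "truth" / f"{sid}.json", "w") as fh:
            json.dump(truth.to_json(), fh)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    manifest = {"seed": seed, "files": {}}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "MANIFEST.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["files"][str(path.relative_to(out))] = digest
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_truth(path: str | Path) -> TruthSet:
    with open(path) as fh:
        return TruthSet.from_json(json.load(fh))
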