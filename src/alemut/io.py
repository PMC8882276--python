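"""Readers and writers for every on-disk format the pipeline touches.

FASTA via Biopython, VCF via pysam, WIG fixedStep and the small TSV manifests
written directly. All coordinates are 1-based inclusive on disk and in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CDSFeature,
    CONTIG_CLASSES,
    DepthTrack,
    DiploidGenotype,
    GenomeIOError,
    GenotypeTable,
    ReferenceGenome,
    SiteRecord,
    warn,
)

log = logging.getLogger("alemut")


# ---------------------------------------------------------------------------
# FASTA + contig class manifest
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, class_manifest: str | Path | None = None) -> ReferenceGenome:
    """Read a reference FASTA into a :class:`ReferenceGenome`.

    Sequences are upper-cased and record order preserved. Contig classes
    default to ``reference`` unless a two-column TSV manifest
    (contig-id, class) overrides them.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeIOError(f"{path}: duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeIOError(f"{path}: empty record {rec.id!r}")
        contigs[rec.id] = seq
    if not contigs:
        raise GenomeIOError(f"{path}: no FASTA records")
    classes = read_class_manifest(class_manifest) if class_manifest else {}
    unknown = set(classes) - set(contigs)
    if unknown:
        raise GenomeIOError(f"class manifest names unknown contigs: {sorted(unknown)}")
    return ReferenceGenome(contigs=contigs, contig_class=classes)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    """Write contigs in input order, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_class_manifest(path: str | Path) -> dict[str, str]:
    classes: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise GenomeIOError(f"{path}:{lineno}: expected 2 tab-separated columns")
        cid, cls = fields
        if cls not in CONTIG_CLASSES:
            raise GenomeIOError(f"{path}:{lineno}: unknown contig class {cls!r}")
        classes[cid] = cls
    return classes


def write_class_manifest(classes: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, cls in classes.items():
            fh.write(f"{cid}\t{cls}\n")


# ---------------------------------------------------------------------------
# GFF3 CDS features
# ---------------------------------------------------------------------------


def read_gff_cds(path: str | Path, genome: ReferenceGenome) -> list[CDSFeature]:
    """Read CDS rows of a GFF3 file, validated against contig lengths.

    Only ``CDS`` rows are returned; the gene id is taken from the ``ID=`` (or
    ``Parent=``) attribute. A CDS whose length is not a codon multiple is kept
    but flagged (``length_ok=False``) with a warning; a CDS outside its
    contig's bounds is an error.
    """
    features: list[CDSFeature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise GenomeIOError(f"{path}:{lineno}: expected 9 GFF3 columns")
        contig, _source, ftype, start, end, _score, strand, phase, attrs = fields
        if ftype != "CDS":
            continue
        attr_map = _parse_attributes(attrs)
        gene_id = attr_map.get("ID") or attr_map.get("Parent")
        if not gene_id:
            raise GenomeIOError(f"{path}:{lineno}: CDS row without ID/Parent attribute")
        start_i, end_i = int(start), int(end)
        if contig not in genome.contigs:
            raise GenomeIOError(f"{path}:{lineno}: unknown contig {contig!r}")
        if start_i < 1 or end_i > genome.length(contig):
            raise GenomeIOError(
                f"{path}:{lineno}: CDS {gene_id} [{start_i},{end_i}] outside "
                f"contig {contig} (length {genome.length(contig)})"
            )
        length_ok = (end_i - start_i + 1) % 3 == 0
        if not length_ok:
            warn(f"{path}:{lineno}: CDS {gene_id} length not a multiple of 3")
        features.append(
            CDSFeature(
                gene_id=gene_id,
                contig=contig,
                start=start_i,
                end=end_i,
                strand=strand,
                phase=int(phase) if phase not in (".", "") else 0,
                length_ok=length_ok,
            )
        )
    _warn_on_overlaps(features)
    return features


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _warn_on_overlaps(features: Sequence[CDSFeature]) -> None:
    by_contig: dict[str, list[CDSFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    for contig, feats in by_contig.items():
        feats = sorted(feats, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            if b.start <= a.end:
                warn(f"overlapping CDS on {contig}: {a.gene_id} and {b.gene_id}")


def write_gff_cds(features: Iterable[CDSFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\talemut\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t"
                f"{f.phase}\tID={f.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def normalize_record(pos: int, ref: str, alleles: tuple[str, str]) -> tuple[int, str, tuple[str, str]]:
    """Minimal left-normalization of an anchored record.

    Trims the shared suffix of (ref, both alleles), then the shared prefix
    while keeping at least one anchor base, so that equivalent indel
    spellings from different callers compare equal.
    """
    seqs = [ref, *alleles]
    # shared suffix
    while min(len(s) for s in seqs) > 1 and len({s[-1] for s in seqs}) == 1:
        seqs = [s[:-1] for s in seqs]
    # shared prefix, keep one anchor base
    while min(len(s) for s in seqs) > 1 and len({s[0] for s in seqs}) == 1:
        # only strip when every sequence stays non-empty AND at least one still
        # has length > 1 afterwards (otherwise we'd lose the anchor)
        stripped = [s[1:] for s in seqs]
        if min(len(s) for s in stripped) < 1:
            break
        seqs = stripped
        pos += 1
    ref2, a, b = seqs
    return pos, ref2, (a, b)


def read_diploid_vcf(path: str | Path) -> GenotypeTable:
    """Read a single-sample diploid VCF into a :class:`GenotypeTable`.

    Phased separators are accepted and treated as unphased; records with a
    missing genotype (``./.``) are skipped (count logged); multi-allelic
    records collapse to the two called alleles. Non-diploid GT is an error.
    """
    records: list[SiteRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise GenomeIOError(f"{path}: expected exactly one sample, got {samples}")
        strain_id = samples[0]
        for rec in vf:
            gt = rec.samples[0].get("GT")
            if gt is None or all(g is None for g in gt):
                skipped += 1
                continue
            if len(gt) != 2 or any(g is None for g in gt):
                raise GenomeIOError(
                    f"{path}: non-diploid GT {gt} at {rec.chrom}:{rec.pos}"
                )
            alleles = rec.alleles  # (ref, alt1, ...)
            try:
                called = (alleles[gt[0]], alleles[gt[1]])
            except IndexError as exc:
                raise GenomeIOError(
                    f"{path}: GT indexes missing allele at {rec.chrom}:{rec.pos}"
                ) from exc
            pos, ref, called = normalize_record(rec.pos, rec.ref.upper(),
                                                tuple(a.upper() for a in called))
            records.append(
                SiteRecord(rec.chrom, pos, ref, DiploidGenotype(called))
            )
    if skipped:
        log.info("%s: skipped %d records with missing GT", path, skipped)
    return GenotypeTable(strain_id=strain_id, records=records)


def write_diploid_vcf(
    table: GenotypeTable, genome: ReferenceGenome, path: str | Path
) -> None:
    """Write a single-sample uncompressed VCF 4.2 for one strain."""
    header = pysam.VariantHeader()
    for cid, seq in genome.contigs.items():
        header.contigs.add(cid, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(table.strain_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in table:
            alts = sorted({a for a in rec.genotype if a != rec.ref})
            if not alts:
                continue  # hom-ref records are not variable sites
            alleles = [rec.ref, *alts]
            idx = {a: i for i, a in enumerate(alleles)}
            gt = tuple(sorted(idx[a] for a in rec.genotype))
            vrec = out.new_record(
                contig=rec.contig,
                start=rec.pos - 1,
                alleles=alleles,
            )
            vrec.samples[table.strain_id]["GT"] = gt
            vrec.samples[table.strain_id].phased = False
            out.write(vrec)


# ---------------------------------------------------------------------------
# WIG fixedStep
# ---------------------------------------------------------------------------


def write_wig(track: Mapping[str, np.ndarray | Sequence[float]], path: str | Path,
              decimals: int = 4) -> None:
    """Write dense per-position values as fixedStep WIG (step=1, span=1)."""
    if not track:
        raise GenomeIOError("empty track")
    with open(path, "w") as fh:
        for contig, values in track.items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise GenomeIOError(f"empty track for contig {contig!r}")
            if np.any(np.isnan(arr)):
                raise GenomeIOError(f"NaN values in track for contig {contig!r}")
            fh.write(f"fixedStep chrom={contig} start=1 step=1 span=1\n")
            np.savetxt(fh, arr, fmt=f"%.{decimals}f")


def read_wig(path: str | Path) -> dict[str, np.ndarray]:
    """Read the fixedStep dialect written by :func:`write_wig`."""
    track: dict[str, list[float]] = {}
    current: list[float] | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("track"):
            continue
        if line.startswith("fixedStep"):
            kv = dict(part.split("=") for part in line.split()[1:])
            if kv.get("step", "1") != "1" or kv.get("start", "1") != "1":
                raise GenomeIOError(f"{path}:{lineno}: only start=1 step=1 supported")
            current = track.setdefault(kv["chrom"], [])
        else:
            if current is None:
                raise GenomeIOError(f"{path}:{lineno}: value before fixedStep header")
            current.append(float(line))
    if not track:
        raise GenomeIOError(f"{path}: no WIG data")
    return {cid: np.asarray(vals) for cid, vals in track.items()}


# ---------------------------------------------------------------------------
# depth TSV (samtools-depth-like: contig, pos, depth)
# ---------------------------------------------------------------------------


def write_depth_tsv(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, arr in track.depths.items():
            for i, d in enumerate(arr, start=1):
                fh.write(f"{contig}\t{i}\t{int(d)}\n")


def read_depth_tsv(path: str | Path) -> DepthTrack:
    depths: dict[str, list[int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        contig, pos, depth = line.split("\t")
        arr = depths.setdefault(contig, [])
        if int(pos) != len(arr) + 1:
            raise GenomeIOError(f"{path}:{lineno}: positions must be dense from 1")
        arr.append(int(depth))
    if not depths:
        raise GenomeIOError(f"{path}: empty depth file")
    return DepthTrack({cid: np.asarray(v, dtype=np.int64) for cid, v in depths.items()})


# ---------------------------------------------------------------------------
# group manifest (strain -> group)
# ---------------------------------------------------------------------------


def read_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV strain-id -> group name."""
    groups: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise GenomeIOError(f"{path}:{lineno}: expected 2 columns")
        groups[fields[0]] = fields[1]
    return groups


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for strain, group in groups.items():
            fh.write(f"{strain}\t{group}\n")
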