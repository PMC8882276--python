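"""End-to-end pipeline driver: classify -> annotate -> LOH -> CNV -> summarize.

Consumes the on-disk cohort layout written by
:func:`alemut.simulate.generate_cohort` (or equivalent hand-built inputs)
and writes per-strain and cohort-level result tables plus a run manifest
recording the package version, configuration hash and seed, so reruns are
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from . import io as gio
from .classify import classify_strain, write_calls
from .cnv import (
    call_chromosome_events,
    events_to_frame,
    gene_copy_number,
    genes_to_frame,
    normalize_coverage,
)
from .effects import annotate_strain, effects_to_frame
from .loh import segment_loh, segments_to_frame
from .models import GenomeIOError
from .summary import per_strain_counts, shared_mutated_genes, tabulate

log = logging.getLogger("alemut")


@dataclass
class PipelineConfig:
    """Paths and tuning knobs for a full cohort analysis run."""

    fasta: str
    gff: str
    parent_vcf: str
    evolved_vcfs: dict[str, str]  # strain id -> vcf path
    groups: str
    out_dir: str
    classes: str | None = None
    depth_tsvs: dict[str, str] = field(default_factory=dict)

    joint_effects: bool = False
    baseline_ploidy: int = 2
    cnv_window: int | None = None
    loh_max_gap: int = 25_000
    loh_min_sites: int = 3
    min_shared_strains: int = 2
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_cohort_dir(cls, cohort_dir: str | Path, out_dir: str | Path) -> "PipelineConfig":
        """Infer a config from a generate_cohort directory layout."""
        d = Path(cohort_dir)
        vcfs = {
            p.stem: str(p)
            for p in sorted(d.glob("*.vcf"))
            if p.stem != "parent"
        }
        depths = {p.name.removesuffix(".depth.tsv"): str(p)
                  for p in sorted(d.glob("*.depth.tsv"))}
        return cls(
            fasta=str(d / "reference.fa"),
            gff=str(d / "genes.gff3"),
            parent_vcf=str(d / "parent.vcf"),
            evolved_vcfs=vcfs,
            groups=str(d / "groups.tsv"),
            classes=str(d / "classes.tsv") if (d / "classes.tsv").exists() else None,
            depth_tsvs=depths,
            out_dir=str(out_dir),
        )

    def digest(self) -> str:
        # out_dir does not influence results, so reruns into different
        # directories hash identically
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages for every strain; returns the in-memory results.

    Output tree under ``config.out_dir``: per strain ``calls/``, ``effects/``,
    ``segments/``, ``cnv/``; cohort-level ``summary.tsv``,
    ``per_strain.tsv``, ``shared_genes.tsv``; and ``run_manifest.json``.
    Any stage failure aborts with the stage name and strain id.
    """
    out = Path(config.out_dir)
    for sub in ("calls", "effects", "segments", "cnv"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    for path in [config.fasta, config.gff, config.parent_vcf, config.groups,
                 *config.evolved_vcfs.values()]:
        if not Path(path).exists():
            raise GenomeIOError(f"input not found: {path}")

    genome = gio.read_fasta(config.fasta, class_manifest=config.classes)
    features = gio.read_gff_cds(config.gff, genome)
    parent = gio.read_diploid_vcf(config.parent_vcf)
    groups = gio.read_groups(config.groups)
    contig_lengths = {c: genome.length(c) for c in genome.contigs}

    annotated_by_strain = {}
    calls_by_strain = {}
    segments_by_strain = {}
    cnv_by_strain = {}

    for sid, vcf in sorted(config.evolved_vcfs.items()):
        stage = "classify"
        try:
            evolved = gio.read_diploid_vcf(vcf)
            calls = classify_strain(parent, evolved, genome)
            write_calls(calls, out / "calls" / f"{sid}.tsv")

            stage = "annotate"
            annotated = annotate_strain(calls, genome, features,
                                        joint=config.joint_effects)
            effects_to_frame(annotated).to_csv(
                out / "effects" / f"{sid}.tsv", sep="\t", index=False
            )

            stage = "loh"
            segments = segment_loh(
                calls, sid, max_gap=config.loh_max_gap,
                min_sites=config.loh_min_sites, contig_lengths=contig_lengths,
            )
            segments_to_frame(segments).to_csv(
                out / "segments" / f"{sid}.tsv", sep="\t", index=False
            )

            stage = "cnv"
            if sid in config.depth_tsvs:
                depth = gio.read_depth_tsv(config.depth_tsvs[sid])
                profile = normalize_coverage(depth)
                genes = gene_copy_number(profile, features,
                                         baseline_ploidy=config.baseline_ploidy)
                events = call_chromosome_events(genes,
                                                baseline_ploidy=config.baseline_ploidy)
                genes_to_frame(genes).to_csv(
                    out / "cnv" / f"{sid}.genes.tsv", sep="\t", index=False
                )
                events_to_frame(events).to_csv(
                    out / "cnv" / f"{sid}.events.tsv", sep="\t", index=False
                )
                gio.write_wig(profile.values, out / "cnv" / f"{sid}.copynumber.wig")
                cnv_by_strain[sid] = (profile, genes, events)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed for strain {sid!r}: {exc}") from exc

        calls_by_strain[sid] = calls
        annotated_by_strain[sid] = annotated
        segments_by_strain[sid] = segments

    stage = "summarize"
    table = tabulate(annotated_by_strain, groups)
    table.to_csv(out / "summary.tsv", sep="\t")
    strain_counts = per_strain_counts(annotated_by_strain)
    strain_counts.to_csv(out / "per_strain.tsv", sep="\t", index=False)
    shared = shared_mutated_genes(annotated_by_strain,
                                  min_strains=config.min_shared_strains)
    shared.to_csv(out / "shared_genes.tsv", sep="\t", index=False)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump({
            "alemut_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_strains": len(config.evolved_vcfs),
        }, fh, indent=2)

    return {
        "calls": calls_by_strain,
        "annotated": annotated_by_strain,
        "segments": segments_by_strain,
        "cnv": cnv_by_strain,
        "summary": table,
        "per_strain": strain_counts,
        "shared_genes": shared,
    }
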