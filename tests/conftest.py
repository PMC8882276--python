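"""Shared fixtures: a tiny hand-built genome and a full simulated cohort.

The cohort fixture uses the generator's default study conditions (eleven
lineages, three 100-kb contigs, heterozygous sites at 1/300 bp, LOH-dominated
with a Poisson-mean-18 de novo load) and is session-scoped because several
test modules score the same pipeline run against the same truth sets.
"""

from __future__ import annotations

import pytest

from alemut.models import CDSFeature, ReferenceGenome
from alemut.pipeline import PipelineConfig, run_pipeline
from alemut.simulate import SimulationConfig, generate_cohort, load_truth


@pytest.fixture()
def toy_genome() -> ReferenceGenome:
    # chrA carries a clean 4-codon ORF (MHW*) at positions 1-12
    return ReferenceGenome(
        contigs={
            "chrA": "ATGCATTGGTAA" + "ACGTACGTACGTACGTACGT",
            "chrB": "GGCCGGCCGGCC",
        }
    )


@pytest.fixture()
def toy_cds() -> CDSFeature:
    return CDSFeature(gene_id="g1", contig="chrA", start=1, end=12, strand="+")


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(SimulationConfig(), out, seed=20260301)
    return out


@pytest.fixture(scope="session")
def cohort_truth(cohort_dir):
    ids = sorted(p.stem for p in (cohort_dir / "truth").glob("*.json"))
    return {sid: load_truth(cohort_dir / "truth" / f"{sid}.json") for sid in ids}


@pytest.fixture(scope="session")
def pipeline_results(cohort_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig.from_cohort_dir(cohort_dir, out)
    results = run_pipeline(cfg)
    results["out_dir"] = out
    return results
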