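"""Full pipeline on a simulated cohort, with the accounting table.

Runs classify -> annotate -> LOH -> CNV -> summarize on an on-disk cohort
and prints the cohort table (group rows are unions of member strains'
mutation keys, so |overall| = |A| + |B| - |shared|) plus the headline
new-variant fraction in printed-percentage form.
"""

import tempfile
from pathlib import Path

from alemut import PipelineConfig, SimulationConfig, generate_cohort, run_pipeline
from alemut.summary import percent_printed

cfg = SimulationConfig(n_contigs=2, contig_length=50_000, n_cds_per_contig=15,
                       n_loh_tracts=4, tract_length_mean=6_000, n_de_novo=8.0,
                       n_lineages=6, group_sizes=(3, 3))

tmp = Path(tempfile.mkdtemp())
generate_cohort(cfg, tmp / "cohort", seed=2024)
res = run_pipeline(PipelineConfig.from_cohort_dir(tmp / "cohort", tmp / "out"))

print("per-strain counts:")
print(res["per_strain"].to_string(index=False))

t = res["summary"]
print("\ncohort totals (distinct mutation keys):")
print(t["total"].unstack(level="scope").to_string())

new = int(res["per_strain"]["new_variants"].sum())
total = int(res["per_strain"]["total"].sum())
print(f"\nnew variants: {new} of {total} calls "
      f"({percent_printed(new, total, 1)}) — the rest are LOH events, "
      "matching the LOH-dominated spectrum the generator plants.")
print(f"\nrecurrently mutated genes (>=2 strains):")
print(res["shared_genes"].to_string(index=False) if len(res["shared_genes"])
      else "  none in this draw")
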