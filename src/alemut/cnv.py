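"""Read-depth copy-number estimation by median normalization.

Per-position depth d_i is converted to an approximate copy number
c_i = 2 * d_i / m, where m is the sample's genome-wide median depth (over all
positions of all contigs). By construction the genome-wide median of c is
exactly 2 in a mostly-diploid sample; segmental gains and losses show up as
plateaus near integer copies. Gene-level copy numbers are the median of c
over each gene span, rounded half-up, with loss/neutral/gain calls against a
configurable baseline ploidy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import CDSFeature, CopyNumberProfile, DepthTrack, GeneCopyNumber


def normalize_coverage(depth: DepthTrack) -> CopyNumberProfile:
    """Median-normalise a depth track into per-position copy numbers.

    Raises ``ValueError`` on a degenerate track whose median depth is zero.
    """
    stacked = np.concatenate(list(depth.depths.values()))
    m = float(np.median(stacked))
    if m == 0:
        raise ValueError("degenerate depth: genome-wide median is zero")
    values = {cid: 2.0 * arr / m for cid, arr in depth.depths.items()}
    return CopyNumberProfile(values=values, median_depth=m)


def smooth_profile(profile: CopyNumberProfile, window: int = 1000) -> CopyNumberProfile:
    """Replace each non-overlapping ``window``-bp block by its median.

    Smoothing is applied after normalization and is cosmetic (for WIG export
    and plotting); gene-level calls use the unsmoothed profile.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = {}
    for cid, arr in profile.values.items():
        out = arr.copy()
        for lo in range(0, len(arr), window):
            block = arr[lo : lo + window]
            out[lo : lo + window] = np.median(block)
        smoothed[cid] = out
    return CopyNumberProfile(values=smoothed, median_depth=profile.median_depth,
                             genes=list(profile.genes))


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def gene_copy_number(
    profile: CopyNumberProfile,
    features: Sequence[CDSFeature],
    baseline_ploidy: int = 2,
) -> list[GeneCopyNumber]:
    """Median copy number over each gene span, rounded to an integer copy.

    ``call`` is ``loss`` below the baseline ploidy, ``gain`` above it.
    """
    genes: list[GeneCopyNumber] = []
    for f in features:
        if f.contig not in profile.values:
            raise ValueError(f"gene {f.gene_id} on contig {f.contig} missing from profile")
        arr = profile.values[f.contig]
        if f.end > len(arr):
            raise ValueError(f"gene {f.gene_id} extends past the depth track")
        med = float(np.median(arr[f.start - 1 : f.end]))
        copy = max(round_half_up(med), 0)
        call = "neutral" if copy == baseline_ploidy else ("loss" if copy < baseline_ploidy else "gain")
        genes.append(GeneCopyNumber(f.gene_id, f.contig, f.start, f.end, med, copy, call))
    profile.genes = genes
    return genes


@dataclass(frozen=True)
class ChromosomeEvent:
    """An aneuploidy-scale call: a whole contig, or a run of consecutive
    genes, sharing the same gain/loss state."""

    contig: str
    scope: str  # whole | partial
    copy_delta: int
    start: int
    end: int
    n_genes: int


def call_chromosome_events(
    genes: Sequence[GeneCopyNumber],
    min_genes: int = 5,
    whole_fraction: float = 0.8,
    min_run: int = 3,
    baseline_ploidy: int = 2,
) -> list[ChromosomeEvent]:
    """Aggregate per-gene calls into chromosome-scale events.

    A whole-contig event is called when at least ``whole_fraction`` of a
    contig's genes (contigs with >= ``min_genes`` genes) share the same
    non-neutral call; otherwise maximal runs of >= ``min_run`` consecutive
    same-call genes are reported as partial events. Scattered single-gene
    changes below the run length produce no event (the genes remain listed
    individually in the per-gene table).
    """
    by_contig: dict[str, list[GeneCopyNumber]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    events: list[ChromosomeEvent] = []
    for contig, glist in by_contig.items():
        glist = sorted(glist, key=lambda g: g.start)
        if len(glist) < min_genes:
            continue
        for state in ("gain", "loss"):
            matching = [g for g in glist if g.call == state]
            if matching and len(matching) / len(glist) >= whole_fraction:
                delta = _mode_delta(matching, baseline_ploidy)
                events.append(ChromosomeEvent(
                    contig, "whole", delta,
                    glist[0].start, glist[-1].end, len(matching),
                ))
                break
        else:
            events.extend(_partial_runs(contig, glist, min_run, baseline_ploidy))
    return events


def _mode_delta(genes: Sequence[GeneCopyNumber], baseline: int) -> int:
    from collections import Counter

    copies = Counter(g.integer_copy for g in genes)
    return copies.most_common(1)[0][0] - baseline


def _partial_runs(contig, glist, min_run, baseline) -> list[ChromosomeEvent]:
    events = []
    run: list[GeneCopyNumber] = []
    for g in glist + [None]:  # sentinel flushes the last run
        if g is not None and g.call != "neutral" and (not run or g.call == run[-1].call):
            run.append(g)
            continue
        if len(run) >= min_run:
            events.append(ChromosomeEvent(
                contig, "partial", _mode_delta(run, baseline),
                run[0].start, run[-1].end, len(run),
            ))
        run = [g] if g is not None and g.call != "neutral" else []
    return events


def genes_to_frame(genes: Sequence[GeneCopyNumber]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id, "contig": g.contig, "start": g.start,
                "end": g.end, "median_copy": round(g.median_copy, 4),
                "integer_copy": g.integer_copy, "call": g.call,
            }
            for g in genes
        ],
        columns=["gene_id", "contig", "start", "end", "median_copy",
                 "integer_copy", "call"],
    )


def events_to_frame(events: Sequence[ChromosomeEvent]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "contig": e.contig, "scope": e.scope, "copy_delta": e.copy_delta,
                "start": e.start, "end": e.end, "n_genes": e.n_genes,
            }
            for e in events
        ],
        columns=["contig", "scope", "copy_delta", "start", "end", "n_genes"],
    )
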