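"""Clustering LOH calls into chromosomal segments and cross-strain sharing.

Mitotic recombination homozygoses contiguous tracts, so a strain's LOH calls
fall in dense runs along a chromosome rather than being scattered. A single
linear scan joins consecutive LOH calls whose spacing is at most ``max_gap``;
clusters with at least ``min_sites`` supporting calls become segments whose
bounds are the outermost supporting calls. Reversion calls support segments
exactly like other LOH calls — they are part of the same tract even though
the evolved strain's own VCF no longer shows them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .models import LOH, NEW_VARIANT, LOHSegment, MutationCall


def segment_loh(
    calls: Sequence[MutationCall],
    strain_id: str,
    max_gap: int = 25_000,
    min_sites: int = 3,
    contig_lengths: Mapping[str, int] | None = None,
    terminal_margin: int = 10_000,
) -> list[LOHSegment]:
    """Cluster a strain's LOH calls into segments.

    With heterozygous sites every ~300 bp and the default ``max_gap`` of
    25 kb, tracts of ~1 kb and up are detectable whenever they cover
    ``min_sites`` parental heterozygous sites.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    loh_calls = sorted(
        (c for c in calls if c.category == LOH), key=lambda c: (c.contig, c.pos)
    )
    segments: list[LOHSegment] = []
    cluster: list[MutationCall] = []

    def flush() -> None:
        if len(cluster) >= min_sites:
            start, end = cluster[0].pos, cluster[-1].pos
            contig = cluster[0].contig
            n_rev = sum(1 for c in cluster if c.is_reversion)
            terminal = False
            if contig_lengths is not None:
                clen = contig_lengths[contig]
                terminal = start <= terminal_margin or end >= clen - terminal_margin + 1
            segments.append(LOHSegment(
                strain_id=strain_id, contig=contig, start=start, end=end,
                n_sites=len(cluster), reversion_fraction=n_rev / len(cluster),
                terminal=terminal,
            ))

    for call in loh_calls:
        if cluster and (call.contig != cluster[-1].contig
                        or call.pos - cluster[-1].pos > max_gap):
            flush()
            cluster = []
        cluster.append(call)
    if cluster:
        flush()
    return segments


@dataclass(frozen=True)
class SharedSegment:
    """A group of reciprocally overlapping segments from several strains,
    reported with the intersection of the member intervals."""

    contig: str
    start: int
    end: int
    strains: tuple[str, ...]
    members: tuple[LOHSegment, ...]


def shared_segments(
    segments: Sequence[LOHSegment],
    min_reciprocal_overlap: float = 0.5,
) -> list[SharedSegment]:
    """Find LOH segments shared between strains.

    Two segments are linked when their reciprocal overlap (intersection over
    the longer of the two lengths... strictly: min of the two coverage
    fractions) reaches the threshold; connected components with members from
    at least two distinct strains are reported.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    n = len(segments)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if segments[i].reciprocal_overlap(segments[j]) >= min_reciprocal_overlap:
                parent[find(i)] = find(j)

    components: dict[int, list[LOHSegment]] = {}
    for i, seg in enumerate(segments):
        components.setdefault(find(i), []).append(seg)

    shared: list[SharedSegment] = []
    for members in components.values():
        strains = sorted({m.strain_id for m in members})
        if len(strains) < 2:
            continue
        start = max(m.start for m in members)
        end = min(m.end for m in members)
        if start > end:  # chained overlaps with empty common core: use the span
            start = min(m.start for m in members)
            end = max(m.end for m in members)
        shared.append(SharedSegment(
            contig=members[0].contig, start=start, end=end,
            strains=tuple(strains),
            members=tuple(sorted(members, key=lambda m: (m.strain_id, m.start))),
        ))
    shared.sort(key=lambda s: (s.contig, s.start))
    return shared


def flag_hitchhikers(
    calls: Sequence[MutationCall], segments: Sequence[LOHSegment]
) -> dict[tuple[str, int], bool]:
    """Flag new-variant calls located inside the strain's LOH segments.

    A de novo mutation inside an LOH tract may have been co-inherited with
    the tract (a hitchhiker) rather than independently selected; only the
    positional flag is computed here.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        spans.setdefault(s.contig, []).append((s.start, s.end))
    flags: dict[tuple[str, int], bool] = {}
    for c in calls:
        if c.category != NEW_VARIANT:
            continue
        flags[(c.contig, c.pos)] = any(
            lo <= c.pos <= hi for lo, hi in spans.get(c.contig, ())
        )
    return flags


def segments_to_frame(segments: Sequence[LOHSegment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "strain_id": s.strain_id, "contig": s.contig, "start": s.start,
                "end": s.end, "n_sites": s.n_sites,
                "reversion_fraction": round(s.reversion_fraction, 4),
                "terminal": str(s.terminal).lower(),
            }
            for s in segments
        ],
        columns=["strain_id", "contig", "start", "end", "n_sites",
                 "reversion_fraction", "terminal"],
    )


def segments_to_bed(segments: Sequence[LOHSegment], path) -> None:
    """BED export: 0-based half-open, name = strain_id, score = n_sites."""
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda s: (s.contig, s.start)):
            fh.write(f"{s.contig}\t{s.start - 1}\t{s.end}\t{s.strain_id}\t{s.n_sites}\n")
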