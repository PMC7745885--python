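"""Consensus interacting regions across samples.

Significant peaks from each sample are expanded to their
[centre - 2 sigma, centre + 2 sigma] footprints; genomic bases covered
by at least ``min_support`` samples form candidate regions, nearby
regions are merged, and each region records its supporting samples with
their best p-values.  Base-level coverage intersection is robust to
per-sample differences in peak width, unlike centre matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .model import ViewpointFit
from .profile import NormalizedProfile

__all__ = ["SampleResult", "ConsensusRegion", "consensus_regions", "consensus_from_intervals"]

Interval = Tuple[str, float, float, float]  # chrom, start, end, p


@dataclass
class SampleResult:
    """A labelled per-sample fit (e.g. one cell type)."""

    label: str
    fit: ViewpointFit
    profile: NormalizedProfile | None = None

    def intervals(self) -> List[Interval]:
        chrom = self.fit.viewpoint.chrom
        out = []
        for pk in self.fit.peaks:
            if pk.significant:
                s, e = pk.interval
                out.append((chrom, float(s), float(e), float(pk.p_value)))
        return out


@dataclass(frozen=True)
class ConsensusRegion:
    chrom: str
    start: int
    end: int
    support: Tuple[str, ...]
    best_p: Dict[str, float]

    @property
    def n_support(self) -> int:
        return len(self.support)


def _union(intervals: List[Tuple[float, float, float]]) -> List[Tuple[float, float, float]]:
    """Self-union of (start, end, p) keeping the best p of merged pieces."""
    out: List[List[float]] = []
    for s, e, p in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
            out[-1][2] = min(out[-1][2], p)
        else:
            out.append([s, e, p])
    return [tuple(t) for t in out]


def consensus_from_intervals(
    sample_intervals: Dict[str, List[Interval]],
    min_support: int,
    merge_gap: float = 0.0,
) -> List[ConsensusRegion]:
    """Base-level coverage consensus over per-sample significant intervals."""
    labels = list(sample_intervals)
    if len(labels) < 2:
        raise ValueError("consensus needs at least 2 samples")
    if len(set(labels)) != len(labels):
        raise ValueError("sample labels must be unique")
    if min_support > len(labels):
        raise ValueError(f"min_support {min_support} exceeds the {len(labels)} samples")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")

    per_chrom: Dict[str, Dict[str, List[Tuple[float, float, float]]]] = {}
    for label in labels:
        for chrom, s, e, p in sample_intervals[label]:
            per_chrom.setdefault(chrom, {}).setdefault(label, []).append((s, e, p))

    regions: List[ConsensusRegion] = []
    for chrom in sorted(per_chrom):
        by_sample = {lab: _union(iv) for lab, iv in per_chrom[chrom].items()}
        events: List[Tuple[float, int]] = []
        for ivs in by_sample.values():
            for s, e, _ in ivs:
                events.append((s, +1))
                events.append((e, -1))
        events.sort()
        segments: List[Tuple[float, float]] = []
        cov, prev = 0, None
        for pos, delta in events:
            if prev is not None and cov >= min_support and pos > prev:
                segments.append((prev, pos))
            cov += delta
            prev = pos
        # merge segments separated by <= merge_gap
        merged: List[List[float]] = []
        for s, e in segments:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            support: List[str] = []
            best: Dict[str, float] = {}
            for lab, ivs in by_sample.items():
                ps = [p for (a, b, p) in ivs if a < e and b > s]
                if ps:
                    support.append(lab)
                    best[lab] = min(ps)
            regions.append(
                ConsensusRegion(
                    chrom=chrom,
                    start=int(s),
                    end=int(e),
                    support=tuple(sorted(support)),
                    best_p=best,
                )
            )
    return regions


def consensus_regions(
    results: Sequence[SampleResult],
    min_support: int,
    merge_gap: float = 0.0,
) -> List[ConsensusRegion]:
    """Shared interacting regions supported by >= ``min_support`` samples."""
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("sample labels must be unique")
    return consensus_from_intervals(
        {r.label: r.intervals() for r in results}, min_support=min_support, merge_gap=merge_gap
    )
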