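"""Super-enhancer calling: stitch, score, hockey-stick cutoff.

The ROSE-style procedure: constituent enhancers fully contained within
+/- 2 kb of a TSS are removed, the remainder are stitched per chromosome
when the gap between consecutive constituents is at most 12.5 kb, stitched
regions are scored by summed background-subtracted member signal
(density x length), and the hockey-stick cutoff separates SEs from TEs.

The cutoff is the tangency point of a slope-1 line on the rank-vs-signal
curve after both axes are normalized to [0, 1]: with signals sorted
ascending s_0..s_{N-1}, x_i = i/(N-1) and y_i = s_i/max(s), the cutoff
index is argmin_i (y_i - x_i), ties broken toward the largest index
(conservative: flat or linear curves yield zero SEs).  Regions strictly
above the cutoff signal are SEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from seforge.genomics_io import GenomicInterval, ReadAlignmentSet, TssAnnotation
from seforge.signal_quant import (
    DensityConfig,
    _ReadIndex,
    background_subtract,
    extend_reads,
    region_density,
)


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    members: list[GenomicInterval]
    signal: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("StitchedRegion requires at least one member")


@dataclass
class SECallResult:
    """Ranked stitched regions with the hockey-stick cutoff applied.

    ``regions`` are sorted by descending signal; ``is_se[i]`` is True iff
    ``regions[i].signal > cutoff_signal``.  ``cutoff_index`` indexes the
    ascending-sorted signal vector.
    """

    regions: list[StitchedRegion]
    cutoff_index: int
    cutoff_signal: float
    is_se: list[bool]

    @property
    def se_regions(self) -> list[StitchedRegion]:
        return [r for r, flag in zip(self.regions, self.is_se) if flag]

    @property
    def te_regions(self) -> list[StitchedRegion]:
        return [r for r, flag in zip(self.regions, self.is_se) if not flag]


def exclude_tss_proximal(
    constituents: list[GenomicInterval],
    tss: list[TssAnnotation],
    window: int = 2000,
) -> list[GenomicInterval]:
    """Drop constituents fully contained in [tss - window, tss + window]."""
    if window < 0:
        raise ValueError("window must be >= 0")
    if not tss:
        return list(constituents)
    by_chrom: dict[str, list[int]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t.position)
    for positions in by_chrom.values():
        positions.sort()
    kept = []
    for c in constituents:
        positions = by_chrom.get(c.chrom, [])
        # contained iff some TSS has tss - window <= start and end <= tss + window
        i = int(np.searchsorted(positions, c.end - window, side="left"))
        contained = any(
            p - window <= c.start and c.end <= p + window
            for p in positions[i:]
            if p - window <= c.start
        )
        if not contained:
            kept.append(c)
    return kept


def stitch(
    constituents: list[GenomicInterval], max_gap: int = 12500
) -> list[StitchedRegion]:
    """Merge constituents per chromosome when gap <= max_gap (inclusive)."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in constituents:
        by_chrom.setdefault(c.chrom, []).append(c)
    regions: list[StitchedRegion] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        group = [members[0]]
        group_end = members[0].end
        for c in members[1:]:
            if c.start - group_end <= max_gap:
                group.append(c)
                group_end = max(group_end, c.end)
            else:
                regions.append(_make_region(group))
                group = [c]
                group_end = c.end
        regions.append(_make_region(group))
    return regions


def _make_region(members: list[GenomicInterval]) -> StitchedRegion:
    start = members[0].start
    end = max(m.end for m in members)
    interval = GenomicInterval(members[0].chrom, start, end)
    return StitchedRegion(interval=interval, members=list(members), signal=0.0)


def score_regions(
    regions: list[StitchedRegion],
    reads: ReadAlignmentSet,
    control: ReadAlignmentSet | None = None,
    cfg: DensityConfig | None = None,
) -> list[StitchedRegion]:
    """Signal = sum over members of background-subtracted density x length."""
    cfg = cfg if cfg is not None else DensityConfig()
    chip_index = _ReadIndex(extend_reads(reads, cfg))
    ctrl_index = _ReadIndex(extend_reads(control, cfg)) if control is not None else None
    out = []
    for region in regions:
        signal = 0.0
        for member in region.members:
            d = region_density(reads, member, cfg, _index=chip_index)
            if ctrl_index is not None:
                c = region_density(control, member, cfg, _index=ctrl_index)
                d = background_subtract(d, c, cfg)
            signal += d * member.length()
        out.append(StitchedRegion(region.interval, region.members, signal))
    return out


def hockey_stick_cutoff(signals) -> tuple[int, float]:
    """Tangency cutoff on the normalized rank-vs-signal curve.

    Returns (cutoff_index into ascending-sorted signals, cutoff signal).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 2:
        raise ValueError("hockey_stick_cutoff requires at least 2 signals")
    smax = s[-1]
    if smax <= 0:
        raise ValueError("all signals are zero; no cutoff exists")
    x = np.arange(n) / (n - 1)
    y = s / smax
    diff = y - x
    # ties broken by the LARGEST index: scan the reversed array
    cutoff_index = int(n - 1 - np.argmin(diff[::-1]))
    return cutoff_index, float(s[cutoff_index])


def call_superenhancers(
    constituents: list[GenomicInterval],
    tss: list[TssAnnotation],
    reads: ReadAlignmentSet,
    control: ReadAlignmentSet | None = None,
    cfg: DensityConfig | None = None,
    max_gap: int = 12500,
    tss_window: int = 2000,
) -> SECallResult:
    """Full pipeline: TSS exclusion -> stitch -> score -> hockey-stick call."""
    kept = exclude_tss_proximal(constituents, tss, window=tss_window)
    regions = stitch(kept, max_gap=max_gap)
    regions = score_regions(regions, reads, control=control, cfg=cfg)
    signals = [r.signal for r in regions]
    cutoff_index, cutoff_signal = hockey_stick_cutoff(signals)
    regions = sorted(regions, key=lambda r: -r.signal)
    flags = [r.signal > cutoff_signal for r in regions]
    return SECallResult(
        regions=regions,
        cutoff_index=cutoff_index,
        cutoff_signal=cutoff_signal,
        is_se=flags,
    )
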