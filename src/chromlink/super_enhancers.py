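"""ROSE-style super-enhancer calling: stitch, rank, elbow cutoff,
multi-set consensus, condition diff, and tissue-specificity counting.

A super-enhancer (SE) is a stitched cluster of cis-regulatory elements
with disproportionately high H3K27ac signal — the points above the
slope-1 tangent of the 0-1-scaled rank/signal "hockey stick".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    GenomicInterval,
    IntervalIndex,
    PeakSet,
    merge_intervals,
    overlap_length,
    sort_intervals,
)
from .peaks import DiffPeaks, consensus_peaks, diff_peaks

__all__ = [
    "StitchedRegion",
    "stitch_and_rank",
    "se_cutoff",
    "se_consensus",
    "se_diff",
    "se_tissue_specificity",
    "call_super_enhancers",
]

DEFAULT_STITCH_GAP = 12_500
DEFAULT_TSS_EXCLUSION = 2_500


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    constituent_count: int
    signal: float
    rank: int = 0  # ascending by signal, 1-based
    is_super: bool = False


def stitch_and_rank(
    cres: Sequence[GenomicInterval],
    h3k27ac_peaks: Sequence[GenomicInterval],
    stitch_gap: int = DEFAULT_STITCH_GAP,
    tss_exclusion: Sequence[GenomicInterval] = (),
) -> list[StitchedRegion]:
    """Stitch CREs within ``stitch_gap`` bp and score by H3K27ac signal.

    Constituents lying fully inside a TSS-exclusion window are dropped
    before stitching.  Region signal is the sum of overlapping peak
    signals, each prorated by the fraction of the peak inside the
    region; regions are ranked ascending by signal (rank 1 = weakest).
    """
    if stitch_gap < 0:
        raise ValueError("stitch_gap must be >= 0")
    for p in h3k27ac_peaks:
        if p.score is not None and p.score < 0:
            raise ValueError(f"negative peak signal at {p}")
    excl = IntervalIndex(tss_exclusion)
    kept = [
        cre
        for cre in sort_intervals(cres)
        if not any(
            w.start <= cre.start and cre.end <= w.end for w in excl.overlapping(cre)
        )
    ]
    stitched = merge_intervals(kept, gap=stitch_gap)
    kept_idx = IntervalIndex(kept)
    peak_idx = IntervalIndex(h3k27ac_peaks)
    regions = []
    for region in stitched:
        n_members = len(kept_idx.overlapping(region))
        signal = 0.0
        for peak in peak_idx.overlapping(region):
            frac = overlap_length(peak, region) / len(peak)
            signal += (peak.score or 0.0) * frac
        regions.append(StitchedRegion(region, n_members, signal))
    regions.sort(key=lambda r: (r.signal, r.interval.chrom, r.interval.start))
    for i, r in enumerate(regions, start=1):
        r.rank = i
    return regions


def se_cutoff(
    signals: Sequence[float], tol: float = 1e-9
) -> tuple[int, np.ndarray]:
    """Rank-curve elbow: the slope-1 tangent point of the scaled curve.

    ``signals`` must be sorted ascending.  Rank and signal are each
    scaled to [0, 1]; the cutoff index i* maximizes x_i - y_i (ties
    broken toward the larger index, i.e. fewer SEs); regions with
    signal strictly greater than signals[i*] are super.  A constant or
    perfectly linear curve (max gap <= ``tol``) yields zero SEs.
    """
    y = np.asarray(signals, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("insufficient regions: se_cutoff needs >= 3")
    if np.any(np.diff(y) < 0):
        raise ValueError("signals must be sorted ascending")
    span = y[-1] - y[0]
    if span == 0:
        warnings.warn("constant signal vector: no super-enhancers called")
        return n - 1, np.zeros(n, dtype=bool)
    x = np.arange(n) / (n - 1)
    ys = (y - y[0]) / span
    gap = x - ys
    if gap.max() <= tol:
        warnings.warn("degenerate (linear) rank curve: no super-enhancers called")
        return n - 1, np.zeros(n, dtype=bool)
    # argmax with ties toward the larger index
    cutoff = int(n - 1 - np.argmax(gap[::-1]))
    flags = y > y[cutoff]
    return cutoff, flags


def call_super_enhancers(
    cres: Sequence[GenomicInterval],
    h3k27ac_peaks: Sequence[GenomicInterval],
    stitch_gap: int = DEFAULT_STITCH_GAP,
    tss_exclusion: Sequence[GenomicInterval] = (),
) -> list[StitchedRegion]:
    """stitch_and_rank + se_cutoff; returns regions with is_super set."""
    regions = stitch_and_rank(cres, h3k27ac_peaks, stitch_gap, tss_exclusion)
    if len(regions) < 3:
        return regions
    _, flags = se_cutoff([r.signal for r in regions])
    for r, f in zip(regions, flags):
        r.is_super = bool(f)
    return regions


def se_consensus(
    se_sets: Sequence[Sequence[GenomicInterval]], k: int
) -> list[GenomicInterval]:
    """k-of-n consensus over SE interval sets (merge-then-count, the
    same semantics as replicate peak consensus)."""
    if not se_sets:
        raise ValueError("se_consensus: empty input")
    peak_sets = [
        PeakSet(mark="H3K27ac", condition="se", replicate=str(i), intervals=list(s))
        for i, s in enumerate(se_sets)
    ]
    return consensus_peaks(peak_sets, k)


def se_diff(
    control: Sequence[GenomicInterval], treated: Sequence[GenomicInterval]
) -> DiffPeaks:
    """Gained / lost / stable SEs by >=1 bp overlap between conditions."""
    return diff_peaks(control, treated, mark="SE")


def se_tissue_specificity(
    tm_ses: Sequence[GenomicInterval],
    catalog: Mapping[str, Sequence[GenomicInterval]],
    min_coverage: float = 0.7,
    stack: bool = False,
) -> list[dict]:
    """Count external-catalog samples whose SEs cover each query SE.

    A catalog sample counts for a query SE iff any *single* SE of that
    sample covers >= ``min_coverage`` of the query SE's length; with
    ``stack=True`` the covered bases of all the sample's SEs are
    combined instead.  Returns one record per query SE with the sample
    count and fraction of the catalog.
    """
    if not catalog:
        raise ValueError("se_tissue_specificity: empty catalog")
    indexes = {sample: IntervalIndex(ses) for sample, ses in catalog.items()}
    n_samples = len(catalog)
    out = []
    for se in sort_intervals(tm_ses):
        need = min_coverage * len(se)
        count = 0
        for idx in indexes.values():
            hits = idx.overlapping(se)
            if stack:
                covered = merge_intervals(
                    [
                        GenomicInterval(
                            se.chrom,
                            max(h.start, se.start),
                            min(h.end, se.end),
                        )
                        for h in hits
                        if overlap_length(h, se) > 0
                    ]
                )
                if sum(len(c) for c in covered) >= need:
                    count += 1
            elif any(overlap_length(se, cat) >= need for cat in hits):
                count += 1
        out.append(
            {
                "se": se,
                "n_samples": count,
                "fraction": count / n_samples,
            }
        )
    return out
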