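"""Enhancer-RNA candidate derivation and expression-based retention.

Candidate eRNA loci are merged enhancer regions that avoid gene bodies,
TSS neighbourhoods, and H3K4me3 (promoter-mark) peaks; candidates are
retained as expressed when their CPM exceeds a threshold in enough
samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    interval_gap,
    merge_intervals,
)

__all__ = ["ErnaCandidate", "call_erna_candidates", "cpm", "filter_expressed"]


@dataclass
class ErnaCandidate:
    interval: GenomicInterval
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)
    expressed: bool = False

    @property
    def passed_all(self) -> bool:
        return all(ok for _, ok in self.filter_trace)


def _min_distance(region: GenomicInterval, idx: IntervalIndex, probe: int) -> float:
    """Edge-to-edge distance from ``region`` to the nearest indexed
    interval on the same chromosome (0 if overlapping), searching
    within ``probe`` bp; inf when nothing is near."""
    query = GenomicInterval(
        region.chrom, max(0, region.start - probe), region.end + probe
    )
    best = float("inf")
    for iv in idx.overlapping(query):
        gap = interval_gap(region, iv)
        if gap is not None:
            best = min(best, gap)
    return best


def call_erna_candidates(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    h3k4me3_peaks: Sequence[GenomicInterval],
    merge_gap: int = 50,
    exclusion_radius: int = 3000,
) -> list[ErnaCandidate]:
    """Geometric filter cascade for putative eRNA loci.

    1. merge enhancer regions with gaps <= ``merge_gap``;
    2. drop regions overlapping any gene body (>= 1 bp);
    3. drop regions whose edge distance to the nearest TSS is
       < ``exclusion_radius`` (strict; overlap counts as distance 0);
    4. the same distance rule against H3K4me3 peaks.

    The filters are conjunctive, so the outcome is order-independent;
    ``filter_trace`` records every test for audit.
    """
    merged = merge_intervals(enhancers, gap=merge_gap)
    body_idx = IntervalIndex([g.body for g in genes])
    tss_idx = IntervalIndex(
        [GenomicInterval(g.chrom, g.tss, g.tss + 1) for g in genes]
    )
    k4me3_idx = IntervalIndex(h3k4me3_peaks)
    out = []
    for region in merged:
        no_body = not body_idx.any_overlap(region)
        tss_far = _min_distance(region, tss_idx, exclusion_radius) >= exclusion_radius
        k4_far = (
            _min_distance(region, k4me3_idx, exclusion_radius) >= exclusion_radius
        )
        out.append(
            ErnaCandidate(
                region,
                filter_trace=[
                    ("gene_body_overlap", no_body),
                    ("tss_distance", tss_far),
                    ("h3k4me3_distance", k4_far),
                ],
            )
        )
    return out


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled to sum to 1e6."""
    libsizes = counts.sum(axis=0)
    if (libsizes <= 0).any():
        bad = list(libsizes.index[libsizes <= 0])
        raise ValueError(f"zero library size in sample(s): {bad}")
    return counts / libsizes * 1e6


def filter_expressed(
    candidates: Sequence[ErnaCandidate],
    erna_counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 2,
) -> list[ErnaCandidate]:
    """Retain surviving candidates with CPM strictly > ``min_cpm`` in
    >= ``min_samples`` samples; returns the expressed subset."""
    mat = cpm(erna_counts)
    survivors = [c for c in candidates if c.passed_all]
    missing = [
        c.interval.name
        for c in survivors
        if (c.interval.name or "") not in mat.index
    ]
    if missing:
        raise KeyError(f"candidates missing from count matrix: {missing}")
    expressed = []
    for c in survivors:
        row = mat.loc[c.interval.name]
        c.expressed = int((row > min_cpm).sum()) >= min_samples
        if c.expressed:
            expressed.append(c)
    return expressed
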