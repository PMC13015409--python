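"""Replicate-consensus peaks, condition-level gain/loss, and
activating/repressive epigenetic-change classification near genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    PeakSet,
    merge_intervals,
    sort_intervals,
)

__all__ = [
    "DiffPeaks",
    "EpigeneticChangeSummary",
    "consensus_peaks",
    "diff_peaks",
    "classify_epigenetic_changes",
]


@dataclass
class DiffPeaks:
    """Condition-level peak changes: treated-only (gained), control-only
    (lost), and shared (stable) consensus peaks for one mark."""

    mark: str
    gained: list[GenomicInterval] = field(default_factory=list)
    lost: list[GenomicInterval] = field(default_factory=list)
    stable: list[GenomicInterval] = field(default_factory=list)


@dataclass(frozen=True)
class EpigeneticChangeSummary:
    gene_id: str
    distance_bin: str
    n_activating: int
    n_repressive: int


def consensus_peaks(
    replicate_sets: Sequence[PeakSet], k: int
) -> list[GenomicInterval]:
    """Merge-then-count replicate consensus.

    Candidate regions are the union-merge of all replicate peaks; a
    region is retained iff >= k replicates have any peak overlapping it
    by >= 1 bp.  Retained regions carry their support count in
    ``score``.
    """
    if not replicate_sets:
        raise ValueError("consensus_peaks: empty replicate list")
    n = len(replicate_sets)
    if not 1 <= k <= n:
        raise ValueError(f"consensus_peaks: need 1 <= k <= {n}, got k={k}")
    marks = {ps.mark for ps in replicate_sets}
    conds = {ps.condition for ps in replicate_sets}
    if len(marks) > 1 or len(conds) > 1:
        raise ValueError(
            f"consensus_peaks: mixed mark/condition inputs ({marks}, {conds})"
        )
    all_peaks = [iv for ps in replicate_sets for iv in ps.intervals]
    candidates = merge_intervals(all_peaks, gap=-1)  # strict overlap merge only
    indexes = [IntervalIndex(ps.intervals) for ps in replicate_sets]
    retained = []
    for region in candidates:
        support = sum(1 for idx in indexes if idx.any_overlap(region))
        if support >= k:
            retained.append(region.with_score(float(support)))
    return retained


def diff_peaks(
    control: Iterable[GenomicInterval],
    treated: Iterable[GenomicInterval],
    mark: str = "",
    reciprocal: float = 0.0,
) -> DiffPeaks:
    """Label consensus peaks stable / lost / gained by >=1 bp overlap.

    A control peak overlapping any treated peak is stable (and vice
    versa); control-only peaks are lost, treated-only gained.  Each
    input peak receives exactly one label.  ``reciprocal`` > 0 requires
    the shared bases to cover that fraction of *both* peaks (off by
    default: any-overlap, the convention this pipeline mirrors).
    """
    from .core import overlap_length

    control = sort_intervals(control)
    treated = sort_intervals(treated)
    t_idx = IntervalIndex(treated)
    c_idx = IntervalIndex(control)

    def hit(iv: GenomicInterval, idx: IntervalIndex) -> bool:
        if reciprocal <= 0:
            return idx.any_overlap(iv)
        return any(
            overlap_length(iv, other) >= reciprocal * max(len(iv), len(other))
            for other in idx.overlapping(iv)
        )

    out = DiffPeaks(mark=mark)
    for iv in control:
        (out.stable if hit(iv, t_idx) else out.lost).append(iv)
    for iv in treated:
        (out.stable if hit(iv, c_idx) else out.gained).append(iv)
    out.stable = sort_intervals(out.stable)
    return out


def _peak_to_tss_distance(peak: GenomicInterval, tss: int) -> int:
    midpoint = (peak.start + peak.end) // 2
    return abs(midpoint - tss)


def classify_epigenetic_changes(
    diff_h3k27ac: DiffPeaks,
    diff_h3k27me3: DiffPeaks,
    genes: Sequence[GeneModel],
    de_table: pd.DataFrame,
    bins: Sequence[int] = (10_000, 100_000, 1_000_000),
) -> list[EpigeneticChangeSummary]:
    """Count activating / repressive epigenetic events per DE gene by
    TSS distance bin.

    Activating events: gained H3K27ac or lost H3K27me3 peaks.
    Repressive events: gained H3K27me3 or lost H3K27ac peaks.  An event
    is assigned to the distance bin of its peak-midpoint-to-TSS
    distance; peaks beyond the last cutoff are ignored.
    """
    if list(bins) != sorted(set(bins)):
        raise ValueError("bins must be strictly increasing")
    gene_by_id = {g.gene_id: g for g in genes}
    de_genes = list(de_table["gene_id"])
    missing = [g for g in de_genes if g not in gene_by_id]
    if missing:
        raise KeyError(f"DE genes absent from gene models: {missing}")

    activating = list(diff_h3k27ac.gained) + list(diff_h3k27me3.lost)
    repressive = list(diff_h3k27me3.gained) + list(diff_h3k27ac.lost)

    labels = _bin_labels(bins)
    out = []
    for gid in de_genes:
        g = gene_by_id[gid]
        counts = {lab: [0, 0] for lab in labels}
        for kind, peaks in (("act", activating), ("rep", repressive)):
            for peak in peaks:
                if peak.chrom != g.chrom:
                    continue
                d = _peak_to_tss_distance(peak, g.tss)
                lab = _bin_of(d, bins, labels)
                if lab is None:
                    continue
                counts[lab][0 if kind == "act" else 1] += 1
        for lab in labels:
            n_act, n_rep = counts[lab]
            out.append(EpigeneticChangeSummary(gid, lab, n_act, n_rep))
    return out


def _bin_labels(bins: Sequence[int]) -> list[str]:
    labels = [f"<={bins[0]}"]
    for lo, hi in zip(bins, bins[1:]):
        labels.append(f"{lo}-{hi}")
    return labels


def _bin_of(distance: int, bins: Sequence[int], labels: Sequence[str]):
    for cutoff, lab in zip(bins, labels):
        if distance <= cutoff:
            return lab
    return None
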