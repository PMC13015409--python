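"""Promoter-loop topology: consensus across samples, two-anchor
differential classification, anchor annotation, cross-tissue sharing,
and loop-change gene ranking.

Two loops "match" when both anchor pairs overlap, in either pairing —
the two-anchor overlap rule used throughout for loop identity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    Loop,
    sort_intervals,
)

__all__ = [
    "LoopDiff",
    "AnchorAnnotation",
    "loops_match",
    "loop_consensus",
    "loop_diff",
    "annotate_anchors",
    "cross_tissue_sharing",
    "top_loop_change_genes",
]


@dataclass
class LoopDiff:
    stable: list[Loop] = field(default_factory=list)
    gained: list[Loop] = field(default_factory=list)
    lost: list[Loop] = field(default_factory=list)


@dataclass
class AnchorAnnotation:
    loop: Loop
    anchor1_features: set[str] = field(default_factory=set)
    anchor2_features: set[str] = field(default_factory=set)

    @property
    def ctcf_feet(self) -> int:
        return int("CTCF" in self.anchor1_features) + int(
            "CTCF" in self.anchor2_features
        )

    def promoter_genes(self) -> set[str]:
        """gene_ids carried by promoter labels on either anchor."""
        return {
            lab.split(":", 1)[1]
            for feats in (self.anchor1_features, self.anchor2_features)
            for lab in feats
            if lab.startswith("promoter:")
        }


def _pad(iv: GenomicInterval, padding: int) -> GenomicInterval:
    if padding <= 0:
        return iv
    return GenomicInterval(iv.chrom, max(0, iv.start - padding), iv.end + padding)


def loops_match(a: Loop, b: Loop, padding: int = 0) -> bool:
    """Two-anchor overlap in either anchor pairing (>=1 bp, optional
    symmetric padding)."""
    a1, a2 = _pad(a.anchor1, padding), _pad(a.anchor2, padding)
    b1, b2 = _pad(b.anchor1, padding), _pad(b.anchor2, padding)
    return (a1.overlaps(b1) and a2.overlaps(b2)) or (
        a1.overlaps(b2) and a2.overlaps(b1)
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _cluster_loops(loops: Sequence[Loop], padding: int = 0) -> list[list[Loop]]:
    """Single-linkage clusters under transitive loops_match."""
    n = len(loops)
    uf = _UnionFind(n)
    # bucket by chromosome pair, sort by anchor1 start, sweep
    buckets: dict[tuple[str, str], list[int]] = {}
    for i, lp in enumerate(loops):
        buckets.setdefault((lp.anchor1.chrom, lp.anchor2.chrom), []).append(i)
    for idxs in buckets.values():
        idxs.sort(key=lambda i: loops[i].anchor1.start)
        for ai in range(len(idxs)):
            i = idxs[ai]
            for aj in range(ai + 1, len(idxs)):
                j = idxs[aj]
                if (
                    loops[j].anchor1.start - padding
                    >= loops[i].anchor1.end + padding
                ):
                    break
                if loops_match(loops[i], loops[j], padding):
                    uf.union(i, j)
    clusters: dict[int, list[Loop]] = {}
    for i, lp in enumerate(loops):
        clusters.setdefault(uf.find(i), []).append(lp)
    return list(clusters.values())


def _cluster_representative(cluster: Sequence[Loop]) -> Loop:
    """Anchor-wise union span; sample set = union of member samples."""
    a1c = cluster[0].anchor1.chrom
    a2c = cluster[0].anchor2.chrom
    a1 = GenomicInterval(
        a1c,
        min(lp.anchor1.start for lp in cluster),
        max(lp.anchor1.end for lp in cluster),
    )
    a2 = GenomicInterval(
        a2c,
        min(lp.anchor2.start for lp in cluster),
        max(lp.anchor2.end for lp in cluster),
    )
    samples = frozenset().union(*(lp.samples for lp in cluster))
    scores = [lp.score for lp in cluster if lp.score is not None]
    score = float(np.mean(scores)) if scores else None
    return Loop.canonical(a1, a2, score=score, samples=samples)


def loop_consensus(
    sample_loops: Mapping[str, Sequence[Loop]], k: int = 2, padding: int = 0
) -> list[Loop]:
    """Loops supported by >= k distinct samples.

    Loops are clustered by transitive two-anchor matching; a cluster is
    retained iff it contains loops from >= k samples, represented by
    the anchor-wise union span with the supporting sample set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tagged = [
        Loop.canonical(lp.anchor1, lp.anchor2, lp.score, samples={sample})
        for sample, lps in sample_loops.items()
        for lp in lps
    ]
    out = []
    for cluster in _cluster_loops(tagged, padding):
        rep = _cluster_representative(cluster)
        if len(rep.samples) >= k:
            out.append(rep)
    out.sort(key=lambda lp: lp.key)
    return out


def loop_diff(
    control_loops: Sequence[Loop],
    treated_loops: Sequence[Loop],
    padding: int = 0,
) -> LoopDiff:
    """Label consensus loops stable / lost / gained by two-anchor
    matching between conditions; stable records both representatives."""
    out = LoopDiff()
    matched_treated: set[int] = set()
    for c in control_loops:
        hit = False
        for j, t in enumerate(treated_loops):
            if loops_match(c, t, padding):
                hit = True
                matched_treated.add(j)
        (out.stable if hit else out.lost).append(c)
    for j, t in enumerate(treated_loops):
        if j in matched_treated:
            out.stable.append(t)
        else:
            out.gained.append(t)
    return out


def annotate_anchors(
    loops: Sequence[Loop],
    genes: Sequence[GeneModel] = (),
    cres_by_class: Mapping[str, Sequence[GenomicInterval]] | None = None,
    ctcf_peaks: Sequence[GenomicInterval] = (),
    variants: Sequence = (),
) -> list[AnchorAnnotation]:
    """Label each anchor with every overlapping feature (>=1 bp).

    Labels: ``promoter:<gene_id>``, ``enhancer``, ``repressor``,
    ``super_enhancer``, ``CTCF``, ``variant:<rsid>``.
    """
    cres_by_class = cres_by_class or {}
    promoter_idx = IntervalIndex(
        [
            GenomicInterval(
                g.promoter.chrom, g.promoter.start, g.promoter.end, name=g.gene_id
            )
            for g in genes
        ]
    )
    class_idx = {
        cls: IntervalIndex(ivs) for cls, ivs in cres_by_class.items()
    }
    ctcf_idx = IntervalIndex(ctcf_peaks)
    var_idx = IntervalIndex([v.interval for v in variants])

    def features(anchor: GenomicInterval) -> set[str]:
        labs = {
            f"promoter:{iv.name}" for iv in promoter_idx.overlapping(anchor)
        }
        for cls, idx in class_idx.items():
            if idx.any_overlap(anchor):
                labs.add(cls)
        if ctcf_idx.any_overlap(anchor):
            labs.add("CTCF")
        labs |= {f"variant:{iv.name}" for iv in var_idx.overlapping(anchor)}
        return labs

    return [
        AnchorAnnotation(lp, features(lp.anchor1), features(lp.anchor2))
        for lp in loops
    ]


def cross_tissue_sharing(
    tm_loops: Sequence[Loop],
    tissue_catalogs: Mapping[str, Sequence[Loop]],
    padding: int = 0,
) -> list[dict]:
    """Per-loop count of external tissues with a matching loop."""
    out = []
    for lp in tm_loops:
        tissues = {
            tissue
            for tissue, cat in tissue_catalogs.items()
            if any(loops_match(lp, other, padding) for other in cat)
        }
        out.append({"loop": lp, "n_tissues": len(tissues), "tissues": tissues})
    return out


def top_loop_change_genes(
    diff: LoopDiff,
    annotations: Sequence[AnchorAnnotation],
    quantile: float = 0.05,
) -> set[str]:
    """Genes with the greatest number of loop changes (top ``quantile``).

    Per gene, the change count is the number of gained + lost loops
    carrying that gene's promoter label on either anchor.  Returns
    genes whose count reaches the (1 - quantile) quantile of the
    positive-count distribution; threshold ties are all included.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    changed_keys = {lp.key for lp in diff.gained} | {lp.key for lp in diff.lost}
    counts: dict[str, int] = {}
    for ann in annotations:
        if ann.loop.key not in changed_keys:
            continue
        for gid in ann.promoter_genes():
            counts[gid] = counts.get(gid, 0) + 1
    if not counts:
        return set()
    values = np.array(list(counts.values()), dtype=float)
    threshold = float(np.quantile(values, 1 - quantile))
    return {gid for gid, c in counts.items() if c >= threshold}
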