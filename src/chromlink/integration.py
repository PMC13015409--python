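"""Multi-level integration: regulatory-change calls per gene, the 16
gene sets, hypergeometric over-representation with Benjamini–Hochberg
correction, and the term × set intersection matrix.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomicInterval, IntervalIndex
from .loops import AnchorAnnotation, LoopDiff
from .peaks import DiffPeaks

__all__ = [
    "RegulatoryChangeCall",
    "EnrichmentResult",
    "classify_regulatory_change",
    "build_gene_sets",
    "hypergeom_ora",
    "term_set_matrix",
]


@dataclass(frozen=True)
class RegulatoryChangeCall:
    gene_id: str
    gained_enhancer_loops: int
    lost_enhancer_loops: int
    gained_repressor_loops: int
    lost_repressor_loops: int

    @property
    def call(self) -> str:
        activating = self.gained_enhancer_loops + self.lost_repressor_loops
        repressive = self.lost_enhancer_loops + self.gained_repressor_loops
        if activating > 0 and repressive == 0:
            return "activating"
        if repressive > 0 and activating == 0:
            return "repressive"
        if activating > 0 and repressive > 0:
            return "mixed"
        return "none"


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    set_name: str
    k: int  # hits
    n: int  # query set size in universe
    K: int  # term size in universe
    N: int  # universe size
    p_value: float
    fdr: float = 1.0


def _count_gene_loops(
    gene_id: str,
    loops: Sequence,
    ann_by_key: Mapping[tuple, AnchorAnnotation],
    other_label: str,
) -> int:
    """Loops where one anchor carries the gene's promoter label and the
    other anchor carries ``other_label``."""
    want = f"promoter:{gene_id}"
    n = 0
    for lp in loops:
        ann = ann_by_key.get(lp.key)
        if ann is None:
            continue
        if (want in ann.anchor1_features and other_label in ann.anchor2_features) or (
            want in ann.anchor2_features and other_label in ann.anchor1_features
        ):
            n += 1
    return n


def classify_regulatory_change(
    gene_id: str,
    diff: LoopDiff,
    annotations: Sequence[AnchorAnnotation],
) -> RegulatoryChangeCall:
    """Activating / repressive / mixed call from promoter-loop changes.

    Activating evidence: gained promoter–enhancer loops and lost
    promoter–repressor loops; repressive is the mirror.
    """
    ann_by_key = {ann.loop.key: ann for ann in annotations}
    return RegulatoryChangeCall(
        gene_id=gene_id,
        gained_enhancer_loops=_count_gene_loops(
            gene_id, diff.gained, ann_by_key, "enhancer"
        ),
        lost_enhancer_loops=_count_gene_loops(
            gene_id, diff.lost, ann_by_key, "enhancer"
        ),
        gained_repressor_loops=_count_gene_loops(
            gene_id, diff.gained, ann_by_key, "repressor"
        ),
        lost_repressor_loops=_count_gene_loops(
            gene_id, diff.lost, ann_by_key, "repressor"
        ),
    )


GENE_SET_NAMES = (
    "de_genes",
    "compartment_shift",
    "atac_change",
    "se_change",
    "cre_change",
    "enhancer_switch",
    "H3K27ac_change",
    "H3K27me3_change",
    "H3K4me1_change",
    "H3K4me3_change",
    "H3K36me3_change",
    "CTCF_change",
    "top_loop_change",
    "promoter_enhancer_loops",
    "promoter_repressor_loops",
    "promoter_se_loops",
)


def _genes_overlapping(
    features: Iterable[GenomicInterval], genes: Sequence[GeneModel]
) -> set[str]:
    """Genes whose body or promoter overlaps any feature by >= 1 bp."""
    spans = []
    for g in genes:
        spans.append(
            GenomicInterval(g.chrom, g.body.start, g.body.end, name=g.gene_id)
        )
        spans.append(
            GenomicInterval(
                g.promoter.chrom, g.promoter.start, g.promoter.end, name=g.gene_id
            )
        )
    idx = IntervalIndex(spans)
    hit = set()
    for f in features:
        hit.update(iv.name for iv in idx.overlapping(f))
    return hit


def _loop_genes_with_label(
    loops: Sequence, ann_by_key: Mapping[tuple, AnchorAnnotation], label: str
) -> set[str]:
    out = set()
    for lp in loops:
        ann = ann_by_key.get(lp.key)
        if ann is None:
            continue
        for a_feats, b_feats in (
            (ann.anchor1_features, ann.anchor2_features),
            (ann.anchor2_features, ann.anchor1_features),
        ):
            if label in b_feats:
                out.update(
                    f.split(":", 1)[1]
                    for f in a_feats
                    if f.startswith("promoter:")
                )
    return out


def build_gene_sets(
    genes: Sequence[GeneModel],
    de_table: pd.DataFrame,
    shifted_windows: Sequence,
    diff_atac: DiffPeaks,
    diff_se: DiffPeaks,
    diff_cre: DiffPeaks,
    enhancer_elements: Sequence,
    diff_by_mark: Mapping[str, DiffPeaks],
    loop_diff: LoopDiff,
    annotations: Sequence[AnchorAnnotation],
    top_loop_genes: set[str],
) -> dict[str, set[str]]:
    """Assemble the 16 gene sets tested for pathway enrichment.

    Gene–feature overlap is feature vs (gene body ∪ promoter), >= 1 bp.
    Membership is non-exclusive: a gene may appear in many sets.
    """
    required_marks = (
        "H3K27ac",
        "H3K27me3",
        "H3K4me1",
        "H3K4me3",
        "H3K36me3",
        "CTCF",
    )
    missing = [m for m in required_marks if m not in diff_by_mark]
    if missing:
        raise KeyError(
            f"build_gene_sets: missing diff peaks for mark(s) {missing} "
            f"(blocks the per-mark change sets)"
        )
    ann_by_key = {ann.loop.key: ann for ann in annotations}
    changed_loops = list(loop_diff.gained) + list(loop_diff.lost)

    sets: dict[str, set[str]] = {}
    sets["de_genes"] = set(de_table["gene_id"])
    sets["compartment_shift"] = _genes_overlapping(
        [w.interval for w in shifted_windows if w.shift != "none"], genes
    )
    sets["atac_change"] = _genes_overlapping(
        list(diff_atac.gained) + list(diff_atac.lost), genes
    )
    sets["se_change"] = _genes_overlapping(
        list(diff_se.gained) + list(diff_se.lost), genes
    )
    sets["cre_change"] = _genes_overlapping(
        list(diff_cre.gained) + list(diff_cre.lost), genes
    )
    sets["enhancer_switch"] = _genes_overlapping(
        [
            e.interval
            for e in enhancer_elements
            if e.switch in ("activated", "deactivated")
        ],
        genes,
    )
    for mark in required_marks:
        d = diff_by_mark[mark]
        sets[f"{mark}_change"] = _genes_overlapping(
            list(d.gained) + list(d.lost), genes
        )
    sets["top_loop_change"] = set(top_loop_genes)
    sets["promoter_enhancer_loops"] = _loop_genes_with_label(
        changed_loops, ann_by_key, "enhancer"
    )
    sets["promoter_repressor_loops"] = _loop_genes_with_label(
        changed_loops, ann_by_key, "repressor"
    )
    sets["promoter_se_loops"] = _loop_genes_with_label(
        changed_loops, ann_by_key, "super_enhancer"
    )
    assert set(sets) == set(GENE_SET_NAMES)
    return sets


def hypergeom_ora(
    gene_set: set[str],
    annotation: Mapping[str, set[str]],
    universe: set[str],
    set_name: str = "",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per term, with
    Benjamini–Hochberg FDR across the tested terms.

    p = P(X >= k) under Hypergeometric(N, K, n) where N is the universe
    size, K the term size in the universe, n the query size and k the
    hit count; terms with K = 0 are skipped.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    N = len(universe)
    n = len(gene_set)
    results = []
    for term in sorted(annotation):
        term_genes = annotation[term] & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(gene_set & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(term, set_name, k, n, K, N, p_value=min(p, 1.0))
        )
    if results:
        _, fdrs, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        results = [
            EnrichmentResult(
                r.term, r.set_name, r.k, r.n, r.K, r.N, r.p_value, float(f)
            )
            for r, f in zip(results, fdrs)
        ]
    return results


def term_set_matrix(
    enrichments: Mapping[str, Sequence[EnrichmentResult]],
    fdr_max: float = 0.05,
    min_sets: int = 4,
) -> pd.DataFrame:
    """Boolean term × set matrix of significant enrichments, filtered
    to terms enriched (fdr <= ``fdr_max``) in >= ``min_sets`` sets;
    rows ordered by descending row-sum then term name."""
    set_names = list(enrichments)
    terms = sorted({r.term for rs in enrichments.values() for r in rs})
    mat = pd.DataFrame(False, index=terms, columns=set_names)
    for set_name, rs in enrichments.items():
        for r in rs:
            if r.fdr <= fdr_max:
                mat.loc[r.term, set_name] = True
    rowsum = mat.sum(axis=1)
    mat = mat.loc[rowsum >= min_sets]
    order = sorted(mat.index, key=lambda t: (-int(mat.loc[t].sum()), t))
    return mat.loc[order]
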