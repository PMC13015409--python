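"""GWAS variant handling and variant-to-gene integration.

Lead variants are expanded with LD proxies (r² and distance filtered),
then mapped to candidate target genes by three mechanisms:

* ``loop`` — one anchor of a promoter loop overlaps the variant and
  the other anchor overlaps a gene promoter;
* ``super_enhancer`` — the variant and >= 1 bp of a gene promoter fall
  inside the same SE interval;
* ``closest`` — nearest gene body by edge distance (ties all kept).

Peri-variant peak-change counting and compartment-shift overlap are
also housed here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    Loop,
    VariantRecord,
    interval_gap,
)
from .compartments import CompartmentWindow
from .peaks import DiffPeaks

logger = logging.getLogger(__name__)

__all__ = [
    "TargetAssignment",
    "read_variants",
    "write_variants",
    "expand_ld",
    "loop_targets",
    "se_targets",
    "closest_genes",
    "snp_compartment_overlap",
    "peri_snp_peak_changes",
]

LD_WINDOW = 1_000_000  # proxies must lie within 1 Mb of their lead


@dataclass(frozen=True)
class TargetAssignment:
    variant: str
    gene_id: Optional[str]
    mechanism: str  # loop | super_enhancer | closest
    evidence: str
    loop_set: Optional[str] = None


def read_variants(path: Union[str, Path]) -> list[VariantRecord]:
    """Read a variant TSV (rsid, chrom, pos_1based, trait, lead_rsid,
    r2); positions converted to 0-based; a row is a lead when
    lead_rsid == rsid."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantRecord(
                rsid=row.rsid,
                chrom=row.chrom,
                pos=int(row.pos_1based) - 1,
                trait=row.trait,
                is_lead=row.lead_rsid == row.rsid,
                lead_rsid=row.lead_rsid,
                r2=float(row.r2),
            )
        )
    return out


def write_variants(path: Union[str, Path], variants: Sequence[VariantRecord]) -> None:
    rows = [
        {
            "rsid": v.rsid,
            "chrom": v.chrom,
            "pos_1based": v.pos + 1,
            "trait": v.trait,
            "lead_rsid": v.lead_rsid,
            "r2": v.r2,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def expand_ld(
    leads: Sequence[VariantRecord],
    proxies: Sequence[VariantRecord],
    r2_min: float = 0.8,
) -> list[VariantRecord]:
    """Leads plus proxies with r² >= ``r2_min`` within 1 Mb of their lead."""
    lead_by_id = {v.rsid: v for v in leads}
    out = list(leads)
    for p in proxies:
        lead = lead_by_id.get(p.lead_rsid)
        if lead is None:
            raise KeyError(f"proxy {p.rsid} references unknown lead {p.lead_rsid}")
        if p.r2 < r2_min:
            continue
        if p.chrom != lead.chrom or abs(p.pos - lead.pos) > LD_WINDOW:
            continue
        out.append(p)
    return out


def loop_targets(
    variants: Sequence[VariantRecord],
    loops: Sequence[Loop],
    genes: Sequence[GeneModel],
    loop_set: Optional[str] = None,
) -> list[TargetAssignment]:
    """Loop-mechanism assignments: variant in one anchor, gene promoter
    overlapping the other anchor (both orderings tested; a variant
    overlapping both anchors yields assignments for either side's
    genes).  Identical (variant, gene, loop) triples are deduplicated.
    """
    promoter_idx = IntervalIndex(
        [
            GenomicInterval(
                g.promoter.chrom, g.promoter.start, g.promoter.end, name=g.gene_id
            )
            for g in genes
        ]
    )
    var_idx = IntervalIndex([v.interval for v in variants])
    seen = set()
    out = []
    for li, lp in enumerate(loops):
        loop_id = f"loop_{li}:{lp.anchor1}|{lp.anchor2}"
        for va, ga in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            hit_vars = var_idx.overlapping(va)
            if not hit_vars:
                continue
            hit_genes = promoter_idx.overlapping(ga)
            for v in hit_vars:
                for g in hit_genes:
                    key = (v.name, g.name, lp.key)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        TargetAssignment(
                            variant=v.name,
                            gene_id=g.name,
                            mechanism="loop",
                            evidence=loop_id,
                            loop_set=loop_set,
                        )
                    )
    return out


def se_targets(
    variants: Sequence[VariantRecord],
    super_enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> list[TargetAssignment]:
    """SE-mechanism assignments: variant position and >= 1 bp of gene
    promoter inside the same SE interval."""
    promoter_idx = IntervalIndex(
        [
            GenomicInterval(
                g.promoter.chrom, g.promoter.start, g.promoter.end, name=g.gene_id
            )
            for g in genes
        ]
    )
    out = []
    seen = set()
    for si, se in enumerate(super_enhancers):
        se_id = se.name or f"SE_{si}:{se}"
        inside = [v for v in variants if se.chrom == v.chrom and se.contains_pos(v.pos)]
        if not inside:
            continue
        for g in promoter_idx.overlapping(se):
            for v in inside:
                key = (v.rsid, g.name, se.chrom, se.start, se.end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    TargetAssignment(
                        variant=v.rsid,
                        gene_id=g.name,
                        mechanism="super_enhancer",
                        evidence=se_id,
                    )
                )
    return out


def closest_genes(
    variants: Sequence[VariantRecord], genes: Sequence[GeneModel]
) -> list[TargetAssignment]:
    """Nearest gene body per variant (edge distance, 0 when inside);
    all genes tied at the minimum distance are reported."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for v in variants:
        cands = by_chrom.get(v.chrom, [])
        if not cands:
            logger.warning("variant %s on chromosome without genes", v.rsid)
            out.append(
                TargetAssignment(v.rsid, None, "closest", "no_gene_on_chrom")
            )
            continue
        dists = [(interval_gap(v.interval, g.body), g) for g in cands]
        dmin = min(d for d, _ in dists)
        for d, g in dists:
            if d == dmin:
                out.append(
                    TargetAssignment(v.rsid, g.gene_id, "closest", str(dmin))
                )
    return out


def snp_compartment_overlap(
    leads: Sequence[VariantRecord], windows: Sequence[CompartmentWindow]
) -> dict[str, str]:
    """Shift label of the (half-open) window containing each variant."""
    shifted = [w for w in windows if w.shift != "none"]
    idx_items = [
        (w.interval, w.shift) for w in shifted
    ]
    idx = IntervalIndex([iv for iv, _ in idx_items])
    shift_by_key = {(iv.chrom, iv.start, iv.end): s for iv, s in idx_items}
    out = {}
    for v in leads:
        hits = idx.at_pos(v.chrom, v.pos)
        out[v.rsid] = (
            shift_by_key[(hits[0].chrom, hits[0].start, hits[0].end)]
            if hits
            else "none"
        )
    return out


def peri_snp_peak_changes(
    leads: Sequence[VariantRecord],
    diff_by_mark: Mapping[str, DiffPeaks],
    radius: int = 5000,
) -> dict[str, dict[str, dict[str, int]]]:
    """Per-variant gained/lost peak counts per mark within ±``radius`` bp.

    The window is [pos - radius, pos + radius + 1); peaks count with
    >= 1 bp overlap.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    indexes = {
        mark: {
            "gained": IntervalIndex(d.gained),
            "lost": IntervalIndex(d.lost),
        }
        for mark, d in diff_by_mark.items()
    }
    out: dict[str, dict[str, dict[str, int]]] = {}
    for v in leads:
        win = GenomicInterval(v.chrom, max(0, v.pos - radius), v.pos + radius + 1)
        out[v.rsid] = {
            mark: {
                "gained": len(idx["gained"].overlapping(win)),
                "lost": len(idx["lost"].overlapping(win)),
            }
            for mark, idx in indexes.items()
        }
    return out
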