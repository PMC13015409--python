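"""Synthetic multi-omic dataset with a machine-readable truth manifest.

The generator emulates the *processed* outputs of a dexamethasone
perturbation study in a cultured cell system: replicate peak sets per
histone mark / ATAC / CTCF, per-sample promoter-loop BEDPE files,
A/B compartment score tracks, a counts matrix with a differential-
expression table, GWAS lead/proxy variant tables, external SE and
tissue-loop catalogs, gene models and a toy annotation GMT.  Every
planted signal (loop gains/losses, enhancer-state switches, SE calls,
compartment flips, DE genes, variant-to-gene mechanisms, eRNA loci) is
recorded in ``truth_manifest.json`` so each downstream stage can be
scored exactly.

Genome layout
-------------
Each chromosome is tiled with 50 kb blocks grouped into 1 Mb periods of
20 blocks: 15 gene blocks, 2 standalone-enhancer blocks, 1
super-enhancer cluster block, 1 decoy block (replicate-unique peaks and
an H3K4me3-proximal enhancer decoy) and 1 repressor/utility block.
Features never share a block, which keeps the planted truth exactly
recoverable under the default replicate jitter.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import GeneModel, GenomicInterval, Loop, promoter_interval
from . import io_formats
from .variant2gene import write_variants
from .core import VariantRecord

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "make_hockey_stick",
    "make_nested_emissions",
    "load_manifest",
]

BLOCK = 50_000
PERIOD_BLOCKS = 20
PERIOD = BLOCK * PERIOD_BLOCKS

MARKS = ("H3K27ac", "H3K27me3", "H3K4me1", "H3K4me3", "H3K36me3", "CTCF", "ATAC")

STATE_PEAKS = {
    # enhancer state -> marks with a peak over the element
    "active": ("H3K27ac", "H3K4me1"),
    "primed": ("H3K4me1",),
    "poised": ("H3K4me1", "H3K27me3"),
    "inactive": (),
}

SE_CONSTITUENT_SIGNAL = 300.0
BG_ENHANCER_SIGNAL = 5.0


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_replicates: int = 3
    consensus_k: int = 2
    peak_jitter_sd: float = 25.0
    peak_drop_fraction: float = 0.10
    loop_fraction_differential: float = 1.0
    nb_dispersion: float = 0.1
    de_log2fc: float = 2.0
    proxy_r2_high: float = 0.9
    proxy_r2_low: float = 0.5
    n_catalog_samples: int = 40
    n_tissues: int = 5
    n_true_states: int = 13
    compartment_window: int = 50_000
    promoter_up: int = 2000
    promoter_down: int = 500

    def validate(self) -> None:
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        if self.chrom_length < PERIOD:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small to place the "
                f"feature layout (needs >= {PERIOD})"
            )
        if self.chrom_length % BLOCK != 0:
            raise ValueError("chrom_length must be a multiple of 50 kb")
        if not 0 <= self.peak_drop_fraction < 1:
            raise ValueError("peak_drop_fraction must be in [0, 1)")
        if not 0 <= self.loop_fraction_differential <= 1:
            raise ValueError("loop_fraction_differential must be in [0, 1]")
        if self.n_replicates < self.consensus_k:
            raise ValueError("n_replicates must be >= consensus_k")
        if self.compartment_window != BLOCK:
            raise ValueError(
                "compartment score tracks are generated on the 50 kb block "
                "grid; compartment_window must equal 50000"
            )


# ---------------------------------------------------------------------------
# internal planning records


@dataclass
class _PlannedPeak:
    mark: str
    interval: GenomicInterval
    score: float
    conditions: tuple[str, ...]  # subset of ("control", "dex")


@dataclass
class _PlannedEnhancer:
    eid: str
    interval: GenomicInterval
    state_control: str
    state_dex: str
    erna_status: str  # candidate | expressed | decoy_body | decoy_tss | decoy_k4me3


@dataclass
class _PlannedLoop:
    lid: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    cls: str  # stable | gained | lost | decoy
    gene_id: Optional[str] = None
    distal_kind: Optional[str] = None  # enhancer | repressor | super_enhancer
    ctcf_feet: int = 0


@dataclass
class _PlannedSE:
    sid: str
    span: GenomicInterval
    role: str  # stable | gained | lost | variant_se | loop_se


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def make_hockey_stick(
    n_points: int, n_super: int, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Ranked-signal fixture with a known super-enhancer breakpoint.

    Returns a non-decreasing signal vector of length ``n_points`` and
    the index of the first "super" point (``n_points`` when
    ``n_super == 0``): the background regime is concave and low, the
    super regime high, so the slope-1 tangent of the scaled curve sits
    at the last background rank.
    """
    if n_super >= n_points:
        raise ValueError("n_super must be < n_points")
    if n_super < 0:
        raise ValueError("n_super must be >= 0")
    rng = np.random.default_rng(seed)
    n_bg = n_points - n_super
    t = np.linspace(0.0, 1.0, n_bg)
    bg = 1.0 + 9.0 * np.sqrt(t)
    if n_super == 0:
        return bg, n_points
    bg = np.sort(bg + rng.normal(0.0, 0.05, size=n_bg))
    sup = np.sort(rng.uniform(100.0, 800.0, size=n_super))
    return np.concatenate([bg, sup]), n_bg


def make_nested_emissions(
    n_true: int = 13,
    marks: tuple[str, ...] = (*MARKS, "H3K4me2", "H3K9me3"),
    k_min: int = 5,
    k_max: int = 16,
    seed: int = 0,
) -> list:
    """Nested chromatin-state emission matrices with a known plateau.

    Models below ``n_true`` states merge groups of the ``n_true``
    distinct prototype rows (group means); models at or above
    ``n_true`` contain every prototype (plus duplicates), so the
    best-match correlation curve reaches its plateau exactly at
    ``n_true``.
    """
    from .chromatin_states import EmissionMatrix

    if not k_min < n_true <= k_max - 2:
        raise ValueError(
            "need k_min < n_true <= k_max - 2 (the plateau is only "
            "observable with at least two larger models)"
        )
    rng = np.random.default_rng(seed)
    n_marks = len(marks)
    # distinct on/off prototype patterns, rescaled into (0, 1)
    protos = np.full((n_true, n_marks), 0.5)
    seen = set()
    for i in range(n_true):
        while True:
            bits = tuple(sorted(rng.permutation(n_marks)[: 2 + i % 4].tolist()))
            if bits not in seen:
                seen.add(bits)
                break
        u = np.full(n_marks, -0.25)
        u[list(bits)] = 0.25
        protos[i] = 0.5 + u - u.mean()
    # models at or above n_true contain every prototype (plus duplicates);
    # below n_true each model is derived from its successor by rotating
    # every row away from its counterpart by an exact correlation step,
    # so the best-match correlation curve rises linearly to its plateau.
    step = 0.03
    models_by_k: dict[int, np.ndarray] = {}
    for k in range(n_true, k_max + 1):
        models_by_k[k] = np.vstack([protos, protos[: k - n_true]])
    for k in range(n_true - 1, k_min - 1, -1):
        parent = models_by_k[k + 1][:k]
        r = max(0.2, 1.0 - step * (n_true - k))
        rows = np.empty_like(parent)
        drng = np.random.default_rng(seed * 1000 + k)
        parent_c = parent - parent.mean(axis=1, keepdims=True)
        parent_u = parent_c / np.linalg.norm(parent_c, axis=1, keepdims=True)
        for i in range(k):
            u = parent_u[i]
            # choose the rotation direction that keeps the counterpart the
            # best match: orthogonal to u, minimal alignment with the
            # other parent rows
            best_w, best_cross = None, np.inf
            for _ in range(8):
                g = drng.standard_normal(n_marks)
                v = g - g.mean()
                for j in range(min(k, n_marks - 2)):
                    v -= (v @ parent_u[j]) * parent_u[j]
                v -= (v @ u) * u
                nv = np.linalg.norm(v)
                if nv < 1e-9:
                    continue
                v /= nv
                w = r * u + np.sqrt(1 - r * r) * v
                others = np.delete(parent_u, i, axis=0)
                cross = np.abs(others @ w).max() if len(others) else 0.0
                if cross < best_cross:
                    best_w, best_cross = w, cross
            rows[i] = 0.5 + 0.45 * best_w
        models_by_k[k] = rows
    return [
        EmissionMatrix(k, list(marks), models_by_k[k])
        for k in range(k_min, k_max + 1)
    ]


# ---------------------------------------------------------------------------


class _Plan:
    """Deterministic feature layout derived from the config."""

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        self.genes: list[GeneModel] = []
        self.strand_of: dict[str, str] = {}
        self.peaks: list[_PlannedPeak] = []
        self.enhancers: list[_PlannedEnhancer] = []
        self.loops: list[_PlannedLoop] = []
        self.ses: list[_PlannedSE] = []
        self.repressors: list[GenomicInterval] = []
        self.variants: list[VariantRecord] = []
        self.proxies: list[VariantRecord] = []
        self.flips: list[tuple[str, int, int, str]] = []  # chrom,start,end,dir
        self.de_up: list[str] = []
        self.de_down: list[str] = []
        self.loop_assign: list[tuple[str, str]] = []  # (rsid, gene)
        self.se_assign: list[tuple[str, str]] = []
        self.compartment_labels: dict[str, str] = {}
        self.erna_expressed: list[str] = []
        self.hot_genes: list[str] = []
        self.down_genes: list[str] = []
        self.ctcf_genes: list[str] = []
        self.switch_gene_ids: list[str] = []

    # -- helpers ----------------------------------------------------------
    def add_peak(self, mark, chrom, start, end, score, conditions):
        self.peaks.append(
            _PlannedPeak(
                mark,
                GenomicInterval(chrom, start, end),
                score,
                tuple(conditions),
            )
        )

    def add_state_peaks(self, chrom, start, end, state_c, state_d, signal):
        """Peaks realising an enhancer's per-condition state pair."""
        marks_c = set(STATE_PEAKS[state_c])
        marks_d = set(STATE_PEAKS[state_d])
        for mark in marks_c | marks_d:
            conds = []
            if mark in marks_c:
                conds.append("control")
            if mark in marks_d:
                conds.append("dex")
            score = signal if mark == "H3K27ac" else 1.0
            self.add_peak(mark, chrom, start, end, score, conds)


def _build_plan(cfg: SyntheticConfig) -> _Plan:
    plan = _Plan(cfg)
    gene_idx = 0
    trait_cycle = ("IOP", "POAG")
    var_i = 0

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n_periods = cfg.chrom_length // PERIOD
        gene_blocks, e_blocks, s_blocks, d_blocks, r_blocks = [], [], [], [], []
        for p in range(n_periods):
            base = p * PERIOD
            for j in range(15):
                gene_blocks.append(base + j * BLOCK)
            e_blocks += [base + 15 * BLOCK, base + 16 * BLOCK]
            s_blocks.append(base + 17 * BLOCK)
            d_blocks.append(base + 18 * BLOCK)
            r_blocks.append(base + 19 * BLOCK)

        # ------------------------------------------------------------ genes
        chrom_genes: list[GeneModel] = []
        role_counters: dict[int, int] = {r: 0 for r in range(10)}
        for b in gene_blocks:
            strand = "+" if gene_idx % 2 == 0 else "-"
            body = GenomicInterval(chrom, b + 20_000, b + 30_000)
            gid = f"G{gene_idx:04d}"
            tss = body.start if strand == "+" else body.end - 1
            promoter = promoter_interval(
                chrom, strand, tss, cfg.promoter_up, cfg.promoter_down
            )
            gene = GeneModel(gid, gid, chrom, strand, body, promoter)
            plan.genes.append(gene)
            chrom_genes.append(gene)
            plan.strand_of[gid] = strand
            gene_idx += 1

        # per-gene housekeeping peaks: promoter H3K4me3 + ATAC, body H3K36me3
        for gi, gene in enumerate(chrom_genes):
            role = gi % 10
            nth = role_counters[role]
            role_counters[role] = nth + 1
            tss = gene.tss
            b = gene.body.start - 20_000
            k4me3_conds = ("control",) if role == 7 else ("control", "dex")
            plan.add_peak(
                "H3K4me3", chrom, tss - 500, tss + 500, 1.0, k4me3_conds
            )
            atac_conds = ("control",) if role == 0 else ("control", "dex")
            plan.add_peak("ATAC", chrom, tss - 300, tss + 300, 1.0, atac_conds)
            plan.add_peak(
                "H3K36me3", chrom, gene.body.start + 2000,
                gene.body.end - 2000, 1.0, ("control", "dex"),
            )
            if role == 0:  # hot: DE up + gained H3K27ac over promoter
                plan.hot_genes.append(gene.gene_id)
                plan.de_up.append(gene.gene_id)
                plan.add_peak(
                    "H3K27ac", chrom, tss - 1500, tss - 700, BG_ENHANCER_SIGNAL,
                    ("dex",),
                )
            elif role == 3:  # DE down + gained H3K27me3 over promoter
                plan.down_genes.append(gene.gene_id)
                plan.de_down.append(gene.gene_id)
                plan.add_peak(
                    "H3K27me3", chrom, tss - 1500, tss - 700, 1.0, ("dex",)
                )
            elif role == 4:  # gained CTCF over promoter
                plan.ctcf_genes.append(gene.gene_id)
                plan.add_peak("CTCF", chrom, tss - 1200, tss - 700, 1.0, ("dex",))
            elif role == 5:
                plan.add_peak(
                    "H3K4me1", chrom, gene.body.start + 4000,
                    gene.body.start + 5000, 1.0, ("dex",),
                )
                if nth < 3:  # near-TSS eRNA decoy (no peaks: geometry only)
                    if gene.strand == "+":
                        iv = GenomicInterval(chrom, tss - 1700, tss - 1200)
                    else:
                        iv = GenomicInterval(chrom, tss + 1201, tss + 1701)
                    plan.enhancers.append(
                        _PlannedEnhancer(
                            f"ENHtss_{gene.gene_id}", iv, "inactive",
                            "inactive", "decoy_tss",
                        )
                    )
            elif role == 6:  # in-body enhancer (eRNA decoy; drives switches)
                iv = GenomicInterval(chrom, b + 24_000, b + 24_500)
                if nth < 5:
                    sc, sd = "inactive", "active"
                elif nth < 10:
                    sc, sd = "active", "inactive"
                else:
                    sc, sd = "active", "active"
                if sc != sd:
                    plan.switch_gene_ids.append(gene.gene_id)
                plan.enhancers.append(
                    _PlannedEnhancer(
                        f"ENHbody_{gene.gene_id}", iv, sc, sd, "decoy_body"
                    )
                )
                plan.add_state_peaks(
                    chrom, iv.start, iv.end, sc, sd, BG_ENHANCER_SIGNAL
                )
            elif role == 9:
                plan.add_peak(
                    "H3K36me3", chrom, gene.body.start + 6000,
                    gene.body.start + 7500, 1.0, ("dex",),
                )

        # -------------------------------------------------- standalone enhancers
        # E-block states repeat with period 20: the first half active in
        # both conditions (expressed eRNA hosts and loop distals), then
        # primed, poised, and one activated + one deactivated switcher
        # (~10% switch rate).
        def e_state(ei: int) -> tuple[str, str]:
            p = ei % 20
            if p < 10:
                return ("active", "active")
            if p < 15:
                return ("primed", "primed")
            if p < 18:
                return ("poised", "poised")
            if p == 18:
                return ("primed", "active")
            return ("active", "poised")

        e_enh: list[GenomicInterval] = []
        for ei, b in enumerate(e_blocks):
            iv = GenomicInterval(chrom, b + 10_000, b + 11_000)
            sc, sd = e_state(ei)
            status = "expressed" if ei % 20 < 10 else "candidate"
            eid = f"ENH_{chrom}_{ei:02d}"
            plan.enhancers.append(_PlannedEnhancer(eid, iv, sc, sd, status))
            if status == "expressed":
                plan.erna_expressed.append(f"{chrom}:{iv.start}-{iv.end}")
            plan.add_state_peaks(chrom, iv.start, iv.end, sc, sd, BG_ENHANCER_SIGNAL)
            e_enh.append(iv)

        # ----------------------------------------------------------- SE blocks
        se_roles = ["stable", "gained", "lost", "variant_se", "loop_se"]
        for si, b in enumerate(s_blocks):
            role = se_roles[si % len(se_roles)]
            span = GenomicInterval(chrom, b + 10_000, b + 23_000)
            sid = f"SE_{chrom}_{si:02d}"
            plan.ses.append(_PlannedSE(sid, span, role))
            state_c, state_d = {
                "stable": ("active", "active"),
                "gained": ("primed", "active"),
                "lost": ("active", "primed"),
                "variant_se": ("active", "active"),
                "loop_se": ("active", "active"),
            }[role]
            for j in range(5):
                s = b + 10_000 + j * 3000
                iv = GenomicInterval(chrom, s, s + 1000)
                plan.enhancers.append(
                    _PlannedEnhancer(
                        f"{sid}_c{j}", iv, state_c, state_d, "candidate"
                    )
                )
                plan.add_state_peaks(
                    chrom, iv.start, iv.end, state_c, state_d,
                    SE_CONSTITUENT_SIGNAL,
                )
            if role == "variant_se":
                # gene whose promoter overlaps the SE span end while its
                # TSS-exclusion window leaves every constituent intact
                body = GenomicInterval(chrom, b + 24_600, b + 34_600)
                gid = f"SEG_{chrom}_{si:02d}"
                promoter = promoter_interval(
                    chrom, "+", body.start, cfg.promoter_up, cfg.promoter_down
                )
                plan.genes.append(
                    GeneModel(gid, gid, chrom, "+", body, promoter)
                )
                plan.strand_of[gid] = "+"
                plan.add_peak(
                    "H3K4me3", chrom, body.start - 500, body.start + 500,
                    1.0, ("control", "dex"),
                )
                rsid = f"rs{9000 + var_i}"
                pos = b + 16_500
                plan.variants.append(
                    VariantRecord(
                        rsid, chrom, pos, trait_cycle[var_i % 2], True, rsid, 1.0
                    )
                )
                plan.se_assign.append((rsid, gid))
                # kept proxy outside the SE span; dropped low-r2 proxy
                plan.proxies.append(
                    VariantRecord(
                        f"rs{9000 + var_i}p1", chrom, b + 24_500,
                        trait_cycle[var_i % 2], False, rsid, cfg.proxy_r2_high,
                    )
                )
                plan.proxies.append(
                    VariantRecord(
                        f"rs{9000 + var_i}p0", chrom, pos + 500,
                        trait_cycle[var_i % 2], False, rsid, cfg.proxy_r2_low,
                    )
                )
                var_i += 1

        # --------------------------------------------------------- repressors
        for ri, b in enumerate(r_blocks):
            if ri < 4:
                seg = GenomicInterval(chrom, b + 10_000, b + 12_000)
                plan.repressors.append(seg)
                plan.add_peak(
                    "H3K27me3", chrom, b + 9800, b + 12_200, 1.0,
                    ("control", "dex"),
                )
            elif ri in (4, 5):
                plan.flips.append((chrom, b, b + BLOCK, "toward_B"))
            elif ri == 6:
                rsid = f"rs{9500 + ci}"
                plan.variants.append(
                    VariantRecord(rsid, chrom, b + 25_000, "IOP", True, rsid, 1.0)
                )

        # -------------------------------------------------------- decoy blocks
        for di, b in enumerate(d_blocks):
            plan.add_peak(
                "H3K4me3", chrom, b + 10_000, b + 10_500, 1.0, ("control", "dex")
            )
            plan.enhancers.append(
                _PlannedEnhancer(
                    f"ENHk4_{chrom}_{di:02d}",
                    GenomicInterval(chrom, b + 11_500, b + 12_000),
                    "inactive",
                    "inactive",
                    "decoy_k4me3",
                )
            )

        # ------------------------------------------------------------- loops
        def promoter_anchor(gene: GeneModel) -> GenomicInterval:
            return GenomicInterval(chrom, gene.tss - 2000, gene.tss + 2000)

        def enhancer_anchor(iv: GenomicInterval) -> GenomicInterval:
            return GenomicInterval(chrom, iv.start - 1500, iv.end + 1500)

        genes_by_role = {
            r: [g for i, g in enumerate(chrom_genes) if i % 10 == r]
            for r in range(10)
        }
        n_li = 0

        def add_loop(gene, distal, cls, kind, ctcf_feet=0):
            nonlocal n_li
            plan.loops.append(
                _PlannedLoop(
                    f"L_{chrom}_{n_li:03d}",
                    promoter_anchor(gene),
                    distal,
                    cls,
                    gene_id=gene.gene_id,
                    distal_kind=kind,
                    ctcf_feet=ctcf_feet,
                )
            )
            n_li += 1

        # distal-anchor budget: quarter of the E blocks per loop family
        q = max(1, len(e_enh) // 4)
        n_fam = min(5, q)

        # variant-loop genes: stable loop + lead variant inside the distal
        for n, gene in enumerate(genes_by_role[1][:n_fam]):
            e_iv = e_enh[n]
            add_loop(gene, enhancer_anchor(e_iv), "stable", "enhancer")
            rsid = f"rs{1000 + var_i}"
            pos = (e_iv.start + e_iv.end) // 2
            plan.variants.append(
                VariantRecord(
                    rsid, chrom, pos, trait_cycle[var_i % 2], True, rsid, 1.0
                )
            )
            plan.loop_assign.append((rsid, gene.gene_id))
            plan.proxies.append(
                VariantRecord(
                    f"rs{1000 + var_i}p1", chrom, e_iv.start - 10_000 + 4000,
                    trait_cycle[var_i % 2], False, rsid, cfg.proxy_r2_high,
                )
            )
            plan.proxies.append(
                VariantRecord(
                    f"rs{1000 + var_i}p0", chrom, pos + 300,
                    trait_cycle[var_i % 2], False, rsid, cfg.proxy_r2_low,
                )
            )
            # peri-SNP signal: a gained H3K27ac peak within 5 kb
            if n < 2:
                plan.add_peak(
                    "H3K27ac", chrom, e_iv.start + 3000, e_iv.start + 4000,
                    BG_ENHANCER_SIGNAL, ("dex",),
                )
            var_i += 1

        for n, gene in enumerate(genes_by_role[0][:n_fam]):  # hot: gained PE loop
            add_loop(gene, enhancer_anchor(e_enh[q + n]), "gained", "enhancer")
        for n, gene in enumerate(genes_by_role[2][:n_fam]):  # lost PE loop
            add_loop(gene, enhancer_anchor(e_enh[2 * q + n]), "lost", "enhancer")
        for n, gene in enumerate(genes_by_role[6][:n_fam]):  # stable + CTCF feet
            feet = 2 if n < 3 else 1
            distal = enhancer_anchor(e_enh[3 * q + n])
            add_loop(gene, distal, "stable", "enhancer", ctcf_feet=feet)
            pa = promoter_anchor(gene)
            mid = (pa.start + pa.end) // 2
            plan.add_peak(
                "CTCF", chrom, mid - 300, mid + 300, 1.0, ("control", "dex")
            )
            if feet == 2:
                dm = (distal.start + distal.end) // 2
                plan.add_peak(
                    "CTCF", chrom, dm - 300, dm + 300, 1.0, ("control", "dex")
                )
        # promoter-repressor loops
        reps = [r for r in plan.repressors if r.chrom == chrom]
        for n, gene in enumerate(genes_by_role[8][: len(reps)]):
            seg = reps[n]
            distal = GenomicInterval(chrom, seg.start - 1000, seg.end + 1000)
            cls = "gained" if n < 2 else "lost"
            add_loop(gene, distal, cls, "repressor")
        # promoter-SE loops from loop_se blocks to role-4 genes
        loop_ses = [
            se for se in plan.ses if se.role == "loop_se" and se.span.chrom == chrom
        ]
        for n, se in enumerate(loop_ses[: len(genes_by_role[4])]):
            gene = genes_by_role[4][n]
            distal = GenomicInterval(
                chrom, se.span.start + 4000, se.span.start + 8000
            )
            cls = "gained" if n % 2 == 0 else "lost"
            add_loop(gene, distal, cls, "super_enhancer")
        # decoy singleton loops in utility blocks 7-9
        for n, b in enumerate(r_blocks[7:10]):
            plan.loops.append(
                _PlannedLoop(
                    f"Ldecoy_{chrom}_{n}",
                    GenomicInterval(chrom, b + 5000, b + 7000),
                    GenomicInterval(chrom, b + 30_000, b + 32_000),
                    "decoy",
                )
            )

        # ----------------------------------------------- compartment variants
        hot5 = genes_by_role[0][:5]
        for gene in hot5:
            b = gene.body.start - 20_000
            plan.flips.append((chrom, b, b + BLOCK, "toward_A"))
        for gene in hot5[3:5]:
            b = gene.body.start - 20_000
            rsid = f"rs{2000 + var_i}"
            plan.variants.append(
                VariantRecord(
                    rsid, chrom, b + 40_000, trait_cycle[var_i % 2], True,
                    rsid, 1.0,
                )
            )
            plan.compartment_labels[rsid] = "toward_A"
            var_i += 1

    # loop_fraction_differential scaling: demote differential loops to stable
    if cfg.loop_fraction_differential < 1.0:
        diffs = [lp for lp in plan.loops if lp.cls in ("gained", "lost")]
        keep = int(round(cfg.loop_fraction_differential * len(diffs)))
        for lp in diffs[keep:]:
            lp.cls = "stable"

    for v in plan.variants:
        if v.rsid not in plan.compartment_labels:
            plan.compartment_labels[v.rsid] = "none"
    return plan


# ---------------------------------------------------------------------------
# emission


def _emit_peaks(plan: _Plan, outdir: Path, rng: np.random.Generator) -> None:
    cfg = plan.cfg
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    for mark in MARKS:
        for cond in ("control", "dex"):
            truth = [
                p
                for p in plan.peaks
                if p.mark == mark and cond in p.conditions
            ]
            # choose surviving replicates per peak: drop ~drop_fraction but
            # always keep >= consensus_k so the consensus recovers the truth
            n = cfg.n_replicates
            rep_peaks: list[list[GenomicInterval]] = [[] for _ in range(n)]
            for p in truth:
                keep = rng.random(n) > cfg.peak_drop_fraction
                while keep.sum() < cfg.consensus_k:
                    keep[rng.integers(n)] = True
                for r in range(n):
                    if not keep[r]:
                        continue
                    ds = int(rng.normal(0, cfg.peak_jitter_sd))
                    de = int(rng.normal(0, cfg.peak_jitter_sd))
                    start = max(0, p.interval.start + ds)
                    end = max(start + 50, p.interval.end + de)
                    rep_peaks[r].append(
                        GenomicInterval(
                            p.interval.chrom, start, end,
                            name=f"{mark}_{cond}_{r}", score=p.score,
                        )
                    )
            # replicate-unique decoy peaks in decoy blocks
            for ci in range(cfg.n_chroms):
                chrom = f"chr{ci + 1}"
                n_periods = cfg.chrom_length // PERIOD
                for pi in range(n_periods):
                    b = pi * PERIOD + 18 * BLOCK
                    r = (pi + MARKS.index(mark)) % n
                    off = 15_000 + 600 * MARKS.index(mark) + (
                        0 if cond == "control" else 300
                    )
                    rep_peaks[r].append(
                        GenomicInterval(
                            chrom, b + off, b + off + 200,
                            name="decoy", score=1.0,
                        )
                    )
            for r in range(n):
                io_formats.write_intervals(
                    outdir / "peaks" / f"{mark}.{cond}.rep{r + 1}.narrowPeak",
                    rep_peaks[r],
                    dialect="narrowPeak",
                )


def _emit_loops(plan: _Plan, outdir: Path, rng: np.random.Generator) -> None:
    cfg = plan.cfg
    (outdir / "loops").mkdir(parents=True, exist_ok=True)
    samples = {
        "control": [f"control_{i + 1}" for i in range(cfg.n_replicates)],
        "dex": [f"dex_{i + 1}" for i in range(cfg.n_replicates)],
    }
    per_sample: dict[str, list[Loop]] = {
        s: [] for ss in samples.values() for s in ss
    }

    def support(cond_samples):
        k = int(rng.integers(2, len(cond_samples) + 1))
        idx = rng.permutation(len(cond_samples))[:k]
        return [cond_samples[i] for i in idx]

    for lp in plan.loops:
        if lp.cls == "stable":
            carriers = support(samples["control"]) + support(samples["dex"])
        elif lp.cls == "lost":
            carriers = support(samples["control"])
        elif lp.cls == "gained":
            carriers = support(samples["dex"])
        else:  # decoy: single sample
            all_s = samples["control"] + samples["dex"]
            carriers = [all_s[int(rng.integers(len(all_s)))]]
        for s in carriers:
            js = [int(rng.normal(0, 25)) for _ in range(4)]
            a1 = GenomicInterval(
                lp.anchor1.chrom,
                max(0, lp.anchor1.start + js[0]),
                lp.anchor1.end + js[1],
            )
            a2 = GenomicInterval(
                lp.anchor2.chrom,
                max(0, lp.anchor2.start + js[2]),
                lp.anchor2.end + js[3],
            )
            per_sample[s].append(Loop.canonical(a1, a2, samples={s}))
    for s, loops in per_sample.items():
        io_formats.write_loops(outdir / "loops" / f"{s}.bedpe", loops)


def _emit_compartments(plan: _Plan, outdir: Path, rng: np.random.Generator) -> None:
    cfg = plan.cfg
    cdir = outdir / "compartments"
    cdir.mkdir(parents=True, exist_ok=True)
    flip_by_key = {(c, s, e): d for c, s, e, d in plan.flips}
    control, treated = [], []
    keys = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        for w in range(cfg.chrom_length // cfg.compartment_window):
            s = w * cfg.compartment_window
            e = s + cfg.compartment_window
            keys.append((chrom, s, e))
            mag = rng.uniform(0.3, 1.0)
            sign = 1.0 if (w // 4) % 2 == 0 else -1.0
            flip = flip_by_key.get((chrom, s, e))
            if flip == "toward_A":
                sc, st = -mag, rng.uniform(0.5, 1.0)
            elif flip == "toward_B":
                sc, st = mag, -rng.uniform(0.5, 1.0)
            else:
                sc = sign * mag
                st = sc + rng.uniform(-0.05, 0.05)
            control.append(GenomicInterval(chrom, s, e, score=round(sc, 4)))
            treated.append(GenomicInterval(chrom, s, e, score=round(st, 4)))
    io_formats.write_intervals(cdir / "score.control.bedgraph", control, "bedgraph")
    io_formats.write_intervals(cdir / "score.dex.bedgraph", treated, "bedgraph")
    # per-window per-mark signal deltas (mean treated-minus-control signal)
    active = ("H3K27ac", "H3K4me1", "H3K36me3", "H3K4me3")
    rows = {}
    for key in keys:
        flip = flip_by_key.get(key, None)
        row = {}
        for mark in MARKS:
            if flip == "toward_A":
                mu = 1.0 if mark in active else -1.0
            elif flip == "toward_B":
                mu = -1.0 if mark in active else 1.0
            else:
                mu = 0.0
            row[mark] = round(float(rng.normal(mu, 0.2)), 4)
        rows[f"{key[0]}:{key[1]}-{key[2]}"] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "window"
    df.to_csv(cdir / "signal_deltas.tsv", sep="\t")


def _emit_expression(plan: _Plan, outdir: Path, rng: np.random.Generator) -> None:
    cfg = plan.cfg
    edir = outdir / "expression"
    edir.mkdir(parents=True, exist_ok=True)
    samples = [f"ctrl_{i + 1}" for i in range(3)] + [f"dex_{i + 1}" for i in range(3)]
    gene_ids = [g.gene_id for g in plan.genes]
    lfc = {g: 0.0 for g in gene_ids}
    for g in plan.de_up:
        lfc[g] = cfg.de_log2fc
    for g in plan.de_down:
        lfc[g] = -cfg.de_log2fc
    base = rng.lognormal(mean=5.0, sigma=1.0, size=len(gene_ids))
    disp = cfg.nb_dispersion
    counts = np.zeros((len(gene_ids), 6), dtype=int)
    for i, g in enumerate(gene_ids):
        mu_c = base[i]
        mu_d = base[i] * 2.0 ** lfc[g]
        for j in range(6):
            mu = mu_c if j < 3 else mu_d
            r = 1.0 / disp
            p = r / (r + mu)
            counts[i, j] = rng.negative_binomial(r, p)
    pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples).to_csv(
        edir / "counts.tsv", sep="\t"
    )
    de_rows = []
    for g in gene_ids:
        is_de = lfc[g] != 0.0
        de_rows.append(
            {
                "gene_id": g,
                "log2FC": lfc[g] if is_de else round(float(rng.normal(0, 0.1)), 3),
                "FDR": 1e-4 if is_de else round(float(rng.uniform(0.3, 0.95)), 3),
            }
        )
    io_formats.write_de_table(edir / "de_table.tsv", pd.DataFrame(de_rows))

    # eRNA counts: rows for every geometry-surviving candidate region
    cand_ids, expressed = _erna_candidate_ids(plan)
    mat = np.zeros((len(cand_ids), 6), dtype=int)
    for i, cid in enumerate(cand_ids):
        if cid in expressed:
            mat[i] = rng.integers(200, 600, size=6)
        else:
            j = int(rng.integers(6))
            mat[i, j] = 1  # at most one non-zero sample: fails ">=2 samples"
    pd.DataFrame(
        mat, index=pd.Index(cand_ids, name="gene_id"), columns=samples
    ).to_csv(edir / "erna_counts.tsv", sep="\t")


def _erna_candidate_ids(plan: _Plan) -> tuple[list[str], set[str]]:
    """Geometry-surviving eRNA candidate region ids, by construction.

    Standalone E-block enhancers always survive; SE constituents survive
    except those within 3 kb of the variant_se gene's TSS/H3K4me3 or
    overlapping its body; planted decoys never survive.
    """
    cand = []
    gene_bodies = [(g.chrom, g.body.start, g.body.end, g.tss) for g in plan.genes]
    k4 = [
        (p.interval.chrom, p.interval.start, p.interval.end)
        for p in plan.peaks
        if p.mark == "H3K4me3"
    ]
    for enh in plan.enhancers:
        if enh.erna_status in ("decoy_body", "decoy_tss", "decoy_k4me3"):
            continue
        iv = enh.interval
        ok = True
        for c, s, e, tss in gene_bodies:
            if c != iv.chrom:
                continue
            if s < iv.end and iv.start < e:
                ok = False
                break
            if max(0, max(iv.start, tss) - min(iv.end, tss + 1)) < 3000:
                ok = False
                break
        if ok:
            for c, s, e in k4:
                if c == iv.chrom and max(0, max(iv.start, s) - min(iv.end, e)) < 3000:
                    ok = False
                    break
        if ok:
            cand.append(f"{iv.chrom}:{iv.start}-{iv.end}")
    return cand, set(plan.erna_expressed)


def _emit_variants(plan: _Plan, outdir: Path) -> None:
    vdir = outdir / "variants"
    vdir.mkdir(parents=True, exist_ok=True)
    write_variants(vdir / "leads.tsv", plan.variants)
    write_variants(vdir / "proxies.tsv", plan.proxies)


def _emit_se_catalogs(plan: _Plan, outdir: Path, rng: np.random.Generator) -> None:
    cfg = plan.cfg
    sdir = outdir / "se"
    (sdir / "catalog").mkdir(parents=True, exist_ok=True)
    stable = [se.span for se in plan.ses if se.role == "stable"]
    gained = [se.span for se in plan.ses if se.role == "gained"]
    lost = [se.span for se in plan.ses if se.role == "lost"]
    var_se = [se.span for se in plan.ses if se.role == "variant_se"]
    loop_se = [se.span for se in plan.ses if se.role == "loop_se"]
    always = stable + var_se + loop_se
    # resource sets: consensus (k=4 of 6) keeps `always` + `gained`
    for s in range(6):
        rows = list(always)
        if s < 4:
            rows += gained
        if s < 3:
            rows += lost
        # one per-set decoy in a utility block
        b = (s % (cfg.chrom_length // PERIOD)) * PERIOD + 19 * BLOCK
        rows.append(GenomicInterval("chr1", b + 35_000, b + 40_000))
        io_formats.write_intervals(sdir / f"resource_set{s + 1}.bed", rows, "bed3")
    # external catalog: ubiquitous = stable (38/n samples), specific = var_se (1)
    n_ubiq = min(38, cfg.n_catalog_samples)
    for s in range(cfg.n_catalog_samples):
        rows = []
        if s < n_ubiq:
            rows += [
                GenomicInterval(iv.chrom, iv.start - 500, iv.end + 500)
                for iv in stable
            ]
        if s == 0:
            rows += list(var_se)
        for _ in range(3):  # unrelated catalog SEs in utility space
            ci = int(rng.integers(cfg.n_chroms))
            b = int(rng.integers(cfg.chrom_length // PERIOD)) * PERIOD + 19 * BLOCK
            start = b + 42_000 + int(rng.integers(0, 2000))
            rows.append(GenomicInterval(f"chr{ci + 1}", start, start + 3000))
        io_formats.write_intervals(
            sdir / "catalog" / f"sample_{s:03d}.bed", rows, "bed3"
        )


def _emit_tissue_loops(plan: _Plan, outdir: Path, rng: np.random.Generator) -> None:
    cfg = plan.cfg
    tdir = outdir / "tissues"
    tdir.mkdir(parents=True, exist_ok=True)
    shared = [
        lp for lp in plan.loops if lp.cls == "stable" and lp.distal_kind == "enhancer"
        and lp.ctcf_feet > 0
    ]
    for t in range(cfg.n_tissues):
        rows = [
            Loop.canonical(lp.anchor1, lp.anchor2, samples={f"tissue{t}"})
            for lp in shared
        ]
        for n in range(5):  # tissue-unique loops in utility blocks
            ci = int(rng.integers(cfg.n_chroms))
            chrom = f"chr{ci + 1}"
            b = int(rng.integers(cfg.chrom_length // PERIOD)) * PERIOD + 19 * BLOCK
            a1 = GenomicInterval(chrom, b + 44_000, b + 45_000)
            a2 = GenomicInterval(chrom, b + 47_000 + n * 100, b + 48_000 + n * 100)
            rows.append(Loop.canonical(a1, a2, samples={f"tissue{t}"}))
        io_formats.write_loops(tdir / f"tissue_{t}.bedpe", rows)


def _emit_annotation(plan: _Plan, outdir: Path, rng: np.random.Generator) -> None:
    gene_ids = [g.gene_id for g in plan.genes]
    gmt = {
        "HOT_PATHWAY": set(plan.hot_genes),
        "DOWN_PATHWAY": set(plan.down_genes),
    }
    for i in range(8):
        gmt[f"RANDOM_{i}"] = set(
            rng.choice(gene_ids, size=20, replace=False).tolist()
        )
    io_formats.write_gmt(outdir / "annotation.gmt", gmt)


def _emit_emissions(plan: _Plan, outdir: Path) -> None:
    edir = outdir / "emissions"
    edir.mkdir(parents=True, exist_ok=True)
    models = make_nested_emissions(
        n_true=plan.cfg.n_true_states, seed=plan.cfg.seed
    )
    for m in models:
        df = pd.DataFrame(m.emissions, columns=m.marks)
        df.index.name = "state"
        df.to_csv(edir / f"model_{m.n_states}.tsv", sep="\t")


def _closest_gene_scan(plan: _Plan) -> dict[str, list[str]]:
    out = {}
    for v in plan.variants + [
        p for p in plan.proxies if p.r2 >= 0.8
    ]:
        best, bestd = [], None
        for g in plan.genes:
            if g.chrom != v.chrom:
                continue
            d = max(0, max(g.body.start, v.pos) - min(g.body.end, v.pos + 1))
            if bestd is None or d < bestd:
                best, bestd = [g.gene_id], d
            elif d == bestd:
                best.append(g.gene_id)
        out[v.rsid] = sorted(best)
    return out


def _peri_snp_scan(plan: _Plan, radius: int = 5000) -> dict:
    diff = {m: {"gained": [], "lost": []} for m in MARKS}
    for p in plan.peaks:
        if p.conditions == ("dex",):
            diff[p.mark]["gained"].append(p.interval)
        elif p.conditions == ("control",):
            diff[p.mark]["lost"].append(p.interval)
    out = {}
    for v in plan.variants:
        lo, hi = v.pos - radius, v.pos + radius + 1
        out[v.rsid] = {
            m: {
                cls: sum(
                    1
                    for iv in diff[m][cls]
                    if iv.chrom == v.chrom and iv.start < hi and lo < iv.end
                )
                for cls in ("gained", "lost")
            }
            for m in MARKS
        }
    return out


def _build_manifest(plan: _Plan) -> dict:
    cfg = plan.cfg
    loops = {
        cls: [
            {
                "id": lp.lid,
                "gene": lp.gene_id,
                "distal_kind": lp.distal_kind,
                "ctcf_feet": lp.ctcf_feet,
                "anchor1": [lp.anchor1.chrom, lp.anchor1.start, lp.anchor1.end],
                "anchor2": [lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.end],
            }
            for lp in plan.loops
            if lp.cls == cls
        ]
        for cls in ("stable", "gained", "lost", "decoy")
    }
    cand_ids, expressed = _erna_candidate_ids(plan)
    shared_loops = [
        lp.lid
        for lp in plan.loops
        if lp.cls == "stable" and lp.distal_kind == "enhancer" and lp.ctcf_feet > 0
    ]
    variant_loops = [
        lp.lid
        for lp in plan.loops
        if lp.gene_id is not None
        and any(g == lp.gene_id for _, g in plan.loop_assign)
    ]
    return {
        "config": asdict(cfg),
        "genes": {g.gene_id: [g.chrom, g.body.start, g.body.end, g.strand]
                  for g in plan.genes},
        "enhancer_states": {
            e.eid: {
                "interval": [e.interval.chrom, e.interval.start, e.interval.end],
                "control": e.state_control,
                "dex": e.state_dex,
                "erna_status": e.erna_status,
            }
            for e in plan.enhancers
        },
        "loops": loops,
        "super_enhancers": {
            "by_role": {
                role: [
                    [se.span.chrom, se.span.start, se.span.end]
                    for se in plan.ses
                    if se.role == role
                ]
                for role in ("stable", "gained", "lost", "variant_se", "loop_se")
            },
            "called_control_roles": ["stable", "lost", "variant_se", "loop_se"],
            "called_dex_roles": ["stable", "gained", "variant_se", "loop_se"],
            "resource_consensus_roles": [
                "stable", "variant_se", "loop_se", "gained"
            ],
            "catalog": {
                "tm_specific_roles": ["variant_se"],
                "tm_specific_fraction": 1 / cfg.n_catalog_samples,
                "ubiquitous_roles": ["stable"],
                "ubiquitous_fraction": min(38, cfg.n_catalog_samples)
                / cfg.n_catalog_samples,
            },
        },
        "compartment_flips": [
            {"chrom": c, "start": s, "end": e, "direction": d}
            for c, s, e, d in plan.flips
        ],
        "de_genes": {"up": plan.de_up, "down": plan.de_down},
        "variants": {
            "loop_assignments": sorted(plan.loop_assign),
            "se_assignments": sorted(plan.se_assign),
            "closest": _closest_gene_scan(plan),
            "compartment_labels": plan.compartment_labels,
            "peri_snp": _peri_snp_scan(plan),
            "decoys": [v.rsid for v in plan.variants if v.rsid.startswith("rs95")],
        },
        "ernas": {
            "candidates": cand_ids,
            "expressed": sorted(expressed),
        },
        "cross_tissue": {
            "shared_loop_ids": shared_loops,
            "shared_count": cfg.n_tissues,
            "tm_specific_loop_ids": variant_loops,
        },
        "emissions": {"n_true_states": cfg.n_true_states},
        "annotation": {
            "multiset_term": "HOT_PATHWAY",
            "hot_genes": plan.hot_genes,
        },
        "switch_gene_ids": plan.switch_gene_ids,
    }


def generate_dataset(config: SyntheticConfig, outdir) -> dict:
    """Write the full synthetic dataset to ``outdir``; returns the truth
    manifest (also saved as ``truth_manifest.json``).

    Deterministic given ``config.seed``: a single seed fans out to
    per-layer child generators, so two runs produce byte-identical
    files.
    """
    config.validate()
    outdir = Path(outdir)
    plan = _build_plan(config)
    outdir.mkdir(parents=True, exist_ok=True)
    (
        rng_peaks,
        rng_loops,
        rng_comp,
        rng_expr,
        rng_cat,
        rng_tis,
        rng_gmt,
    ) = _rng_children(config.seed, 7)

    io_formats.write_gene_models(outdir / "genes.gtf", plan.genes)
    io_formats.write_intervals(
        outdir / "enhancers.bed",
        [
            GenomicInterval(
                e.interval.chrom, e.interval.start, e.interval.end, name=e.eid
            )
            for e in plan.enhancers
        ],
        "bed6",
    )
    segments = [
        GenomicInterval(
            e.interval.chrom, e.interval.start, e.interval.end, name="enhancer"
        )
        for e in plan.enhancers
    ] + [
        GenomicInterval(g.chrom, g.tss - 500, g.tss + 500, name="promoter")
        for g in plan.genes
    ]
    io_formats.write_intervals(outdir / "state_segments.bed", segments, "bed6")
    io_formats.write_intervals(outdir / "repressors.bed", plan.repressors, "bed3")

    _emit_peaks(plan, outdir, rng_peaks)
    _emit_loops(plan, outdir, rng_loops)
    _emit_compartments(plan, outdir, rng_comp)
    _emit_expression(plan, outdir, rng_expr)
    _emit_variants(plan, outdir)
    _emit_se_catalogs(plan, outdir, rng_cat)
    _emit_tissue_loops(plan, outdir, rng_tis)
    _emit_annotation(plan, outdir, rng_gmt)
    _emit_emissions(plan, outdir)

    manifest = _build_manifest(plan)
    with open(outdir / "truth_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    return manifest


def load_manifest(dataset_dir) -> dict:
    with open(Path(dataset_dir) / "truth_manifest.json") as fh:
        return json.load(fh)
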