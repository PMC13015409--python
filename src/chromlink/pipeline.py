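"""End-to-end orchestration over a dataset directory.

``run_pipeline`` consumes the directory layout written by
``synthetic.generate_dataset`` (or user data arranged the same way),
executes every stage, writes per-stage tables to the output directory
and returns an in-memory :class:`PipelineResult` for programmatic use.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import (
    chromatin_states,
    compartments,
    ernas,
    integration,
    io_formats,
    loops as loops_mod,
    peaks as peaks_mod,
    super_enhancers,
    variant2gene,
)
from .core import GenomicInterval, PeakSet

logger = logging.getLogger(__name__)

MARKS = ("H3K27ac", "H3K27me3", "H3K4me1", "H3K4me3", "H3K36me3", "CTCF", "ATAC")


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    dataset_dir: str
    output_dir: str
    consensus_k: int = 2
    loop_k: int = 2
    n_replicates: int = 3
    stitch_gap: int = 12_500
    tss_exclusion: int = 2_500
    se_consensus_k: int = 4
    r2_min: float = 0.8
    peri_snp_radius: int = 5000
    compartment_delta: float = 0.3
    erna_merge_gap: int = 50
    erna_exclusion_radius: int = 3000
    erna_min_cpm: float = 1.0
    erna_min_samples: int = 2
    loop_quantile: float = 0.05
    fdr_max: float = 0.05
    min_sets: int = 4
    de_fdr_max: float = 0.05
    promoter_up: int = 2000
    promoter_down: int = 500

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    consensus: dict = field(default_factory=dict)  # (mark, cond) -> intervals
    diff_by_mark: dict = field(default_factory=dict)
    enhancer_elements: list = field(default_factory=list)
    se_calls: dict = field(default_factory=dict)  # cond -> [StitchedRegion]
    se_diff: Optional[object] = None
    se_resource_consensus: list = field(default_factory=list)
    se_specificity: list = field(default_factory=list)
    erna_candidates: list = field(default_factory=list)
    erna_expressed: list = field(default_factory=list)
    loop_consensus: dict = field(default_factory=dict)  # cond -> [Loop]
    loop_diff: Optional[object] = None
    annotations: list = field(default_factory=list)
    top_loop_genes: set = field(default_factory=set)
    shifted_windows: list = field(default_factory=list)
    signal_tests: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    leads: list = field(default_factory=list)
    loop_assignments: list = field(default_factory=list)
    se_assignments: list = field(default_factory=list)
    closest_assignments: list = field(default_factory=list)
    compartment_labels: dict = field(default_factory=dict)
    peri_snp: dict = field(default_factory=dict)
    de_genes: set = field(default_factory=set)
    gene_sets: dict = field(default_factory=dict)
    enrichments: dict = field(default_factory=dict)
    term_matrix: Optional[pd.DataFrame] = None
    cross_tissue: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _read_consensus(ddir: Path, cfg: RunConfig, mark: str, cond: str):
    sets = []
    for r in range(1, cfg.n_replicates + 1):
        path = ddir / "peaks" / f"{mark}.{cond}.rep{r}.narrowPeak"
        if not path.exists():
            raise FileNotFoundError(f"peak stage: missing input {path}")
        sets.append(
            PeakSet(
                mark=mark,
                condition=cond,
                replicate=str(r),
                intervals=io_formats.read_intervals(path, "narrowPeak"),
            )
        )
    return sets


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    ddir = Path(cfg.dataset_dir)
    outdir = Path(cfg.output_dir)
    for required in ("genes.gtf", "enhancers.bed"):
        if not (ddir / required).exists():
            raise FileNotFoundError(f"input not found: {ddir / required}")
    outdir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()

    genes = io_formats.read_gene_models(
        ddir / "genes.gtf", cfg.promoter_up, cfg.promoter_down
    )

    # ---- stage: replicate consensus and condition diff per mark ----------
    replicate_sets = {}
    for mark in MARKS:
        for cond in ("control", "dex"):
            sets = _read_consensus(ddir, cfg, mark, cond)
            replicate_sets[(mark, cond)] = sets
            res.consensus[(mark, cond)] = peaks_mod.consensus_peaks(
                sets, cfg.consensus_k
            )
        res.diff_by_mark[mark] = peaks_mod.diff_peaks(
            res.consensus[(mark, "control")],
            res.consensus[(mark, "dex")],
            mark=mark,
        )

    # ---- stage: enhancer states -----------------------------------------
    enhancers = io_formats.read_intervals(ddir / "enhancers.bed", "bed6")
    peaks_by_condition = {
        cond: {
            mark: res.consensus[(mark, cond)]
            for mark in ("H3K27ac", "H3K4me1", "H3K27me3")
        }
        for cond in ("control", "dex")
    }
    res.enhancer_elements = chromatin_states.classify_enhancers(
        enhancers, peaks_by_condition
    )

    # ---- stage: CREs and super-enhancers --------------------------------
    segments = [
        (iv, iv.name)
        for iv in io_formats.read_intervals(ddir / "state_segments.bed", "bed6")
    ]
    cres = chromatin_states.assemble_cres(segments)
    tss_windows = [
        GenomicInterval(
            g.chrom, max(0, g.tss - cfg.tss_exclusion), g.tss + cfg.tss_exclusion
        )
        for g in genes
    ]
    for cond in ("control", "dex"):
        k27_replicates = [
            iv for ps in replicate_sets[("H3K27ac", cond)] for iv in ps.intervals
        ]
        res.se_calls[cond] = super_enhancers.call_super_enhancers(
            cres, k27_replicates, cfg.stitch_gap, tss_windows
        )
    control_ses = [r.interval for r in res.se_calls["control"] if r.is_super]
    dex_ses = [r.interval for r in res.se_calls["dex"] if r.is_super]
    res.se_diff = super_enhancers.se_diff(control_ses, dex_ses)

    resource_files = sorted((ddir / "se").glob("resource_set*.bed"))
    if resource_files:
        se_sets = [io_formats.read_intervals(p, "bed3") for p in resource_files]
        res.se_resource_consensus = super_enhancers.se_consensus(
            se_sets, cfg.se_consensus_k
        )
    catalog_files = sorted((ddir / "se" / "catalog").glob("*.bed"))
    if catalog_files:
        catalog = {
            p.stem: io_formats.read_intervals(p, "bed3") for p in catalog_files
        }
        res.se_specificity = super_enhancers.se_tissue_specificity(
            control_ses, catalog
        )

    # ---- stage: eRNA candidates and expression --------------------------
    k4me3 = res.consensus[("H3K4me3", "control")]
    candidates = ernas.call_erna_candidates(
        enhancers, genes, k4me3, cfg.erna_merge_gap, cfg.erna_exclusion_radius
    )
    for c in candidates:  # stable region ids for the count matrix
        iv = c.interval
        c.interval = GenomicInterval(
            iv.chrom, iv.start, iv.end, name=f"{iv.chrom}:{iv.start}-{iv.end}"
        )
    res.erna_candidates = candidates
    erna_counts_path = ddir / "expression" / "erna_counts.tsv"
    if erna_counts_path.exists():
        erna_counts = io_formats.read_counts(erna_counts_path)
        res.erna_expressed = ernas.filter_expressed(
            candidates, erna_counts, cfg.erna_min_cpm, cfg.erna_min_samples
        )

    # ---- stage: loops ----------------------------------------------------
    sample_loops = {"control": {}, "dex": {}}
    for path in sorted((ddir / "loops").glob("*.bedpe")):
        sample = path.stem
        cond = "control" if sample.startswith("control") else "dex"
        sample_loops[cond][sample] = io_formats.read_loops(path, sample)
    for cond in ("control", "dex"):
        res.loop_consensus[cond] = loops_mod.loop_consensus(
            sample_loops[cond], cfg.loop_k
        )
    res.loop_diff = loops_mod.loop_diff(
        res.loop_consensus["control"], res.loop_consensus["dex"]
    )

    # ---- stage: variants -------------------------------------------------
    res.leads = variant2gene.read_variants(ddir / "variants" / "leads.tsv")
    proxies = variant2gene.read_variants(ddir / "variants" / "proxies.tsv")
    res.variants = variant2gene.expand_ld(res.leads, proxies, cfg.r2_min)

    # ---- stage: anchor annotation ---------------------------------------
    repressors = io_formats.read_intervals(ddir / "repressors.bed", "bed3")
    se_union = control_ses + [
        iv
        for iv in dex_ses
        if not any(iv.overlaps(c) for c in control_ses)
    ]
    all_loops = (
        res.loop_diff.stable + res.loop_diff.gained + res.loop_diff.lost
    )
    res.annotations = loops_mod.annotate_anchors(
        all_loops,
        genes=genes,
        cres_by_class={
            "enhancer": enhancers,
            "repressor": repressors,
            "super_enhancer": se_union,
        },
        ctcf_peaks=res.consensus[("CTCF", "control")],
        variants=res.variants,
    )
    res.top_loop_genes = loops_mod.top_loop_change_genes(
        res.loop_diff, res.annotations, cfg.loop_quantile
    )

    # ---- stage: compartments --------------------------------------------
    control_track = io_formats.read_intervals(
        ddir / "compartments" / "score.control.bedgraph", "bedgraph"
    )
    dex_track = io_formats.read_intervals(
        ddir / "compartments" / "score.dex.bedgraph", "bedgraph"
    )
    res.shifted_windows = compartments.detect_shifts(
        control_track, dex_track, "delta_threshold", cfg.compartment_delta
    )
    deltas_path = ddir / "compartments" / "signal_deltas.tsv"
    if deltas_path.exists():
        deltas = pd.read_csv(deltas_path, sep="\t", index_col=0)
        by_dir: dict[str, list[str]] = {"toward_A": [], "toward_B": []}
        for w in res.shifted_windows:
            if w.shift in by_dir:
                key = f"{w.interval.chrom}:{w.interval.start}-{w.interval.end}"
                by_dir[w.shift].append(key)
        for direction, keys in by_dir.items():
            keys = [k for k in keys if k in deltas.index]
            if len(keys) < 2:
                continue
            for mark in deltas.columns:
                res.signal_tests.append(
                    compartments.signal_shift_test(
                        deltas.loc[keys, mark].to_numpy(), mark, direction
                    )
                )

    # ---- stage: variant-to-gene -----------------------------------------
    for loop_set, cond_loops in (
        ("control", res.loop_consensus["control"]),
        ("dex", res.loop_consensus["dex"]),
    ):
        res.loop_assignments += variant2gene.loop_targets(
            res.variants, cond_loops, genes, loop_set=loop_set
        )
    res.se_assignments = variant2gene.se_targets(res.variants, control_ses, genes)
    res.closest_assignments = variant2gene.closest_genes(res.leads, genes)
    res.compartment_labels = variant2gene.snp_compartment_overlap(
        res.leads, res.shifted_windows
    )
    res.peri_snp = variant2gene.peri_snp_peak_changes(
        res.leads, res.diff_by_mark, cfg.peri_snp_radius
    )

    # ---- stage: cross-tissue sharing ------------------------------------
    tissue_files = sorted((ddir / "tissues").glob("*.bedpe"))
    if tissue_files:
        catalogs = {
            p.stem: io_formats.read_loops(p, p.stem) for p in tissue_files
        }
        res.cross_tissue = loops_mod.cross_tissue_sharing(
            res.loop_consensus["control"], catalogs
        )

    # ---- stage: gene sets and enrichment --------------------------------
    de_table = io_formats.read_de_table(ddir / "expression" / "de_table.tsv")
    de_sig = de_table[de_table["FDR"] <= cfg.de_fdr_max]
    res.de_genes = set(de_sig["gene_id"])
    # CRE gains/losses follow the per-mark peak dynamics restricted to CREs
    cre_diff = _cre_diff(cres, res.diff_by_mark)
    res.gene_sets = integration.build_gene_sets(
        genes=genes,
        de_table=de_sig,
        shifted_windows=res.shifted_windows,
        diff_atac=res.diff_by_mark["ATAC"],
        diff_se=res.se_diff,
        diff_cre=cre_diff,
        enhancer_elements=res.enhancer_elements,
        diff_by_mark=res.diff_by_mark,
        loop_diff=res.loop_diff,
        annotations=res.annotations,
        top_loop_genes=res.top_loop_genes,
    )
    gmt_path = ddir / "annotation.gmt"
    if gmt_path.exists():
        annotation = io_formats.read_gmt(gmt_path)
        universe = {g.gene_id for g in genes}
        for name, gene_set in res.gene_sets.items():
            res.enrichments[name] = integration.hypergeom_ora(
                gene_set & universe, annotation, universe, set_name=name
            )
        res.term_matrix = integration.term_set_matrix(
            res.enrichments, cfg.fdr_max, cfg.min_sets
        )

    _write_outputs(res, cfg, outdir)
    return res


def _cre_diff(cres, diff_by_mark):
    """A CRE counts as gained/lost when it overlaps a gained/lost peak
    of any enhancer/promoter-defining mark and no stable one."""
    from .core import IntervalIndex

    marks = ("H3K27ac", "H3K4me1", "H3K4me3")
    gained_idx = IntervalIndex(
        [iv for m in marks for iv in diff_by_mark[m].gained]
    )
    lost_idx = IntervalIndex([iv for m in marks for iv in diff_by_mark[m].lost])
    out = peaks_mod.DiffPeaks(mark="CRE")
    for cre in cres:
        g = gained_idx.any_overlap(cre)
        l = lost_idx.any_overlap(cre)
        if g and not l:
            out.gained.append(cre)
        elif l and not g:
            out.lost.append(cre)
        else:
            out.stable.append(cre)
    return out


def _write_outputs(res: PipelineResult, cfg: RunConfig, outdir: Path) -> None:
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    for (mark, cond), ivs in res.consensus.items():
        io_formats.write_intervals(
            outdir / f"consensus.{mark}.{cond}.bed", ivs, "bed6"
        )
    rows = []
    for e in res.enhancer_elements:
        rows.append(
            {
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "state_control": e.state_control,
                "state_dex": e.state_treated,
                "switch": e.switch,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "enhancer_states.tsv", sep="\t", index=False)
    for cond, regions in res.se_calls.items():
        pd.DataFrame(
            [
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "rank": r.rank,
                    "signal": r.signal,
                    "is_super": r.is_super,
                }
                for r in regions
            ]
        ).to_csv(outdir / f"se_calls.{cond}.tsv", sep="\t", index=False)
    assign_rows = [
        asdict(a)
        for a in (
            res.loop_assignments + res.se_assignments + res.closest_assignments
        )
    ]
    pd.DataFrame(assign_rows).to_csv(
        outdir / "variant_targets.tsv", sep="\t", index=False
    )
    if res.term_matrix is not None:
        res.term_matrix.to_csv(outdir / "term_set_matrix.tsv", sep="\t")
    pd.DataFrame(
        [asdict(t) for t in res.signal_tests]
    ).to_csv(outdir / "compartment_signal_tests.tsv", sep="\t", index=False)

    res.summary = {
        "consensus_peaks": {
            f"{mark}.{cond}": len(ivs) for (mark, cond), ivs in res.consensus.items()
        },
        "diff_peaks": {
            mark: {
                "gained": len(d.gained),
                "lost": len(d.lost),
                "stable": len(d.stable),
            }
            for mark, d in res.diff_by_mark.items()
        },
        "super_enhancers": {
            cond: sum(1 for r in regions if r.is_super)
            for cond, regions in res.se_calls.items()
        },
        "loops": {
            "control": len(res.loop_consensus.get("control", [])),
            "dex": len(res.loop_consensus.get("dex", [])),
            "stable": len(res.loop_diff.stable) if res.loop_diff else 0,
            "gained": len(res.loop_diff.gained) if res.loop_diff else 0,
            "lost": len(res.loop_diff.lost) if res.loop_diff else 0,
        },
        "shifted_windows": sum(
            1 for w in res.shifted_windows if w.shift != "none"
        ),
        "erna": {
            "candidates": sum(1 for c in res.erna_candidates if c.passed_all),
            "expressed": len(res.erna_expressed),
        },
        "assignments": {
            "loop": len({(a.variant, a.gene_id) for a in res.loop_assignments}),
            "super_enhancer": len(
                {(a.variant, a.gene_id) for a in res.se_assignments}
            ),
            "closest": len(res.closest_assignments),
        },
        "de_genes": len(res.de_genes),
        "term_matrix_shape": list(res.term_matrix.shape)
        if res.term_matrix is not None
        else [0, 0],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
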