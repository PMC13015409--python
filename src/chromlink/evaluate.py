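"""Score pipeline outputs against a synthetic truth manifest.

Each function returns ``{"precision": float, "recall": float, ...}``
for one planted layer; :func:`evaluate_all` aggregates them.  Matching
is by exact key where the pipeline reproduces input coordinates
(windows, enhancer ids, eRNA region ids, variant-gene pairs) and by
two-anchor / interval overlap where replicate jitter moves boundaries
(loops, SE spans).
"""
from __future__ import annotations

from typing import Sequence

from .core import GenomicInterval, Loop
from .loops import loops_match
from .pipeline import PipelineResult


def _pr(n_hit_truth: int, n_truth: int, n_hit_called: int, n_called: int) -> dict:
    return {
        "recall": n_hit_truth / n_truth if n_truth else 1.0,
        "precision": n_hit_called / n_called if n_called else 1.0,
        "n_truth": n_truth,
        "n_called": n_called,
    }


def _truth_loop(rec: dict) -> Loop:
    a1 = GenomicInterval(*rec["anchor1"][:1], rec["anchor1"][1], rec["anchor1"][2])
    a2 = GenomicInterval(*rec["anchor2"][:1], rec["anchor2"][1], rec["anchor2"][2])
    return Loop.canonical(a1, a2)


def score_loop_diff(result: PipelineResult, manifest: dict) -> dict:
    out = {}
    called = {
        "stable": result.loop_diff.stable,
        "gained": result.loop_diff.gained,
        "lost": result.loop_diff.lost,
    }
    # stable loops appear twice (control + treated representative)
    for cls in ("stable", "gained", "lost"):
        truth = [_truth_loop(r) for r in manifest["loops"][cls]]
        hit_truth = sum(
            1 for t in truth if any(loops_match(t, c) for c in called[cls])
        )
        hit_called = sum(
            1 for c in called[cls] if any(loops_match(t, c) for t in truth)
        )
        out[cls] = _pr(hit_truth, len(truth), hit_called, len(called[cls]))
    return out


def score_se_calls(result: PipelineResult, manifest: dict) -> dict:
    roles = manifest["super_enhancers"]["by_role"]
    out = {}
    for cond, role_key in (
        ("control", "called_control_roles"),
        ("dex", "called_dex_roles"),
    ):
        truth = [
            GenomicInterval(c, s, e)
            for role in manifest["super_enhancers"][role_key]
            for c, s, e in roles[role]
        ]
        called = [r.interval for r in result.se_calls[cond] if r.is_super]
        hit_truth = sum(1 for t in truth if any(t.overlaps(c) for c in called))
        hit_called = sum(1 for c in called if any(t.overlaps(c) for t in truth))
        out[cond] = _pr(hit_truth, len(truth), hit_called, len(called))
    return out


def score_se_diff(result: PipelineResult, manifest: dict) -> dict:
    roles = manifest["super_enhancers"]["by_role"]
    out = {}
    for cls in ("gained", "lost"):
        truth = [GenomicInterval(c, s, e) for c, s, e in roles[cls]]
        called = getattr(result.se_diff, cls)
        hit_truth = sum(1 for t in truth if any(t.overlaps(c) for c in called))
        hit_called = sum(1 for c in called if any(t.overlaps(c) for t in truth))
        out[cls] = _pr(hit_truth, len(truth), hit_called, len(called))
    return out


def score_enhancer_switches(result: PipelineResult, manifest: dict) -> dict:
    truth = manifest["enhancer_states"]
    by_key = {
        (e.interval.chrom, e.interval.start, e.interval.end): e
        for e in result.enhancer_elements
    }
    n_match = 0
    n = 0
    for rec in truth.values():
        c, s, e = rec["interval"]
        called = by_key.get((c, s, e))
        n += 1
        if (
            called is not None
            and called.state_control == rec["control"]
            and called.state_treated == rec["dex"]
        ):
            n_match += 1
    return {"n": n, "state_accuracy": n_match / n if n else 1.0}


def score_compartments(result: PipelineResult, manifest: dict) -> dict:
    truth = {
        (f["chrom"], f["start"], f["end"]): f["direction"]
        for f in manifest["compartment_flips"]
    }
    called = {
        (w.interval.chrom, w.interval.start, w.interval.end): w.shift
        for w in result.shifted_windows
        if w.shift != "none"
    }
    hit_truth = sum(1 for k, d in truth.items() if called.get(k) == d)
    hit_called = sum(1 for k, d in called.items() if truth.get(k) == d)
    return _pr(hit_truth, len(truth), hit_called, len(called))


def score_ernas(result: PipelineResult, manifest: dict) -> dict:
    truth = set(manifest["ernas"]["expressed"])
    called = {c.interval.name for c in result.erna_expressed}
    return _pr(
        len(truth & called), len(truth), len(called & truth), len(called)
    )


def score_variant_assignments(result: PipelineResult, manifest: dict) -> dict:
    out = {}
    truth_loop = {tuple(t) for t in manifest["variants"]["loop_assignments"]}
    called_loop = {(a.variant, a.gene_id) for a in result.loop_assignments}
    out["loop"] = _pr(
        len(truth_loop & called_loop),
        len(truth_loop),
        len(called_loop & truth_loop),
        len(called_loop),
    )
    truth_se = {tuple(t) for t in manifest["variants"]["se_assignments"]}
    called_se = {(a.variant, a.gene_id) for a in result.se_assignments}
    out["super_enhancer"] = _pr(
        len(truth_se & called_se),
        len(truth_se),
        len(called_se & truth_se),
        len(called_se),
    )
    truth_closest = manifest["variants"]["closest"]
    called_closest: dict[str, set] = {}
    for a in result.closest_assignments:
        called_closest.setdefault(a.variant, set()).add(a.gene_id)
    n_lead = 0
    n_match = 0
    for rsid, genes in truth_closest.items():
        if rsid not in called_closest:
            continue
        n_lead += 1
        if called_closest[rsid] == set(genes):
            n_match += 1
    out["closest"] = {"n": n_lead, "accuracy": n_match / n_lead if n_lead else 1.0}
    truth_comp = manifest["variants"]["compartment_labels"]
    n_comp = sum(
        1
        for rsid, lab in truth_comp.items()
        if result.compartment_labels.get(rsid) == lab
    )
    out["compartment"] = {
        "n": len(truth_comp),
        "accuracy": n_comp / len(truth_comp) if truth_comp else 1.0,
    }
    truth_peri = manifest["variants"]["peri_snp"]
    n_peri = 0
    n_peri_match = 0
    for rsid, per_mark in truth_peri.items():
        called = result.peri_snp.get(rsid)
        if called is None:
            continue
        n_peri += 1
        if all(
            called[m]["gained"] == per_mark[m]["gained"]
            and called[m]["lost"] == per_mark[m]["lost"]
            for m in per_mark
        ):
            n_peri_match += 1
    out["peri_snp"] = {
        "n": n_peri,
        "accuracy": n_peri_match / n_peri if n_peri else 1.0,
    }
    return out


def score_de(result: PipelineResult, manifest: dict) -> dict:
    truth = set(manifest["de_genes"]["up"]) | set(manifest["de_genes"]["down"])
    called = result.de_genes
    return _pr(
        len(truth & called), len(truth), len(called & truth), len(called)
    )


def score_cross_tissue(result: PipelineResult, manifest: dict) -> dict:
    truth_shared = manifest["cross_tissue"]["shared_loop_ids"]
    expect = manifest["cross_tissue"]["shared_count"]
    loops_by_cls = {
        rec["id"]: _truth_loop(rec)
        for cls in ("stable", "gained", "lost")
        for rec in manifest["loops"][cls]
    }
    counts = {
        rec["loop"].key: rec["n_tissues"] for rec in result.cross_tissue
    }

    def count_for(lid):
        t = loops_by_cls[lid]
        for rec in result.cross_tissue:
            if loops_match(t, rec["loop"]):
                return rec["n_tissues"]
        return None

    shared_ok = sum(1 for lid in truth_shared if count_for(lid) == expect)
    specific = manifest["cross_tissue"]["tm_specific_loop_ids"]
    specific_ok = sum(1 for lid in specific if count_for(lid) == 0)
    return {
        "shared_n": len(truth_shared),
        "shared_correct": shared_ok,
        "specific_n": len(specific),
        "specific_correct": specific_ok,
    }


def evaluate_all(result: PipelineResult, manifest: dict) -> dict:
    return {
        "loop_diff": score_loop_diff(result, manifest),
        "se_calls": score_se_calls(result, manifest),
        "se_diff": score_se_diff(result, manifest),
        "enhancer_states": score_enhancer_switches(result, manifest),
        "compartment_shifts": score_compartments(result, manifest),
        "ernas": score_ernas(result, manifest),
        "variants": score_variant_assignments(result, manifest),
        "de_genes": score_de(result, manifest),
        "cross_tissue": score_cross_tissue(result, manifest),
    }
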