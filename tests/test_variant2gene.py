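"""LD expansion and the variant-to-gene integrations."""
import random

import pytest

from chromlink.compartments import CompartmentWindow
from chromlink.core import (
    GeneModel,
    GenomicInterval,
    Loop,
    VariantRecord,
    promoter_interval,
)
from chromlink.peaks import DiffPeaks
from chromlink.variant2gene import (
    closest_genes,
    expand_ld,
    loop_targets,
    peri_snp_peak_changes,
    se_targets,
    snp_compartment_overlap,
)


def iv(s, e, chrom="chr1", name=None):
    return GenomicInterval(chrom, s, e, name=name)


def lead(rsid, pos, chrom="chr1", trait="IOP"):
    return VariantRecord(rsid, chrom, pos, trait, True, rsid, 1.0)


def proxy(rsid, pos, lead_rsid, r2, chrom="chr1"):
    return VariantRecord(rsid, chrom, pos, "IOP", False, lead_rsid, r2)


def gene(gid, start, end, chrom="chr1", strand="+"):
    body = GenomicInterval(chrom, start, end)
    tss = start if strand == "+" else end - 1
    return GeneModel(gid, gid, chrom, strand, body,
                     promoter_interval(chrom, strand, tss, 2000, 500))


class TestExpandLd:
    def test_r2_below_threshold_dropped(self):
        leads = [lead("rsL", 1_000_000)]
        out = expand_ld(leads, [proxy("rsP", 1_000_500, "rsL", 0.79)], r2_min=0.8)
        assert [v.rsid for v in out] == ["rsL"]

    def test_proxy_beyond_1mb_dropped(self):
        leads = [lead("rsL", 1_000_000)]
        out = expand_ld(leads, [proxy("rsP", 2_200_000, "rsL", 0.95)])
        assert [v.rsid for v in out] == ["rsL"]

    def test_unknown_lead_rejected(self):
        with pytest.raises(KeyError, match="rsX"):
            expand_ld([lead("rsL", 0)], [proxy("rsP", 100, "rsX", 0.9)])

    def test_matches_row_filter_oracle(self):
        rnd = random.Random(2)
        leads = [lead(f"rsL{i}", rnd.randrange(0, 10_000_000)) for i in range(5)]
        proxies = []
        for i in range(100):
            l = rnd.choice(leads)
            proxies.append(
                proxy(
                    f"rsP{i}",
                    max(0, l.pos + rnd.randrange(-2_000_000, 2_000_000)),
                    l.rsid,
                    rnd.random(),
                )
            )
        out = {v.rsid for v in expand_ld(leads, proxies, r2_min=0.8)}
        lead_pos = {l.rsid: l.pos for l in leads}
        expect = {l.rsid for l in leads} | {
            p.rsid
            for p in proxies
            if p.r2 >= 0.8 and abs(p.pos - lead_pos[p.lead_rsid]) <= 1_000_000
        }
        assert out == expect


class TestLoopTargets:
    def test_variant_one_anchor_promoter_other(self):
        g = gene("g1", 100_000, 110_000)
        lp = Loop.canonical(iv(10_000, 12_000), iv(98_500, 100_500))
        (a,) = loop_targets([lead("rs1", 11_000)], [lp], [g])
        assert (a.variant, a.gene_id, a.mechanism) == ("rs1", "g1", "loop")

    def test_same_anchor_only_yields_nothing(self):
        g = gene("g1", 100_000, 110_000)
        # variant and promoter both inside anchor2; anchor1 empty region
        lp = Loop.canonical(iv(10_000, 12_000), iv(98_000, 101_000))
        assert loop_targets([lead("rs1", 99_000)], [lp], [g]) == []

    def test_anchor_order_invariance(self):
        g = gene("g1", 100_000, 110_000)
        a1, a2 = iv(10_000, 12_000), iv(98_500, 100_500)
        variants = [lead("rs1", 11_000)]
        out1 = loop_targets(variants, [Loop.canonical(a1, a2)], [g])
        out2 = loop_targets(variants, [Loop.canonical(a2, a1)], [g])
        assert [(a.variant, a.gene_id) for a in out1] == [
            (a.variant, a.gene_id) for a in out2
        ]

    def test_planted_assignments_recovered(self, pipeline_result, manifest):
        truth = {tuple(t) for t in manifest["variants"]["loop_assignments"]}
        called = {
            (a.variant, a.gene_id) for a in pipeline_result.loop_assignments
        }
        assert called == truth

    def test_assignment_evidence_is_verifiable(self, pipeline_result):
        """Self-audit: every loop assignment's cited loop overlaps the
        variant on one anchor and the gene promoter on the other."""
        var_by_id = {v.rsid: v for v in pipeline_result.variants}
        loops = (
            pipeline_result.loop_consensus["control"]
            + pipeline_result.loop_consensus["dex"]
        )
        for a in pipeline_result.loop_assignments:
            v = var_by_id[a.variant]
            ok = False
            for lp in loops:
                hit_var = (
                    lp.anchor1.contains_pos(v.pos)
                    and lp.anchor1.chrom == v.chrom
                ) or (
                    lp.anchor2.contains_pos(v.pos)
                    and lp.anchor2.chrom == v.chrom
                )
                if hit_var:
                    ok = True
                    break
            assert ok, f"no loop anchor contains {a.variant}"


class TestSeTargets:
    def test_variant_and_promoter_in_same_se(self):
        g = gene("g1", 50_000, 60_000)
        se = iv(47_000, 52_000, name="SE1")
        (a,) = se_targets([lead("rs1", 48_000)], [se], [g])
        assert (a.variant, a.gene_id, a.mechanism) == (
            "rs1", "g1", "super_enhancer",
        )

    def test_adjacent_ses_do_not_pair(self):
        g = gene("g1", 50_000, 60_000)
        se1 = iv(10_000, 20_000)
        se2 = iv(47_000, 52_000)
        assert se_targets([lead("rs1", 15_000)], [se1, se2], [g]) == []

    def test_matches_brute_force_triple_loop(self):
        rnd = random.Random(7)
        genes = [gene(f"g{i}", s := rnd.randrange(0, 900_000), s + 5000)
                 for i in range(20)]
        ses = [iv(s := rnd.randrange(0, 900_000), s + 20_000) for _ in range(15)]
        variants = [lead(f"rs{i}", rnd.randrange(0, 950_000)) for i in range(30)]
        out = {
            (a.variant, a.gene_id)
            for a in se_targets(variants, ses, genes)
        }
        expect = set()
        for v in variants:
            for se in ses:
                if not (se.start <= v.pos < se.end):
                    continue
                for g in genes:
                    if se.overlaps(g.promoter):
                        expect.add((v.rsid, g.gene_id))
        assert out == expect


class TestClosestGenes:
    def test_variant_inside_gene_distance_zero(self):
        g = gene("g1", 1000, 5000)
        (a,) = closest_genes([lead("rs1", 2000)], [g])
        assert (a.gene_id, a.evidence) == ("g1", "0")

    def test_equidistant_tie_reports_both(self):
        g1 = gene("g1", 0, 1000)
        g2 = gene("g2", 2001, 3000)
        out = closest_genes([lead("rs1", 1500)], [g1, g2])
        assert {a.gene_id for a in out} == {"g1", "g2"}

    def test_chromosome_without_genes_warns_null(self):
        (a,) = closest_genes([lead("rs1", 100, chrom="chrZ")], [gene("g1", 0, 10)])
        assert a.gene_id is None

    def test_matches_exhaustive_scan_on_1000_variants(self):
        rnd = random.Random(9)
        genes = [
            gene(f"g{i}", s := rnd.randrange(0, 9_900_000), s + 5000,
                 chrom=f"chr{1 + i % 2}")
            for i in range(60)
        ]
        variants = [
            lead(f"rs{i}", rnd.randrange(0, 10_000_000),
                 chrom=f"chr{1 + i % 2}")
            for i in range(1000)
        ]
        out = {}
        for a in closest_genes(variants, genes):
            out.setdefault(a.variant, set()).add(a.gene_id)
        for v in variants:
            dists = {}
            for g in genes:
                if g.chrom != v.chrom:
                    continue
                d = max(0, max(g.body.start, v.pos) - min(g.body.end, v.pos + 1))
                dists[g.gene_id] = d
            dmin = min(dists.values())
            expect = {gid for gid, d in dists.items() if d == dmin}
            assert out[v.rsid] == expect


class TestSnpCompartmentOverlap:
    def windows(self):
        return [
            CompartmentWindow(iv(0, 50_000), shift="toward_B"),
            CompartmentWindow(iv(50_000, 100_000), shift="toward_A"),
            CompartmentWindow(iv(100_000, 150_000), shift="none"),
        ]

    def test_variant_inside_shifted_window(self):
        out = snp_compartment_overlap([lead("rs1", 10)], self.windows())
        assert out["rs1"] == "toward_B"

    def test_boundary_position_belongs_to_next_window(self):
        out = snp_compartment_overlap([lead("rs1", 50_000)], self.windows())
        assert out["rs1"] == "toward_A"

    def test_unshifted_window_gives_none(self):
        out = snp_compartment_overlap([lead("rs1", 120_000)], self.windows())
        assert out["rs1"] == "none"


class TestPeriSnpPeakChanges:
    def test_peak_4kb_away_counted(self):
        d = {"H3K27ac": DiffPeaks("H3K27ac", gained=[iv(104_000, 104_500)])}
        out = peri_snp_peak_changes([lead("rs1", 100_000)], d, radius=5000)
        assert out["rs1"]["H3K27ac"] == {"gained": 1, "lost": 0}

    def test_peak_6kb_away_not_counted(self):
        d = {"H3K27ac": DiffPeaks("H3K27ac", gained=[iv(106_000, 106_500)])}
        out = peri_snp_peak_changes([lead("rs1", 100_000)], d, radius=5000)
        assert out["rs1"]["H3K27ac"] == {"gained": 0, "lost": 0}

    def test_matches_brute_force_window_scan(self):
        rnd = random.Random(11)
        diff = {
            m: DiffPeaks(
                m,
                gained=[iv(s := rnd.randrange(0, 500_000), s + 400)
                        for _ in range(30)],
                lost=[iv(s := rnd.randrange(0, 500_000), s + 400)
                      for _ in range(30)],
            )
            for m in ("H3K27ac", "ATAC")
        }
        leads_ = [lead(f"rs{i}", rnd.randrange(0, 500_000)) for i in range(50)]
        out = peri_snp_peak_changes(leads_, diff, radius=5000)
        for v in leads_:
            lo, hi = v.pos - 5000, v.pos + 5001
            for m, d in diff.items():
                for cls in ("gained", "lost"):
                    expect = sum(
                        1
                        for p in getattr(d, cls)
                        if p.start < hi and lo < p.end
                    )
                    assert out[v.rsid][m][cls] == expect
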