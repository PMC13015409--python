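"""Two-anchor loop matching, consensus, diff, annotation, ranking."""
import random

import pytest
from hypothesis import given, settings, strategies as st

from chromlink.core import GeneModel, GenomicInterval, Loop, promoter_interval
from chromlink.loops import (
    annotate_anchors,
    cross_tissue_sharing,
    loop_consensus,
    loop_diff,
    loops_match,
    top_loop_change_genes,
    LoopDiff,
)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def mkloop(s1, e1, s2, e2, chrom="chr1", samples=()):
    return Loop.canonical(iv(s1, e1, chrom), iv(s2, e2, chrom), samples=samples)


loop_st = st.builds(
    lambda s1, w1, s2, w2: mkloop(s1, s1 + w1, s2, s2 + w2),
    st.integers(0, 50_000),
    st.integers(100, 3000),
    st.integers(0, 50_000),
    st.integers(100, 3000),
)


class TestLoopsMatch:
    def test_jittered_anchors_match(self):
        a = mkloop(100, 200, 5000, 5100)
        b = mkloop(150, 250, 5050, 5150)
        assert loops_match(a, b)

    def test_swapped_anchor_order_matches(self):
        a = mkloop(100, 200, 5000, 5100)
        b = Loop.canonical(iv(5050, 5150), iv(150, 250))
        assert loops_match(a, b)

    def test_against_direct_four_way_overlap(self):
        rnd = random.Random(0)
        for _ in range(200):
            a = mkloop(
                rnd.randrange(0, 20_000), rnd.randrange(20_000, 21_000),
                rnd.randrange(0, 20_000), rnd.randrange(20_000, 21_000),
            )
            b = mkloop(
                rnd.randrange(0, 20_000), rnd.randrange(20_000, 21_000),
                rnd.randrange(0, 20_000), rnd.randrange(20_000, 21_000),
            )
            direct = (
                a.anchor1.overlaps(b.anchor1) and a.anchor2.overlaps(b.anchor2)
            ) or (a.anchor1.overlaps(b.anchor2) and a.anchor2.overlaps(b.anchor1))
            assert loops_match(a, b) == direct

    @settings(max_examples=100, derandomize=True)
    @given(loop_st, loop_st)
    def test_symmetric(self, a, b):
        assert loops_match(a, b) == loops_match(b, a)

    @settings(max_examples=50, derandomize=True)
    @given(loop_st)
    def test_reflexive(self, a):
        assert loops_match(a, a)


class TestLoopConsensus:
    def test_two_of_three_samples_retained(self):
        base = mkloop(1000, 2000, 9000, 10_000)
        out = loop_consensus({"s1": [base], "s2": [base], "s3": []}, k=2)
        assert len(out) == 1 and out[0].samples == frozenset({"s1", "s2"})

    def test_singleton_dropped(self):
        out = loop_consensus({"s1": [mkloop(0, 100, 500, 600)], "s2": []}, k=2)
        assert out == []

    def test_monotone_in_k(self):
        rnd = random.Random(3)
        sample_loops = {}
        for s in range(4):
            loops = []
            for i in range(15):
                b = 10_000 + i * 10_000
                j = rnd.randrange(-50, 50)
                if rnd.random() < 0.7:
                    loops.append(mkloop(b + j, b + 1000 + j, b + 5000, b + 6000))
            sample_loops[f"s{s}"] = loops
        prev = None
        for k in (1, 2, 3, 4):
            out = loop_consensus(sample_loops, k)
            if prev is not None:
                # every k-consensus loop matches a (k-1)-consensus loop
                for lp in out:
                    assert any(loops_match(lp, q) for q in prev)
            prev = out

    def test_matches_brute_force_transitive_clusters(self):
        rnd = random.Random(5)
        tagged = []
        for s in range(3):
            for i in range(12):
                b = rnd.randrange(0, 30) * 3000
                tagged.append(
                    (f"s{s}", mkloop(b, b + 1500, b + 9000, b + 10_500))
                )
        sample_loops = {}
        for s, lp in tagged:
            sample_loops.setdefault(s, []).append(lp)
        out = loop_consensus(sample_loops, k=2)
        # brute force: union-find over all pairs
        loops = [
            Loop.canonical(lp.anchor1, lp.anchor2, samples={s})
            for s, lp in tagged
        ]
        parent = list(range(len(loops)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(loops)):
            for j in range(i + 1, len(loops)):
                if loops_match(loops[i], loops[j]):
                    parent[find(j)] = find(i)
        clusters = {}
        for i, lp in enumerate(loops):
            clusters.setdefault(find(i), []).append(lp)
        expect = []
        for members in clusters.values():
            samples = frozenset(s for lp in members for s in lp.samples)
            if len(samples) >= 2:
                expect.append(samples)
        assert sorted(tuple(sorted(lp.samples)) for lp in out) == sorted(
            tuple(sorted(s)) for s in expect
        )


class TestLoopDiff:
    def test_disjoint_sets_all_lost_and_gained(self):
        c = [mkloop(0, 100, 5000, 5100)]
        t = [mkloop(20_000, 20_100, 30_000, 30_100)]
        d = loop_diff(c, t)
        assert d.lost == c and d.gained == t and not d.stable

    def test_identical_sets_all_stable(self):
        c = [mkloop(0, 100, 5000, 5100)]
        d = loop_diff(c, list(c))
        assert not d.lost and not d.gained and len(d.stable) == 2

    def test_planted_diff_recovered(self, pipeline_result, manifest):
        for cls in ("gained", "lost"):
            truth = [
                mkloop(r["anchor1"][1], r["anchor1"][2],
                       r["anchor2"][1], r["anchor2"][2], chrom=r["anchor1"][0])
                for r in manifest["loops"][cls]
            ]
            called = getattr(pipeline_result.loop_diff, cls)
            assert len(called) == len(truth)
            for t in truth:
                assert any(loops_match(t, c) for c in called)


def mkgene(gid, tss, chrom="chr1"):
    body = GenomicInterval(chrom, tss, tss + 5000)
    return GeneModel(gid, gid, chrom, "+", body,
                     promoter_interval(chrom, "+", tss, 2000, 500))


class TestAnnotateAnchors:
    def test_ctcf_both_anchors_two_feet(self):
        lp = mkloop(0, 1000, 9000, 10_000)
        (ann,) = annotate_anchors([lp], ctcf_peaks=[iv(500, 600), iv(9500, 9600)])
        assert ann.ctcf_feet == 2

    def test_two_promoters_both_gene_ids(self):
        lp = mkloop(0, 3000, 9000, 10_000)
        genes = [mkgene("g1", 2100), mkgene("g2", 2500)]
        (ann,) = annotate_anchors([lp], genes=genes)
        assert ann.promoter_genes() == {"g1", "g2"}

    def test_matches_brute_force_overlap(self):
        rnd = random.Random(6)
        loops = [
            mkloop(s := rnd.randrange(0, 40_000), s + 2000,
                   t := rnd.randrange(0, 40_000), t + 2000)
            for _ in range(30)
        ]
        enh = [iv(s := rnd.randrange(0, 42_000), s + 500) for _ in range(20)]
        ctcf = [iv(s := rnd.randrange(0, 42_000), s + 300) for _ in range(20)]
        anns = annotate_anchors(
            loops, cres_by_class={"enhancer": enh}, ctcf_peaks=ctcf
        )
        for lp, ann in zip(loops, anns):
            for anchor, feats in (
                (lp.anchor1, ann.anchor1_features),
                (lp.anchor2, ann.anchor2_features),
            ):
                assert ("enhancer" in feats) == any(
                    anchor.overlaps(e) for e in enh
                )
                assert ("CTCF" in feats) == any(
                    anchor.overlaps(c) for c in ctcf
                )


class TestCrossTissue:
    def test_counts_and_order_invariance(self):
        lp = mkloop(0, 1000, 9000, 10_000)
        other = mkloop(50_000, 51_000, 60_000, 61_000)
        catalogs = {"t1": [lp], "t2": [lp], "t3": []}
        out = cross_tissue_sharing([lp, other], catalogs)
        assert out[0]["n_tissues"] == 2 and out[1]["n_tissues"] == 0
        rev = cross_tissue_sharing(
            [lp, other], dict(reversed(list(catalogs.items())))
        )
        assert [r["n_tissues"] for r in rev] == [r["n_tissues"] for r in out]


class TestTopLoopChangeGenes:
    def annotated_diff(self, counts):
        """One gained loop per unit count, each labeled with its gene."""
        diff = LoopDiff()
        anns = []
        pos = 0
        for gid, n in counts.items():
            for _ in range(n):
                lp = mkloop(pos, pos + 100, pos + 5000, pos + 5100)
                diff.gained.append(lp)
                anns.append(
                    annotate_anchors(
                        [lp], genes=[mkgene(gid, pos + 50)]
                    )[0]
                )
                pos += 20_000
        return diff, anns

    def test_hand_computed_quantile_with_distinct_counts(self):
        counts = {f"g{i}": i + 1 for i in range(20)}  # 1..20, distinct
        diff, anns = self.annotated_diff(counts)
        out = top_loop_change_genes(diff, anns, quantile=0.05)
        # 95th percentile (linear) of 1..20 is 19.05 -> only g19 (count 20)
        assert out == {"g19"}

    def test_no_changes_empty(self):
        assert top_loop_change_genes(LoopDiff(), [], 0.05) == set()

    def test_quantile_one_returns_all_changed_genes(self):
        counts = {"a": 1, "b": 3}
        diff, anns = self.annotated_diff(counts)
        assert top_loop_change_genes(diff, anns, quantile=1.0) == {"a", "b"}
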