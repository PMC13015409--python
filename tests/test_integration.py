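"""Regulatory-change calls, gene sets, over-representation, term matrix."""
import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from chromlink.core import GeneModel, GenomicInterval, Loop, promoter_interval
from chromlink.integration import (
    EnrichmentResult,
    RegulatoryChangeCall,
    classify_regulatory_change,
    hypergeom_ora,
    term_set_matrix,
)
from chromlink.loops import LoopDiff, annotate_anchors


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def gene(gid, tss, chrom="chr1"):
    body = GenomicInterval(chrom, tss, tss + 5000)
    return GeneModel(gid, gid, chrom, "+", body,
                     promoter_interval(chrom, "+", tss, 2000, 500))


class TestRegulatoryChangeCall:
    def make(self, ge, le, gr, lr):
        return RegulatoryChangeCall("g", ge, le, gr, lr)

    def test_single_gained_enhancer_loop_is_activating(self):
        assert self.make(1, 0, 0, 0).call == "activating"

    def test_gained_enhancer_plus_gained_repressor_is_mixed(self):
        assert self.make(1, 0, 1, 0).call == "mixed"

    def test_exhaustive_enumeration_of_small_counts(self):
        for ge, le, gr, lr in itertools.product(range(4), repeat=4):
            call = self.make(ge, le, gr, lr).call
            act, rep = ge + lr, le + gr
            if act > 0 and rep == 0:
                assert call == "activating"
            elif rep > 0 and act == 0:
                assert call == "repressive"
            elif act > 0 and rep > 0:
                assert call == "mixed"
            else:
                assert call == "none"

    def test_counts_derived_from_annotated_loops(self):
        g = gene("g1", 100_000)
        enh = [iv(10_000, 11_000)]
        rep = [iv(300_000, 301_000)]
        gained = Loop.canonical(iv(9_500, 11_500), iv(99_000, 101_000))
        lost = Loop.canonical(iv(99_000, 101_000), iv(299_500, 301_500))
        diff = LoopDiff(gained=[gained], lost=[lost])
        anns = annotate_anchors(
            [gained, lost], genes=[g],
            cres_by_class={"enhancer": enh, "repressor": rep},
        )
        call = classify_regulatory_change("g1", diff, anns)
        assert call.gained_enhancer_loops == 1
        assert call.lost_repressor_loops == 1
        assert call.call == "activating"


def exact_hypergeom_tail(N, K, n, k):
    """P(X >= k) by direct combinatorial summation (independent oracle)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeomOra:
    def test_all_hits_exact_value(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        out = hypergeom_ora(term, {"T": term}, universe)
        assert out[0].p_value == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_hits_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = hypergeom_ora(
            {"g10", "g11"}, {"T": {"g0", "g1"}}, universe
        )
        assert out[0].k == 0 and out[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_below_30(self):
        rnd = random.Random(3)
        for _ in range(20):
            N = rnd.randrange(5, 31)
            universe = {f"g{i}" for i in range(N)}
            term = set(rnd.sample(sorted(universe), rnd.randrange(1, N)))
            query = set(rnd.sample(sorted(universe), rnd.randrange(1, N)))
            (res,) = hypergeom_ora(query, {"T": term}, universe)
            expect = exact_hypergeom_tail(N, len(term), len(query), res.k)
            assert res.p_value == pytest.approx(expect, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_ora(set(), {"T": {"a"}}, set())

    def test_bh_fdr_monotone_and_not_below_p(self):
        rng = np.random.default_rng(5)
        universe = {f"g{i}" for i in range(100)}
        annotation = {
            f"T{j}": set(rng.choice(sorted(universe), size=15, replace=False))
            for j in range(20)
        }
        query = set(rng.choice(sorted(universe), size=25, replace=False))
        results = hypergeom_ora(query, annotation, universe)
        assert all(r.fdr >= r.p_value - 1e-12 for r in results)
        ordered = sorted(results, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in ordered]
        assert all(b >= a - 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_invariant_to_gene_relabeling(self):
        universe = {f"g{i}" for i in range(30)}
        term = {f"g{i}" for i in range(8)}
        query = {f"g{i}" for i in range(4, 14)}
        relabel = {g: f"x_{g}" for g in universe}
        (a,) = hypergeom_ora(query, {"T": term}, universe)
        (b,) = hypergeom_ora(
            {relabel[g] for g in query},
            {"T": {relabel[g] for g in term}},
            set(relabel.values()),
        )
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)


class TestTermSetMatrix:
    def res(self, term, set_name, fdr):
        return EnrichmentResult(term, set_name, 1, 1, 1, 10, fdr, fdr)

    def test_three_sets_dropped_at_min_four(self):
        enr = {
            f"s{i}": [self.res("T", f"s{i}", 0.01 if i < 3 else 0.5)]
            for i in range(6)
        }
        mat = term_set_matrix(enr, fdr_max=0.05, min_sets=4)
        assert mat.empty

    def test_significant_everywhere_retained(self):
        enr = {f"s{i}": [self.res("T", f"s{i}", 0.001)] for i in range(16)}
        mat = term_set_matrix(enr)
        assert mat.loc["T"].sum() == 16

    def test_matches_row_sum_filter_oracle(self):
        rng = np.random.default_rng(6)
        terms = [f"T{i}" for i in range(12)]
        sets = [f"s{i}" for i in range(8)]
        fdr = {(t, s): float(rng.uniform(0, 0.2)) for t in terms for s in sets}
        enr = {
            s: [self.res(t, s, fdr[(t, s)]) for t in terms] for s in sets
        }
        mat = term_set_matrix(enr, fdr_max=0.05, min_sets=3)
        for t in terms:
            rowsum = sum(1 for s in sets if fdr[(t, s)] <= 0.05)
            assert (t in mat.index) == (rowsum >= 3)
            if t in mat.index:
                assert mat.loc[t].sum() == rowsum


class TestGeneSetsOnPlantedData:
    def test_sixteen_sets_present(self, pipeline_result):
        assert len(pipeline_result.gene_sets) == 16

    def test_hot_genes_land_in_expected_sets(self, pipeline_result, manifest):
        hot = set(manifest["annotation"]["hot_genes"])
        sets = pipeline_result.gene_sets
        assert hot <= sets["de_genes"]
        assert hot <= sets["H3K27ac_change"]
        assert hot <= sets["atac_change"]
        # the first hot genes per chromosome sit in flipped windows and
        # carry gained promoter-enhancer loops
        assert sets["compartment_shift"] <= hot
        assert len(sets["compartment_shift"]) > 0
        assert sets["promoter_enhancer_loops"] & hot

    def test_switch_genes_in_enhancer_switch_set(self, pipeline_result, manifest):
        assert set(manifest["switch_gene_ids"]) == pipeline_result.gene_sets[
            "enhancer_switch"
        ]

    def test_planted_term_retained_in_matrix(self, pipeline_result, manifest):
        assert manifest["annotation"]["multiset_term"] in (
            pipeline_result.term_matrix.index
        )

    def test_empty_de_table_only_empties_set_one(self, dataset_dir, tmp_path):
        import warnings

        from chromlink import RunConfig, run_pipeline

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(
                RunConfig(
                    dataset_dir=str(dataset_dir),
                    output_dir=str(tmp_path / "out"),
                    de_fdr_max=1e-9,  # nothing passes
                )
            )
        assert res.gene_sets["de_genes"] == set()
        assert len(res.gene_sets["H3K27ac_change"]) > 0
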