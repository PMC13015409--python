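"""Super-enhancer stitching, elbow cutoff, consensus, diff, specificity."""
import random
import warnings

import numpy as np
import pytest

from chromlink.core import GenomicInterval
from chromlink.super_enhancers import (
    se_consensus,
    se_cutoff,
    se_diff,
    se_tissue_specificity,
    stitch_and_rank,
)
from chromlink.synthetic import make_hockey_stick


def iv(s, e, chrom="chr1", score=None):
    return GenomicInterval(chrom, s, e, score=score)


class TestStitchAndRank:
    def test_gap_at_threshold_is_stitched(self):
        regions = stitch_and_rank(
            [iv(0, 1000), iv(13_400, 14_000)], [], stitch_gap=12_500
        )
        assert len(regions) == 1 and regions[0].constituent_count == 2

    def test_gap_beyond_threshold_stays_split(self):
        regions = stitch_and_rank(
            [iv(0, 1000), iv(13_600, 14_000)], [], stitch_gap=12_500
        )
        assert len(regions) == 2

    def test_tss_proximal_constituents_dropped(self):
        regions = stitch_and_rank(
            [iv(0, 1000), iv(5000, 6000)],
            [],
            stitch_gap=12_500,
            tss_exclusion=[iv(4500, 6500)],
        )
        assert len(regions) == 1 and regions[0].interval == iv(0, 1000)

    def test_signal_prorated_matches_brute_force(self):
        rnd = random.Random(4)
        cres = [iv(s := rnd.randrange(0, 190_000), s + 800) for _ in range(40)]
        peaks = [
            iv(s := rnd.randrange(0, 190_000), s + rnd.randrange(100, 900),
               score=float(rnd.randrange(1, 50)))
            for _ in range(80)
        ]
        regions = stitch_and_rank(cres, peaks, stitch_gap=2_000)
        for r in regions:
            expect = 0.0
            for p in peaks:
                ov = max(0, min(p.end, r.interval.end) - max(p.start, r.interval.start))
                if ov:
                    expect += p.score * ov / (p.end - p.start)
            assert r.signal == pytest.approx(expect, abs=1e-9)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            stitch_and_rank([iv(0, 100)], [iv(0, 100, score=-1.0)])


class TestSeCutoff:
    def test_hockey_stick_recovered_over_50_seeds(self):
        for seed in range(50):
            signals, breakpoint = make_hockey_stick(100, 8, seed=seed)
            _, flags = se_cutoff(signals)
            first_super = int(np.argmax(flags)) if flags.any() else len(signals)
            assert abs(first_super - breakpoint) <= 1

    def test_five_point_single_outlier(self):
        _, flags = se_cutoff([1, 1, 1, 1, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_signal_yields_zero_supers(self):
        with pytest.warns(UserWarning):
            _, flags = se_cutoff([3.0] * 10)
        assert not flags.any()

    def test_linear_signal_yields_zero_supers(self):
        with pytest.warns(UserWarning):
            _, flags = se_cutoff(np.linspace(0, 10, 20))
        assert not flags.any()

    def test_affine_rescaling_invariance(self):
        signals, _ = make_hockey_stick(80, 6, seed=1)
        _, flags = se_cutoff(signals)
        _, flags2 = se_cutoff(signals * 13.5 + 200.0)
        assert np.array_equal(flags, flags2)

    def test_argmax_equals_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            y = np.sort(rng.uniform(0, 100, size=rng.integers(5, 60)))
            if y[-1] == y[0]:
                continue
            cutoff, _ = se_cutoff(y)
            x = np.arange(y.size) / (y.size - 1)
            ys = (y - y[0]) / (y[-1] - y[0])
            gap = x - ys
            if gap.max() <= 1e-9:
                continue
            best = max(range(y.size), key=lambda i: (gap[i], i))
            assert cutoff == best

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            se_cutoff([1.0, 2.0])


class TestSeConsensusAndDiff:
    def test_four_of_six_retained_three_dropped(self):
        keep = iv(0, 5000)
        drop = iv(20_000, 25_000)
        sets = []
        for s in range(6):
            rows = []
            if s < 4:
                rows.append(keep)
            if s < 3:
                rows.append(drop)
            sets.append(rows)
        out = se_consensus(sets, k=4)
        assert len(out) == 1 and out[0].start == 0

    def test_consensus_matches_per_base_oracle(self):
        rnd = random.Random(8)
        sets = [
            [iv(s := rnd.randrange(0, 9000), s + 600) for _ in range(10)]
            for _ in range(5)
        ]
        out = se_consensus(sets, k=3)
        got = set()
        for r in out:
            got.update(range(r.start, r.end))
        union = set()
        for rows in sets:
            for r in rows:
                union.update(range(r.start, r.end))
        expect = set()
        b = 0
        while b < 10_000:
            if b in union:
                start = b
                while b in union:
                    b += 1
                comp = range(start, b)
                support = sum(
                    1
                    for rows in sets
                    if any(r.start < b and start < r.end for r in rows)
                )
                if support >= 3:
                    expect.update(comp)
            else:
                b += 1
        assert got == expect

    def test_diff_boundary_single_base_overlap_stable(self):
        d = se_diff([iv(0, 100)], [iv(99, 200)])
        assert not d.gained and not d.lost

    def test_diff_treated_only_gained(self):
        d = se_diff([], [iv(0, 100)])
        assert d.gained == [iv(0, 100)]


class TestTissueSpecificity:
    def test_sub_threshold_coverage_not_counted(self):
        tm = iv(0, 10_000)
        out = se_tissue_specificity([tm], {"s1": [iv(0, 6990)]})
        assert out[0]["n_samples"] == 0

    def test_full_containment_counted(self):
        tm = iv(1000, 2000)
        out = se_tissue_specificity([tm], {"s1": [iv(0, 10_000)]})
        assert out[0]["n_samples"] == 1 and out[0]["fraction"] == 1.0

    def test_exact_70_percent_counted(self):
        tm = iv(0, 1000)
        out = se_tissue_specificity([tm], {"s1": [iv(0, 700)]})
        assert out[0]["n_samples"] == 1

    def test_stacked_coverage_mode(self):
        # two 400 bp SEs only reach 70% together, not alone
        tm = iv(0, 1000)
        cat = {"s1": [iv(0, 400), iv(500, 900)]}
        assert se_tissue_specificity([tm], cat)[0]["n_samples"] == 0
        assert se_tissue_specificity([tm], cat, stack=True)[0]["n_samples"] == 1

    def test_planted_catalog_fractions(self, pipeline_result, manifest):
        cat = manifest["super_enhancers"]["catalog"]
        roles = manifest["super_enhancers"]["by_role"]
        spec = {
            (c, s, e): r["fraction"]
            for r in pipeline_result.se_specificity
            for (c, s, e) in [(r["se"].chrom, r["se"].start, r["se"].end)]
        }

        def frac_for(span):
            c, s, e = span
            for (cc, cs, ce), f in spec.items():
                if cc == c and cs < e and s < ce:
                    return f
            return None

        for span in roles["variant_se"]:
            assert frac_for(span) == pytest.approx(cat["tm_specific_fraction"])
            assert frac_for(span) < 0.05
        for span in roles["stable"]:
            assert frac_for(span) == pytest.approx(cat["ubiquitous_fraction"])
            assert frac_for(span) > 0.9


def test_called_supers_match_planted_roles(pipeline_result, manifest):
    roles = manifest["super_enhancers"]["by_role"]
    for cond, key in (("control", "called_control_roles"),
                      ("dex", "called_dex_roles")):
        truth = {
            (c, s, e)
            for role in manifest["super_enhancers"][key]
            for (c, s, e) in map(tuple, roles[role])
        }
        called = [
            r.interval for r in pipeline_result.se_calls[cond] if r.is_super
        ]
        assert len(called) == len(truth)
        for c in called:
            assert any(
                c.chrom == tc and c.start < te and ts < c.end
                for tc, ts, te in truth
            )
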