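"""Homozygous/heterozygous site classification and chain resolution."""

import numpy as np
import pytest

from methap.methylation_calls import ReadCallSet, SitePileup, pileup
from methap.zygosity import (
    JointPatternCounts,
    TruePatternSet,
    ZygosityClass,
    confidence,
    initial_classify,
    joint_pattern_counts,
    reclassify_from_patterns,
    resolve_chain,
    resolve_region,
    select_true_patterns,
)


def _site(n_meth, n_unmeth, idx=0):
    return SitePileup(cpg_index=idx, n_meth=n_meth, n_unmeth=n_unmeth)


class TestInitialClassify:
    @pytest.mark.parametrize(
        "counts,expected_class,expected_status",
        [
            ((12, 0), ZygosityClass.HOMOZYGOUS, 1),
            ((0, 15), ZygosityClass.HOMOZYGOUS, 0),
            ((6, 5), ZygosityClass.CANDIDATE_HET, None),
            ((5, 5), ZygosityClass.CANDIDATE_HET, None),
            ((4, 4), ZygosityClass.FILTERED, None),  # depth 8 < 10
            ((11, 2), ZygosityClass.HOMOZYGOUS, 1),  # minor = noise
            ((2, 11), ZygosityClass.HOMOZYGOUS, 0),
            ((0, 0), ZygosityClass.FILTERED, None),
        ],
    )
    def test_th_dp_10_rules(self, counts, expected_class, expected_status):
        call = initial_classify(_site(*counts), th_dp=10)
        assert call.zclass is expected_class
        if expected_status is not None:
            assert call.homozygous_status == expected_status

    def test_rule_matches_enumeration_oracle(self):
        """Exhaustive check of the decision table at th_dp=10."""
        for n_meth in range(0, 25):
            for n_unmeth in range(0, 25):
                call = initial_classify(_site(n_meth, n_unmeth), th_dp=10)
                depth = n_meth + n_unmeth
                if depth < 10:
                    expected = ZygosityClass.FILTERED
                elif n_meth == 0 or n_unmeth == 0:
                    expected = ZygosityClass.HOMOZYGOUS
                elif min(n_meth, n_unmeth) >= 5:
                    expected = ZygosityClass.CANDIDATE_HET
                else:
                    expected = ZygosityClass.HOMOZYGOUS
                assert call.zclass is expected, (n_meth, n_unmeth)

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            initial_classify(_site(5, 5), th_dp=1)


def _counts(**f):
    full = {p: 0 for p in ("00", "01", "10", "11")}
    full.update({k.lstrip("p"): v for k, v in f.items()})
    return JointPatternCounts(u=0, v=1, f=full)


class TestSelectTruePatterns:
    def test_dominant_single_pattern(self):
        tp = select_true_patterns(_counts(p11=20, p01=2, p00=1))
        assert tp.patterns == ("11",)  # 00 filtered (<2); 20/22 > 0.6

    def test_two_true_patterns(self):
        tp = select_true_patterns(_counts(p00=9, p11=7, p01=1))
        assert set(tp.patterns) == {"00", "11"}  # 9/16 <= 0.6; 7/9 >= 0.4

    def test_three_way_tie_is_ambiguous(self):
        tp = select_true_patterns(_counts(p00=5, p11=5, p01=5))
        assert tp.patterns == ()

    def test_all_below_min_freq_is_ambiguous(self):
        assert select_true_patterns(_counts(p00=1, p11=1)).patterns == ()

    def test_second_ratio_boundary_is_inclusive(self):
        # 10/17 <= 0.6; second/top = 4/10 = 0.4 exactly -> two patterns
        tp = select_true_patterns(_counts(p00=10, p01=4, p11=3))
        assert set(tp.patterns) == {"00", "01"}
        # 13/22 <= 0.6; 5/13 < 0.4 -> unresolvable
        assert select_true_patterns(_counts(p00=13, p01=5, p11=4)).patterns == ()

    def test_tied_runners_up_are_ambiguous(self):
        tp = select_true_patterns(_counts(p00=10, p11=4, p01=4))
        assert tp.patterns == ()  # no identifiable top two

    def test_single_ratio_boundary_is_strict(self):
        # top/total exactly 0.6 must NOT give a single pattern
        tp = select_true_patterns(_counts(p00=6, p11=4))
        assert set(tp.patterns) == {"00", "11"}


class TestReclassify:
    @pytest.mark.parametrize(
        "patterns,expect_u,expect_v",
        [
            (("11",), (ZygosityClass.HOMOZYGOUS, 1), (ZygosityClass.HOMOZYGOUS, 1)),
            (("00", "11"), (ZygosityClass.HETEROZYGOUS, None), (ZygosityClass.HETEROZYGOUS, None)),
            (("11", "01"), (ZygosityClass.HETEROZYGOUS, None), (ZygosityClass.HOMOZYGOUS, 1)),
        ],
    )
    def test_status_sets(self, patterns, expect_u, expect_v):
        tp = TruePatternSet(0, 1, patterns, {p: 5 for p in patterns})
        cu, cv = reclassify_from_patterns(tp)
        assert (cu.zclass, cu.homozygous_status) == expect_u
        assert (cv.zclass, cv.homozygous_status) == expect_v

    def test_empty_patterns_both_ambiguous(self):
        cu, cv = reclassify_from_patterns(TruePatternSet(0, 1, ()))
        assert cu.zclass is ZygosityClass.AMBIGUOUS
        assert cv.zclass is ZygosityClass.AMBIGUOUS


class TestConfidence:
    def test_direct_arithmetic(self):
        tp = TruePatternSet(0, 1, ("11", "00"), {"11": 8, "00": 6})
        assert confidence(tp, 15, 16, 20) == pytest.approx(14 / 20)

    def test_empty_tp_is_zero(self):
        assert confidence(TruePatternSet(0, 1, ()), 10, 10, 10) == 0.0

    def test_zero_depth_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert confidence(TruePatternSet(0, 1, ("11",), {"11": 3}), 0, 0, 0) == 0.0

    def test_matches_arithmetic_oracle_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            counts = {p: int(rng.integers(0, 30)) for p in ("00", "01", "10", "11")}
            k = int(rng.integers(1, 3))
            patterns = tuple(rng.choice(["00", "01", "10", "11"], size=k, replace=False))
            depths = rng.integers(1, 60, size=3)
            tp = TruePatternSet(0, 1, patterns, counts)
            expected = sum(counts[p] for p in patterns) / max(depths)
            assert confidence(tp, *depths) == pytest.approx(expected)


def _reads_from_patterns(pattern_counts, n_cpg=3):
    """Reads covering all sites, drawn per multi-site pattern string."""
    rcs = ReadCallSet("r0", n_cpg=n_cpg)
    k = 0
    for pattern, count in pattern_counts.items():
        for _ in range(count):
            rcs.add_read(f"read{k}", {i: int(c) for i, c in enumerate(pattern)})
            k += 1
    return rcs


class TestResolveChain:
    def test_single_chs_stays_ambiguous(self):
        rcs = _reads_from_patterns({"0": 6, "1": 6}, n_cpg=1)
        calls, links = resolve_chain([0], rcs, pileup(rcs))
        assert calls[0].zclass is ZygosityClass.AMBIGUOUS
        assert links == []

    def test_two_chs_anti_patterns_both_heterozygous(self):
        rcs = _reads_from_patterns({"00": 6, "11": 6}, n_cpg=2)
        calls, links = resolve_chain([0, 1], rcs, pileup(rcs))
        assert calls[0].zclass is ZygosityClass.HETEROZYGOUS
        assert calls[1].zclass is ZygosityClass.HETEROZYGOUS
        assert len(links) == 1 and set(links[0].patterns) == {"00", "11"}

    def test_higher_confidence_earlier_pair_keeps_middle_site(self):
        """With conf(u,v) > conf(v,w), v keeps its (u,v)-derived class and w
        is derived from the (v,w) patterns given v's class."""
        rcs = ReadCallSet("r0", n_cpg=3)
        k = 0
        # pair (0,1): strong anti-correlated het evidence (TP freq 20)
        for pat in ["00"] * 10 + ["11"] * 10:
            rcs.add_read(f"a{k}", {0: int(pat[0]), 1: int(pat[1])})
            k += 1
        # pair (1,2): weaker single-pattern evidence (5/7 > 0.6 -> {11})
        for pat in ["11"] * 5 + ["00"] * 2:
            rcs.add_read(f"b{k}", {1: int(pat[0]), 2: int(pat[1])})
            k += 1
        calls, _ = resolve_chain([0, 1, 2], rcs, pileup(rcs))
        assert calls[0].zclass is ZygosityClass.HETEROZYGOUS
        # conf(u,v)=20/27 > conf(v,w)=5/27: v's het class is retained
        assert calls[1].zclass is ZygosityClass.HETEROZYGOUS
        # w follows the single surviving (v,w) pattern 11
        assert calls[2].zclass is ZygosityClass.HOMOZYGOUS
        assert calls[2].homozygous_status == 1

    def test_higher_confidence_later_pair_revises_middle_site(self):
        """With conf(u,v) < conf(v,w), v is revised from the (v,w) patterns."""
        rcs = ReadCallSet("r0", n_cpg=3)
        k = 0
        for pat in ["00"] * 10 + ["11"] * 10:
            rcs.add_read(f"a{k}", {0: int(pat[0]), 1: int(pat[1])})
            k += 1
        # overwhelming homozygous evidence on (1,2): TP {11}, freq 25
        for pat in ["11"] * 25 + ["00"] * 3:
            rcs.add_read(f"b{k}", {1: int(pat[0]), 2: int(pat[1])})
            k += 1
        calls, links = resolve_chain([0, 1, 2], rcs, pileup(rcs))
        assert calls[1].zclass is ZygosityClass.HOMOZYGOUS
        assert calls[1].homozygous_status == 1
        assert calls[2].zclass is ZygosityClass.HOMOZYGOUS
        # the (0,1) phase link contradicts the revised class and is dropped
        assert all((l.u, l.v) != (0, 1) for l in links)

    def test_output_deterministic(self):
        rng = np.random.default_rng(5)
        rcs = ReadCallSet("r0", n_cpg=4)
        for k in range(50):
            rcs.add_read(
                f"read{k}",
                {i: int(rng.integers(0, 2)) for i in range(4)},
            )
        first = resolve_chain([0, 1, 2, 3], rcs, pileup(rcs))
        second = resolve_chain([0, 1, 2, 3], rcs, pileup(rcs))
        assert [c.zclass for c in first[0].values()] == [
            c.zclass for c in second[0].values()
        ]
        assert first[1] == second[1]


class TestResolveRegion:
    def test_every_site_gets_exactly_one_class(self, noisy_consistent_scenario):
        scenario, reads = noisy_consistent_scenario
        for region in scenario.regions[:10]:
            result = resolve_region(reads["sample1"][region.region_id])
            assert sorted(result.calls) == list(range(region.n_cpg))

    def test_error_free_two_template_classification(self, clean_x_scenario):
        """All sites of an all-het planted region classify heterozygous;
        no homozygous site appears at zero error rate."""
        scenario, reads = clean_x_scenario
        for region in scenario.regions:
            result = resolve_region(reads["sample1"][region.region_id])
            classes = {c.zclass for c in result.calls.values()}
            assert classes == {ZygosityClass.HETEROZYGOUS}

    def test_noisy_recall_and_specificity(self):
        """At 1% call error, depth 30/homolog: het recall >= 0.95 on planted
        het sites and <= 1% misclassification of planted homozygous sites."""
        from methap import simulate as sim

        het_total = het_found = 0
        hom_total = hom_wrong = 0
        for kind, seed in (("x_inactivation", 21), ("consistent", 22)):
            scenario = sim.make_scenario(kind, n_regions=100, seed=seed)
            reads = sim.emit_reads(scenario)["sample1"]
            for rec in scenario.truth:
                t1, t2 = rec.templates["sample1"]
                result = resolve_region(reads[rec.region_id])
                for i, call in result.calls.items():
                    if t1[i] != t2[i]:
                        het_total += 1
                        het_found += call.zclass is ZygosityClass.HETEROZYGOUS
                    else:
                        hom_total += 1
                        hom_wrong += call.zclass is ZygosityClass.HETEROZYGOUS
        assert het_found / het_total >= 0.95
        assert hom_wrong / hom_total <= 0.01
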