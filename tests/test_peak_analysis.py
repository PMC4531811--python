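import numpy as np
import pytest

from sumoscape.genome_model import GenomicInterval
from sumoscape.peak_analysis import (
    Peak,
    PeakCallerParams,
    PeakSet,
    add_tag_counts,
    call_peaks,
    classify_condition,
    cooccurrence,
    filter_min_reads,
    fold_enrichment_class,
    intersect_replicates,
    venn_counts,
)
from sumoscape.signal_io import build_coverage
from sumoscape.synthetic_data import simulate_chip, score_against_truth

from .conftest import make_readset

SIZES = {"chr1": 1_000_000}


def peakset(regions, sample_id="s", condition="C", **tags):
    peaks = [Peak(GenomicInterval("chr1", s, e)) for s, e in regions]
    for p in peaks:
        for k, v in tags.items():
            p.raw_tags[k] = v
            p.norm_tags[k] = float(v)
    return PeakSet(sample_id, condition, peaks)


def _uniform_reads(rng, n, length=200, chrom_len=1_000_000):
    starts = rng.integers(0, chrom_len - length, n)
    return [GenomicInterval("chr1", int(s), int(s) + length) for s in starts]


def _planted_reads(rng, n, center, width=300):
    c = rng.integers(center - width // 2, center + width // 2, n)
    return [GenomicInterval("chr1", int(x) - 100, int(x) + 100) for x in c]


class TestCallPeaks:
    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(0)
        bg = _uniform_reads(rng, 100_000)
        site = _planted_reads(rng, 250, 500_000)  # ~8-fold over the 200-bp window background
        cov = build_coverage(make_readset(bg + site), SIZES, 50)
        ctl = build_coverage(make_readset(_uniform_reads(rng, 100_000)), SIZES, 50)
        ps = call_peaks(cov, ctl)
        assert len(ps) == 1
        assert ps.peaks[0].interval.overlaps(GenomicInterval("chr1", 499_850, 500_150))

    def test_two_sites_two_peaks(self):
        rng = np.random.default_rng(1)
        reads = (
            _uniform_reads(rng, 100_000)
            + _planted_reads(rng, 250, 300_000)
            + _planted_reads(rng, 250, 310_000)
        )
        cov = build_coverage(make_readset(reads), SIZES, 50)
        ctl = build_coverage(make_readset(_uniform_reads(rng, 100_000)), SIZES, 50)
        assert len(call_peaks(cov, ctl)) == 2

    def test_self_vs_self_null(self):
        """Sample drawn from the control's model yields ~no peaks (20 seeds)."""
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cov = build_coverage(make_readset(_uniform_reads(rng, 100_000)), SIZES, 50)
            ctl = build_coverage(make_readset(_uniform_reads(rng, 100_000)), SIZES, 50)
            total += len(call_peaks(cov, ctl))
        assert total / 20 <= 1.0

    def test_empty_control_uniform_fallback(self):
        rng = np.random.default_rng(2)
        reads = _uniform_reads(rng, 50_000) + _planted_reads(rng, 80, 500_000)
        cov = build_coverage(make_readset(reads), SIZES, 50)
        empty = build_coverage(make_readset([]), SIZES, 50)
        with pytest.warns(UserWarning, match="empty control"):
            ps = call_peaks(cov, empty)
        assert len(ps) >= 1


class TestIntersectReplicates:
    def test_basepair_intersection(self):
        out = intersect_replicates(peakset([(100, 300)]), peakset([(200, 400)]))
        assert [(p.interval.start, p.interval.end) for p in out.peaks] == [(200, 300)]

    def test_single_replicate_peak_dropped(self):
        out = intersect_replicates(peakset([(100, 300), (1000, 1200)]), peakset([(100, 300)]))
        assert len(out) == 1

    def test_identity_and_idempotence(self):
        a = peakset([(100, 300), (5_000, 5_400)])
        once = intersect_replicates(a, a)
        twice = intersect_replicates(once, a)
        assert [p.interval for p in once.peaks] == [p.interval for p in a.peaks]
        assert [p.interval for p in twice.peaks] == [p.interval for p in once.peaks]

    def test_output_within_inputs(self):
        rng = np.random.default_rng(3)
        mk = lambda: peakset(
            sorted((int(s), int(s) + int(w) + 100)
                   for s, w in zip(rng.integers(0, 90_000, 40), rng.integers(0, 400, 40)))
        )
        a, b = mk(), mk()
        out = intersect_replicates(a, b)
        for p in out.peaks:
            assert any(q.interval.start <= p.interval.start and p.interval.end <= q.interval.end
                       for q in a.peaks)

    def test_disjoint_chromosome_namespaces_error(self):
        a = peakset([(0, 100)])
        b = PeakSet("s", "C", [Peak(GenomicInterval("scaffold_1", 0, 100))])
        with pytest.raises(ValueError, match="namespace"):
            intersect_replicates(a, b)


class TestFilterMinReads:
    def test_strict_boundary(self):
        """The '<9 reads' rule: 8 reads removed, 9 reads kept."""
        ps = peakset([(0, 100)], s=8)
        ps.peaks.extend(peakset([(200, 300)], s=9).peaks)
        out = filter_min_reads(ps, "s", 9)
        assert [p.raw_tags["s"] for p in out.peaks] == [9]

    def test_zero_threshold_is_identity(self):
        ps = peakset([(0, 100), (200, 300)], s=0)
        assert len(filter_min_reads(ps, "s", 0)) == 2

    def test_missing_counts_error(self):
        ps = peakset([(0, 100)])
        with pytest.raises(KeyError):
            filter_min_reads(ps, "nope", 9)


class TestClassifyCondition:
    def test_overlap_is_shared(self):
        cc = classify_condition(peakset([(0, 100)]), peakset([(50, 150)], condition="HS"))
        assert len(cc.shared) == 1 and not cc.c_unique and not cc.hs_unique

    def test_disjoint_all_unique(self):
        cc = classify_condition(peakset([(0, 100)]), peakset([(500, 600)], condition="HS"))
        assert len(cc.c_unique) == 1 and len(cc.hs_unique) == 1 and not cc.shared

    def test_partition_counts(self):
        rng = np.random.default_rng(4)
        mk = lambda: peakset(
            sorted((int(s), int(s) + 150) for s in rng.choice(900_000, 60, replace=False))
        )
        c, hs = mk(), mk()
        cc = classify_condition(c, hs)
        assert len(cc.c_unique) + len(cc.shared) == len(c)
        assert len(cc.hs_unique) + cc.n_shared_hs == len(hs)


class TestFoldEnrichmentClass:
    @pytest.mark.parametrize(
        "hs,c,expected",
        [
            (41.0, 10.0, "HS_enriched"),   # ratio 4.1 > 4
            (40.0, 10.0, "unchanged"),     # ratio exactly 4: strict >
            (2.0, 10.0, "HS_depleted"),    # ratio 0.2 < 0.25
        ],
    )
    def test_thresholds(self, hs, c, expected):
        ps = peakset([(0, 100)])
        ps.peaks[0].norm_tags = {"HS": hs, "C": c}
        out = fold_enrichment_class(ps, "HS", "C", pseudo=0.0)
        assert len(out[expected]) == 1

    def test_pseudocount_guards_zero(self):
        ps = peakset([(0, 100)])
        ps.peaks[0].norm_tags = {"HS": 10.0, "C": 0.0}
        out = fold_enrichment_class(ps, "HS", "C", pseudo=1.0)
        assert ps.peaks[0].enrichment_class == "HS_enriched"
        assert len(out["HS_enriched"]) == 1


class TestCooccurrence:
    def test_half_overlap(self):
        tf = peakset([(i * 1000, i * 1000 + 100) for i in range(10)])
        ref = peakset([(i * 1000, i * 1000 + 100) for i in range(5)])
        assert cooccurrence(tf, ref) == 50.0

    def test_superset_reference_is_100(self):
        tf = peakset([(0, 100), (500, 600)])
        ref = peakset([(0, 100), (500, 600), (900, 1000)])
        assert cooccurrence(tf, ref) == 100.0

    def test_empty_query_errors(self):
        with pytest.raises(ValueError):
            cooccurrence(peakset([]), peakset([(0, 100)]))

    def test_monotone_in_reference(self):
        rng = np.random.default_rng(5)
        tf = peakset([(int(s), int(s) + 200) for s in sorted(rng.choice(500_000, 50, replace=False))])
        ref_regions = sorted((int(s), int(s) + 200) for s in rng.choice(500_000, 50, replace=False))
        prev = 0.0
        for k in (5, 20, 50):
            cur = cooccurrence(tf, peakset(ref_regions[:k]))
            assert cur >= prev
            prev = cur


class TestVennCounts:
    def test_disjoint_two_sets(self):
        a = peakset([(0, 10), (100, 110), (200, 210)], "A")
        b = peakset([(1000 + i * 100, 1010 + i * 100) for i in range(4)], "B")
        out = venn_counts([a, b])
        assert out == {frozenset({"A"}): 3, frozenset({"B"}): 4}

    def test_identical_sets_all_shared(self):
        a = peakset([(0, 10), (100, 110)], "A")
        b = peakset([(0, 10), (100, 110)], "B")
        assert venn_counts([a, b]) == {frozenset({"A", "B"}): 2}

    def test_three_sets_against_bruteforce(self):
        rng = np.random.default_rng(6)
        sets = []
        for name in "ABC":
            regions = sorted((int(s), int(s) + 80) for s in rng.choice(20_000, 30, replace=False))
            sets.append(peakset(regions, name))
        out = venn_counts(sets)
        # brute force: first-member-of-pattern counting
        expect = {}
        names = ["A", "B", "C"]
        for i, ps in enumerate(sets):
            for p in ps.peaks:
                pat = frozenset(
                    n for n, qs in zip(names, sets)
                    if n == names[i] or any(p.interval.overlaps(q.interval) for q in qs.peaks)
                )
                if min(names.index(n) for n in pat) == i:
                    expect[pat] = expect.get(pat, 0) + 1
        assert out == expect

    def test_too_many_sets_error(self):
        with pytest.raises(ValueError):
            venn_counts([peakset([(0, 10)], n) for n in "ABCD"])


class TestPipelineOnSimulatedChip:
    def test_planted_site_recovery_and_tag_counts(self, small_scenario):
        cfg, genes, truth = small_scenario
        sizes = truth.chrom_sizes
        ctl = simulate_chip(cfg, genes, truth, "INPUT", "C", 1)
        ctl_cov = build_coverage(ctl, sizes, 50)
        reps = []
        for rep in (1, 2):
            rs = simulate_chip(cfg, genes, truth, "SUMO", "HS", rep)
            reps.append((rs, call_peaks(build_coverage(rs, sizes, 50), ctl_cov)))
        inter = intersect_replicates(reps[0][1], reps[1][1])
        add_tag_counts(inter, {"hs": reps[0][0]})
        planted = [s.interval() for s in truth.sites["SUMO"]
                   if s.fold.get("HS", 1) >= 8 and s.replicates == (1, 2)]
        sc = score_against_truth(inter.intervals(), planted)
        assert sc["recall"] >= 0.9
        assert all(p.raw_tags["hs"] > 0 for p in inter.peaks)
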