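"""Targeting, overlap statistics, permutation null and the spreading
classifier."""

import numpy as np
import pytest
from scipy import stats

from k27compare.gene_annotation import (
    assign_targets,
    count_overlapping,
    fisher_region_enrichment,
    group_target_enrichment,
    overlap_fraction,
    permutation_overlap_test,
    spreading_classifier,
)
from k27compare.intervals import GeneModel, GenomicInterval
from k27compare.peak_calling import Peak, TagTrack
from tests.conftest import make_intervals


def _peak(start, end, summit=None, chrom="chr1"):
    return Peak(
        GenomicInterval(chrom, start, end),
        summit if summit is not None else (start + end) // 2,
        0, 0.0, 1.0,
    )


def _gene(gene_id, start, end, strand):
    return GeneModel(gene_id, GenomicInterval("chr1", start, end, strand))


class TestAssignTargets:
    def test_overlapping_peak_assigned(self):
        (t,) = assign_targets([_peak(4200, 4600)], [_gene("g1", 4000, 8000, "+")])
        assert t.gene_id == "g1" and t.relation == "overlap"

    def test_upstream_window_plus_strand(self):
        (t,) = assign_targets([_peak(3400, 3600)], [_gene("g1", 4000, 8000, "+")])
        assert t.gene_id == "g1" and t.relation == "upstream-window"

    def test_upstream_window_minus_strand(self):
        (t,) = assign_targets([_peak(8200, 8400)], [_gene("g1", 4000, 8000, "-")])
        assert t.gene_id == "g1" and t.relation == "upstream-window"

    def test_nearest_tss_wins_with_id_tiebreak(self):
        genes = [
            _gene("gB", 4000, 8000, "+"),
            _gene("gA", 5000, 9000, "+"),
        ]
        (t,) = assign_targets([_peak(4900, 5100, summit=5000)], genes)
        assert t.gene_id == "gA"  # TSS 5000 at distance 0
        # exact tie: both TSS equidistant -> lexicographic id
        genes = [_gene("gB", 4000, 8000, "+"), _gene("gA", 6000, 9000, "+")]
        (t,) = assign_targets([_peak(4990, 5010, summit=5000)], genes)
        assert t.gene_id == "gA"

    def test_no_candidate_unassigned(self):
        (t,) = assign_targets([_peak(100, 200)], [_gene("g1", 9000, 9900, "+")])
        assert t.gene_id is None


class TestOverlapFraction:
    def test_full_and_zero_coverage(self):
        q = make_intervals([(0, 10), (50, 60)])
        assert overlap_fraction(q, make_intervals([(0, 100)])) == 1.0
        assert overlap_fraction(q, make_intervals([(200, 300)])) == 0.0

    def test_matches_bruteforce_on_random_regions(self):
        rng = np.random.default_rng(0)
        def rand_regions(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 100_000))
                out.append(
                    GenomicInterval(
                        f"chr{rng.integers(1, 4)}", s, s + int(rng.integers(1, 400))
                    )
                )
            return out

        q, r = rand_regions(1000), rand_regions(300)
        brute = sum(any(iv.overlaps(rv) for rv in r) for iv in q)
        assert count_overlapping(q, r) == brute

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError):
            overlap_fraction([], make_intervals([(0, 10)]))


class TestPermutationTest:
    def test_always_overlapping_gives_p_one(self):
        genome = {"chr1": 1000}
        query = make_intervals([(0, 1000)])
        ref = make_intervals([(100, 200)])
        p, obs, null = permutation_overlap_test(query, ref, genome, n=50, seed=0)
        assert p == 1.0 and obs == 1 and (null == 1).all()

    def test_minimum_p_with_plus_one_correction(self):
        # query on chr1 only; reference shuffled across a genome where
        # chr2 dominates -> observed (1) beats nearly every shuffle
        genome = {"chr1": 100, "chr2": 1_000_000}
        query = make_intervals([(0, 100)], chrom="chr1")
        ref = make_intervals([(10, 20)], chrom="chr1")
        p, obs, null = permutation_overlap_test(
            query, ref, genome, n=1000, seed=1
        )
        assert 1 / 1001 <= p <= 1
        assert p < 1e-2

    def test_toy_genome_null_matches_enumeration(self):
        # 3-position genome, unit-length reference: 3 equally likely
        # placements; query covers position 0 only -> overlap prob 1/3
        genome = {"c": 3}
        query = make_intervals([(0, 1)], chrom="c")
        ref = make_intervals([(2, 3)], chrom="c")
        _, _, null = permutation_overlap_test(query, ref, genome, n=3000, seed=2)
        rate = null.mean()
        se = np.sqrt((1 / 3) * (2 / 3) / 3000)
        assert abs(rate - 1 / 3) < 3 * se


class TestFisher:
    def test_nested_sets_minimal_p_matches_hypergeometric(self):
        universe = set(range(100))
        sub = set(range(50))
        odds, p = fisher_region_enrichment(sub, sub, universe)
        expected = stats.hypergeom.pmf(50, 100, 50, 50)
        assert p == pytest.approx(expected, rel=1e-8)
        assert odds > 1

    def test_independent_sets_p_uniform(self):
        rng = np.random.default_rng(3)
        universe = set(range(200))
        pvals = []
        for _ in range(200):
            a = set(rng.choice(200, 40, replace=False))
            b = set(rng.choice(200, 40, replace=False))
            pvals.append(fisher_region_enrichment(a, b, universe)[1])
        # discrete conservatism allowed: reject-rate at 0.05 must not exceed it
        assert np.mean(np.array(pvals) < 0.05) <= 0.07

    def test_expected_overlap_gives_odds_near_one(self):
        universe = set(range(100))
        a = set(range(50))
        b = set(range(25, 75))
        odds, _ = fisher_region_enrichment(a, b, universe)
        assert odds == pytest.approx(1.0)


class TestGroupEnrichment:
    def test_score_arithmetic(self):
        universe = set(range(1000))
        group = set(range(20))
        de = set(range(10)) | set(range(500, 590))
        res = group_target_enrichment({"g": group}, de, universe)
        assert res["g"]["score"] == pytest.approx(10 / 2.0)

    def test_de_equals_universe(self):
        universe = set(range(100))
        res = group_target_enrichment({"g": set(range(10))}, universe, universe)
        assert res["g"]["score"] == 1.0 and res["g"]["pvalue"] == 1.0

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            res = group_target_enrichment(
                {"g": set()}, {1}, set(range(10))
            )
        assert res == {}


class TestSpreading:
    def _tracks(self, flank_ratio, summit_ratio, n=4000, seed=0):
        """wt uniform over [0, 2000); mutant thinned by region."""
        rng = np.random.default_rng(seed)
        wt = rng.integers(0, 2000, n)
        keep = np.where(
            np.abs(wt - 1000) < 250,
            rng.random(n) < summit_ratio,
            rng.random(n) < flank_ratio,
        )
        return TagTrack({"chr1": wt}), TagTrack({"chr1": wt[keep]})

    def test_flank_biased_region_flagged(self):
        wt, mut = self._tracks(flank_ratio=1 / 3, summit_ratio=1.0)
        call = spreading_classifier(
            GenomicInterval("chr1", 0, 2000), 1000, wt, mut
        )
        assert call.flank_biased
        assert call.m_flank == pytest.approx(np.log2(1 / 3), abs=0.2)
        assert call.m_summit == pytest.approx(0.0, abs=0.2)

    def test_uniform_reduction_not_flagged(self):
        wt, mut = self._tracks(flank_ratio=0.25, summit_ratio=0.25)
        call = spreading_classifier(
            GenomicInterval("chr1", 0, 2000), 1000, wt, mut
        )
        assert not call.flank_biased
        assert call.m_summit == pytest.approx(-2.0, abs=0.3)

    def test_flag_invariant_under_common_rescaling(self):
        wt, mut = self._tracks(flank_ratio=1 / 3, summit_ratio=1.0, seed=5)
        region = GenomicInterval("chr1", 0, 2000)
        base = spreading_classifier(region, 1000, wt, mut)
        # doubling both tracks' tags leaves the decision unchanged
        wt2 = TagTrack({"chr1": np.concatenate([wt.positions["chr1"]] * 2)})
        mut2 = TagTrack({"chr1": np.concatenate([mut.positions["chr1"]] * 2)})
        doubled = spreading_classifier(region, 1000, wt2, mut2)
        assert base.flank_biased == doubled.flank_biased

    def test_preconditions(self):
        wt, mut = self._tracks(1.0, 1.0)
        with pytest.raises(ValueError, match="classified down"):
            spreading_classifier(
                GenomicInterval("chr1", 0, 2000), 1000, wt, mut,
                region_class="unchanged",
            )
        with pytest.raises(ValueError, match="wider"):
            spreading_classifier(
                GenomicInterval("chr1", 0, 400), 200, wt, mut
            )
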