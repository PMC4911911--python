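"""Feature assignment, un-merging, 3' bias, overlap and rank statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pufclip import landscape
from pufclip.landscape import (
    assign_feature,
    overlap_test,
    rank_correlation,
    three_prime_bias,
    unmerge,
)
from pufclip.model import Annotation, CoverageTrack, TranscriptModel
from pufclip.peaks import CandidatePeak, PeakCallConfig


def _ann():
    coding = TranscriptModel("g1", "t1", "chr1", "+", [(0, 1000)], (100, 700))
    nc = TranscriptModel("g2", "t2", "chr1", "+", [(2000, 2500)], None,
                         biotype="ncRNA")
    return Annotation([coding, nc])


def _peak(max_pos, start=None, end=None, height=20, strand="+"):
    start = max_pos - 10 if start is None else start
    end = max_pos + 10 if end is None else end
    return CandidatePeak("chr1", strand, start, end, height, max_pos)


class TestAssignFeature:
    def test_max_pos_in_3utr(self):
        fa = assign_feature(_peak(800), _ann())
        assert fa.region == "3UTR"
        assert fa.gene_id == "g1"
        assert fa.distance_to_3p_end == 1000 - 1 - 800

    def test_boundary_peak_follows_max_pos_not_span(self):
        # span crosses the CDS/3'UTR boundary but max_pos is in the CDS
        fa = assign_feature(_peak(690, start=680, end=720), _ann())
        assert fa.region == "CDS"

    def test_ncrna_host(self):
        assert assign_feature(_peak(2200), _ann()).region == "ncRNA"

    def test_intergenic(self):
        assert assign_feature(_peak(1500), _ann()).region == "intergenic"

    def test_five_utr(self):
        assert assign_feature(_peak(50), _ann()).region == "5UTR"

    def test_fractions_sum_to_one(self, default_sim):
        truth = default_sim.truth
        peaks = [
            _peak(int(r.genomic_motif_start), strand=r.strand)
            for r in truth.itertuples()
        ]
        for p in peaks:
            p.chrom = "synChrI"
        fr = landscape.feature_fractions(
            [assign_feature(p, default_sim.annotation) for p in peaks]
        )
        assert fr.sum() == pytest.approx(1.0)


class TestUnmerge:
    def _track(self, values):
        return CoverageTrack("chr1", "+", np.asarray(values))

    def test_unimodal_span_is_idempotent(self):
        v = [0] * 10 + [2, 5, 12, 5, 2] + [0] * 10
        peak = _peak(12, start=10, end=15, height=12)
        subs = unmerge(peak, self._track(v), PeakCallConfig(min_height=5))
        assert len(subs) == 1
        assert subs[0].height == 12

    def test_bimodal_with_deep_valley_splits(self):
        v = [0] * 5 + [10] + [1] * 3 + [8] + [0] * 5
        peak = _peak(5, start=5, end=10, height=10)
        subs = unmerge(peak, self._track(v), PeakCallConfig(min_height=5))
        assert [s.height for s in subs] == [10, 8]  # ordered by height

    def test_valley_exactly_at_threshold_does_not_split(self):
        # valley == border_frac * min(neighbour heights): strict < to split
        v = [0] * 5 + [10, 2, 10] + [0] * 5
        peak = _peak(5, start=5, end=8, height=10)
        subs = unmerge(peak, self._track(v), PeakCallConfig(min_height=5))
        assert len(subs) == 1

    def test_refinement_property(self, default_sim, default_candidates):
        cov = default_sim.coverage(default_sim.replicates[0])
        for cand in default_candidates[0][:40]:
            subs = unmerge(cand, cov[(cand.chrom, cand.strand)])
            for s in subs:
                assert cand.start <= s.start < s.end <= cand.end
                assert s.height <= cand.height


class TestMultiPeakSummary:
    def test_all_single_peak_genes(self):
        ann = _ann()
        df, p = landscape.multi_peak_summary({"g1": [_peak(800)]}, ann)
        assert not df["multi"].any()
        assert math.isnan(p)

    def test_counts_match_groupby_oracle(self, default_sim, default_candidates):
        from pufclip import consensus as cns

        by_gene = {}
        for cand in default_candidates[0]:
            gid = cns.assign_gene(cand, default_sim.annotation)
            if gid:
                by_gene.setdefault(gid, []).append(cand)
        df, _ = landscape.multi_peak_summary(by_gene, default_sim.annotation)
        for row in df.itertuples():
            assert row.n_peaks == len(by_gene[row.gene_id])

    def test_planted_length_bias_detected(self, default_sim, default_candidates):
        # the generator plants extra sites preferentially on long
        # transcripts, so multi-peak genes should be longer
        from pufclip import consensus as cns

        by_gene = {}
        for cand in default_candidates[0]:
            gid = cns.assign_gene(cand, default_sim.annotation)
            if gid:
                by_gene.setdefault(gid, []).append(cand)
        df, p = landscape.multi_peak_summary(by_gene, default_sim.annotation)
        if df["multi"].sum() >= 5:
            multi_med = df.loc[df.multi, "mature_length"].median()
            single_med = df.loc[~df.multi, "mature_length"].median()
            assert multi_med > single_med
            assert p < 0.05


class TestThreePrimeBias:
    def _setup(self, cov_values):
        tx = TranscriptModel("g1", "t1", "chr1", "+", [(0, 400)], (50, 200))
        ann = Annotation([tx])
        tracks = {("chr1", "+"): CoverageTrack("chr1", "+",
                                               np.asarray(cov_values))}
        return ann, tracks

    def test_monotone_coverage_gives_rho_one(self):
        # coverage strictly increasing toward the 3' end
        ann, tracks = self._setup(np.arange(400))
        hits = [("t1", p) for p in (220, 260, 300, 340, 370)]
        rho, p = three_prime_bias(hits, tracks, ann)
        assert rho == pytest.approx(1.0)

    def test_five_point_example_matches_rank_formula(self):
        cov = np.zeros(400)
        heights = {210: 7, 250: 3, 290: 9, 330: 1, 360: 5}
        for pos, h in heights.items():
            cov[pos : pos + 8] = h
        ann, tracks = self._setup(cov)
        hits = [("t1", p) for p in heights]
        rho, _ = three_prime_bias(hits, tracks, ann)
        # oracle: Spearman via the d^2 formula on hand-assigned ranks
        cov_ranks = stats.rankdata([heights[p] for p in heights])
        prox_ranks = stats.rankdata([-(400 - 1 - (p + 7)) for p in heights])
        d2 = ((cov_ranks - prox_ranks) ** 2).sum()
        n = 5
        want = 1 - 6 * d2 / (n * (n**2 - 1))
        assert rho == pytest.approx(want)

    def test_too_few_points_flagged(self):
        ann, tracks = self._setup(np.ones(400))
        with pytest.warns(UserWarning, match="undefined"):
            rho, p = three_prime_bias([("t1", 300)], tracks, ann)
        assert math.isnan(rho)

    def test_null_coverage_uncorrelated(self, rng):
        ann, tracks = self._setup(rng.integers(1, 50, size=400))
        hits = [("t1", int(p)) for p in rng.integers(210, 380, size=30)]
        rho, p = three_prime_bias(hits, tracks, ann)
        assert abs(rho) < 0.6
        assert p > 1e-4

    def test_default_simulation_shows_three_prime_bias(self, default_sim):
        # planted 3'UTR sites are skewed toward the 3' end with coverage
        # from real signal
        truth = default_sim.truth
        utr3 = truth[truth.feature_region == "3UTR"]
        hits = [(r.transcript_id, int(r.site_position)) for r in utr3.itertuples()]
        cov = default_sim.coverage(default_sim.pooled_experiment)
        rho, p = three_prime_bias(hits, cov, default_sim.annotation)
        assert rho > 0
        assert p < 0.01


def test_utr3_fbe_hits_find_planted_3utr_sites(default_sim):
    hits = landscape.utr3_fbe_hits(
        default_sim.annotation, default_sim.transcriptome.genome
    )
    got = {(tid, pos) for tid, pos in hits}
    truth = default_sim.truth
    planted = truth[
        (truth.feature_region == "3UTR")
        & truth.site_class.isin(["canonical", "canonical_context"])
    ]
    for r in planted.itertuples():
        assert (r.transcript_id, int(r.site_position)) in got


def fisher_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration: sum the
    probabilities of all tables (fixed margins) no more probable than the
    observed one."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = a + b + c + d

    def hyper(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = hyper(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestOverlapTest:
    def test_identical_lists_minimal_p(self):
        genes = [f"g{i}" for i in range(30)]
        odds, p = overlap_test(genes, genes, 100)
        assert math.isinf(odds)
        assert p < 1e-15

    def test_disjoint_lists_covering_universe(self):
        a = [f"g{i}" for i in range(50)]
        b = [f"g{i}" for i in range(50, 100)]
        odds, p = overlap_test(a, b, 100)
        assert odds == 0.0

    def test_table_matches_hypergeometric_oracle(self):
        # membership table (10,5;3,82)
        a = [f"x{i}" for i in range(15)]
        b = [f"x{i}" for i in range(10)] + [f"y{i}" for i in range(3)]
        odds, p = overlap_test(a, b, 100)
        assert p == pytest.approx(fisher_oracle([[10, 5], [3, 82]]), rel=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a_n, b_n = int(rng.integers(1, 20)), int(rng.integers(1, 20))
        both = int(rng.integers(0, min(a_n, b_n) + 1))
        universe = int(rng.integers(a_n + b_n + 5, 120))
        a = [f"s{i}" for i in range(a_n)]
        b = [f"s{i}" for i in range(both)] + [f"t{i}" for i in range(b_n - both)]
        _, p = overlap_test(a, b, universe)
        table = [
            [both, a_n - both],
            [b_n - both, universe - a_n - (b_n - both)],
        ]
        assert p == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(["a"], ["a"], 0)


class TestRankCorrelation:
    def test_identical_rankings(self):
        genes = list("abcdefgh")
        rho, _ = rank_correlation(genes, genes)
        assert rho == pytest.approx(1.0)

    def test_reversed_rankings(self):
        genes = list("abcdefgh")
        rho, _ = rank_correlation(genes, genes[::-1])
        assert rho == pytest.approx(-1.0)

    def test_small_n_permutation_exact_p(self):
        a = list("abcde")
        b = ["b", "a", "c", "e", "d"]
        rho, p = rank_correlation(a, b)
        # oracle: enumerate all 5! orderings of b
        ra = np.arange(5, dtype=float)
        rhos = []
        for perm in itertools.permutations(range(5)):
            rb = np.asarray(perm, dtype=float)
            rhos.append(stats.pearsonr(ra, rb).statistic)
        want = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(want)

    def test_shared_subset_only(self):
        a = ["a", "b", "c", "d", "q1", "q2"]
        b = ["d", "c", "b", "a", "z9"]
        rho, _ = rank_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_too_few_shared_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            rho, p = rank_correlation(["a", "b"], ["b", "a"])
        assert math.isnan(rho)
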