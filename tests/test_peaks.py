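"""Peak discovery, binning, background models, multiple-testing control."""

import math

import numpy as np
import pytest
from scipy import stats

from pufclip import peaks
from pufclip.model import CoverageTrack, ReadAlignment
from pufclip.peaks import (
    PeakCallConfig,
    Region,
    background_pvalue,
    benjamini_hochberg,
    bin_reads,
    find_candidate_peaks,
)


def _track(values, strand="+"):
    return CoverageTrack("chr1", strand, np.asarray(values))


def _read5p(pos, strand="+", chrom="chr1"):
    if strand == "+":
        return ReadAlignment(chrom, "+", pos, pos + 20)
    return ReadAlignment(chrom, "-", pos - 19, pos + 1)


# ---------------------------------------------------------------------------
# candidate discovery


def bruteforce_peaks(values, min_height, border_frac):
    """Independent oracle: enumerate local maxima, extend by threshold,
    merge overlaps by direct interval arithmetic."""
    v = list(values)
    n = len(v)
    spans = []
    for i in range(n):
        if v[i] < min_height:
            continue
        if i > 0 and v[i - 1] >= v[i]:
            continue
        j = i
        while j + 1 < n and v[j + 1] <= v[i]:
            # walk the plateau only
            if v[j + 1] < v[i]:
                break
            j += 1
        if (i == 0 or v[i - 1] < v[i]) and (j + 1 >= n or v[j + 1] < v[i]):
            thr = border_frac * v[i]
            lo = i
            while lo > 0 and v[lo - 1] >= thr:
                lo -= 1
            hi = j
            while hi + 1 < n and v[hi + 1] >= thr:
                hi += 1
            spans.append((lo, hi + 1))
    merged = []
    for s, e in sorted(spans):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [
        (s, e, max(v[s:e]), s + int(np.argmax(v[s:e]))) for s, e in merged
    ]


class TestFindCandidatePeaks:
    def test_twenty_percent_border_rule(self):
        # height 10 -> threshold 2; positions with coverage >= 2 are kept
        got = find_candidate_peaks(
            _track([0, 1, 5, 10, 5, 1, 0]), PeakCallConfig(min_height=5)
        )
        assert len(got) == 1
        p = got[0]
        assert (p.start, p.end, p.height, p.max_pos) == (2, 5, 10, 3)

    def test_flat_zero_track_has_no_peaks(self):
        assert find_candidate_peaks(_track([0] * 50)) == []

    def test_overlapping_maxima_merge_to_taller(self):
        v = [0, 0, 10, 4, 8, 0, 0]
        got = find_candidate_peaks(_track(v), PeakCallConfig(min_height=5))
        assert len(got) == 1
        assert got[0].height == 10
        assert got[0].max_pos == 2

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 25, size=120)
        cfg = PeakCallConfig(min_height=8)
        got = find_candidate_peaks(_track(v), cfg)
        want = bruteforce_peaks(v, cfg.min_height, cfg.border_frac)
        assert [(p.start, p.end, p.height) for p in got] == [
            (s, e, h) for s, e, h, _ in want
        ]


# ---------------------------------------------------------------------------
# binning


class TestBinReads:
    def test_bin_boundaries_by_five_prime(self):
        reads = [_read5p(p) for p in (0, 49, 50)]
        counts = bin_reads(reads, (0, 100), bin_width=50, chrom="chr1", strand="+")
        assert list(counts) == [2, 1]

    def test_empty_reads_zero_vector(self):
        counts = bin_reads([], (0, 130), bin_width=50, chrom="chr1", strand="+")
        assert list(counts) == [0, 0, 0]  # partial last bin kept

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_histogram_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = rng.integers(0, 500, size=200)
        reads = [_read5p(int(p)) for p in positions]
        counts = bin_reads(reads, (0, 500), bin_width=50, chrom="chr1", strand="+")
        want, _ = np.histogram(positions, bins=np.arange(0, 550, 50))
        assert np.array_equal(counts, want)

    def test_multi_interval_region_concatenates(self):
        region = Region("chr1", "+", [(0, 50), (100, 150)])
        reads = [_read5p(p) for p in (10, 110, 140)]
        counts = bin_reads(reads, region, bin_width=50)
        assert list(counts) == [1, 2]


# ---------------------------------------------------------------------------
# background models


def poisson_sf_oracle(k_minus_1, lam, terms=200):
    """Series summation of the Poisson upper tail, independent of scipy."""
    total = 0.0
    for i in range(0, k_minus_1 + 1):
        total += math.exp(-lam) * lam**i / math.factorial(i)
    return 1.0 - total


class TestBackgroundPvalue:
    @pytest.mark.parametrize("model", ["gaussian", "poisson", "negbinom"])
    def test_x_max_zero_is_certain(self, model):
        assert background_pvalue(0, np.array([3, 4, 5]), model) == 1.0

    def test_poisson_tail_equals_series_summation(self):
        bins = np.ones(100)  # lambda = 1
        p = background_pvalue(10, bins, "poisson")
        want = poisson_sf_oracle(9, 1.0)
        assert p == pytest.approx(want, rel=1e-9)
        assert p == pytest.approx(1.11e-7, rel=0.01)

    def test_gaussian_at_mean_is_half(self):
        assert background_pvalue(5, np.full(20, 5.0), "gaussian") == pytest.approx(0.5)

    def test_gaussian_tail_matches_erfc_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            bins = rng.integers(0, 30, size=rng.integers(5, 40))
            x = int(rng.integers(1, 60))
            p = background_pvalue(x, bins, "gaussian")
            mu, sd = bins.mean(), max(bins.std(), 1.0)
            want = 0.5 * math.erfc((x - mu) / (sd * math.sqrt(2)))
            assert p == pytest.approx(max(min(want, 1.0), 1e-300), abs=1e-12)

    def test_negbinom_falls_back_to_poisson_when_underdispersed(self):
        bins = np.full(30, 4.0)  # zero variance
        assert background_pvalue(9, bins, "negbinom") == pytest.approx(
            background_pvalue(9, bins, "poisson")
        )

    def test_negbinom_moment_fit_matches_scipy_construction(self):
        rng = np.random.default_rng(3)
        bins = rng.negative_binomial(5, 0.4, size=200)
        mu, var = bins.mean(), bins.var()
        n_param, p_param = mu * mu / (var - mu), mu / var
        want = stats.nbinom.sf(14, n_param, p_param)
        assert background_pvalue(15, bins, "negbinom") == pytest.approx(want)

    def test_empty_background_poisson_floor(self):
        p = background_pvalue(3, np.zeros(10), "poisson")
        assert 0 < p < 1e-3  # lambda floored at 1/n_bins

    def test_monotone_in_x_max(self):
        rng = np.random.default_rng(5)
        bins = rng.integers(0, 12, size=20)
        for model in ("gaussian", "poisson", "negbinom"):
            ps = [background_pvalue(x, bins, model) for x in range(0, 40)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_x_max_rejected(self):
        with pytest.raises(ValueError):
            background_pvalue(-1, np.ones(5), "poisson")


# ---------------------------------------------------------------------------
# multiple testing


def bh_oracle(pvals, q):
    """Brute-force BH step-up: largest k with p_(k) <= k/m * q rejected."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank / m * q:
            k_star = rank
    return {order[i] for i in range(k_star)}


class TestBenjaminiHochberg:
    def test_known_rejection_count(self):
        q = benjamini_hochberg([0.001, 0.02, 0.5])
        assert int((q <= 0.01).sum()) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_rejections_match_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        p = rng.random(n) ** rng.integers(1, 4)
        alpha = float(rng.choice([0.01, 0.05, 0.1]))
        rejected = set(np.flatnonzero(benjamini_hochberg(p) <= alpha))
        assert rejected == bh_oracle(list(p), alpha)

    def test_bonferroni_is_simple_multiplication(self):
        # a peak with p_raw = 1e-4 modeled over 10 bins
        calls = peaks.call_peaks(
            [peaks.CandidatePeak("chr1", "+", 240, 260, 30, 250)],
            [_read5p(250) for _ in range(30)],
            [],
            [],
            method=4,
            annotation=None,
            config=PeakCallConfig(),
            chrom_lengths={"chr1": 1000},
        )
        (c,) = calls
        assert c.p_bonferroni == pytest.approx(min(1.0, c.p_raw * c.n_bins_modeled))
        assert c.n_bins_modeled == 10


# ---------------------------------------------------------------------------
# six-method caller


class TestCallPeaks:
    def test_zero_background_candidate_survives_fdr(self):
        cand = peaks.CandidatePeak("chr1", "+", 240, 260, 50, 250)
        exp = [_read5p(250) for _ in range(50)]
        calls = peaks.call_peaks(
            [cand], exp, [], [], method=4, annotation=None,
            config=PeakCallConfig(), chrom_lengths={"chr1": 1000},
        )
        assert calls[0].significant
        assert calls[0].q_bh <= 0.01

    def test_method_mapping_background_and_region(self):
        assert peaks.METHOD_BACKGROUND[3] == peaks.METHOD_BACKGROUND[4] == "control"
        assert peaks.METHOD_BACKGROUND[1] == "rnaseq"
        assert peaks.METHOD_BACKGROUND[6] == "self"
        assert peaks.METHOD_REGION[1] == peaks.METHOD_REGION[3] == "whole_gene"
        assert peaks.METHOD_REGION[2] == peaks.METHOD_REGION[6] == "local"

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            peaks.call_peaks([], [], [], [], method=7, annotation=None)

    def test_whole_gene_fallback_outside_annotation_warns(self, small_sim):
        cand = peaks.CandidatePeak("synChrI", "+", 5, 15, 20, 10)
        # place the candidate in a spacer: find one
        ann = small_sim.annotation
        spacer_pos = max(tx.span[1] for tx in ann) + 50
        cand = peaks.CandidatePeak("synChrI", "+", spacer_pos, spacer_pos + 10,
                                   20, spacer_pos + 5)
        exp = [_read5p(cand.max_pos, chrom="synChrI") for _ in range(20)]
        with pytest.warns(UserWarning, match="local"):
            calls = peaks.call_peaks(
                [cand], exp, [], [], method=3, annotation=ann,
                config=PeakCallConfig(),
                chrom_lengths=small_sim.transcriptome.chrom_lengths,
            )
        assert calls[0].n_bins_modeled == 10  # local 500/50

    def test_self_background_always_poisson(self):
        # method 6 on a flat self background: tall bin against bin-mean lambda
        cand = peaks.CandidatePeak("chr1", "+", 240, 260, 30, 250)
        exp = [_read5p(250) for _ in range(30)] + [
            _read5p(int(p)) for p in np.linspace(0, 480, 20)
        ]
        calls = peaks.call_peaks(
            [cand], exp, [], [], method=6, annotation=None,
            config=PeakCallConfig(background_model="gaussian"),
            chrom_lengths={"chr1": 1000},
        )
        (c,) = calls
        region_reads = [r for r in exp if 0 <= r.five_prime_pos < 500]
        lam = np.mean(
            bin_reads(region_reads, (0, 500), 50, chrom="chr1", strand="+")
        )
        want = stats.poisson.sf(c.max_bin_count - 1, lam)
        assert c.p_raw == pytest.approx(want)
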