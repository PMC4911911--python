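"""Binding-landscape statistics.

Where does the protein bind within transcripts?  This module assigns peaks
to transcript features (5'UTR / CDS / 3'UTR / ncRNA / intergenic) by the
position of the peak maximum, decomposes merged peak regions into primary
and secondary sub-peaks ("un-merging"), quantifies the bias of binding
toward 3' ends, and provides the generic two-list overlap (Fisher exact)
and rank-correlation (Spearman) statistics used for target-list
comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Annotation, CoverageTrack
from .peaks import CandidatePeak, PeakCallConfig


@dataclass
class FeatureAssignment:
    peak: object
    gene_id: str | None
    region: str  # 5UTR|CDS|3UTR|ncRNA|intergenic
    distance_to_3p_end: int | None  # mature-transcript coordinates


def assign_feature(peak, annotation: Annotation) -> FeatureAssignment:
    """Feature region of the transcript interval containing the peak
    maximum; multi-isoform positions resolve to the longest mature
    transcript."""
    tx = annotation.best(peak.chrom, peak.strand, peak.max_pos)
    if tx is None:
        return FeatureAssignment(peak, None, "intergenic", None)
    region = tx.region_of(peak.max_pos)
    t = tx.genomic_to_transcript(peak.max_pos)
    return FeatureAssignment(peak, tx.gene_id, region, tx.mature_length - 1 - t)


def feature_fractions(assignments: Sequence[FeatureAssignment]) -> pd.Series:
    labels = [a.region for a in assignments]
    s = pd.Series(labels).value_counts(normalize=True)
    return s


def unmerge(
    peak,
    track: CoverageTrack,
    config: PeakCallConfig | None = None,
) -> list[CandidatePeak]:
    """Decompose a (possibly merged) peak region into distinct sub-peaks.

    Local maxima within the span become separate sub-peaks when the valley
    between neighbours falls strictly below border_frac times the smaller
    neighbour's height; otherwise they remain one peak.  Sub-peaks are
    returned ordered by height (tallest = primary).
    """
    config = config or PeakCallConfig()
    a, b = peak.start, peak.end
    v = np.asarray(track.values[a:b], dtype=np.int64)
    if v.size == 0 or v.max() < config.min_height:
        return []
    # local maxima (plateau-left representatives) above min_height
    maxima: list[int] = []
    for i in range(len(v)):
        if v[i] < config.min_height:
            continue
        if i > 0 and v[i - 1] >= v[i]:
            continue
        if i + 1 < len(v) and v[i + 1] > v[i]:
            continue
        maxima.append(i)
    if not maxima:
        maxima = [int(np.argmax(v))]
    # split at valleys strictly below threshold
    groups: list[list[int]] = [[maxima[0]]]
    for m_prev, m_next in zip(maxima, maxima[1:]):
        valley = v[m_prev : m_next + 1].min()
        thr = config.border_frac * min(v[m_prev], v[m_next])
        if valley < thr:
            groups.append([m_next])
        else:
            groups[-1].append(m_next)
    out: list[CandidatePeak] = []
    bounds: list[int] = [0]
    for g1, g2 in zip(groups, groups[1:]):
        lo, hi = g1[-1], g2[0]
        bounds.append(lo + int(np.argmin(v[lo : hi + 1])))
    bounds.append(len(v))
    for (s, e), g in zip(zip(bounds, bounds[1:]), groups):
        seg = v[s:e]
        mp = s + int(np.argmax(seg))
        h = int(seg.max())
        thr = config.border_frac * h
        lo = mp
        while lo > s and seg[lo - 1 - s] >= thr:
            lo -= 1
        hi = mp
        while hi + 1 < e and seg[hi + 1 - s] >= thr:
            hi += 1
        out.append(
            CandidatePeak(
                chrom=peak.chrom,
                strand=peak.strand,
                start=a + lo,
                end=a + hi + 1,
                height=h,
                max_pos=a + mp,
                replicate_id=getattr(peak, "replicate_id", 0),
            )
        )
    out.sort(key=lambda p: (-p.height, p.start))
    return out


def multi_peak_summary(
    sub_peaks_by_gene: dict[str, Sequence],
    annotation: Annotation,
) -> tuple[pd.DataFrame, float]:
    """Per-gene distinct-peak counts plus a two-sided rank-sum comparison
    of mature transcript length between multi-peak and single-peak genes.

    Returns (per-gene table, rank-sum p-value; NaN when either group is
    empty)."""
    rows = []
    for gid, plist in sorted(sub_peaks_by_gene.items()):
        txs = [t for t in annotation if t.gene_id == gid]
        mlen = max((t.mature_length for t in txs), default=np.nan)
        rows.append(
            dict(
                gene_id=gid,
                n_peaks=len(plist),
                multi=len(plist) > 1,
                mature_length=mlen,
            )
        )
    df = pd.DataFrame(rows, columns=["gene_id", "n_peaks", "multi", "mature_length"])
    multi = df.loc[df["multi"], "mature_length"].dropna()
    single = df.loc[~df["multi"], "mature_length"].dropna()
    if len(multi) and len(single):
        p = float(stats.mannwhitneyu(multi, single, alternative="two-sided").pvalue)
    else:
        p = float("nan")
    return df, p


def three_prime_bias(
    fbe_hits: Sequence[tuple[str, int]],
    coverage_by_strand: dict[tuple[str, str], CoverageTrack],
    annotation: Annotation,
    motif_length: int = 8,
) -> tuple[float, float]:
    """Spearman correlation between local read coverage of 3'UTR binding
    elements and their proximity to the transcript 3' end.

    ``fbe_hits`` are (transcript_id, motif start in mature coordinates).
    Proximity is the negative distance to the 3' end, so a positive rho
    means more heavily covered elements sit closer to the 3' terminus.
    Ties receive average ranks (the Spearman convention).  Fewer than
    three points is undefined: returns (nan, nan) with a warning.
    """
    cov_vals = []
    prox = []
    for tid, t_pos in fbe_hits:
        tx = annotation.by_id[tid]
        g_positions = [
            tx.transcript_to_genomic(t)
            for t in range(t_pos, min(t_pos + motif_length, tx.mature_length))
        ]
        track = coverage_by_strand.get((tx.chrom, tx.strand))
        if track is None:
            continue
        vals = [track.values[g] for g in g_positions if g < len(track.values)]
        if not vals:
            continue
        cov_vals.append(float(np.mean(vals)))
        dist = tx.mature_length - 1 - (t_pos + motif_length - 1)
        prox.append(-dist)
    if len(cov_vals) < 3:
        warnings.warn("three_prime_bias undefined for fewer than 3 elements")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(cov_vals, prox)
    return float(rho), float(p)


def utr3_fbe_hits(
    annotation: Annotation, genome: dict[str, str]
) -> list[tuple[str, int]]:
    """Canonical FBE occurrences inside annotated 3'UTRs, as
    (transcript_id, motif start in mature coordinates) pairs — the input
    expected by :func:`three_prime_bias`."""
    from .motifs import FBE, scan

    out: list[tuple[str, int]] = []
    for tx in annotation:
        bounds = tx.cds_transcript_bounds()
        if bounds is None:
            continue
        mat = tx.mature_sequence(genome)
        utr3_seq = mat[bounds[1] :]
        for hit in scan(utr3_seq, FBE):
            out.append((tx.transcript_id, bounds[1] + hit.offset))
    return out


def overlap_test(
    list_a: Sequence[str], list_b: Sequence[str], universe_size: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test for overlap of two gene lists drawn
    from a universe of the given size.  Returns (odds ratio, p)."""
    if universe_size <= 0:
        raise ValueError("universe must be non-empty")
    a, b = set(list_a), set(list_b)
    if len(a | b) > universe_size:
        raise ValueError("lists exceed the stated universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = universe_size - both - only_a - only_b
    odds, p = stats.fisher_exact(
        [[both, only_a], [only_b, neither]], alternative="two-sided"
    )
    return float(odds), float(p)


def rank_correlation(
    ranked_a: Sequence[str], ranked_b: Sequence[str]
) -> tuple[float, float]:
    """Spearman rank correlation between two ranked target lists over
    their shared items.

    Ranks are positions within each list restricted to the intersection.
    The p-value uses exact permutation enumeration for n <= 9 and the
    t-approximation otherwise.  Fewer than three shared items is
    undefined: returns (nan, nan).
    """
    pos_a = {g: i for i, g in enumerate(ranked_a)}
    pos_b = {g: i for i, g in enumerate(ranked_b)}
    shared = [g for g in ranked_a if g in pos_b]
    n = len(shared)
    if n < 3:
        warnings.warn("rank_correlation undefined for fewer than 3 shared items")
        return float("nan"), float("nan")
    ra = stats.rankdata([pos_a[g] for g in shared])
    rb = stats.rankdata([pos_b[g] for g in shared])
    rho = float(stats.spearmanr(ra, rb).statistic)
    if n <= 9:
        # exact permutation null on the rank vector
        null = []
        for perm in itertools.permutations(range(n)):
            null.append(abs(_pearson(ra, np.asarray(perm, dtype=float))))
        null = np.asarray(null)
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(ra, rb).pvalue)
    return rho, p


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom else 0.0
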