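"""Candidate peak discovery and the six background-model peak callers.

Candidate peaks are local coverage maxima whose borders are placed where
read density falls to 20% of the peak height; overlapping candidates are
merged.  Each candidate's tallest 50-nt bin of read 5' ends is then tested
against one of three background read sources (RNA-seq, negative-control
iCLIP, or the experimental iCLIP signal itself) binned over one of two
regions (all exons of the target transcript, "whole gene", or the 500-bp
genomic window around the candidate maximum, "local"):

    method 1: RNA-seq background, whole gene     method 2: RNA-seq, local
    method 3: control iCLIP,     whole gene      method 4: control, local
    method 5: self iCLIP,        whole gene      method 6: self,    local

RNA-seq and control backgrounds are modeled as a Gaussian or a negative
binomial fit to the background bins; the self-iCLIP background is always
modeled as a Poisson on the assumption that sharp signal enrichments are
true peaks and background looks like flat coverage.  Raw p-values receive a
per-peak Bonferroni factor (the number of bins used for modeling) and a
Benjamini-Hochberg correction over the full candidate set at a 1% FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Annotation, CoverageTrack, Interval, ReadAlignment

METHOD_BACKGROUND = {1: "rnaseq", 2: "rnaseq", 3: "control", 4: "control",
                     5: "self", 6: "self"}
METHOD_REGION = {1: "whole_gene", 2: "local", 3: "whole_gene", 4: "local",
                 5: "whole_gene", 6: "local"}


@dataclass
class PeakCallConfig:
    bin_width: int = 50
    local_window: int = 500
    border_frac: float = 0.2
    min_height: int = 10
    fdr_q: float = 0.01
    background_model: Literal["gaussian", "poisson", "negbinom"] = "gaussian"
    gaussian_sigma_floor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.border_frac < 1.0:
            raise ValueError("border_frac must be in (0, 1)")
        if self.bin_width < 1 or self.local_window < self.bin_width:
            raise ValueError("bad bin/window sizes")


@dataclass
class CandidatePeak:
    chrom: str
    strand: str
    start: int
    end: int
    height: int
    max_pos: int
    replicate_id: int = 0

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass
class PeakCall:
    candidate: CandidatePeak
    method: int
    max_bin_count: int
    p_raw: float
    p_bonferroni: float
    n_bins_modeled: int
    q_bh: float = float("nan")
    significant: bool = False

    def __getattr__(self, item):
        # convenience passthrough (chrom, strand, start, end, height, ...)
        return getattr(object.__getattribute__(self, "candidate"), item)


def find_candidate_peaks(
    track: CoverageTrack,
    config: PeakCallConfig | None = None,
    merge: bool = True,
    replicate_id: int = 0,
) -> list[CandidatePeak]:
    """Local maxima with height >= min_height, extended bidirectionally
    until coverage drops below border_frac x height; overlapping spans are
    merged (merged height = max of members).  Deterministic left-to-right
    processing."""
    config = config or PeakCallConfig()
    v = np.asarray(track.values)
    n = len(v)
    spans: list[tuple[int, int, int, int]] = []  # start, end, height, max_pos
    i = 0
    while i < n:
        # candidate must clear the height threshold and be a plateau-left
        if v[i] < config.min_height or (i > 0 and v[i - 1] >= v[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 < n and v[j + 1] > v[i]:  # rising plateau, not a maximum
            i = j + 1
            continue
        h = int(v[i])
        thr = config.border_frac * h
        lo = i
        while lo > 0 and v[lo - 1] >= thr:
            lo -= 1
        hi = j
        while hi + 1 < n and v[hi + 1] >= thr:
            hi += 1
        seg = v[lo : hi + 1]
        mp = lo + int(np.argmax(seg))
        spans.append((lo, hi + 1, int(seg.max()), mp))
        i = j + 1  # every local maximum is processed; overlaps merge below
    if merge:
        spans = _merge_spans(spans)
    return [
        CandidatePeak(track.chrom, track.strand, s, e, h, mp, replicate_id)
        for s, e, h, mp in spans
    ]


def _merge_spans(spans):
    merged = []
    for s, e, h, mp in sorted(spans):
        if merged and s < merged[-1][1]:
            ps, pe, ph, pmp = merged[-1]
            nh, nmp = (h, mp) if h > ph else (ph, pmp)
            merged[-1] = (ps, max(pe, e), nh, nmp)
        else:
            merged.append((s, e, h, mp))
    return merged


class Region:
    """A (possibly multi-interval) genomic region with a concatenated
    coordinate axis, used for binning reads."""

    def __init__(self, chrom: str, strand: str, intervals: Sequence[Interval]):
        self.chrom = chrom
        self.strand = strand
        self.intervals = sorted((int(a), int(b)) for a, b in intervals)
        self._offsets = np.cumsum([0] + [b - a for a, b in self.intervals])
        self.length = int(self._offsets[-1])

    def to_region_coord(self, g: int) -> int | None:
        for (a, b), off in zip(self.intervals, self._offsets):
            if a <= g < b:
                return int(off) + (g - a)
        return None


def bin_reads(
    reads: Iterable[ReadAlignment],
    region: Region | Interval,
    bin_width: int = 50,
    chrom: str | None = None,
    strand: str | None = None,
) -> np.ndarray:
    """Counts of read 5' ends per non-overlapping ``bin_width``-nt bin tiled
    from the region start; a partial last bin is kept."""
    if not isinstance(region, Region):
        if chrom is None or strand is None:
            raise ValueError("chrom/strand required for a bare interval")
        region = Region(chrom, strand, [region])
    if region.length < bin_width:
        raise ValueError("region shorter than one bin")
    n_bins = int(np.ceil(region.length / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    for r in reads:
        if r.chrom != region.chrom or r.strand != region.strand:
            continue
        rc = region.to_region_coord(r.five_prime_pos)
        if rc is not None:
            counts[rc // bin_width] += 1
    return counts


def background_pvalue(
    x_max: int,
    background_bins: np.ndarray,
    model: str,
    sigma_floor: float = 1.0,
) -> float:
    """Upper-tail probability of a bin with at least ``x_max`` reads under a
    distribution fit to the background bins.

    gaussian:  P(X >= x_max) for Normal(mean, sd) with sd floored;
    poisson:   survival at x_max - 1 with lambda = bin mean (floored at
               1/n_bins when the background is empty);
    negbinom:  method-of-moments fit, falling back to Poisson when the
               variance does not exceed the mean.
    """
    if x_max < 0:
        raise ValueError("x_max must be nonnegative")
    bins = np.asarray(background_bins, dtype=float)
    if bins.size == 0:
        raise ValueError("background_bins must be non-empty")
    if x_max == 0:
        return 1.0
    mu = float(bins.mean())
    if model == "gaussian":
        sd = max(float(bins.std()), sigma_floor)
        p = float(stats.norm.sf(x_max, loc=mu, scale=sd))
    elif model == "poisson":
        lam = mu if mu > 0 else 1.0 / bins.size
        p = float(stats.poisson.sf(x_max - 1, lam))
    elif model == "negbinom":
        var = float(bins.var())
        if var <= mu or mu == 0:
            lam = mu if mu > 0 else 1.0 / bins.size
            p = float(stats.poisson.sf(x_max - 1, lam))
        else:
            n_param = mu * mu / (var - mu)
            p_param = mu / var
            p = float(stats.nbinom.sf(x_max - 1, n_param, p_param))
    else:
        raise ValueError(f"unknown background model {model!r}")
    return min(max(p, 1e-300), 1.0)


def _local_region(cand: CandidatePeak, window: int, chrom_len: int | None) -> Region:
    half = window // 2
    a = max(0, cand.max_pos - half)
    b = cand.max_pos + half
    if chrom_len is not None:
        b = min(b, chrom_len)
        a = max(0, min(a, b - window)) if b - a < window and b >= window else a
    return Region(cand.chrom, cand.strand, [(a, b)])


def call_peaks(
    candidates: Sequence[CandidatePeak],
    experiment_reads: Sequence[ReadAlignment],
    control_reads: Sequence[ReadAlignment],
    rnaseq_reads: Sequence[ReadAlignment],
    method: int,
    annotation: Annotation | None,
    config: PeakCallConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[PeakCall]:
    """Score every candidate with one of the six methods and apply
    Bonferroni (per peak) and Benjamini-Hochberg (over the candidate set)
    corrections.  Calls with q <= fdr_q are flagged significant."""
    config = config or PeakCallConfig()
    if method not in METHOD_BACKGROUND:
        raise ValueError(f"method must be 1..6, got {method}")
    source = {
        "rnaseq": rnaseq_reads,
        "control": control_reads,
        "self": experiment_reads,
    }[METHOD_BACKGROUND[method]]
    model = "poisson" if METHOD_BACKGROUND[method] == "self" else config.background_model
    whole_gene = METHOD_REGION[method] == "whole_gene"

    calls: list[PeakCall] = []
    for cand in candidates:
        region = None
        if whole_gene:
            tx = annotation.best(cand.chrom, cand.strand, cand.max_pos) if annotation else None
            if tx is None:
                warnings.warn(
                    f"candidate at {cand.chrom}:{cand.max_pos} outside any "
                    "transcript; falling back to local region"
                )
            elif tx.mature_length >= config.bin_width:
                region = Region(cand.chrom, cand.strand, tx.exons)
        if region is None:
            region = _local_region(
                cand, config.local_window,
                (chrom_lengths or {}).get(cand.chrom),
            )
        exp_bins = bin_reads(experiment_reads, region, config.bin_width)
        bg_bins = bin_reads(source, region, config.bin_width)
        x_max = _max_bin_in_span(exp_bins, region, cand, config.bin_width)
        p_raw = background_pvalue(
            x_max, bg_bins, model, sigma_floor=config.gaussian_sigma_floor
        )
        calls.append(
            PeakCall(
                candidate=cand,
                method=method,
                max_bin_count=int(x_max),
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * len(bg_bins)),
                n_bins_modeled=len(bg_bins),
            )
        )
    if calls:
        q = benjamini_hochberg([c.p_raw for c in calls])
        for c, qv in zip(calls, q):
            c.q_bh = float(qv)
            c.significant = qv <= config.fdr_q
    return calls


def _max_bin_in_span(exp_bins, region: Region, cand: CandidatePeak, bw: int) -> int:
    idx = set()
    for g in (cand.start, cand.max_pos, cand.end - 1):
        rc = region.to_region_coord(g)
        if rc is not None:
            idx.add(rc // bw)
    # include every bin overlapped by the candidate span
    for g in range(cand.start, cand.end, bw):
        rc = region.to_region_coord(g)
        if rc is not None:
            idx.add(rc // bw)
    if not idx:
        return int(exp_bins.max(initial=0))
    return int(max(exp_bins[i] for i in sorted(idx) if i < len(exp_bins)))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up q-values over the full candidate set."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significant_calls(calls: Iterable[PeakCall]) -> list[PeakCall]:
    return [c for c in calls if c.significant]
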