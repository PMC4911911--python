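"""Replicate consensus and secondary filtering.

After per-replicate peak calling, peaks are kept only if (i) an overlapping
peak range was called in at least ``k_required`` replicates (3-of-3 for a
single protein; 5-of-6 when two proteins' replicates are combined), and
(ii) experimental iCLIP reads exceed negative-control reads at least
fivefold within the local 500-bp window around the peak maximum, with the
control floored at one read.  Peak heights are normalized to RNA abundance
using RNA-seq, and a per-gene target list is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Annotation, Interval, ReadAlignment
from .peaks import CandidatePeak, PeakCall


@dataclass
class FilterConfig:
    min_ratio: float = 5.0
    window: int = 500
    k_required: int = 3
    # alternative normalized reads-in-peak filters used for replicate
    # Venn-style reporting only
    merged_ratio: float = 3.0
    per_replicate_ratio: float = 2.5

    def __post_init__(self) -> None:
        if self.min_ratio < 0:
            raise ValueError("min_ratio must be >= 0")


@dataclass
class ConsensusPeak:
    chrom: str
    strand: str
    start: int  # union of overlapping replicate spans
    end: int
    height: int  # max over members
    max_pos: int  # max_pos of the tallest member
    support: int  # number of distinct replicates contributing
    members: list = field(default_factory=list)
    enrichment_ratio: float | None = None
    normalized_height: float | None = None
    gene_id: str | None = None
    rank: int | None = None

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


def _reads_in_window(
    reads: Sequence[ReadAlignment], chrom: str, strand: str, a: int, b: int
) -> int:
    return sum(
        1
        for r in reads
        if r.chrom == chrom and r.strand == strand and r.start < b and r.end > a
    )


def enrichment_filter(
    peaks: Sequence,
    experiment_reads: Sequence[ReadAlignment],
    control_reads: Sequence[ReadAlignment],
    config: FilterConfig | None = None,
) -> list:
    """Keep peaks with >= min_ratio-fold more experimental than control
    reads in the window centered on the peak maximum (control floored at
    1 read; the boundary ratio is kept).  Records the ratio on peaks that
    expose an ``enrichment_ratio`` attribute."""
    config = config or FilterConfig()
    half = config.window // 2
    kept = []
    for p in peaks:
        a, b = p.max_pos - half, p.max_pos + half
        n_exp = _reads_in_window(experiment_reads, p.chrom, p.strand, a, b)
        n_ctl = _reads_in_window(control_reads, p.chrom, p.strand, a, b)
        ratio = n_exp / max(n_ctl, 1)
        if hasattr(p, "enrichment_ratio"):
            p.enrichment_ratio = ratio
        if ratio >= config.min_ratio:
            kept.append(p)
    return kept


def reproducible_peaks(
    replicate_peak_sets: Sequence[Sequence],
    k_required: int = 3,
) -> list[ConsensusPeak]:
    """Cluster peaks across replicates by span overlap (>= 1 nt, same
    chromosome and strand; transitive chains merge into one cluster) and
    keep clusters supported by at least ``k_required`` replicates.

    The consensus span is the union of member spans, the height the
    maximum over members.
    """
    if not replicate_peak_sets:
        raise ValueError("need at least one replicate peak set")
    items = []  # (chrom, strand, start, end, replicate_idx, peak)
    for ridx, peaks in enumerate(replicate_peak_sets):
        for p in peaks:
            items.append((p.chrom, p.strand, p.start, p.end, ridx, p))
    items.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    out: list[ConsensusPeak] = []
    cluster: list = []

    def _flush():
        if not cluster:
            return
        support = len({ridx for *_x, ridx, _p in cluster})
        if support >= k_required:
            tallest = max((p for *_x, _r, p in cluster), key=lambda p: p.height)
            out.append(
                ConsensusPeak(
                    chrom=cluster[0][0],
                    strand=cluster[0][1],
                    start=min(c[2] for c in cluster),
                    end=max(c[3] for c in cluster),
                    height=int(tallest.height),
                    max_pos=int(tallest.max_pos),
                    support=support,
                    members=[(ridx, p) for *_x, ridx, p in cluster],
                )
            )

    cur_end = None
    cur_key = None
    for chrom, strand, s, e, ridx, p in items:
        key = (chrom, strand)
        if cluster and key == cur_key and s < cur_end:
            cluster.append((chrom, strand, s, e, ridx, p))
            cur_end = max(cur_end, e)
        else:
            _flush()
            cluster = [(chrom, strand, s, e, ridx, p)]
            cur_key, cur_end = key, e
    _flush()
    return out


def assign_gene(peak, annotation: Annotation) -> str | None:
    """Assign a peak to the transcript whose exons contain its maximum;
    among several, the longest mature transcript wins."""
    tx = annotation.best(peak.chrom, peak.strand, peak.max_pos)
    return None if tx is None else tx.gene_id


def normalize_height(
    peak,
    rnaseq_reads: Sequence[ReadAlignment],
    annotation: Annotation,
    epsilon: float = 0.1,
    total_mapped: int | None = None,
) -> float | None:
    """Peak height divided by the gene's RNA-seq density.

    Density is gene read count per mature kilobase... concretely:
    (reads in gene / mature_length) scaled per million mapped reads,
    floored at ``epsilon`` so sparsely covered genes do not explode.
    Returns None when the peak lies outside the annotation.
    """
    tx = annotation.best(peak.chrom, peak.strand, peak.max_pos)
    if tx is None:
        return None
    total = total_mapped if total_mapped is not None else max(len(rnaseq_reads), 1)
    count = sum(
        1
        for r in rnaseq_reads
        if r.chrom == tx.chrom and r.strand == tx.strand and tx.contains(r.five_prime_pos)
    )
    density = (count / tx.mature_length) * (1e6 / total)
    return float(peak.height) / max(density, epsilon)


def attach_normalized_heights(
    peaks: Iterable[ConsensusPeak],
    rnaseq_reads: Sequence[ReadAlignment],
    annotation: Annotation,
    epsilon: float = 0.1,
) -> None:
    total = max(len(rnaseq_reads), 1)
    for p in peaks:
        p.gene_id = assign_gene(p, annotation)
        p.normalized_height = normalize_height(
            p, rnaseq_reads, annotation, epsilon=epsilon, total_mapped=total
        )


def reads_in_peak_ratio(
    peak,
    experiment_reads: Sequence[ReadAlignment],
    control_reads: Sequence[ReadAlignment],
    exp_total: int | None = None,
    ctrl_total: int | None = None,
) -> float:
    """Library-size-normalized experiment/control read ratio over the peak
    span itself (not the surrounding window); control floored at 1 read."""
    n_exp = _reads_in_window(experiment_reads, peak.chrom, peak.strand,
                             peak.start, peak.end)
    n_ctl = _reads_in_window(control_reads, peak.chrom, peak.strand,
                             peak.start, peak.end)
    exp_total = exp_total if exp_total else max(len(experiment_reads), 1)
    ctrl_total = ctrl_total if ctrl_total else max(len(control_reads), 1)
    return (n_exp / exp_total) / (max(n_ctl, 1) / ctrl_total)


def replicate_target_venn(
    per_replicate_peaks: Sequence[Sequence],
    reads_per_replicate: Sequence[Sequence[ReadAlignment]],
    control_reads: Sequence[ReadAlignment],
    annotation: Annotation,
    config: FilterConfig | None = None,
) -> tuple[list[set[str]], dict[str, int]]:
    """Per-replicate target gene sets under the normalized reads-in-peak
    filter, for Venn-style reproducibility reporting.

    Individual replicate peaks pass at ``per_replicate_ratio`` (2.5); the
    slightly stricter ``merged_ratio`` (3) applies to merged peak regions
    elsewhere.  Returns the per-replicate gene sets and the counts of every
    non-empty replicate combination (keys like ``"0&2"``).
    """
    config = config or FilterConfig()
    gene_sets: list[set[str]] = []
    for peaks_i, reads_i in zip(per_replicate_peaks, reads_per_replicate):
        genes: set[str] = set()
        for p in peaks_i:
            ratio = reads_in_peak_ratio(p, reads_i, control_reads)
            if ratio >= config.per_replicate_ratio:
                gid = assign_gene(p, annotation)
                if gid is not None:
                    genes.add(gid)
        gene_sets.append(genes)
    counts: dict[str, int] = {}
    all_genes = set().union(*gene_sets) if gene_sets else set()
    for gene in all_genes:
        combo = "&".join(
            str(i) for i, s in enumerate(gene_sets) if gene in s
        )
        counts[combo] = counts.get(combo, 0) + 1
    return gene_sets, counts


def build_target_list(
    consensus_peaks: Sequence[ConsensusPeak], annotation: Annotation
) -> tuple[pd.DataFrame, list[ConsensusPeak]]:
    """One row per gene: peak count, tallest peak height/location, and rank
    by tallest normalized height (ties broken by gene id).  Peaks that fall
    outside the annotation are returned separately."""
    unassigned: list[ConsensusPeak] = []
    per_gene: dict[str, list[ConsensusPeak]] = {}
    for p in consensus_peaks:
        gid = p.gene_id if p.gene_id is not None else assign_gene(p, annotation)
        p.gene_id = gid
        if gid is None:
            unassigned.append(p)
        else:
            per_gene.setdefault(gid, []).append(p)
    rows = []
    for gid, plist in per_gene.items():
        tallest = max(plist, key=lambda p: (p.height, -p.start))
        norm = tallest.normalized_height
        rows.append(
            dict(
                gene_id=gid,
                peak_count=len(plist),
                tallest_height=tallest.height,
                tallest_normalized_height=norm,
                chrom=tallest.chrom,
                strand=tallest.strand,
                tallest_start=tallest.start,
                tallest_end=tallest.end,
                tallest_max_pos=tallest.max_pos,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "peak_count",
            "tallest_height",
            "tallest_normalized_height",
            "chrom",
            "strand",
            "tallest_start",
            "tallest_end",
            "tallest_max_pos",
        ],
    )
    if len(df):
        key = df["tallest_normalized_height"]
        if key.isna().all():
            key = df["tallest_height"]
        df = df.sort_values(
            by=[key.name, "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        df["rank"] = pd.Series(dtype=int)
    return df, unassigned
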