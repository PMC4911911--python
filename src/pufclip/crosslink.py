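"""Crosslink-site inference from reverse-transcription errors.

Two signals locate the protein-RNA crosslink at nucleotide resolution:

* CIMS (crosslinking-induced mutation sites): read-through cDNAs retain a
  single-base deletion at the crosslinked nucleotide.  Each position with
  deletions is tested with an upper-tail binomial against the global
  deletion rate (total deletions / total covered bases).
* CITS (crosslinking-induced truncation sites): most cDNAs terminate at
  the crosslink, so read 5' ends pile up one base 3' of it.  The crosslink
  position is the base immediately upstream (in the read's 5' direction)
  of the read start; pile-ups are tested against a Poisson whose rate is
  the mean start rate over the containing gene's exonic span (reads
  outside the annotation are pooled into a genome-wide background rate).

Sites with p < 0.001 in at least ``min_support`` replicates are reported
as reproducible.  Only deletions and truncations are considered;
substitution- or insertion-based signals are not.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Annotation, ReadAlignment

P_THRESHOLD = 1e-3


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    strand: str
    position: int
    kind: str  # "CIMS" | "CITS"
    event_count: int
    depth: int
    p_value: float
    replicate_support: int = 1


_CIMS_COLUMNS = ["chrom", "strand", "position", "k", "n", "p"]


def find_cims(reads: Sequence[ReadAlignment]) -> pd.DataFrame:
    """Per-position deletion test for one replicate.

    Returns every position carrying >= 1 deletion with its deletion count
    ``k``, read depth ``n``, and upper-tail binomial p-value against the
    global per-base deletion rate.  Positions without deletions have p = 1
    and are omitted from the table; the size of the full per-position test
    universe (distinct covered positions) is recorded as
    ``df.attrs["n_positions_tested"]`` for type-I-rate accounting.
    """
    if not reads:
        df = pd.DataFrame(columns=_CIMS_COLUMNS)
        df.attrs["n_positions_tested"] = 0
        return df
    del_counts: Counter = Counter()
    total_covered = 0
    total_dels = 0
    intervals: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for r in reads:
        total_covered += r.length
        intervals[(r.chrom, r.strand)].append((r.start, r.end))
        for d in r.deletion_positions:
            del_counts[(r.chrom, r.strand, d)] += 1
            total_dels += 1
    n_tested = 0
    for ivs in intervals.values():
        ivs.sort()
        cur_a, cur_b = ivs[0]
        for a, b in ivs[1:]:
            if a <= cur_b:
                cur_b = max(cur_b, b)
            else:
                n_tested += cur_b - cur_a
                cur_a, cur_b = a, b
        n_tested += cur_b - cur_a
    if total_covered == 0 or total_dels == 0:
        df = pd.DataFrame(columns=_CIMS_COLUMNS)
        df.attrs["n_positions_tested"] = n_tested
        return df
    rate = total_dels / total_covered
    # depth at deletion positions only (span-based coverage)
    depth: Counter = Counter()
    keys = set(del_counts)
    by_cs: dict[tuple[str, str], list[int]] = defaultdict(list)
    for chrom, strand, pos in keys:
        by_cs[(chrom, strand)].append(pos)
    for (chrom, strand), positions in by_cs.items():
        positions = np.array(sorted(positions))
        for r in reads:
            if r.chrom != chrom or r.strand != strand:
                continue
            lo = np.searchsorted(positions, r.start, side="left")
            hi = np.searchsorted(positions, r.end - 1, side="right")
            for p in positions[lo:hi]:
                depth[(chrom, strand, int(p))] += 1
    rows = []
    for (chrom, strand, pos), k in sorted(del_counts.items()):
        n = depth[(chrom, strand, pos)]
        p = float(stats.binom.sf(k - 1, n, rate))
        rows.append(dict(chrom=chrom, strand=strand, position=pos, k=k, n=n, p=p))
    df = pd.DataFrame(rows, columns=_CIMS_COLUMNS)
    df.attrs["n_positions_tested"] = n_tested
    return df


_CITS_COLUMNS = ["chrom", "strand", "position", "k", "lam", "p"]


def _cits_position(r: ReadAlignment) -> int:
    """Crosslink = base immediately 5' (read orientation) of the read start."""
    return r.five_prime_pos - 1 if r.strand == "+" else r.five_prime_pos + 1


def find_cits(
    reads: Sequence[ReadAlignment], annotation: Annotation | None
) -> pd.DataFrame:
    """Truncation pile-up test for one replicate.

    ``k`` counts read starts whose inferred crosslink is the position;
    the Poisson rate is per-base over the containing gene's exonic span.
    Positions without starts have p ~ 1 and are omitted from the table;
    ``df.attrs["n_positions_tested"]`` records the full per-position test
    universe (exonic span of every gene holding >= 1 start, plus the
    genome-background span when unassigned reads exist).
    """
    if not reads:
        df = pd.DataFrame(columns=_CITS_COLUMNS)
        df.attrs["n_positions_tested"] = 0
        return df
    starts: Counter = Counter()
    for r in reads:
        starts[(r.chrom, r.strand, _cits_position(r))] += 1

    # split positions by containing transcript to set the local null rate
    gene_counts: Counter = Counter()
    gene_of: dict[tuple, str | None] = {}
    unassigned_total = 0
    for key, k in starts.items():
        chrom, strand, pos = key
        tx = annotation.best(chrom, strand, pos) if annotation is not None else None
        gene_of[key] = tx.transcript_id if tx is not None else None
        if tx is not None:
            gene_counts[tx.transcript_id] += k
        else:
            unassigned_total += k
    genome_len = 0
    if annotation is not None and len(annotation):
        genome_len = max(tx.span[1] for tx in annotation)
    genome_len = max(genome_len, max((p for _, _, p in starts), default=0) + 1)
    bg_lambda = max(unassigned_total, 1) / max(genome_len, 1)

    rows = []
    for (chrom, strand, pos), k in sorted(starts.items()):
        tid = gene_of[(chrom, strand, pos)]
        if tid is not None:
            tx = annotation.by_id[tid]
            lam = gene_counts[tid] / tx.mature_length
        else:
            lam = bg_lambda
        p = float(stats.poisson.sf(k - 1, lam))
        rows.append(
            dict(chrom=chrom, strand=strand, position=pos, k=k, lam=lam, p=p)
        )
    df = pd.DataFrame(rows, columns=_CITS_COLUMNS)
    tested = sum(
        annotation.by_id[tid].mature_length for tid in gene_counts
    ) if annotation is not None else 0
    if unassigned_total > 0:
        tested += genome_len
    df.attrs["n_positions_tested"] = tested
    return df


def significant_sites(df: pd.DataFrame, alpha: float = P_THRESHOLD) -> pd.DataFrame:
    """Rows below the raw significance threshold (no multiple-testing
    correction; the interface is a raw P < 0.001 cutoff)."""
    if df.empty:
        return df
    return df[df["p"] < alpha].reset_index(drop=True)


def reproducible_sites(
    replicate_site_dfs: Sequence[pd.DataFrame],
    kind: str,
    min_support: int = 2,
    alpha: float = P_THRESHOLD,
) -> list[CrosslinkSite]:
    """Sites significant at identical (chrom, strand, position) in at least
    ``min_support`` replicates; merged event count is the sum."""
    if len(replicate_site_dfs) < 1:
        return []
    tally: dict[tuple, list[tuple[int, int, float]]] = defaultdict(list)
    for df in replicate_site_dfs:
        sig = significant_sites(df, alpha)
        for row in sig.itertuples():
            depth = getattr(row, "n", None)
            if depth is None or (isinstance(depth, float) and np.isnan(depth)):
                depth = row.k
            tally[(row.chrom, row.strand, int(row.position))].append(
                (int(row.k), int(depth), float(row.p))
            )
    out = []
    for (chrom, strand, pos), events in sorted(tally.items()):
        if len(events) < min_support:
            continue
        out.append(
            CrosslinkSite(
                chrom=chrom,
                strand=strand,
                position=pos,
                kind=kind,
                event_count=sum(k for k, _, _ in events),
                depth=max(d for _, d, _ in events),
                p_value=min(p for _, _, p in events),
                replicate_support=len(events),
            )
        )
    return out


def crosslink_profile(
    sites: Sequence[CrosslinkSite],
    fbe_anchors: Sequence[tuple[str, str, int]],
    window: int = 20,
) -> pd.DataFrame:
    """Counts of crosslink sites at each offset relative to the FBE start
    (U1 = offset 0), strand-aware, normalized to sum 1.

    ``fbe_anchors`` are (chrom, strand, genomic position of the motif's
    first base) for FBE occurrences inside peaks; each site is tallied
    against its nearest anchor within the window.
    """
    offsets = np.arange(-window, window + 1)
    counts = np.zeros_like(offsets, dtype=float)
    anchors_by = defaultdict(list)
    for chrom, strand, pos in fbe_anchors:
        anchors_by[(chrom, strand)].append(pos)
    for v in anchors_by.values():
        v.sort()
    for s in sites:
        arr = anchors_by.get((s.chrom, s.strand))
        if not arr:
            continue
        i = int(np.searchsorted(arr, s.position))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                d = abs(s.position - arr[j])
                if best is None or d < best[0]:
                    best = (d, arr[j])
        if best is None:
            continue
        anchor = best[1]
        off = s.position - anchor if s.strand == "+" else anchor - s.position
        if -window <= off <= window:
            counts[off + window] += 1
    total = counts.sum()
    frac = counts / total if total > 0 else counts
    return pd.DataFrame({"offset": offsets, "count": counts.astype(int),
                         "fraction": frac})


def site_windows(
    sites: Sequence[CrosslinkSite],
    genome: Mapping[str, str],
    flank: int = 10,
) -> list[tuple[str, str]]:
    """21-nt (2*flank+1) RNA-sense windows centered on each site, for
    downstream motif searches."""
    from .motifs import extract_window

    out = []
    for i, s in enumerate(sites):
        seq, _ = extract_window(genome, s.chrom, s.strand, s.position,
                                2 * flank + 1)
        out.append((f"{s.kind}_{s.chrom}_{s.position}_{s.strand}", seq))
    return out
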