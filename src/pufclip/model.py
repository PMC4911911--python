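"""Core data structures shared across the pipeline.

Coordinates are 0-based half-open genomic intervals throughout; GFF3's
1-based closed convention is converted at the I/O boundary only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped, deduplicated read.

    ``deletion_positions`` are genomic coordinates of single-base CIGAR
    deletions (reference consumed, query skipped).  ``five_prime_pos`` is the
    strand-aware coordinate of the read's 5' end: ``start`` on the plus
    strand, ``end - 1`` on the minus strand.
    """

    chrom: str
    strand: str
    start: int
    end: int
    mapq: int = 255
    barcode: str = ""
    deletion_positions: tuple[int, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty read interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for d in self.deletion_positions:
            if not (self.start <= d < self.end):
                raise ValueError("deletion outside read span")

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A transcript: exons, optional CDS, and derived UTRs.

    Exons are stored sorted by genomic coordinate; transcript (mature)
    coordinates run 5'->3' in the orientation given by ``strand``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_span: Interval | None = None
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise ValueError("empty exon")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b:
                raise ValueError("overlapping exons")
        if self.cds_span is not None:
            c0, c1 = self.cds_span
            if not any(a <= c0 and c1 <= b for a, b in self._merged_hull()):
                # CDS must lie within the exonic territory
                if not self._contains_interval(c0, c1):
                    raise ValueError(
                        f"CDS {self.cds_span} outside exons of {self.transcript_id}"
                    )

    def _merged_hull(self) -> list[Interval]:
        return [(self.exons[0][0], self.exons[-1][1])]

    def _contains_interval(self, c0: int, c1: int) -> bool:
        """True if every base of [c0, c1) is exonic."""
        need = c1 - c0
        got = 0
        for a, b in self.exons:
            got += max(0, min(b, c1) - max(a, c0))
        return got == need

    # -- coordinate maps -------------------------------------------------
    @property
    def mature_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def contains(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.exons)

    def genomic_to_transcript(self, g: int) -> int:
        off = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for a, b in exons:
            if a <= g < b:
                return off + (g - a if self.strand == "+" else b - 1 - g)
            off += b - a
        raise ValueError(f"{g} not exonic in {self.transcript_id}")

    def transcript_to_genomic(self, t: int) -> int:
        if not 0 <= t < self.mature_length:
            raise ValueError("transcript coordinate out of range")
        off = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for a, b in exons:
            ln = b - a
            if t < off + ln:
                i = t - off
                return a + i if self.strand == "+" else b - 1 - i
            off += ln
        raise AssertionError("unreachable")

    def transcript_interval_to_genomic(self, t0: int, t1: int) -> list[Interval]:
        """Map mature-coordinate interval [t0, t1) to genomic interval(s)."""
        if t0 >= t1:
            return []
        out: list[Interval] = []
        for t in range(t0, t1):
            g = self.transcript_to_genomic(t)
            if out and (out[-1][1] == g):
                out[-1] = (out[-1][0], g + 1)
            elif out and (out[-1][0] == g + 1):
                out[-1] = (g, out[-1][1])
            else:
                out.append((g, g + 1))
        return sorted(out)

    # -- CDS / UTRs in transcript coordinates ----------------------------
    def cds_transcript_bounds(self) -> Interval | None:
        """CDS as a [start, end) interval in mature coordinates."""
        if self.cds_span is None:
            return None
        c0, c1 = self.cds_span
        ta = self.genomic_to_transcript(c0)
        tb = self.genomic_to_transcript(c1 - 1)
        lo, hi = min(ta, tb), max(ta, tb)
        return (lo, hi + 1)

    @property
    def utr5(self) -> list[Interval]:
        b = self.cds_transcript_bounds()
        if b is None:
            return []
        return self.transcript_interval_to_genomic(0, b[0])

    @property
    def utr3(self) -> list[Interval]:
        b = self.cds_transcript_bounds()
        if b is None:
            return []
        return self.transcript_interval_to_genomic(b[1], self.mature_length)

    def mature_sequence(self, genome) -> str:
        """Spliced transcript sequence in 5'->3' orientation (DNA letters)."""
        chrom_seq = genome[self.chrom]
        if not isinstance(chrom_seq, str):
            chrom_seq = str(chrom_seq[:])
        seq = "".join(chrom_seq[a:b] for a, b in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def region_of(self, g: int) -> str:
        """Feature region (5UTR|CDS|3UTR|ncRNA) of an exonic genomic position."""
        if not self.is_coding:
            return "ncRNA"
        t = self.genomic_to_transcript(g)
        lo, hi = self.cds_transcript_bounds()
        if t < lo:
            return "5UTR"
        if t >= hi:
            return "3UTR"
        return "CDS"


class Annotation:
    """Strand-aware lookup over a set of transcript models."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: list[TranscriptModel] = list(transcripts)
        self._by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
        for tx in self.transcripts:
            self._by_key.setdefault((tx.chrom, tx.strand), []).append(tx)
        for txs in self._by_key.values():
            txs.sort(key=lambda t: t.span)
        self.by_id = {t.transcript_id: t for t in self.transcripts}

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def find(self, chrom: str, strand: str, pos: int) -> list[TranscriptModel]:
        """Transcripts whose exons contain ``pos`` on the given strand."""
        out = []
        for tx in self._by_key.get((chrom, strand), []):
            if tx.span[0] > pos:
                break
            if tx.contains(pos):
                out.append(tx)
        return out

    def best(self, chrom: str, strand: str, pos: int) -> TranscriptModel | None:
        """The containing transcript; ties broken by longest mature form."""
        hits = self.find(chrom, strand, pos)
        if not hits:
            return None
        return max(hits, key=lambda t: (t.mature_length, t.transcript_id))


@dataclass
class CoverageTrack:
    """Per-base read-overlap counts for one strand of one chromosome."""

    chrom: str
    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if (self.values < 0).any():
            raise ValueError("negative coverage")

    def __len__(self) -> int:
        return len(self.values)

    def slice(self, start: int, end: int) -> np.ndarray:
        return self.values[start:end]
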