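"""Readers and writers for the standard formats the pipeline exchanges.

Internal coordinates are 0-based half-open; GFF3 (1-based, closed) and SAM
(1-based POS) are converted at this boundary.  Barcodes travel in the read
name as a ``_BC:<seq>`` suffix.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping, Sequence

import pysam

from .model import Annotation, CoverageTrack, ReadAlignment, TranscriptModel
from .simulate import revcomp


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(annotation: Iterable[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in annotation:
            s0, s1 = tx.span
            common = (tx.chrom, "pufclip", s0 + 1, s1, ".", tx.strand, ".")
            fh.write(_gff_line(*common[:2], "gene", *common[2:],
                               f"ID={tx.gene_id}"))
            kind = tx.biotype if not tx.is_coding else "mRNA"
            fh.write(_gff_line(tx.chrom, "pufclip", kind, s0 + 1, s1, ".",
                               tx.strand, ".",
                               f"ID={tx.transcript_id};Parent={tx.gene_id}"))
            for i, (a, b) in enumerate(tx.exons):
                fh.write(_gff_line(tx.chrom, "pufclip", "exon", a + 1, b, ".",
                                   tx.strand, ".",
                                   f"ID={tx.transcript_id}.e{i};Parent={tx.transcript_id}"))
            if tx.cds_span is not None:
                a, b = tx.cds_span
                fh.write(_gff_line(tx.chrom, "pufclip", "CDS", a + 1, b, ".",
                                   tx.strand, "0",
                                   f"ID={tx.transcript_id}.cds;Parent={tx.transcript_id}"))


def _gff_line(chrom, source, kind, start, end, score, strand, phase, attrs) -> str:
    return "\t".join(
        [chrom, source, kind, str(start), str(end), str(score), strand,
         str(phase), attrs]
    ) + "\n"


def _cigar_and_query(read: ReadAlignment, genome: Mapping[str, str] | None):
    """CIGAR string plus a reference-derived query sequence."""
    dels = sorted(read.deletion_positions)
    parts = []
    pos = read.start
    for d in dels:
        if d - pos > 0:
            parts.append(f"{d - pos}M")
        parts.append("1D")
        pos = d + 1
    if read.end - pos > 0:
        parts.append(f"{read.end - pos}M")
    cigar = "".join(parts)
    if genome is None:
        return cigar, None
    ref = genome[read.chrom][read.start : read.end]
    q = "".join(
        b for i, b in enumerate(ref) if (read.start + i) not in read.deletion_positions
    )
    if read.strand == "-":
        q = revcomp(q)
    return cigar, q


def write_sam(
    reads: Sequence[ReadAlignment],
    chrom_lengths: Mapping[str, int],
    path: str,
    genome: Mapping[str, str] | None = None,
) -> None:
    """Write reads as SAM with @SQ headers and M/D CIGARs.

    If ``genome`` is given, query sequences are reconstructed from the
    reference (reverse-complemented for minus-strand reads); otherwise SEQ
    is ``*``.
    """
    names = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(chrom_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name or f"read{i}_BC:{r.barcode}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            cigar, q = _cigar_and_query(r, genome)
            a.cigarstring = cigar
            if q is not None:
                a.query_sequence = q
                a.query_qualities = pysam.qualitystring_to_array("I" * len(q))
            out.write(a)


def write_bed(intervals, path: str) -> None:
    """BED6(+) writer; each item supplies chrom, start, end, name, score, strand
    and optionally extra columns."""
    with open(path, "w") as fh:
        for item in intervals:
            fh.write("\t".join(str(x) for x in item) + "\n")


def reads_to_bed6(reads: Sequence[ReadAlignment]):
    for r in reads:
        yield (r.chrom, r.start, r.end, r.name or r.barcode, r.mapq, r.strand)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Sparse bedGraph of one strand's coverage (zero runs omitted)."""
    v = track.values
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.chrom}({track.strand})"\n')
        i = 0
        n = len(v)
        while i < n:
            j = i
            while j < n and v[j] == v[i]:
                j += 1
            if v[i] != 0:
                fh.write(f"{track.chrom}\t{i}\t{j}\t{int(v[i])}\n")
            i = j


def write_manifest(path: str, **entries) -> None:
    """Run manifest: inputs, parameters and package version, as JSON."""
    from . import __version__

    payload = {"pufclip_version": __version__, **entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
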