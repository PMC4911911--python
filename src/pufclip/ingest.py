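"""Input loading and cleaning: annotation, mapped reads, duplicate collapse,
control pooling, and strand-aware coverage."""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pysam

from .model import Annotation, CoverageTrack, ReadAlignment, TranscriptModel

DEFAULT_MIN_MAPQ = 20
BARCODE_TAG = "_BC:"

TRANSCRIPT_TYPES = {"mRNA", "ncRNA", "lincRNA", "lnc_RNA", "transcript"}


def load_annotation(gff3_path: str) -> Annotation:
    """Parse a GFF3 into transcript models with derived UTRs.

    Expects gene / (mRNA|ncRNA) / exon / CDS features linked by ID/Parent.
    Transcripts whose CDS falls outside their exons are rejected with a
    warning; exon or CDS records with missing parent links raise.
    """
    import gffutils

    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: list[TranscriptModel] = []
    tx_features = [f for f in db.all_features() if f.featuretype in TRANSCRIPT_TYPES]
    known_parents = {f.id for f in tx_features}
    for kind in ("exon", "CDS"):
        for f in db.features_of_type(kind):
            parents = f.attributes.get("Parent", [])
            if not parents or not any(p in known_parents for p in parents):
                raise ValueError(f"{kind} record {f.id!r} has no transcript parent")

    for f in tx_features:
        gene_parents = f.attributes.get("Parent", [f.id])
        exons = [
            (e.start - 1, e.end)
            for e in db.children(f, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [(f.start - 1, f.end)]
        cds = [
            (c.start - 1, c.end)
            for c in db.children(f, featuretype="CDS", order_by="start")
        ]
        cds_span = None
        if cds and f.featuretype == "mRNA":
            cds_span = (min(a for a, _ in cds), max(b for _, b in cds))
        biotype = f.featuretype if f.featuretype != "mRNA" else "mRNA"
        try:
            transcripts.append(
                TranscriptModel(
                    gene_id=gene_parents[0],
                    transcript_id=f.id,
                    chrom=f.seqid,
                    strand=f.strand,
                    exons=exons,
                    cds_span=cds_span,
                    biotype=biotype,
                )
            )
        except ValueError as exc:
            warnings.warn(f"rejecting transcript {f.id}: {exc}")
    return Annotation(transcripts)


def load_reads(
    sam_path: str, min_mapq: int = DEFAULT_MIN_MAPQ, strict: bool = False
) -> list[ReadAlignment]:
    """Load mapped reads, dropping unmapped records and MAPQ below threshold.

    Deletions are taken from CIGAR D operations; the random barcode is
    parsed from the ``_BC:<seq>`` read-name suffix.  With ``strict``, a
    missing barcode raises; otherwise it is left empty.
    """
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.mapping_quality < min_mapq:
                continue
            name = a.query_name or ""
            if BARCODE_TAG in name:
                barcode = name.rsplit(BARCODE_TAG, 1)[1]
            elif strict:
                raise ValueError(f"read {name!r} lacks a {BARCODE_TAG} barcode suffix")
            else:
                barcode = ""
            dels: list[int] = []
            pos = a.reference_start
            for op, ln in a.cigartuples or []:
                if op in (0, 7, 8):  # M/=/X consume both
                    pos += ln
                elif op == 2:  # D consumes reference
                    dels.extend(range(pos, pos + ln))
                    pos += ln
                elif op == 3:  # N consumes reference
                    pos += ln
                # I/S/H/P do not consume reference
            out.append(
                ReadAlignment(
                    chrom=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    start=a.reference_start,
                    end=a.reference_end,
                    mapq=a.mapping_quality,
                    barcode=barcode,
                    deletion_positions=tuple(dels),
                    name=name,
                )
            )
    return out


def collapse_duplicates(reads: Iterable[ReadAlignment]) -> list[ReadAlignment]:
    """Collapse PCR duplicates on (chromosome, strand, 5' position, barcode).

    One read is retained per group: the longest, ties broken by
    lexicographically smallest name.  Idempotent and order-independent.
    """
    best: dict[tuple, ReadAlignment] = {}
    for r in reads:
        key = (r.chrom, r.strand, r.five_prime_pos, r.barcode)
        cur = best.get(key)
        if (
            cur is None
            or r.length > cur.length
            or (r.length == cur.length and r.name < cur.name)
        ):
            best[key] = r
    return sorted(best.values(), key=lambda r: (r.chrom, r.strand, r.start, r.name))


def pool_controls(*replicate_reads: Sequence[ReadAlignment]) -> list[ReadAlignment]:
    """Combine negative-control replicates into a single data set
    (concatenation followed by duplicate collapse)."""
    merged: list[ReadAlignment] = []
    for rs in replicate_reads:
        merged.extend(rs)
    return collapse_duplicates(merged)


def coverage(
    reads: Iterable[ReadAlignment],
    chrom: str,
    strand: str,
    length: int | None = None,
) -> CoverageTrack:
    """Per-base read-overlap counts: position i counts reads whose
    [start, end) contains i."""
    sel = [r for r in reads if r.chrom == chrom and r.strand == strand]
    if length is None:
        length = max((r.end for r in sel), default=0)
    diff = np.zeros(length + 1, dtype=np.int64)
    for r in sel:
        if r.start < length:
            diff[r.start] += 1
            diff[min(r.end, length)] -= 1
    return CoverageTrack(chrom=chrom, strand=strand, values=np.cumsum(diff[:-1]))
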