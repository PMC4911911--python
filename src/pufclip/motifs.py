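"""PUF binding-element scanning and enrichment.

The canonical FBF binding element (FBE) is UGUNNNAU; high-affinity variants
carry a cytosine one or two bases upstream.  The in vivo consensus is best
described as a -1 or -2 C followed by UGURCCAUR.  Peaks lacking an FBE are
enriched for a shorter FBE-like 7-mer, UGURNAU.  This module scans IUPAC
patterns over peak sequences, classifies upstream context, scores
mismatches to the consensus, masks canonical elements so alternate motifs
can be sought exclusively of the FBE, and computes empirical enrichment
against mononucleotide-shuffled sequences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "W": "AU", "S": "CG", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

MASK_CHAR = "x"  # lowercase: matches nothing, survives re-scanning


@dataclass(frozen=True)
class MotifDef:
    """An IUPAC motif, optionally with a required upstream context base.

    ``context`` is (base, offsets): the base must appear at one of the
    given negative offsets relative to the match start.
    """

    name: str
    pattern: str
    context: tuple[str, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace("T", "U")
        if not pat or any(ch not in IUPAC for ch in pat):
            raise ValueError(f"invalid IUPAC pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)


FBE = MotifDef("FBE", "UGUNNNAU")
FBE_MINUS1C = MotifDef("FBE_-1C", "UGUNNNAU", context=("C", (-1,)))
FBE_MINUS2C = MotifDef("FBE_-2C", "UGUNNNAU", context=("C", (-2,)))
SEVEN_MER = MotifDef("7mer", "UGURNAU")
SEVEN_MER_REFINED = MotifDef("7mer_refined", "UGUGAAUR")


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    motif: str
    matched_sequence: str
    c_minus1: bool = False
    c_minus2: bool = False
    c_minus3: bool = False
    c_minus4: bool = False


def _normalize(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    for ch in s:
        if ch not in "ACGU" and ch != MASK_CHAR.upper():
            if ch == MASK_CHAR:
                continue
            raise ValueError(f"invalid base {ch!r} in sequence")
    # masked characters are kept lowercase so they never match
    return "".join(MASK_CHAR if c.upper() == MASK_CHAR.upper() else c for c in s)


def _matches_at(seq: str, pat: str, i: int) -> bool:
    for j, p in enumerate(pat):
        if seq[i + j] not in IUPAC[p]:
            return False
    return True


def scan(seq: str, motif: MotifDef, sequence_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) matches of the motif in the sequence.

    T is treated as U.  Upstream-context flags report a cytosine at -1
    through -4 where those bases exist; motifs with a ``context``
    requirement only report offsets satisfying it.
    """
    s = _normalize(seq)
    pat = motif.pattern
    hits: list[MotifHit] = []
    for i in range(0, len(s) - len(pat) + 1):
        if not _matches_at(s, pat, i):
            continue
        flags = {
            k: (i + off >= 0 and s[i + off] == "C")
            for k, off in (("c_minus1", -1), ("c_minus2", -2),
                           ("c_minus3", -3), ("c_minus4", -4))
        }
        if motif.context is not None:
            base, offs = motif.context
            if not any(i + o >= 0 and s[i + o] == base.upper() for o in offs):
                continue
        hits.append(
            MotifHit(
                sequence_id=sequence_id,
                offset=i,
                motif=motif.name,
                matched_sequence=s[i : i + len(pat)],
                **flags,
            )
        )
    return hits


@dataclass(frozen=True)
class ConsensusSpec:
    """The in vivo consensus: a -1 or -2 C followed by UGURCCAUR."""

    core: str = "UGURCCAUR"
    context_base: str = "C"
    context_offsets: tuple[int, ...] = (-1, -2)


def consensus_mismatches(
    site_with_flanks: str, spec: ConsensusSpec | None = None
) -> tuple[int, list[int]]:
    """Mismatch count of a site against the consensus.

    The consensus core is aligned at a UGU anchor (the anchor minimizing
    the mismatch count when several UGUs occur); core positions 4-9
    (1-based, i.e. everything beyond the invariant UGU) are compared, and
    the upstream-C requirement contributes one further mismatch when no C
    sits at -1 or -2.  Returns (count, 1-based core positions violated;
    position 0 denotes the upstream-context violation).
    """
    spec = spec or ConsensusSpec()
    s = _normalize(site_with_flanks)
    anchors = [i for i in range(len(s) - 2) if s[i : i + 3] == "UGU"]
    if not anchors:
        raise ValueError("no UGU anchor in site")
    best: tuple[int, list[int]] | None = None
    for a in anchors:
        mism: list[int] = []
        if not any(
            a + o >= 0 and s[a + o] == spec.context_base for o in spec.context_offsets
        ):
            mism.append(0)
        for j in range(3, len(spec.core)):  # core positions 4..9 (1-based)
            pos = a + j
            if pos >= len(s) or s[pos] not in IUPAC[spec.core[j]]:
                mism.append(j + 1)
        if best is None or len(mism) < len(best[1]):
            best = (a, mism)
    assert best is not None
    return len(best[1]), best[1]


def mask_fbe(seq: str, motif: MotifDef = FBE) -> str:
    """Replace every canonical-FBE match with mask characters so later
    scans cannot match inside them; overlapping matches mask their union."""
    s = _normalize(seq)
    out = list(s)
    for hit in scan(s, motif):
        for i in range(hit.offset, hit.offset + len(motif)):
            out[i] = MASK_CHAR
    return "".join(out)


def shuffle_enrichment(
    sequences: Sequence[str],
    motif: MotifDef,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fraction of sequences with >= 1 motif hit, and an empirical p-value
    against per-sequence mononucleotide shuffles.

    p = (1 + #{shuffles with fraction >= observed}) / (n_shuffles + 1).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = [_normalize(s) for s in sequences]
    observed = np.mean([1.0 if scan(s, motif) else 0.0 for s in seqs])
    arrays = [np.array(list(s)) for s in seqs]
    n_ge = 0
    for _ in range(n_shuffles):
        frac = np.mean(
            [
                1.0 if scan("".join(rng.permutation(a)), motif) else 0.0
                for a in arrays
            ]
        )
        if frac >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_shuffles + 1)
    return float(observed), float(p)


def context_class(hit: MotifHit) -> str:
    if hit.c_minus1:
        return "-1C"
    if hit.c_minus2:
        return "-2C"
    return "none"


def extract_window(
    genome: dict[str, str] | "object",
    chrom: str,
    strand: str,
    center: int,
    window: int = 71,
) -> tuple[str, bool]:
    """Strand-aware window of odd length centered on ``center``; returns
    (RNA-sense sequence, clipped flag).  Minus-strand windows are
    reverse-complemented."""
    from .simulate import revcomp

    half = window // 2
    seq = genome[chrom]
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        seq = str(seq[:])  # pyfaidx FastaRecord
    a, b = center - half, center + half + 1
    clipped = a < 0 or b > len(seq)
    a2, b2 = max(0, a), min(len(seq), b)
    s = seq[a2:b2]
    if strand == "-":
        s = revcomp(s)
    return s.upper().replace("T", "U"), clipped


def peak_motif_summary(
    peaks: Sequence,
    genome: dict[str, str],
    motif_defs: Sequence[MotifDef] | None = None,
    window: int = 71,
    n_deciles: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak motif presence over windows centered on each peak maximum,
    plus fraction-with-FBE per peak-rank decile.

    Peaks are ranked by normalized height when available, else raw height.
    Alternate motifs are scanned on FBE-masked sequence so their presence
    is exclusive of the canonical element.
    """
    motif_defs = list(motif_defs) if motif_defs is not None else default_motifs()
    rows = []
    for i, p in enumerate(peaks):
        seq, clipped = extract_window(genome, p.chrom, p.strand, p.max_pos, window)
        fbe_hits = scan(seq, FBE)
        # context from the element closest to the peak maximum
        center = len(seq) // 2
        central = min(
            fbe_hits, key=lambda h: abs(h.offset + len(FBE) // 2 - center),
            default=None,
        )
        ctx = context_class(central) if central else "none"
        masked = mask_fbe(seq)
        row = dict(
            peak_index=i,
            chrom=p.chrom,
            strand=p.strand,
            max_pos=p.max_pos,
            height=getattr(p, "height", np.nan),
            normalized_height=getattr(p, "normalized_height", None),
            window_clipped=clipped,
            has_fbe=bool(fbe_hits),
            fbe_context=ctx,
        )
        for m in motif_defs:
            target = seq if m.name.startswith("FBE") or m.name == "FBE" else masked
            row[f"has_{m.name}"] = bool(scan(target, m))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df, pd.DataFrame(columns=["decile", "n", "frac_fbe"])
    rank_key = df["normalized_height"]
    if rank_key.isna().all():
        rank_key = df["height"]
    order = rank_key.rank(ascending=False, method="first")
    decile = np.ceil(order / len(df) * n_deciles).astype(int)
    dec = (
        df.assign(decile=decile)
        .groupby("decile")
        .agg(n=("has_fbe", "size"), frac_fbe=("has_fbe", "mean"))
        .reset_index()
    )
    return df, dec


def default_motifs() -> list[MotifDef]:
    """The bundled motif table (canonical FBE and context variants, the
    7-mer, UGU half-mers, and editable stand-ins for in vitro selection
    motifs)."""
    path = importlib.resources.files("pufclip").joinpath("data/motifs.tsv")
    return load_motif_table(str(path))


def load_motif_table(path: str) -> list[MotifDef]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        ctx = None
        if isinstance(row.get("context"), str) and row["context"].strip():
            base, offs = row["context"].split("@")
            ctx = (base, tuple(int(o) for o in offs.split(",")))
        out.append(MotifDef(str(row["name"]), str(row["pattern"]), ctx))
    return out
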