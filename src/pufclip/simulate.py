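"""Seeded synthetic iCLIP benchmark generator.

Emulates the statistical structure the downstream analysis assumes:

* a synthetic genome carrying non-overlapping transcripts on both strands,
  separated by spacers, each with a 5'UTR/CDS/3'UTR architecture;
* planted PUF binding elements of graded affinity classes (canonical FBE
  with an upstream cytosine, plain FBE, the shorter FBE-like 7-mer, and an
  alternate U/G-rich element), biased toward the 3' ends of 3'UTRs;
* iCLIP reads whose 5' ends truncate one base past the crosslink (the CITS
  signal) and whose read-through bodies carry single-base deletions at the
  crosslink (the CIMS signal);
* abundance-coupled nonspecific background drawn from per-transcript
  "sticky" hotspot positions that are shared between the experimental and
  negative-control iCLIP libraries (crosslinked background is a property of
  the RNA, not of the tagged protein), plus a uniform component;
* a negative-control iCLIP library (background process only) and an RNA-seq
  library (uniform along each transcript, abundance-proportional counts);
* random barcodes with PCR duplication.

Every output is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Annotation, Interval, ReadAlignment, TranscriptModel, revcomp

CHROM = "synChrI"

# Planted site sequences (sense strand, DNA alphabet).  Each string embeds
# the motif with two fixed upstream bases so the upstream-context class is
# controlled; ``motif_offset`` is the index of the UGU start in the string.
SITE_SEQUENCES: dict[str, tuple[str, int]] = {
    # upstream C at -2 followed by a perfect consensus core (the strongest
    # validated element in gld-1)
    "canonical_context": ("CATGTGCCATA", 2),
    # plain canonical FBE (UGUNNNAU) with non-C upstream bases
    "canonical": ("AATGTAATATT", 2),
    # FBE-like 7-mer (UGURNAU) that does not satisfy the canonical pattern
    "seven_mer": ("AATGTGAATC", 2),
    # alternate U/G-rich half-mer composite; matches neither FBE nor 7-mer
    "alternate": ("AATGTGATGTG", 2),
}

SITE_CLASSES = tuple(SITE_SEQUENCES)


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Affinity levels are mean crosslinked molecules per site per replicate
    for a transcript of mean abundance; actual site counts are Poisson with
    mean ``affinity * abundance / mean_abundance`` so that signal and
    background scale together with expression.
    """

    n_transcripts: int = 200
    transcript_length_range: tuple[int, int] = (500, 2500)
    n_target_fraction: float = 0.5
    affinity_levels: dict[str, float] = field(
        default_factory=lambda: {
            "canonical_context": 60.0,
            "canonical": 45.0,
            "seven_mer": 34.0,
            "alternate": 30.0,
        }
    )
    site_class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "canonical_context": 0.40,
            "canonical": 0.30,
            "seven_mer": 0.20,
            "alternate": 0.10,
        }
    )
    # log-normal abundance: exp(Normal(mu, sigma))
    abundance_mu: float = 1.0
    abundance_sigma: float = 1.0
    background_rate: float = 1.5  # nonspecific reads per transcript per unit abundance
    # weight of the abundance-proportional component of site signal: bound
    # sites saturate with protein occupancy, so signal depends on abundance
    # only partially, while nonspecific background scales fully with it
    abundance_coupling: float = 0.4
    # crosslinking efficiency rises toward the transcript 3' terminus
    # (terminal elements are bound most strongly): multiplicative boost
    # 1 + three_prime_boost * exp(-distance_to_3p_end / three_prime_tau)
    three_prime_boost: float = 1.5
    three_prime_tau: float = 150.0
    truncation_prob: float = 0.65
    deletion_prob: float = 0.6  # deletion at crosslink given read-through
    bg_deletion_prob: float = 0.002  # stray RT deletions per background read
    barcode_length: int = 9
    pcr_duplicate_rate: float = 1.0  # extra copies ~ Poisson(rate)
    n_replicates: int = 3
    read_length: int = 35
    spacer: int = 150
    # nonspecific "sticky" background structure (shared with the control)
    hotspot_frac: float = 0.7
    hotspots_mean: float = 2.0
    hotspot_jitter_sd: float = 2.0
    rnaseq_rate: float = 1.5
    n_crosslinks_per_site: int = 2
    # transcript architecture and site placement
    utr5_frac: float = 0.10
    cds_frac: float = 0.60
    frac_sites_3utr: float = 0.75
    frac_sites_cds: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_target_fraction",
            "truncation_prob",
            "deletion_prob",
            "bg_deletion_prob",
            "hotspot_frac",
            "frac_sites_3utr",
            "frac_sites_cds",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        lo, hi = self.transcript_length_range
        if lo > hi or lo < 150:
            raise ValueError(
                "transcript length range too short to host planted motifs "
                f"(need >= 150 nt, got {self.transcript_length_range})"
            )
        a = self.affinity_levels
        order = ["canonical_context", "canonical", "seven_mer", "alternate"]
        vals = [a[k] for k in order]
        if not all(x >= y for x, y in zip(vals, vals[1:])) or vals[-1] <= 0:
            raise ValueError("affinity ordering violated")
        if self.n_transcripts < 0 or self.n_replicates < 1:
            raise ValueError("counts must be nonnegative / positive")


# Discretized crosslink-offset distribution relative to motif start
# (position of U1 = offset 0): mode at -2, heavier mass upstream of the
# motif than downstream.
CROSSLINK_OFFSETS = np.arange(-10, 9)


def crosslink_offset_weights() -> np.ndarray:
    w = np.empty_like(CROSSLINK_OFFSETS, dtype=float)
    for i, o in enumerate(CROSSLINK_OFFSETS):
        if o <= -2:
            w[i] = np.exp(-(-2 - o) / 3.0)
        else:
            w[i] = np.exp(-(o + 2) / 1.5)
    return w / w.sum()


@dataclass
class Transcriptome:
    """Synthetic genome, annotation, and latent per-transcript structure."""

    genome: dict[str, str]
    annotation: Annotation
    abundance: dict[str, float]
    # per transcript: hotspot transcript-coordinates and weights
    hotspots: dict[str, tuple[np.ndarray, np.ndarray]]
    config: SimConfig

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


def _transcript_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASES = np.array(list("ACGT"))


def make_transcriptome(config: SimConfig) -> tuple[Transcriptome, pd.DataFrame]:
    """Build the genome, annotation and ground-truth site table.

    Returns the transcriptome plus a truth table with one row per planted
    site (transcript id, site class, motif start in transcript and genomic
    coordinates, planted crosslink offsets, and hosting feature region).
    """
    rng = np.random.default_rng(config.seed)
    offsets_w = crosslink_offset_weights()

    n = config.n_transcripts
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    abund = np.exp(rng.normal(config.abundance_mu, config.abundance_sigma, size=n))
    is_target = rng.random(n) < config.n_target_fraction
    class_names = list(config.site_class_weights)
    class_p = np.array([config.site_class_weights[c] for c in class_names], float)
    class_p = class_p / class_p.sum()

    transcripts: list[TranscriptModel] = []
    abundance: dict[str, float] = {}
    hotspots: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth_rows: list[dict] = []
    chrom_parts: list[str] = []
    cursor = 0

    for i in range(n):
        L = int(lengths[i])
        strand = "+" if i % 2 == 0 else "-"
        tid = f"tx{i:04d}"
        gid = f"gene{i:04d}"
        seq = _transcript_sequence(rng, L)  # sense-strand ints

        # architecture in mature coordinates
        u5 = max(20, int(round(config.utr5_frac * L)))
        cds_len = max(60, int(round(config.cds_frac * L)))
        cds_len -= cds_len % 3
        if u5 + cds_len > L - 40:
            cds_len = (L - 40 - u5) // 3 * 3
        cds_t = (u5, u5 + cds_len)

        site_rows = []
        if is_target[i]:
            cls = str(rng.choice(class_names, p=class_p))
            site_rows.append((cls, _place_site(rng, config, L, cds_t)))
            # longer transcripts may host a second, independent site
            if L > 1200 and rng.random() < 0.35:
                cls2 = str(rng.choice(class_names, p=class_p))
                pos2 = _place_site(rng, config, L, cds_t)
                if abs(pos2 - site_rows[0][1]) > 120:
                    site_rows.append((cls2, pos2))

        for cls, pos in site_rows:
            s, moff = SITE_SEQUENCES[cls]
            start = pos - moff
            for j, base in enumerate(s):
                seq[start + j] = "ACGT".index(base)
            k = config.n_crosslinks_per_site
            offs = rng.choice(CROSSLINK_OFFSETS, size=k, replace=False, p=offsets_w)
            offs = np.sort(offs)
            offs = offs[(pos + offs >= 1) & (pos + offs < L - 1)]
            truth_rows.append(
                dict(
                    transcript_id=tid,
                    gene_id=gid,
                    site_class=cls,
                    site_position=pos,
                    crosslink_offsets=",".join(str(int(o)) for o in offs),
                    _offs=offs,
                    _strand=strand,
                )
            )

        # latent sticky hotspots shared by every iCLIP library
        n_hot = 1 + rng.poisson(config.hotspots_mean)
        hot_pos = rng.integers(10, max(11, L - config.read_length), size=n_hot)
        hot_w = rng.dirichlet(np.ones(n_hot) * 1.0)
        hotspots[tid] = (hot_pos, hot_w)

        # lay transcript onto the chromosome
        g_start = cursor
        sense = "".join(_BASES[seq])
        chrom_parts.append(sense if strand == "+" else revcomp(sense))
        spacer_seq = "".join(_BASES[rng.integers(0, 4, size=config.spacer)])
        chrom_parts.append(spacer_seq)
        cursor += L + config.spacer

        exons = [(g_start, g_start + L)]
        if strand == "+":
            cds_g = (g_start + cds_t[0], g_start + cds_t[1])
        else:
            cds_g = (g_start + L - cds_t[1], g_start + L - cds_t[0])
        tx = TranscriptModel(
            gene_id=gid,
            transcript_id=tid,
            chrom=CHROM,
            strand=strand,
            exons=exons,
            cds_span=cds_g,
        )
        transcripts.append(tx)
        abundance[tid] = float(abund[i])

    genome = {CHROM: "".join(chrom_parts)} if n > 0 else {CHROM: ""}
    ann = Annotation(transcripts)

    # finalize truth with genomic coordinates and feature region
    for row in truth_rows:
        tx = ann.by_id[row["transcript_id"]]
        pos = row["site_position"]
        row["chrom"] = tx.chrom
        row["strand"] = tx.strand
        row["genomic_motif_start"] = tx.transcript_to_genomic(pos)
        g_cl = [tx.transcript_to_genomic(pos + int(o)) for o in row.pop("_offs")]
        row["genomic_crosslink_positions"] = ",".join(str(g) for g in g_cl)
        row["feature_region"] = tx.region_of(row["genomic_motif_start"])
        row.pop("_strand")

    cols = [
        "transcript_id",
        "gene_id",
        "site_class",
        "site_position",
        "crosslink_offsets",
        "chrom",
        "strand",
        "genomic_motif_start",
        "genomic_crosslink_positions",
        "feature_region",
    ]
    truth = pd.DataFrame(truth_rows, columns=cols)
    tr = Transcriptome(
        genome=genome,
        annotation=ann,
        abundance=abundance,
        hotspots=hotspots,
        config=config,
    )
    return tr, truth


def _place_site(
    rng: np.random.Generator, config: SimConfig, L: int, cds_t: Interval
) -> int:
    """Pick a motif-start position in mature coordinates.

    Most sites land in the 3'UTR with a positional skew toward the 3' end;
    the remainder fall in the CDS or 5'UTR.
    """
    margin = 14  # room for the planted string plus crosslink offsets
    u = rng.random()
    if u < config.frac_sites_3utr:
        a, b = cds_t[1], L
    elif u < config.frac_sites_3utr + config.frac_sites_cds:
        a, b = cds_t
    else:
        a, b = 0, cds_t[0]
    a, b = a + margin, b - margin
    if b <= a:  # degenerate region; fall back to mid-transcript
        a, b = margin, L - margin
    if u < config.frac_sites_3utr:
        frac = rng.beta(3.0, 1.0)  # biased toward the 3' end
    else:
        frac = rng.random()
    return int(a + frac * (b - 1 - a))


# ---------------------------------------------------------------------------
# read simulation


def _barcode(rng: np.random.Generator, k: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=k)])


def _emit_molecule(
    rng: np.random.Generator,
    config: SimConfig,
    tx: TranscriptModel,
    t_start: int,
    t_end: int,
    del_t: int | None,
    reads: list[ReadAlignment],
    prefix: str,
    duplicates: bool = True,
) -> None:
    """Emit one unique molecule (plus PCR duplicates) as ReadAlignments.

    ``t_start``/``t_end`` bound the read in mature coordinates (half-open);
    ``del_t`` is an optional deleted transcript position strictly inside.
    """
    L = tx.mature_length
    t_start = max(0, t_start)
    t_end = min(L, t_end)
    if t_end - t_start < 15:  # too short after clipping
        return
    g_a = tx.transcript_to_genomic(t_start)
    g_b = tx.transcript_to_genomic(t_end - 1)
    start, end = (g_a, g_b + 1) if tx.strand == "+" else (g_b, g_a + 1)
    dels: tuple[int, ...] = ()
    if del_t is not None and t_start < del_t < t_end - 1:
        dels = (tx.transcript_to_genomic(del_t),)
    bc = _barcode(rng, config.barcode_length)
    n_copies = 1 + (rng.poisson(config.pcr_duplicate_rate) if duplicates else 0)
    for j in range(n_copies):
        reads.append(
            ReadAlignment(
                chrom=tx.chrom,
                strand=tx.strand,
                start=start,
                end=end,
                mapq=42,
                barcode=bc,
                deletion_positions=dels,
                name=f"{prefix}d{j}_BC:{bc}",
            )
        )


def _background_reads(
    rng: np.random.Generator,
    config: SimConfig,
    tr: Transcriptome,
    rate: float,
    prefix: str,
    with_hotspots: bool = True,
    duplicates: bool = True,
) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    for tx in tr.annotation:
        a = tr.abundance[tx.transcript_id]
        lam = rate * a
        n_mol = rng.poisson(lam)
        if n_mol == 0:
            continue
        hot_pos, hot_w = tr.hotspots[tx.transcript_id]
        L = tx.mature_length
        for m in range(n_mol):
            if with_hotspots and rng.random() < config.hotspot_frac:
                h = rng.choice(hot_pos, p=hot_w)
                t0 = int(h + round(rng.normal(0.0, config.hotspot_jitter_sd)))
            else:
                t0 = int(rng.integers(0, max(1, L - config.read_length)))
            t0 = min(max(t0, 0), max(0, L - 16))
            del_t = None
            if rng.random() < config.bg_deletion_prob:
                del_t = t0 + int(rng.integers(2, config.read_length - 2))
            _emit_molecule(
                rng,
                config,
                tx,
                t0,
                t0 + config.read_length,
                del_t,
                reads,
                f"{prefix}{tx.transcript_id}m{m}_",
                duplicates=duplicates,
            )
    return reads


def simulate_iclip(
    transcriptome: Transcriptome,
    truth: pd.DataFrame,
    config: SimConfig,
    replicate_index: int,
) -> list[ReadAlignment]:
    """One experimental iCLIP replicate: planted-site signal plus background.

    Crosslinked molecules either truncate (5' end one base 3' of the
    crosslink; probability ``truncation_prob``) or read through, in which
    case a single-base deletion is left at the crosslink with probability
    ``deletion_prob``.
    """
    if not 0 <= replicate_index < config.n_replicates:
        raise ValueError(
            f"replicate_index {replicate_index} out of range "
            f"(n_replicates={config.n_replicates})"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1000 + replicate_index])
    )
    reads: list[ReadAlignment] = []
    ab_mean = np.exp(config.abundance_mu + config.abundance_sigma**2 / 2.0)

    for ridx, row in truth.iterrows():
        tx = transcriptome.annotation.by_id[row.transcript_id]
        offs = [int(o) for o in str(row.crosslink_offsets).split(",") if o != ""]
        if not offs:
            continue
        a = transcriptome.abundance[row.transcript_id]
        affinity = config.affinity_levels[row.site_class]
        coupling = config.abundance_coupling
        L = tx.mature_length
        dist_3p = max(0, L - 1 - (int(row.site_position) + 7))
        boost = 1.0 + config.three_prime_boost * np.exp(
            -dist_3p / config.three_prime_tau
        )
        n_mol = rng.poisson(
            affinity * boost * ((1 - coupling) + coupling * a / ab_mean)
        )
        for m in range(n_mol):
            c = int(row.site_position) + offs[int(rng.integers(0, len(offs)))]
            c = min(max(c, 1), L - 2)
            if rng.random() < config.truncation_prob:
                t0, del_t = c + 1, None
            else:
                u = int(rng.integers(3, 16))
                t0 = max(0, c - u)
                del_t = c if rng.random() < config.deletion_prob else None
            _emit_molecule(
                rng,
                config,
                tx,
                t0,
                t0 + config.read_length + (1 if del_t is not None else 0),
                del_t,
                reads,
                f"site{ridx}m{m}_",
            )

    reads.extend(
        _background_reads(
            rng, config, transcriptome, config.background_rate, f"bgR{replicate_index}_"
        )
    )
    return reads


def simulate_controls(
    transcriptome: Transcriptome, config: SimConfig
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Negative-control iCLIP and RNA-seq read sets.

    The control is the nonspecific background process alone (same sticky
    hotspots as the experimental libraries, no planted sites); one library
    is generated per replicate and the replicates are combined into a
    single negative data set.  RNA-seq reads are uniform along each
    transcript with counts proportional to abundance.
    """
    control: list[ReadAlignment] = []
    for i in range(config.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2000 + i]))
        control.extend(
            _background_reads(
                rng, config, transcriptome, config.background_rate, f"ctrl{i}_"
            )
        )
    rng2 = np.random.default_rng(np.random.SeedSequence([config.seed, 3000]))
    rnaseq = _background_reads(
        rng2, config, transcriptome, config.rnaseq_rate, "rna_",
        with_hotspots=False, duplicates=False,
    )
    return control, rnaseq
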