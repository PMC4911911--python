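"""End-to-end orchestration of the synthetic benchmark and analysis.

These helpers run the full chain — simulate, collapse duplicates, find
candidates, call peaks with a chosen background method, apply the
enrichment and reproducibility filters — and score the outcome against the
planted ground truth.  They are shared by the command-line driver and the
reproducibility script so every consumer executes the same code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import consensus as cns
from . import crosslink as xl
from . import ingest, landscape, motifs, peaks, simulate
from .model import Annotation, CoverageTrack, ReadAlignment


@dataclass
class SimData:
    """A simulated experiment: transcriptome, truth, and cleaned read sets."""

    config: simulate.SimConfig
    transcriptome: simulate.Transcriptome
    truth: pd.DataFrame
    replicates: list[list[ReadAlignment]]  # deduplicated experimental reads
    control: list[ReadAlignment]
    rnaseq: list[ReadAlignment]

    @property
    def annotation(self) -> Annotation:
        return self.transcriptome.annotation

    @property
    def pooled_experiment(self) -> list[ReadAlignment]:
        out: list[ReadAlignment] = []
        for r in self.replicates:
            out.extend(r)
        return out

    def coverage(self, reads: Sequence[ReadAlignment]) -> dict[tuple, CoverageTrack]:
        lengths = self.transcriptome.chrom_lengths
        out = {}
        for chrom, ln in lengths.items():
            for strand in "+-":
                out[(chrom, strand)] = ingest.coverage(reads, chrom, strand, ln)
        return out


def simulate_experiment(config: simulate.SimConfig) -> SimData:
    """Generate a full synthetic experiment with duplicates collapsed."""
    tr, truth = simulate.make_transcriptome(config)
    reps = []
    for i in range(config.n_replicates):
        raw = simulate.simulate_iclip(tr, truth, config, i)
        reps.append(ingest.collapse_duplicates(raw))
    control, rnaseq = simulate.simulate_controls(tr, config)
    control = ingest.collapse_duplicates(control)
    return SimData(config, tr, truth, reps, control, rnaseq)


def candidate_peaks_per_replicate(
    sim: SimData, config: peaks.PeakCallConfig
) -> list[list[peaks.CandidatePeak]]:
    out = []
    for i, reads in enumerate(sim.replicates):
        cands: list[peaks.CandidatePeak] = []
        for track in sim.coverage(reads).values():
            cands.extend(peaks.find_candidate_peaks(track, config, replicate_id=i))
        out.append(cands)
    return out


def call_method(
    sim: SimData,
    method: int,
    config: peaks.PeakCallConfig,
    candidates_per_rep: list[list[peaks.CandidatePeak]] | None = None,
) -> list[list[peaks.PeakCall]]:
    """Per-replicate significant peak calls under one of the six methods."""
    if candidates_per_rep is None:
        candidates_per_rep = candidate_peaks_per_replicate(sim, config)
    lengths = sim.transcriptome.chrom_lengths
    out = []
    for i, cands in enumerate(candidates_per_rep):
        calls = peaks.call_peaks(
            cands,
            sim.replicates[i],
            sim.control,
            sim.rnaseq,
            method,
            sim.annotation,
            config,
            chrom_lengths=lengths,
        )
        out.append(peaks.significant_calls(calls))
    return out


@dataclass
class PeakPipelineResult:
    method: int
    per_replicate_calls: list[list[peaks.PeakCall]]
    consensus_unfiltered: list[cns.ConsensusPeak]
    consensus: list[cns.ConsensusPeak]
    target_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_peak_pipeline(
    sim: SimData,
    method: int = 4,
    peak_config: peaks.PeakCallConfig | None = None,
    filter_config: cns.FilterConfig | None = None,
    candidates_per_rep: list[list[peaks.CandidatePeak]] | None = None,
) -> PeakPipelineResult:
    """Peak calling + k-of-n consensus + fivefold enrichment filter +
    abundance normalization + target list, for one method."""
    peak_config = peak_config or peaks.PeakCallConfig()
    filter_config = filter_config or cns.FilterConfig(
        k_required=sim.config.n_replicates
    )
    calls = call_method(sim, method, peak_config, candidates_per_rep)
    consensus_all = cns.reproducible_peaks(calls, filter_config.k_required)
    pooled = sim.pooled_experiment
    kept = cns.enrichment_filter(consensus_all, pooled, sim.control, filter_config)
    cns.attach_normalized_heights(kept, sim.rnaseq, sim.annotation)
    targets, _ = cns.build_target_list(kept, sim.annotation)
    return PeakPipelineResult(method, calls, consensus_all, kept, targets)


# ---------------------------------------------------------------------------
# truth-based evaluation


def truth_site_intervals(truth: pd.DataFrame, margin: int = 25):
    """Genomic intervals around planted motifs used for overlap scoring."""
    out = []
    for row in truth.itertuples():
        g = int(row.genomic_motif_start)
        out.append((row.chrom, row.strand, g - margin, g + 8 + margin))
    return out


def _overlaps(peak, iv) -> bool:
    chrom, strand, a, b = iv
    return (
        peak.chrom == chrom
        and peak.strand == strand
        and peak.start < b
        and peak.end > a
    )


def evaluate_calls(peak_list: Sequence, truth: pd.DataFrame, margin: int = 25):
    """Recall over planted sites and empirical FDR over calls."""
    ivs = truth_site_intervals(truth, margin)
    n_sites = len(ivs)
    recalled = sum(1 for iv in ivs if any(_overlaps(p, iv) for p in peak_list))
    n_calls = len(peak_list)
    true_calls = sum(1 for p in peak_list if any(_overlaps(p, iv) for iv in ivs))
    recall = recalled / n_sites if n_sites else float("nan")
    fdr = (n_calls - true_calls) / n_calls if n_calls else 0.0
    return dict(
        n_sites=n_sites,
        n_calls=n_calls,
        recall=recall,
        fdr=fdr,
        truth_fraction=true_calls / n_calls if n_calls else float("nan"),
    )


def fbe_fraction(peak_list: Sequence, genome: dict[str, str], window: int = 71) -> float:
    """Fraction of peaks whose centered window contains a canonical FBE."""
    if not peak_list:
        return float("nan")
    n = 0
    for p in peak_list:
        seq, _ = motifs.extract_window(genome, p.chrom, p.strand, p.max_pos, window)
        if motifs.scan(seq, motifs.FBE):
            n += 1
    return n / len(peak_list)


# ---------------------------------------------------------------------------
# crosslink-site pipeline


@dataclass
class CrosslinkResult:
    cims_per_rep: list[pd.DataFrame]
    cits_per_rep: list[pd.DataFrame]
    reproducible: list[xl.CrosslinkSite]


def run_crosslink_pipeline(
    sim: SimData, min_support: int = 2, alpha: float = xl.P_THRESHOLD
) -> CrosslinkResult:
    cims = [xl.find_cims(reads) for reads in sim.replicates]
    cits = [xl.find_cits(reads, sim.annotation) for reads in sim.replicates]
    sites = xl.reproducible_sites(cims, "CIMS", min_support, alpha)
    sites += xl.reproducible_sites(cits, "CITS", min_support, alpha)
    return CrosslinkResult(cims, cits, sites)


def crosslink_recovery(
    result: CrosslinkResult, truth: pd.DataFrame, tolerance: int = 1
) -> float:
    """Fraction of planted crosslink positions recovered within +-tolerance."""
    planted = []
    for row in truth.itertuples():
        for g in str(row.genomic_crosslink_positions).split(","):
            if g:
                planted.append((row.chrom, row.strand, int(g)))
    if not planted:
        return float("nan")
    by_cs: dict[tuple, list[int]] = {}
    for s in result.reproducible:
        by_cs.setdefault((s.chrom, s.strand), []).append(s.position)
    hit = 0
    for chrom, strand, g in planted:
        found = by_cs.get((chrom, strand), [])
        if any(abs(g - f) <= tolerance for f in found):
            hit += 1
    return hit / len(planted)


def fbe_anchors_from_truth(
    truth: pd.DataFrame, site_classes=("canonical_context", "canonical")
) -> list[tuple[str, str, int]]:
    """Genomic FBE start positions of planted canonical sites (for
    crosslink-profile construction on synthetic data)."""
    out = []
    for row in truth.itertuples():
        if row.site_class in site_classes:
            out.append((row.chrom, row.strand, int(row.genomic_motif_start)))
    return out


def fbe_anchors_from_peaks(
    peak_list: Sequence, genome: dict[str, str], window: int = 71
) -> list[tuple[str, str, int]]:
    """Genomic FBE start positions found inside peak windows."""
    out = []
    half = window // 2
    for p in peak_list:
        seq, clipped = motifs.extract_window(
            genome, p.chrom, p.strand, p.max_pos, window
        )
        if clipped:
            continue
        for hit in motifs.scan(seq, motifs.FBE):
            # genomic coordinate of the motif's first (U1) base
            if p.strand == "+":
                g = p.max_pos - half + hit.offset
            else:
                g = p.max_pos + half - hit.offset
            out.append((p.chrom, p.strand, g))
    return out
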