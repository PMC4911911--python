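# Methods

## Scope and design

`pufclip` analyzes iCLIP data for PUF-family RNA-binding proteins whose
binding element (FBE, UGUNNNAU) is known, and bundles a synthetic-data
generator so that every analysis stage can be validated against planted
ground truth. The package consumes mapped reads (SAM), a genome (FASTA)
and a transcript annotation (GFF3); it does not perform alignment, de novo
motif discovery, or gene-ontology/network retrieval. All internal
coordinates are 0-based half-open; GFF3 and SAM conventions are converted
at the I/O boundary. Barcodes travel in the read name as a `_BC:<seq>`
suffix.

## Read cleaning

Unmapped reads and reads with MAPQ < 20 are dropped. PCR duplicates are
collapsed exactly on the key (chromosome, strand, 5′ position, barcode),
keeping the longest read (ties: lexicographically smallest name). iCLIP
molecules are defined by their truncation point, which is why the 5′
position rather than the full span keys the collapse. The collapse is
idempotent and order-independent. Negative-control replicates are pooled
(concatenated, then collapsed) into a single control data set before use.

## Peak calling

Candidate peaks are local coverage maxima with height ≥ `min_height`
(default 10 reads — the upstream peak-shape algorithm's exact parameters
are not published, so this is configurable), extended in both directions
until coverage falls below `border_frac` (0.2) of the peak height;
overlapping candidates merge, taking the maximum height. Read 5′ ends are
binned in 50-nt bins over either the union of the target transcript's
exons ("whole gene") or a 500-bp window centered on the peak maximum
("local"). The tallest experimental bin overlapping the candidate is
tested against a background fit to the same region's bins from one of
three sources, giving the six-method grid (RNA-seq ×2, negative-control
iCLIP ×2, self ×2).

Numerical choices:

* Gaussian background: σ is floored at 1.0 read — counts are integers and
  an all-equal background would otherwise give a degenerate test.
* Negative binomial: method-of-moments fit, falling back to Poisson when
  the variance does not exceed the mean; keeps the fit deterministic.
* Self background is always Poisson (sharp enrichments are assumed to be
  signal; background is assumed flat), with λ computed over all region
  bins including the peak bin — the conservative reading.
* Empty backgrounds: Poisson λ is floored at 1/n_bins so p stays defined.
* x_max = 0 returns p = 1 for every model.
* The per-peak Bonferroni factor is the number of bins used for modeling
  the region (the literal reading of a per-peak correction); BH at
  q ≤ 0.01 is applied over the complete candidate set.

## Consensus and enrichment filtering

Peaks overlapping by ≥ 1 nt on the same strand across replicates cluster
transitively (single linkage); a cluster is kept when ≥ k replicates
contribute (3-of-3 per protein, 5-of-6 for a combined list). The
consensus span is the union of member spans, which can exceed any single
replicate's span. The secondary filter requires experimental/control
reads ≥ 5 in the 500-bp window centered on the peak maximum, with the
control floored at one read; the window (rather than the bare peak span)
is used because the peak span shrinks as filters tighten. The boundary
ratio (exactly 5) passes. An alternative normalized reads-in-peak mode
(ratio 3 for merged regions, 2.5 for individual replicates,
library-size-normalized) is provided solely for replicate-Venn reporting.

Peak heights are normalized to RNA abundance: height ÷ max(gene RNA-seq
density, 0.1), density = (gene 5′-end count / mature length) per million
mapped reads. Peak→gene assignment follows the peak maximum into exons;
among overlapping isoforms the longest mature transcript wins.

## Motifs

IUPAC scanning is positional (overlaps allowed), T is read as U, and
upstream-context flags (C at −1…−4) are attached per hit. The in vivo
consensus is scored by anchoring UGURCCAUR at a UGU and counting
violations over core positions 4–9 plus the upstream −1/−2 C requirement;
with several UGU anchors the minimal-mismatch anchor is used. Canonical
FBE matches can be masked (union of overlapping spans) so alternate-motif
scans are exclusive of the canonical element. Shuffle enrichment permutes
letters within each sequence (mononucleotide shuffle — the minimal null
given no compositional statement to preserve beyond base frequency) and
reports p = (1 + #{shuffles ≥ observed}) / (n_shuffles + 1). Per-peak
summaries use 71-nt windows centered on peak maxima, reverse-complemented
for minus-strand peaks; the context class comes from the FBE closest to
the window center. In vitro selection motifs in the bundled table are
clearly labelled synthetic stand-ins and are user-editable.

## Crosslink sites

CIMS: for each position with ≥ 1 read-through deletion, k deletions among
n covering reads are tested with an upper-tail binomial at the global
deletion rate r = Σk/Σn. CITS: read starts pile up one base 3′ of the
crosslink (the reverse transcriptase stops one base past the crosslinked
nucleotide), so the site is start − 1 in read orientation; pile-ups are
tested against a Poisson whose rate is the containing gene's mean start
rate per exonic base, with unannotated reads pooled into a genome-wide
rate. Sites use a raw P < 0.001 threshold without multiple-testing
correction (the interface is a raw cutoff), and must replicate exactly
(same position and kind) in ≥ 2 replicates. Because positions without
events have p ≈ 1 by construction, type-I accounting uses the full
modeled universe (all covered positions for CIMS; the exonic span of
genes holding ≥ 1 start for CITS), reported as
`DataFrame.attrs["n_positions_tested"]`.

Profiles count reproducible sites at each offset from the nearest FBE
start (U1 = offset 0, strand-aware, ±20 nt) and normalize to sum 1.

## Landscape statistics

Feature assignment (5′UTR/CDS/3UTR/ncRNA/intergenic) follows the peak
maximum, not the span majority, matching single-label usage. Un-merging
re-scans coverage within a consensus span: neighbouring local maxima
split into sub-peaks when the valley between them falls strictly below
`border_frac` × the smaller neighbour's height (a valley exactly at the
threshold does not split). Multi-peak versus single-peak genes are
compared on mature transcript length with a two-sided rank-sum test. The
3′-bias statistic is the Spearman correlation (average ranks on ties)
between the local coverage of 3′UTR FBEs and their proximity to the
transcript 3′ end. Overlap of gene lists uses the two-sided Fisher exact
test; rank agreement uses Spearman's ρ over shared items with exact
permutation p-values for n ≤ 9.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
at desk scale (defaults: 200 transcripts of 0.5–2.5 kb on alternating
strands of one chromosome, separated by 150-nt spacers; 3 replicates;
35-nt reads; 9-nt barcodes; ~1 PCR duplicate per molecule; log-normal
abundance with µ = 1, σ = 1).

* **Sites.** Half the transcripts carry a planted element: canonical FBE
  with a −2C context (weight 0.40, mean 60 crosslinked molecules per
  replicate at mean abundance), plain FBE (0.30 / 45), the 7-mer
  (0.20 / 34), or an alternate U/G-rich element (0.10 / 30). Affinities
  were chosen for clear signal at this scale while preserving the
  ordering context ≥ canonical ≥ 7-mer ≥ alternate. 75% of sites sit in
  the 3′UTR with a Beta(3,1) skew toward the 3′ end; long transcripts may
  carry a second site.
* **Signal model.** Site molecule counts are Poisson with mean
  affinity × (0.6 + 0.4·a/ā): bound sites saturate with protein
  occupancy, so signal is only partially abundance-coupled, while
  nonspecific background scales fully with abundance. A further
  multiplicative boost 1 + 1.5·exp(−d/150 nt), d = distance to the 3′
  end, makes terminal elements the most heavily crosslinked — the
  landscape property the 3′-bias statistic measures.
* **Crosslink chemistry.** Each site carries 2 crosslink offsets drawn
  from a discretized skewed distribution over −10…+8 with mode −2 and
  more mass upstream of the motif. A molecule truncates with probability
  0.65 (5′ end at crosslink+1); otherwise it reads through and leaves a
  single-base deletion at the crosslink with probability 0.6. Background
  reads carry stray deletions at 0.002 per read.
* **Background.** Every iCLIP library (experimental and control) draws
  70% of its nonspecific reads from per-transcript "sticky" hotspot
  positions shared across libraries (crosslinked background is a property
  of the RNA), the rest uniformly; RNA-seq background is uniform and
  duplicate-free. This is what makes the negative control the best
  background: self and RNA-seq backgrounds cannot explain the hotspots.
  The control is generated as one library per replicate and pooled.

What the generator does **not** emulate: sequencing errors beyond
crosslink deletions, substitution-type crosslink signatures, splice
junctions within reads, paired-end structure, mappability variation, or
isoform complexity. Passing tests therefore demonstrate correctness of
the statistical machinery and qualitative reproduction of the method
ranking, not performance on real libraries, where background is rougher
and annotation imperfect.

## Validation summary

The test suite checks each primitive against independent brute-force
oracles (BH step-up, Fisher by hypergeometric enumeration, Spearman by
the d² formula and exact permutation, binomial/Poisson tails by series
summation, coverage and binning by direct recount, border placement by
exhaustive scan), plus end-to-end properties on the default simulation:
≥ 90% planted-site recall at ≤ 5% empirical FDR for method 4 with the
fivefold and 3-of-3 filters at q = 0.01; a higher truth-overlap fraction
for control-background methods than self-background methods; ≥ 80%
crosslink recovery within ±1 nt with an upstream profile mode; and
null-simulation error rates within nominal bounds. The problem sizes are
those of the default configuration above; `scripts/acceptance.py`
recomputes all of these quantities from scratch for any seed.

## Known limitations

* The enrichment filter can drop genuinely bound low-affinity sites on
  highly abundant transcripts whose enrichment ratio hovers near the
  fivefold boundary — the price of optimizing for specificity.
* CIMS singleton deletions can reach P < 0.001 when the global deletion
  rate is very low; the replicate-reproducibility requirement is the
  intended guard.
* Whole-gene regions require the peak to fall inside an annotated
  transcript; intergenic candidates fall back to the local window with a
  warning.
* The exact-collapse treatment of barcodes does not model sequencing
  errors within the barcode itself.
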