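# pufclip

iCLIP analysis for PUF-family RNA-binding proteins: background-model peak
calling, replicate-consensus and enrichment filtering, binding-element
(FBE) motif scanning, crosslink-site inference from truncations and
deletions, and binding-landscape statistics — together with a fully seeded
synthetic-data generator that emulates FBF-style iCLIP experiments for
benchmarking every stage.

## Who this is for

iCLIP (individual-nucleotide resolution UV crosslinking and
immunoprecipitation) maps where an RNA-binding protein touches the
transcriptome. Reads truncate at the protein–RNA crosslink or read through
it leaving a deletion, so both the *peak* of read density and the exact
*crosslinked nucleotide* are recoverable. The hard part is background:
iCLIP libraries carry abundance-coupled, covalently crosslinked
nonspecific signal that RNA-seq does not model. `pufclip` implements and
compares the standard choices on a grid of six methods, and ships a
generator with planted ground truth so each choice can be scored.

## The model

**Candidate peaks.** Local coverage maxima above a height threshold,
extended until read density falls to 20% of the peak height; overlapping
candidates are merged.

**Six calling methods.** Read 5′ ends are placed in 50-nt bins. For each
candidate, the maximum experimental bin count x_max is tested against a
background distribution fit to one of three read sources over one of two
regions:

| method | background            | region            | model    |
|--------|-----------------------|-------------------|----------|
| 1 / 2  | RNA-seq               | whole gene / local 500 bp | Gaussian (or NB) |
| 3 / 4  | negative-control iCLIP| whole gene / local 500 bp | Gaussian (or NB) |
| 5 / 6  | iCLIP signal itself   | whole gene / local 500 bp | Poisson  |

with p = P(X ≥ x_max), a per-peak Bonferroni factor (number of modeled
bins), and Benjamini–Hochberg control at a 1% FDR over all candidates.

**Filters.** A peak must be called in k of n replicates (3-of-3 per
protein; 5-of-6 for a combined list) and show ≥ 5-fold more experimental
than control reads in its local 500-bp window (control floored at 1 read).

**Motifs.** The canonical FBE is UGUNNNAU; high-affinity variants carry a
cytosine at −1 or −2, and the in vivo consensus is a −1/−2 C followed by
UGURCCAUR. Peaks lacking an FBE are scanned (after masking canonical
elements) for the shorter 7-mer UGURNAU and alternate motifs, with
empirical enrichment against mononucleotide-shuffled peak sequences.

**Crosslink sites.** CIMS: per-position deletion counts vs. an upper-tail
binomial at the global deletion rate. CITS: read-start pile-ups vs. a
Poisson at the gene's mean start rate; the crosslink is the base
immediately 5′ of the read start. Sites at P < 0.001 reproducible in ≥ 2
replicates are reported, and profiles are aggregated relative to FBE
starts.

## Worked example

Everything is driven from a seeded synthetic experiment; no external data
is needed:

```bash
printf 'n_transcripts = 60\nseed = 4\n' > demo.cfg
pufclip --seed 4 --config demo.cfg --outdir demo_out run-all
```

prints

```
wrote synthetic data for 60 transcripts to demo_out
81 significant peak calls (method 4)
27 consensus peaks in 23 target genes
motif tables for 27 peaks written to demo_out
202 reproducible crosslink sites
4 multi-peak genes; length-comparison p = 0.188; 3' bias rho = 0.407 (p = 0.0101)
```

Reading the output: the 81 per-replicate method-4 calls collapse to 27
consensus peaks present in all three replicates and ≥ 5-fold enriched over
the pooled negative control. `demo_out/consensus_peaks.tsv` holds one row
per peak, e.g.

```
chrom    strand start  end    height max_pos support enrichment_ratio normalized_height gene_id
synChrI  +      25009  25053  73     25018   3       206.0            49.3              gene0012
```

— a 44-nt peak of height 73 reads, 206-fold enriched over control, assigned
to `gene0012`, with its height normalized to RNA-seq abundance.
`crosslink_profile.tsv` aggregates the 202 reproducible CIMS/CITS sites
relative to FBE starts; its maximum falls at offset −2, i.e. crosslinking
concentrates immediately upstream of the binding element. The 3′-bias
statistic (Spearman ρ = 0.41, p = 0.01) confirms that heavily covered
3′UTR elements sit closer to transcript 3′ ends.

The library surface mirrors the CLI: `pufclip.simulate` (generator),
`pufclip.ingest` (GFF3/SAM loading, MAPQ ≥ 20 filter, barcode collapse,
coverage), `pufclip.peaks`, `pufclip.consensus`, `pufclip.motifs`,
`pufclip.crosslink`, `pufclip.landscape`, and `pufclip.pipeline` for
end-to-end runs.

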