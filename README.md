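# rloopkit

Strand-specific R-loop profiling, end to end, on synthetic genomes with
planted ground truth.

R-loops are three-stranded structures that form during transcription: the
nascent RNA base-pairs with the template DNA strand (a DNA:RNA hybrid) and
the non-template strand is displaced as single-stranded DNA (ssDNA).
Nuclease-based profiling (targeting micrococcal nuclease to hybrids with a
catalytically dead RNase H) releases R-loop fragments genome-wide, but a
conventional sequencing library cannot tell which strand carried the
hybrid.  A bisulfite-based extension fixes this chemically:

1. non-denaturing bisulfite deaminates C→U **only on exposed ssDNA** — the
   displaced strand — while duplexed DNA (including the hybrid) is protected;
2. second-strand synthesis replaces the RNA with a dUTP-containing DNA
   strand;
3. uracil-DNA glycosylase (UDG) destroys every uracil-bearing strand,
   leaving only the untouched hybrid (template) DNA strand to be
   directionally tagged and sequenced.

`rloopkit` implements this chemistry as a mechanistic simulator, plus the
full downstream analysis: SAM-flag strand assignment (first-mate flags
16/83/163 → forward dataset, 0/99/147 → reverse), blacklist-filtered
RPM-normalized 5-bp strand tracks sharing one combined-total factor,
TSS-centered signal matrices, the strandedness statistic
(template − non-template RPM), strand-specificity classification
(|log2 F/R| ≥ 1.5), bidirectional-promoter detection (two head-to-head
TSSs ≤ 1 kb, both genes ≥ 1 CPM in every sample), k-means enhancer
clustering (k = 4), GC skew ((G−C)/(G+C), 100-bp windows, 10-bp step),
IUPAC motif scanning and re-centering, and hypergeometric set-overlap
enrichment.  Four library modes are simulated: `bismapr` (directional),
`bismapr_rnaseA` (RNase A pre-digestion control), `mapr` (conventional
non-directional prep), and `mapr_nbss` (second-strand synthesis + UDG but
no bisulfite).

It is written for methods developers and analysts who want every stage of
a strand-specific R-loop pipeline testable against known truth before
touching real sequencing data.

## Worked example

```python
import rloopkit as rk
from rloopkit import promoters as pm

g = rk.simulate_genome(1, 1_200_000, gc=0.42, seed=1)
genes, loci = rk.annotate_genes(g, 120, divergent_fraction=0.75,
                                expressed_fraction=1.0, seed=1)
records = rk.run_chemistry(g, loci, "bismapr", p_conv=1.0, seed=61)
track = rk.build_tracks(records, g.lengths)          # 5-bp RPM tracks
anchors = pm.tss_anchors(genes)
fwd = pm.reference_point_matrix(track.forward, 5, anchors, 1000, 1000)
rev = pm.reference_point_matrix(track.reverse, 5, anchors, 1000, 1000)
profile = pm.strandedness_profile(fwd, rev)          # strandedness metaprofile
```

Running the narrative drivers (`python analysis/03_promoter_strandedness.py`
etc.) on this world prints:

```
bismapr   downstream |strandedness| = 811.2 RPM
mapr_nbss downstream |strandedness| = 40.7 RPM (ratio 0.050)
mapr      downstream |strandedness| = 0.0 RPM
nbss magnitude vs ssDNA-loss fraction: Spearman rho = 1.00 over [0.0, 0.25, 0.5, 1.0]
divergent sign pattern: upstream mean -282.4 (sign test p=8.3e-17), downstream 787.0 (p=7e-46)
```

i.e. the directional chemistry recovers strong template-strand signal in
gene bodies and antisense (non-template) signal upstream of divergent
promoters; the conventional library shows none; and the no-bisulfite
control shows a faint copy whose size tracks the fraction of hybrids that
lost their ssDNA strand.  The enhancer driver
(`analysis/05_enhancer_analysis.py`) recovers the four planted enhancer
groups (adjusted Rand index 0.97), their opposite dominant strands
(unidirectionality 0.99), and the planted non-template GC skew
(0.39/0.41 recovered for a planted 0.4; −0.01 in the silent group).

The numbered scripts under `analysis/` are thin drivers over the library;
each writes its tables to `results/`.  A `rloopkit` CLI
(`rloopkit run-all --seed 1 --out out/`, plus `simulate`, `tracks`,
`profiles`, `enhancers`, `fixtures` subcommands) wraps the same pipeline.

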