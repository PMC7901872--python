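# Methods

## The model

An R-loop locus is an interval with a designated hybrid-carrying strand
(the template strand of the transcription event that formed it) and an
expected fragment yield (`strength`).  Nuclease release draws
Poisson(`strength` × `depth_scale`) fragments per locus, centered uniformly
within it, with Gaussian lengths (mean 150 bp, sd 20 bp, floor 30 bp), plus
a genome-wide Poisson duplex background (`background_rate`, default 0.2
fragments/kb).  Each R-loop fragment carries three strands: the hybrid DNA
strand (RNA-paired, protected), the displaced ssDNA strand, and the RNA.
With probability `ssdna_free_fraction` (default 0.1) the fragment is a
"hybrid-only" duplex that lost its ssDNA strand during release.  These
hybrid-only fragments are the carrier of the faint residual strandedness
of the no-bisulfite control, where only a small subset of regions behaves
strand-specifically.

The four chemistries are composed from five primitive operations
(`release → [digest] → [convert] → [synthesize] → select → sequence`):

* **bisulfite conversion** deaminates each cytosine on a ssDNA strand
  independently with probability `p_conv` (default 0.95; the acceptance
  benchmarks use 1.0).  One converted base is enough to doom a strand at
  the UDG step; C-free ssDNA stretches would survive, a real failure mode,
  but default fragments (~150 bp at GC 0.42) essentially always contain a C.
* **RNase A digestion** removes the RNA of an R-loop with probability
  `efficiency` (default 0.9 in the RNase control mode, 1.0 in the
  conventional mode); the DNA strands re-anneal into a protected duplex.
* **second-strand synthesis** replaces every remaining RNA with a
  dUTP-marked DNA strand on the opposite genomic strand.
* **UDG selection** removes every uracil-bearing strand (converted or
  dUTP); survivors keep their genomic strand identity.
* **sequencing** emits one placed read pair per surviving strand, with the
  SAM flag convention that a surviving '+' strand yields mate-1 on the
  reverse strand (flags 83/163, assigned to the forward dataset) and a
  surviving '−' strand yields flags 99/147 (reverse dataset).  Records are
  placed directly (chromosome, position, fragment length); sequence-level
  alignment is out of scope and flag semantics are the analysis contract.

The conventional (`mapr`) mode models a double-stranded adaptor ligation:
after full RNase digestion, fragments missing a complementary strand
(hybrid-only duplexes reduced to a lone strand) cannot be ligated and are
dropped, and both strands of every retained duplex are sequenced.  This
makes the conventional library exactly balanced per fragment, while the
no-bisulfite control — which synthesizes the missing strand before
ligation and then loses only the dUTP strand — retains hybrid-only
fragments as single directional survivors.  That asymmetry, not bisulfite,
is what gives the control its faint strandedness, and it scales as
f/(2−f) with the hybrid-only fraction f (0.053 at the default 0.1, which
is what the benchmarks measure).

## Synthetic worlds

`simulate_genome` draws i.i.d. bases at a target GC fraction (default
0.42, a mammalian-like composition).  Genes are placed on a jittered TSS
grid (spacing 8 kb, lengths 1.5–4 kb); each expressed gene gets a sense
locus from TSS−200 to TSS+800 (gene-oriented) with the hybrid on the
template strand, and with probability `divergent_fraction` (default 0.75,
the reported fraction of active mammalian genes with divergent antisense
transcription) an upstream divergent locus from TSS−700 to TSS−100 on the
opposite strand at 0.6× the sense strength.  The locus extents are a
design choice, picked to reproduce the canonical metaprofile shape —
signal flanking the TSS on both sides, stronger and longer into the gene
body.  Expression is a shifted log-normal (always above the
1-CPM threshold) for expressed genes and uniform below 1 CPM for silent
ones, so the generator's expressed flag and the ≥1-CPM-in-every-sample
detector agree.  Locus strengths are log-normal around `strength_mean`
(default 30 fragments) with log-sd 0.5, giving the across-promoter
dynamic range that the forward/reverse correlation analyses need.

Head-to-head pairs place a '−' gene TSS exactly `span` bases left of a
'+' gene TSS (both expressed, sense loci on opposite hybrid strands).
Enhancers come in four planted groups: reverse-unidirectional and
forward-unidirectional (strength 50 on one strand), bidirectional medium
(10 per strand), and near-silent (0.5 per strand).  The two unidirectional
groups carry a GC-box consensus (GGGGCGGGG, the KLF/SP family site)
written at the enhancer centre on the non-template strand, and their
non-template strand is drawn with (G−C)/(G+C) expectation equal to the
planted skew (default 0.4).  Because bases are i.i.d., a G excess on the
'−' strand is planted as a C excess on '+' without reversing the
sequence, which keeps the motif midpoint exactly at the enhancer centre.

What the generator does **not** model: real sequence composition (repeats,
CpG islands, isochores), mappability, PCR duplicates, base qualities, or
fragment-length biases.  Passing benchmarks therefore demonstrate that the
analysis logic is correct and that the chemistry's strand logic has the
claimed consequences — not that real libraries are free of the alignment
and amplification artifacts these simplifications ignore.

## Analysis conventions

Coordinates are 0-based half-open throughout (BED convention).  Tracks use
5-bp bins; each properly-paired fragment counts once and contributes
full-fragment coverage; bins overlapping a blacklist are zeroed; both
strands are scaled by one factor, 1e6/(combined assigned fragments), so
doubling every record leaves RPM tracks bitwise unchanged.  Per-region
"read density" is the mean binned RPM over TSS ± 1000 bp (a symmetric
window of this size is a choice; mean, rather than summed, density is the
default, and both are supported).  Log-ratios add a 0.1-RPM pseudocount;
the strand-specificity threshold |log2 F/R| ≥ 1.5 is inclusive.
Strandedness is reverse−forward for '+' genes and forward−reverse for '−'
genes (template minus non-template, given the flag convention above), and
TSS matrices flip '−'-anchor rows so downstream is always rightward.
Bidirectional promoters require divergent (pointing-away) orientation;
convergent opposite-strand pairs within 1 kb are excluded; each gene joins
at most one pair, nearest partner first, ties by smaller span then gene id.

Enhancer clustering features are the mean RPM in 10 coarse bins per strand
over midpoint ± 1000 bp, log2(x+1)-transformed, z-scored per feature, and
winsorized at |z| = 2 before k-means (k = 4, 25 restarts, fixed seed).
The log transform stops the strongest groups from dominating every
feature's variance (linear features merge the medium and silent groups);
the winsorizing — the usual heatmap zMax treatment — stops the k-means
objective from spending a cluster on a handful of zero-coverage outlier
profiles, which otherwise happens on a minority of seeds even though the
planted partition has lower within-cluster variance almost everywhere.
Groups are relabeled deterministically by descending max(forward, reverse)
mean signal, with the reverse-dominant group first when two clusters are
within 1.5× of each other, so "group 1" is stably the
reverse-unidirectional group.  GC-skew windows with no G or C score 0
(keeps vectors numeric; matches the null-skew reading).  Motif scanning is
exact IUPAC matching on both strands of the central 500 bp; re-centering
keeps the hit nearest the enhancer midpoint (ties upstream); profiles are
not flipped by motif strand by default (the anchor tuples carry the strand
so callers can).  Enrichment is upper-tail hypergeometric with
fold = observed/expected; "high" signal sets, where needed, are defined by
k-means (k = 2) on mean densities.

## Benchmark sizes and numerical choices

The benchmark routines (`rloopkit.evaluation`) use worlds of 120–200 genes
on 0.8–1.7 Mb single chromosomes and 4 × 40 enhancers — large enough that
binomial/Poisson noise sits well inside the tested margins (e.g. the
strand-recovery bound of 95% at strength 30, where the conventional
library's misclassification probability per locus is ~0.5%), small enough
that the whole acceptance run takes seconds.  Every random draw flows from
an explicit integer seed through `numpy.random.default_rng`; stage seeds
are small fixed offsets of the user seed.  Reruns of the pipeline with the
same config are byte-identical (the manifest hashes every output;
timestamps are never written).

Known limitations: the simulator emits placed records, so mappability and
alignment ambiguity are untested; enhancer groups are planted with equal
sizes and sharp strength ratios, whereas real enhancer classes are
unbalanced and graded; and conversion failure on C-free stretches is
modelled but rarely exercised at default fragment lengths.
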