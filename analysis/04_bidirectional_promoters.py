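#!/usr/bin/env python
"""Detect divergent (head-to-head) promoters and check the planted pairs.

Plants pairs at the two hallmark TSS separations (294 and 125 bases) among
ordinary genes, runs the <=1 kb both-expressed detector, and shows that the
directional chemistry resolves the two opposing sense R-loops that the pair
geometry implies.
"""

from pathlib import Path

import rloopkit as rk
from rloopkit import promoters as pm
from rloopkit.tracks import region_mean_density

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

g = rk.simulate_genome(1, 900_000, 0.42, seed=SEED)
genes, loci = rk.annotate_genes(g, 50, seed=SEED)
for span in (294, 125):
    pairs, pair_loci = rk.plant_bidirectional_pairs(g, genes, 2, span,
                                                    seed=SEED + span,
                                                    id_prefix=f"bd{span}_")
    genes += [x for p in pairs for x in p]
    loci += pair_loci

found = pm.find_bidirectional_promoters(genes, max_span=1000)
recs = rk.run_chemistry(g, loci, "bismapr", p_conv=1.0, seed=SEED + 4)
track = rk.build_tracks(recs, g.lengths)

with open(OUT / "04_bidirectional.tsv", "w") as fh:
    fh.write("minus_gene\tplus_gene\tspan\tminus_fwd_rpm\tplus_rev_rpm\n")
    for gm, gp, span in found:
        # the '-' gene's sense hybrid is on '+' (forward track), and vice versa
        f = region_mean_density(track.forward, track.bin_size,
                                [(gm.chrom, gm.tss - 800, gm.tss + 200)])[0]
        r = region_mean_density(track.reverse, track.bin_size,
                                [(gp.chrom, gp.tss - 200, gp.tss + 800)])[0]
        fh.write(f"{gm.gene_id}\t{gp.gene_id}\t{span}\t{f:.1f}\t{r:.1f}\n")
        print(f"{gm.gene_id} <-> {gp.gene_id}: span {span} bp, "
              f"forward R-loop {f:.0f} RPM / reverse {r:.0f} RPM")

planted = {294, 125}
print(f"\nDetected {len(found)} divergent promoters; planted separations "
      f"{sorted(planted)} are all present: "
      f"{planted <= {s for _, _, s in found}}")
print(f"Table: {OUT / '04_bidirectional.tsv'}")
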