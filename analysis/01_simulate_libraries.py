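#!/usr/bin/env python
"""Simulate one synthetic mESC-like world and sequence it with all four
library chemistries.

Reports, per mode, how many read pairs the library yields and what fraction
of R-loop-derived pairs fall on the hybrid (template) strand — the raw
material for every downstream comparison.
"""

from pathlib import Path

import rloopkit as rk

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

cfg = rk.PipelineConfig(seed=SEED, n_chroms=1, chrom_len=1_200_000,
                        n_genes=80, n_enhancers_per_group=10)
g, genes, loci, enhancers, pairs = rk.simulate_world(cfg)
truth_strand = {l.locus_id: l.hybrid_strand for l in loci}

rows = []
for mode in ("bismapr", "bismapr_rnaseA", "mapr", "mapr_nbss"):
    recs = rk.run_chemistry(g, loci, mode, p_conv=cfg.p_conv,
                            rnase_efficiency=cfg.rnase_efficiency,
                            seed=SEED + 21)
    rloop = [r for r in recs if r.origin_locus != "background"]
    on_hybrid = sum(
        1 for r in rloop
        if ("+" if r.mate1_orientation == "R" else "-")
        == truth_strand[r.origin_locus])
    rows.append((mode, len(recs), len(rloop),
                 on_hybrid / len(rloop) if rloop else float("nan")))
    print(f"{mode:15s} {len(recs):6d} pairs, {len(rloop):6d} from R-loops, "
          f"{100 * rows[-1][3]:.1f}% on the hybrid strand")

with open(OUT / "01_library_summary.tsv", "w") as fh:
    fh.write("mode\tread_pairs\trloop_pairs\tfrac_on_hybrid_strand\n")
    for mode, n, nr, frac in rows:
        fh.write(f"{mode}\t{n}\t{nr}\t{frac:.4f}\n")

print(f"\nThe fully directional chemistry puts ~100% of R-loop reads on the "
      f"hybrid strand;\nthe conventional prep is split 50/50, and the "
      f"controls sit in between.\nTable: {OUT / '01_library_summary.tsv'}")
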