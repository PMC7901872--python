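#!/usr/bin/env python
"""Forward-vs-reverse read densities at active TSSs, per chemistry.

A conventional library sequences both strands of every fragment, so the two
densities track each other (Pearson r near 1).  The directional chemistry
splits strand-specific promoters onto the axes, collapsing the correlation.
Writes the per-mode correlations and the per-gene density table.
"""

from pathlib import Path

import rloopkit as rk
from rloopkit import evaluation as ev

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

res = ev.tss_strand_correlations(SEED)
with open(OUT / "02_tss_correlations.tsv", "w") as fh:
    fh.write("mode\tpearson_r\tn_tss\n")
    fh.write(f"mapr\t{res['pearson_r_mapr']:.4f}\t{res['n_mapr']}\n")
    fh.write(f"bismapr(strand-specific)\t{res['pearson_r_bismapr']:.4f}\t"
             f"{res['n_bismapr']}\n")

print(f"conventional library : r = {res['pearson_r_mapr']:.3f} "
      f"over {res['n_mapr']} TSSs")
print(f"directional library  : r = {res['pearson_r_bismapr']:.3f} "
      f"over {res['n_bismapr']} strand-specific TSSs")
print(f"\nStrand selection destroys the forward/reverse coupling at "
      f"strand-specific promoters.\nTable: {OUT / '02_tss_correlations.tsv'}")
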