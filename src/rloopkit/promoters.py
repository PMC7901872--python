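"""TSS-centered signal matrices, strandedness, and promoter classification.

Strandedness is the template-minus-non-template signal around a gene's TSS.
Because the hybrid DNA strand of an R-loop is the template strand and the
flag rule sends hybrid '+' strands to the forward dataset, template signal
for a forward gene lives on the *reverse* track: strandedness is
reverse-forward for '+' genes and forward-reverse for '-' genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genome import GeneModel, ParameterError
from .tracks import StrandedTrack

logger = logging.getLogger(__name__)


class TssClass(Enum):
    FORWARD_SPECIFIC = "FORWARD_SPECIFIC"
    REVERSE_SPECIFIC = "REVERSE_SPECIFIC"
    UNSPECIFIC = "UNSPECIFIC"


@dataclass
class SignalMatrix:
    """Loci x bins signal matrix anchored at reference points.

    Rows are oriented along each anchor's strand: downstream of the anchor
    is always rightward, so '-' anchors have their bins flipped.
    """
    ids: list[str]
    values: np.ndarray  # rows = loci, cols = bins, RPM
    bin_size: int
    upstream: int
    downstream: int
    anchor_strands: list[str]

    def __post_init__(self):
        expect = (self.upstream + self.downstream) // self.bin_size
        if self.values.shape != (len(self.ids), expect):
            raise ParameterError("matrix shape inconsistent with window/bin")

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-center offsets relative to the anchor, in bases."""
        n = self.values.shape[1]
        return (np.arange(n) - self.upstream // self.bin_size) * self.bin_size \
            + self.bin_size // 2


def expressed_genes(expr_table: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Genes with at least ``threshold`` CPM in every sample (inclusive)."""
    if expr_table.empty:
        return set()
    ok = (expr_table >= threshold).all(axis=1)
    return set(expr_table.index[ok])


def load_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def reference_point_matrix(arrays: dict[str, np.ndarray], bin_size: int,
                           anchors: list[tuple[str, str, int, str]],
                           upstream: int = 2000, downstream: int = 2000,
                           ) -> SignalMatrix:
    """Signal around anchor points, deepTools reference-point style.

    ``anchors`` are (id, chrom, position, strand) tuples.  Anchors whose
    window falls outside the chromosome are dropped with a log message.
    """
    up_bins, down_bins = upstream // bin_size, downstream // bin_size
    ids, strands, rows = [], [], []
    for aid, chrom, pos, strand in anchors:
        if chrom not in arrays:
            logger.warning("anchor %s on unknown chromosome %s dropped", aid, chrom)
            continue
        arr = arrays[chrom]
        abin = pos // bin_size
        lo, hi = abin - up_bins, abin + down_bins
        if lo < 0 or hi > len(arr):
            logger.warning("anchor %s window out of bounds; row dropped", aid)
            continue
        row = arr[lo:hi]
        if strand == "-":
            row = row[::-1]
        ids.append(aid)
        strands.append(strand)
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, up_bins + down_bins))
    return SignalMatrix(ids, values, bin_size, upstream, downstream, strands)


def tss_anchors(genes: list[GeneModel]) -> list[tuple[str, str, int, str]]:
    return [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes]


def strandedness_matrix(fwd: SignalMatrix, rev: SignalMatrix) -> np.ndarray:
    """Per-gene template-minus-non-template signal.

    reverse-forward for '+' anchors, forward-reverse for '-' anchors.
    """
    if fwd.ids != rev.ids or fwd.values.shape != rev.values.shape:
        raise ParameterError("forward/reverse matrices must align on loci")
    sign = np.where(np.array(fwd.anchor_strands) == "+", 1.0, -1.0)[:, None]
    return sign * (rev.values - fwd.values)


def strandedness_profile(fwd: SignalMatrix, rev: SignalMatrix) -> np.ndarray:
    """Column-wise mean strandedness across genes (the metaprofile curve)."""
    m = strandedness_matrix(fwd, rev)
    return m.mean(axis=0) if len(m) else m.sum(axis=0)


def classify_tss_strand(fwd_density, rev_density, log2_threshold: float = 1.5,
                        pseudocount: float = 0.1):
    """Label each TSS by its forward/reverse log2 ratio (inclusive threshold)."""
    f = np.atleast_1d(np.asarray(fwd_density, dtype=float))
    r = np.atleast_1d(np.asarray(rev_density, dtype=float))
    if (f < 0).any() or (r < 0).any():
        raise ParameterError("densities must be non-negative")
    ratio = np.log2((f + pseudocount) / (r + pseudocount))
    out = np.where(ratio >= log2_threshold, TssClass.FORWARD_SPECIFIC,
                   np.where(ratio <= -log2_threshold, TssClass.REVERSE_SPECIFIC,
                            TssClass.UNSPECIFIC))
    if np.isscalar(fwd_density) or np.ndim(fwd_density) == 0:
        return out.item()
    return list(out)


def find_bidirectional_promoters(genes: list[GeneModel], max_span: int = 1000,
                                 expressed: set[str] | None = None,
                                 ) -> list[tuple[GeneModel, GeneModel, int]]:
    """Divergent head-to-head promoter pairs within ``max_span`` (inclusive).

    A pair is a '-' gene and a '+' gene on the same chromosome, both
    expressed, with the '-' TSS at or left of the '+' TSS (transcription
    pointing away from each other).  Each gene joins at most one pair; the
    nearest partner wins, ties broken by smaller span then gene id.
    Returns (minus_gene, plus_gene, span) sorted by position.
    """
    if expressed is None:
        expressed = {g.gene_id for g in genes if g.expressed}
    cands = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.gene_id in expressed:
            by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        minus = [g for g in gs if g.strand == "-"]
        plus = [g for g in gs if g.strand == "+"]
        for gm in minus:
            for gp in plus:
                span = gp.tss - gm.tss
                if 0 <= span <= max_span:
                    cands.append((span, gm.gene_id, gp.gene_id, gm, gp))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[str] = set()
    pairs = []
    for span, idm, idp, gm, gp in cands:
        if idm in used or idp in used:
            continue
        used.update((idm, idp))
        pairs.append((gm, gp, span))
    pairs.sort(key=lambda t: (t[0].chrom, t[0].tss))
    return pairs


def promoter_density_table(track: StrandedTrack, genes: list[GeneModel],
                           half_window: int = 1000,
                           log2_threshold: float = 1.5,
                           pseudocount: float = 0.1) -> pd.DataFrame:
    """Per-gene forward/reverse mean densities over TSS +/- half_window and
    the resulting strand-specificity call."""
    from .tracks import region_mean_density

    regions = [(g.chrom, g.tss - half_window, g.tss + half_window)
               for g in genes]
    f = region_mean_density(track.forward, track.bin_size, regions)
    r = region_mean_density(track.reverse, track.bin_size, regions)
    calls = classify_tss_strand(f, r, log2_threshold, pseudocount)
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "strand": [g.strand for g in genes],
        "fwd_density": f,
        "rev_density": r,
        "call": [c.value for c in calls],
    }).set_index("gene_id")
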