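"""Synthetic genome, gene annotation and ground-truth R-loop loci.

The generator produces the statistical structure the downstream analysis
assumes: expressed genes carry a co-transcriptional R-loop on the template
strand downstream of the TSS; a configurable fraction of active promoters
(default 0.75, the fraction of active mammalian genes with divergent
antisense transcription) additionally carry an upstream R-loop on the
opposite strand; head-to-head gene pairs emulate bidirectional promoters;
and intergenic enhancers come in four planted groups — reverse-strand
unidirectional, forward-strand unidirectional, bidirectional medium, and
near-silent — with a GC-box motif and positive GC skew written onto the
non-template strand of the two unidirectional groups.

Coordinates are 0-based, half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


class CapacityError(RuntimeError):
    """The genome cannot accommodate the requested number of features."""


@dataclass(frozen=True)
class GenomeModel:
    chrom_names: tuple[str, ...]
    chrom_seqs: tuple[str, ...]

    def __post_init__(self):
        if not self.chrom_names:
            raise ParameterError("genome needs at least one chromosome")
        for seq in self.chrom_seqs:
            if set(seq) - set("ACGT"):
                raise ParameterError("genome sequences must be over {A,C,G,T}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in zip(self.chrom_names, self.chrom_seqs)}

    def seq(self, chrom: str) -> str:
        return self.chrom_seqs[self.chrom_names.index(chrom)]

    def with_seq(self, chrom: str, seq: str) -> "GenomeModel":
        i = self.chrom_names.index(chrom)
        seqs = list(self.chrom_seqs)
        if len(seq) != len(seqs[i]):
            raise ParameterError("replacement sequence must keep chromosome length")
        seqs[i] = seq
        return replace(self, chrom_seqs=tuple(seqs))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str
    cpm_per_sample: tuple[float, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError(f"bad strand {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ParameterError("forward gene needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ParameterError("reverse gene needs tss > tes")
        if any(c < 0 for c in self.cpm_per_sample):
            raise ParameterError("cpm must be non-negative")

    @property
    def expressed(self) -> bool:
        return all(c >= 1.0 for c in self.cpm_per_sample)


@dataclass(frozen=True)
class RLoopLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    hybrid_strand: str
    strength: float
    klass: str
    ssdna_free_fraction: float = 0.1

    def __post_init__(self):
        if not self.start < self.end:
            raise ParameterError("locus needs start < end")
        if self.hybrid_strand not in "+-":
            raise ParameterError("hybrid_strand must be + or -")
        if self.strength < 0:
            raise ParameterError("strength must be >= 0")
        if not 0.0 <= self.ssdna_free_fraction <= 1.0:
            raise ParameterError("ssdna_free_fraction must be in [0,1]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class MotifModel:
    consensus: str
    name: str = "motif"

    def __post_init__(self):
        if not self.consensus:
            raise ParameterError("motif consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(IUPAC_CODES)
        if bad:
            raise ParameterError(f"invalid IUPAC letters in consensus: {sorted(bad)}")


@dataclass(frozen=True)
class Enhancer:
    enh_id: str
    chrom: str
    start: int
    end: int
    truth_group: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


#: GC-box consensus shared by the KLF/SP family of zinc-finger factors.
KLF_MOTIF = MotifModel("GGGGCGGGG", name="KLF")

# --------------------------------------------------------------------------
# generators


def simulate_genome(n_chroms: int, chrom_len: int, gc: float = 0.42,
                    seed: int = 0) -> GenomeModel:
    """I.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if chrom_len < 10_000:
        raise ParameterError("chrom_len must be >= 10000")
    if not 0.0 < gc < 1.0:
        raise ParameterError("gc must be in (0,1)")
    if n_chroms < 1:
        raise ParameterError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    names, seqs = [], []
    for i in range(n_chroms):
        names.append(f"chr{i + 1}")
        seqs.append("".join(BASES[rng.choice(4, size=chrom_len, p=p)]))
    return GenomeModel(tuple(names), tuple(seqs))


def _slot_positions(genome: GenomeModel, spacing: int, margin: int):
    slots = []
    for chrom, length in genome.lengths.items():
        for pos in range(margin, length - margin, spacing):
            slots.append((chrom, pos))
    return slots


# Geometry of the truth loci relative to the TSS, in gene-oriented
# coordinates (negative = upstream).  The sense locus runs from just
# upstream of the TSS into the gene body; the divergent locus sits wholly
# upstream on the opposite strand.
SENSE_SPAN = (-200, 800)
DIVERGENT_SPAN = (-700, -100)


def _gene_loci(gene: GeneModel, strength: float, divergent: bool,
               divergent_ratio: float, ssdna_free_fraction: float):
    """Truth loci for one expressed gene; hybrid forms on the template strand."""
    loci = []
    sgn = 1 if gene.strand == "+" else -1
    template = "-" if gene.strand == "+" else "+"
    a, b = sorted((gene.tss + sgn * SENSE_SPAN[0], gene.tss + sgn * SENSE_SPAN[1]))
    loci.append(RLoopLocus(f"{gene.gene_id}_sense", gene.chrom, a, b,
                           hybrid_strand=template, strength=strength,
                           klass="gene_sense",
                           ssdna_free_fraction=ssdna_free_fraction))
    if divergent:
        a, b = sorted((gene.tss + sgn * DIVERGENT_SPAN[0],
                       gene.tss + sgn * DIVERGENT_SPAN[1]))
        loci.append(RLoopLocus(f"{gene.gene_id}_divergent", gene.chrom, a, b,
                               hybrid_strand=gene.strand,
                               strength=strength * divergent_ratio,
                               klass="gene_divergent",
                               ssdna_free_fraction=ssdna_free_fraction))
    return loci


def _draw_cpm(rng, expressed: bool, n_samples: int) -> tuple[float, ...]:
    if expressed:
        # shifted log-normal keeps every sample above the 1-CPM threshold
        return tuple(1.0 + rng.lognormal(2.0, 1.0, size=n_samples))
    return tuple(rng.uniform(0.0, 0.9, size=n_samples))


def annotate_genes(genome: GenomeModel, n_genes: int,
                   divergent_fraction: float = 0.75,
                   expressed_fraction: float = 0.8,
                   seed: int = 0, *,
                   spacing: int = 8000, margin: int = 5000,
                   gene_len_range: tuple[int, int] = (1500, 4000),
                   strength_mean: float = 30.0, strength_sigma: float = 0.5,
                   divergent_ratio: float = 0.6,
                   ssdna_free_fraction: float = 0.1,
                   n_samples: int = 3) -> tuple[list[GeneModel], list[RLoopLocus]]:
    """Place genes on a regular grid of TSS slots and emit their truth loci.

    Expressed genes get a template-strand sense locus spanning the TSS into
    the gene body and, with probability ``divergent_fraction``, an upstream
    divergent locus on the opposite strand.  Silent genes get no loci.
    """
    for name, v in [("divergent_fraction", divergent_fraction),
                    ("expressed_fraction", expressed_fraction)]:
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must be in [0,1]")
    rng = np.random.default_rng(seed)
    slots = _slot_positions(genome, spacing, margin)
    if n_genes > len(slots):
        raise CapacityError(f"genome fits {len(slots)} TSS slots, "
                            f"{n_genes} genes requested")
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_genes, replace=False)]
    chosen.sort()
    genes, loci = [], []
    for i, (chrom, pos) in enumerate(chosen):
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(*gene_len_range))
        tss = pos + int(rng.integers(-1000, 1000))
        tes = tss + glen if strand == "+" else tss - glen
        expressed = rng.random() < expressed_fraction
        gene = GeneModel(f"g{i:04d}", chrom, tss, tes, strand,
                         _draw_cpm(rng, expressed, n_samples))
        genes.append(gene)
        if expressed:
            strength = strength_mean * float(
                np.exp(strength_sigma * rng.standard_normal()
                       - strength_sigma ** 2 / 2))
            divergent = rng.random() < divergent_fraction
            loci.extend(_gene_loci(gene, strength, divergent,
                                   divergent_ratio, ssdna_free_fraction))
    return genes, loci


def _occupied_intervals(genes, enhancers=(), pad: int = 2500):
    occ: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        a, b = sorted((g.tss, g.tes))
        occ.setdefault(g.chrom, []).append((a - pad, b + pad))
    for e in enhancers:
        occ.setdefault(e.chrom, []).append((e.start - pad, e.end + pad))
    return occ


def _collides(occ, chrom, start, end):
    return any(start < b and a < end for a, b in occ.get(chrom, ()))


def plant_bidirectional_pairs(genome: GenomeModel, genes: list[GeneModel],
                              n_pairs: int, span: int = 300, seed: int = 0, *,
                              gene_len_range: tuple[int, int] = (1500, 4000),
                              strength_mean: float = 30.0,
                              ssdna_free_fraction: float = 0.1,
                              n_samples: int = 3,
                              max_tries: int = 500,
                              pad: int = 2500,
                              id_prefix: str = "bd",
                              ) -> tuple[list[tuple[GeneModel, GeneModel]], list[RLoopLocus]]:
    """Head-to-head expressed gene pairs with TSSs exactly ``span`` bases apart.

    The reverse-strand gene sits on the left, transcribing leftward, and the
    forward-strand gene on the right — a divergent promoter.  Both genes are
    expressed and each gets a sense locus, so the pair carries R-loop truth
    on opposite hybrid strands.
    """
    rng = np.random.default_rng(seed)
    occ = _occupied_intervals(genes, pad=pad)
    lengths = genome.lengths
    chroms = list(lengths)
    pairs, new_loci = [], []
    for j in range(n_pairs):
        placed = False
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            glen_l = int(rng.integers(*gene_len_range))
            glen_r = int(rng.integers(*gene_len_range))
            tss_minus = int(rng.integers(glen_l + 2000,
                                         lengths[chrom] - span - glen_r - 2000))
            tss_plus = tss_minus + span
            lo, hi = tss_minus - glen_l, tss_plus + glen_r
            if _collides(occ, chrom, lo - pad, hi + pad):
                continue
            gm = GeneModel(f"{id_prefix}{j:03d}m", chrom, tss_minus,
                           tss_minus - glen_l, "-",
                           _draw_cpm(rng, True, n_samples))
            gp = GeneModel(f"{id_prefix}{j:03d}p", chrom, tss_plus,
                           tss_plus + glen_r, "+",
                           _draw_cpm(rng, True, n_samples))
            occ.setdefault(chrom, []).append((lo, hi))
            for g in (gm, gp):
                new_loci.extend(_gene_loci(g, strength_mean, False, 0.0,
                                           ssdna_free_fraction))
            pairs.append((gm, gp))
            placed = True
            break
        if not placed:
            raise CapacityError(f"could not place bidirectional pair {j}")
    return pairs, new_loci


def _skewed_sequence(rng, length: int, gc: float, skew: float) -> str:
    """Random sequence whose (G-C)/(G+C) expectation equals ``skew``."""
    p = np.array([(1 - gc) / 2, gc * (1 - skew) / 2, gc * (1 + skew) / 2,
                  (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def instantiate_motif(motif: MotifModel, rng) -> str:
    return "".join(IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))]
                   for c in motif.consensus.upper())


# Planted per-group emission strengths (released fragments per enhancer
# strand); groups 1-2 are 5x the per-strand strength of group 3.
ENHANCER_STRENGTHS = {1: 50.0, 2: 50.0, 3: 10.0, 4: 0.5}


def plant_enhancers(genome: GenomeModel, n_per_group: tuple[int, int, int, int],
                    motif: MotifModel = KLF_MOTIF, skew: float = 0.4,
                    seed: int = 0, *, genes: list[GeneModel] = (),
                    enhancer_len: int = 1000, gc: float = 0.42,
                    strengths: dict[int, float] = ENHANCER_STRENGTHS,
                    ssdna_free_fraction: float = 0.1,
                    max_tries: int = 1000,
                    pad: int = 2500,
                    ) -> tuple[GenomeModel, list[Enhancer], list[RLoopLocus]]:
    """Intergenic enhancers in four planted groups.

    group 1: unidirectional R-loop, hybrid on '-', non-template strand '+'
    group 2: unidirectional R-loop, hybrid on '+', non-template strand '-'
    group 3: medium bidirectional R-loops, no planted skew or motif
    group 4: near-silent, no planted skew or motif

    Groups 1-2 get the motif consensus written at the enhancer centre on the
    non-template strand and a G-over-C excess of ``skew`` on that strand.
    """
    if not -1.0 < skew < 1.0:
        raise ParameterError("skew must be in (-1,1)")
    rng = np.random.default_rng(seed)
    occ = _occupied_intervals(genes, pad=pad)
    lengths = genome.lengths
    chroms = list(lengths)
    enhancers, loci = [], []
    new_seqs = {c: list(genome.seq(c)) for c in chroms}
    i = 0
    for group, count in zip((1, 2, 3, 4), n_per_group):
        for _ in range(count):
            placed = False
            for _try in range(max_tries):
                chrom = chroms[rng.integers(len(chroms))]
                start = int(rng.integers(2000, lengths[chrom] - enhancer_len - 2000))
                end = start + enhancer_len
                if _collides(occ, chrom, start - pad, end + pad):
                    continue
                occ.setdefault(chrom, []).append((start, end))
                placed = True
                break
            if not placed:
                raise CapacityError("could not place enhancer; genome too crowded")
            enh = Enhancer(f"e{i:04d}", chrom, start, end, group)
            enhancers.append(enh)
            if group in (1, 2):
                hybrid = "-" if group == 1 else "+"
                non_template = "+" if group == 1 else "-"
                # i.i.d. bases: G excess on the '-' strand is just C excess
                # on '+', so flip the sign instead of reversing the sequence
                # (keeps the motif midpoint exactly at the enhancer centre)
                plus_skew = skew if non_template == "+" else -skew
                plus_seq = _skewed_sequence(rng, enhancer_len, gc, plus_skew)
                inst = instantiate_motif(motif, rng)
                if non_template == "-":
                    inst = reverse_complement(inst)
                mid = enhancer_len // 2 - len(inst) // 2
                plus_seq = plus_seq[:mid] + inst + plus_seq[mid + len(inst):]
                new_seqs[chrom][start:end] = plus_seq
                loci.append(RLoopLocus(f"{enh.enh_id}_uni", chrom, start, end,
                                       hybrid_strand=hybrid,
                                       strength=strengths[group],
                                       klass="enhancer_uni",
                                       ssdna_free_fraction=ssdna_free_fraction))
            else:
                for s in "+-":
                    loci.append(RLoopLocus(f"{enh.enh_id}_{'p' if s == '+' else 'm'}",
                                           chrom, start, end, hybrid_strand=s,
                                           strength=strengths[group],
                                           klass="background",
                                           ssdna_free_fraction=ssdna_free_fraction))
            i += 1
    out = genome
    for c in chroms:
        out = out.with_seq(c, "".join(new_seqs[c]))
    return out, enhancers, loci


# --------------------------------------------------------------------------
# writers (FASTA / BED6 / expression TSV)


def write_fasta(genome: GenomeModel, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(genome.chrom_names, genome.chrom_seqs):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_genes_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            a, b = sorted((g.tss, g.tes))
            fh.write(f"{g.chrom}\t{a}\t{b}\t{g.gene_id}\t0\t{g.strand}\n")


def write_loci_bed(loci, path) -> None:
    """Truth loci as BED6: name=class, strand=hybrid strand, score=strength."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.klass}\t"
                     f"{l.strength:g}\t{l.hybrid_strand}\n")


def write_enhancers_bed(enhancers, path) -> None:
    with open(path, "w") as fh:
        for e in enhancers:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.enh_id}\t"
                     f"{e.truth_group}\t.\n")


def write_expression_tsv(genes, path) -> None:
    with open(path, "w") as fh:
        n = len(genes[0].cpm_per_sample) if genes else 0
        fh.write("gene_id\t" + "\t".join(f"sample{i + 1}" for i in range(n)) + "\n")
        for g in genes:
            fh.write(g.gene_id + "\t" +
                     "\t".join(f"{c:.4f}" for c in g.cpm_per_sample) + "\n")
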