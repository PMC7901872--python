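"""Fragment release and the four library chemistries.

A released R-loop fragment carries three strands: the hybrid DNA strand
(base-paired to RNA, hence protected), the displaced single-stranded
non-template DNA, and the RNA itself.  The four protocol modes differ in
which strands reach the sequencer:

bismapr        non-denaturing bisulfite converts C->U on the exposed ssDNA;
               second-strand synthesis replaces the RNA with a dUTP-marked
               DNA strand; UDG destroys every uracil-bearing strand, leaving
               only the hybrid DNA strand -> fully directional libraries.
bismapr_rnaseA RNase A pre-digestion collapses most R-loops back to duplex
               DNA before conversion, erasing most strand specificity.
mapr           RNase A digestion, then a conventional double-stranded prep:
               both strands of every duplex are ligated, so each fragment
               contributes one read pair per strand -> balanced libraries.
mapr_nbss      second-strand synthesis + UDG but no bisulfite: the intact
               ssDNA strand survives alongside the hybrid strand; only
               hybrid-only fragments (those that lost their ssDNA strand)
               are strand-specific -> weak residual directionality.

Strand bookkeeping uses 'top' for the genomic '+' strand and 'bottom' for
'-'.  Reads are emitted as placed alignment records with SAM flag semantics;
no sequence-level realignment is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genome import GenomeModel, ParameterError, RLoopLocus

logger = logging.getLogger(__name__)


class StrandState(Enum):
    DNA_PROTECTED = "DNA_PROTECTED"
    DNA_SSDNA = "DNA_SSDNA"
    ABSENT = "ABSENT"


MODES = ("bismapr", "bismapr_rnaseA", "mapr", "mapr_nbss")


@dataclass
class MoleculeState:
    """One released fragment with per-strand chemical state.

    ``rna_paired`` names the DNA strand hybridised to RNA ('+'/'-'/None);
    ``synth_strand`` appears after second-strand synthesis and always carries
    uracil (dUTP incorporation).  Cytosine offsets are positions within the
    fragment where the given strand has a C (for the bottom strand these are
    positions where the top sequence reads G).
    """
    chrom: str
    start: int
    end: int
    top_state: StrandState
    bottom_state: StrandState
    rna_paired: str | None = None
    c_offsets_top: tuple[int, ...] = ()
    c_offsets_bottom: tuple[int, ...] = ()
    converted_cytosines_top: frozenset[int] = frozenset()
    converted_cytosines_bottom: frozenset[int] = frozenset()
    has_uracil_top: bool = False
    has_uracil_bottom: bool = False
    synth_strand: str | None = None
    synth_has_uracil: bool = False
    origin_locus: str = "background"

    def is_rloop(self) -> bool:
        return self.rna_paired is not None

    def state(self, strand: str) -> StrandState:
        return self.top_state if strand == "+" else self.bottom_state


@dataclass(frozen=True)
class SurvivingStrand:
    """A single DNA strand that survives to adaptor ligation."""
    chrom: str
    start: int
    end: int
    strand: str
    origin_locus: str


@dataclass(frozen=True)
class AlignmentRecord:
    """A placed read pair.  ``pos`` is the leftmost 0-based coordinate of the
    fragment; flags follow SAM semantics (83/163 <=> mate1 on the reverse
    strand, 99/147 <=> mate1 forward)."""
    chrom: str
    pos: int
    fragment_len: int
    mate1_orientation: str  # 'F' or 'R'
    flags_mate1: int
    flags_mate2: int
    origin_locus: str = "background"

    def __post_init__(self):
        if self.mate1_orientation == "R" and (self.flags_mate1, self.flags_mate2) != (83, 163):
            raise ParameterError("mate1 reverse requires flags 83/163")
        if self.mate1_orientation == "F" and (self.flags_mate1, self.flags_mate2) != (99, 147):
            raise ParameterError("mate1 forward requires flags 99/147")


def _c_offsets(seq: str) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Cytosine offsets on the top and bottom strands of a fragment."""
    top = tuple(i for i, b in enumerate(seq) if b == "C")
    bottom = tuple(i for i, b in enumerate(seq) if b == "G")
    return top, bottom


def release_fragments(genome: GenomeModel, loci: list[RLoopLocus],
                      background_rate: float = 0.2,
                      frag_len_mean: float = 150.0, frag_len_sd: float = 20.0,
                      depth_scale: float = 1.0, seed: int = 0,
                      ) -> list[MoleculeState]:
    """Nuclease release: Poisson fragment counts per locus plus genome-wide
    duplex background at ``background_rate`` fragments per kb.

    Each R-loop fragment has the hybrid strand protected (RNA-paired) and the
    other strand displaced as ssDNA — or, with probability
    ``ssdna_free_fraction``, absent entirely (a hybrid that lost its ssDNA
    strand during release).
    """
    if frag_len_mean <= 0:
        raise ParameterError("frag_len_mean must be > 0")
    if background_rate < 0 or depth_scale < 0:
        raise ParameterError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    mols: list[MoleculeState] = []

    def fragment(chrom: str, center: int) -> tuple[int, int]:
        flen = max(30, int(round(rng.normal(frag_len_mean, frag_len_sd))))
        start = max(0, center - flen // 2)
        end = min(lengths[chrom], start + flen)
        return start, end

    for locus in loci:
        n = rng.poisson(locus.strength * depth_scale)
        for _ in range(n):
            center = int(rng.integers(locus.start, locus.end))
            start, end = fragment(locus.chrom, center)
            top, bottom = _c_offsets(genome.seq(locus.chrom)[start:end])
            hybrid = locus.hybrid_strand
            ssdna_free = rng.random() < locus.ssdna_free_fraction
            other = StrandState.ABSENT if ssdna_free else StrandState.DNA_SSDNA
            mols.append(MoleculeState(
                locus.chrom, start, end,
                top_state=StrandState.DNA_PROTECTED if hybrid == "+" else other,
                bottom_state=StrandState.DNA_PROTECTED if hybrid == "-" else other,
                rna_paired=hybrid,
                c_offsets_top=top, c_offsets_bottom=bottom,
                origin_locus=locus.locus_id))
    for chrom, length in lengths.items():
        n = rng.poisson(background_rate * depth_scale * length / 1000.0)
        for _ in range(n):
            center = int(rng.integers(0, length))
            start, end = fragment(chrom, center)
            top, bottom = _c_offsets(genome.seq(chrom)[start:end])
            mols.append(MoleculeState(
                chrom, start, end,
                top_state=StrandState.DNA_PROTECTED,
                bottom_state=StrandState.DNA_PROTECTED,
                c_offsets_top=top, c_offsets_bottom=bottom))
    return mols


def bisulfite_convert(mols: list[MoleculeState], p_conv: float,
                      seed: int = 0) -> list[MoleculeState]:
    """Non-denaturing bisulfite: C->U on exposed ssDNA only.

    Each cytosine on a DNA_SSDNA strand deaminates independently with
    probability ``p_conv``; protected (duplexed or RNA-paired) strands are
    untouched.  A strand with at least one conversion is uracil-marked.
    """
    if not 0.0 <= p_conv <= 1.0:
        raise ParameterError("p_conv must be in [0,1]")
    rng = np.random.default_rng(seed)
    for m in mols:
        if m.top_state is StrandState.DNA_SSDNA and m.c_offsets_top:
            hits = np.asarray(m.c_offsets_top)[
                rng.random(len(m.c_offsets_top)) < p_conv]
            m.converted_cytosines_top = frozenset(int(h) for h in hits)
            m.has_uracil_top = bool(len(hits))
        if m.bottom_state is StrandState.DNA_SSDNA and m.c_offsets_bottom:
            hits = np.asarray(m.c_offsets_bottom)[
                rng.random(len(m.c_offsets_bottom)) < p_conv]
            m.converted_cytosines_bottom = frozenset(int(h) for h in hits)
            m.has_uracil_bottom = bool(len(hits))
    return mols


def rnase_a_digest(mols: list[MoleculeState], efficiency: float,
                   seed: int = 0) -> list[MoleculeState]:
    """RNase A removes the RNA of an R-loop with the given efficiency.

    When digestion succeeds the two DNA strands re-anneal to a protected
    duplex; a hybrid-only fragment is left as a lone unpaired DNA strand
    (DNA_SSDNA).  Failed digestions leave the fragment unchanged.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ParameterError("efficiency must be in [0,1]")
    rng = np.random.default_rng(seed)
    for m in mols:
        if m.rna_paired is None:
            continue
        if rng.random() < efficiency:
            m.rna_paired = None
            for attr in ("top_state", "bottom_state"):
                st = getattr(m, attr)
                if st is StrandState.ABSENT:
                    continue
                partner = m.bottom_state if attr == "top_state" else m.top_state
                setattr(m, attr,
                        StrandState.DNA_SSDNA if partner is StrandState.ABSENT
                        else StrandState.DNA_PROTECTED)
    return mols


def second_strand_synthesis(mols: list[MoleculeState]) -> list[MoleculeState]:
    """Replace the RNA of every hybrid with a dUTP-containing DNA strand.

    The synthesized strand occupies the genomic strand opposite the hybrid
    strand and is always uracil-marked.  Fragments without RNA are unchanged.
    """
    for m in mols:
        if m.rna_paired is None:
            continue
        m.synth_strand = "-" if m.rna_paired == "+" else "+"
        m.synth_has_uracil = True
        m.rna_paired = None
    return mols


def duplex_only(mols: list[MoleculeState]) -> list[MoleculeState]:
    """Double-stranded adaptor ligation: drop fragments missing a strand.

    Models a conventional (non-directional) prep in which lone single
    strands cannot be ligated; used by the mapr mode.
    """
    return [m for m in mols
            if m.top_state is not StrandState.ABSENT
            and m.bottom_state is not StrandState.ABSENT]


def udg_select(mols: list[MoleculeState]) -> list[SurvivingStrand]:
    """UDG degrades every uracil-bearing strand (bisulfite- or dUTP-marked).

    Each fragment yields 0, 1 or 2 surviving DNA strands; survivors keep
    their genomic strand identity.  RNA is never sequenced and synthesized
    strands always carry uracil, so neither appears among survivors.
    """
    out: list[SurvivingStrand] = []
    for m in mols:
        if m.top_state is not StrandState.ABSENT and not m.has_uracil_top:
            out.append(SurvivingStrand(m.chrom, m.start, m.end, "+",
                                       m.origin_locus))
        if m.bottom_state is not StrandState.ABSENT and not m.has_uracil_bottom:
            out.append(SurvivingStrand(m.chrom, m.start, m.end, "-",
                                       m.origin_locus))
    return out


def sequence_library(survivors: list[SurvivingStrand], read_len: int = 50,
                     mode: str = "bismapr", seed: int = 0,
                     ) -> list[AlignmentRecord]:
    """Directional ligation: each surviving strand emits one read pair.

    A surviving '+' strand yields mate1 on the reverse strand (flags 83/163)
    and a surviving '-' strand yields mate1 forward (flags 99/147), so that
    the downstream flag rule maps each pair back to its strand of origin.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; expected one of {MODES}")
    records = []
    for s in survivors:
        if s.strand == "+":
            rec = AlignmentRecord(s.chrom, s.start, s.end - s.start, "R",
                                  83, 163, s.origin_locus)
        else:
            rec = AlignmentRecord(s.chrom, s.start, s.end - s.start, "F",
                                  99, 147, s.origin_locus)
        records.append(rec)
    return records


def run_chemistry(genome: GenomeModel, loci: list[RLoopLocus], mode: str,
                  *, p_conv: float = 0.95, rnase_efficiency: float = 0.9,
                  background_rate: float = 0.2, depth_scale: float = 1.0,
                  frag_len_mean: float = 150.0, frag_len_sd: float = 20.0,
                  read_len: int = 50, seed: int = 0) -> list[AlignmentRecord]:
    """Release fragments and run the full chemistry for one protocol mode."""
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; expected one of {MODES}")
    mols = release_fragments(genome, loci, background_rate=background_rate,
                             frag_len_mean=frag_len_mean,
                             frag_len_sd=frag_len_sd,
                             depth_scale=depth_scale, seed=seed)
    if mode == "bismapr":
        mols = bisulfite_convert(mols, p_conv, seed=seed + 1)
        mols = second_strand_synthesis(mols)
        survivors = udg_select(mols)
    elif mode == "bismapr_rnaseA":
        mols = rnase_a_digest(mols, rnase_efficiency, seed=seed + 2)
        mols = bisulfite_convert(mols, p_conv, seed=seed + 1)
        mols = second_strand_synthesis(mols)
        survivors = udg_select(mols)
    elif mode == "mapr":
        mols = rnase_a_digest(mols, 1.0, seed=seed + 2)
        survivors = udg_select(duplex_only(mols))
    else:  # mapr_nbss
        mols = second_strand_synthesis(mols)
        survivors = udg_select(mols)
    return sequence_library(survivors, read_len=read_len, mode=mode,
                            seed=seed + 3)


# --------------------------------------------------------------------------
# SAM-dialect IO


def write_sam(records: list[AlignmentRecord], chrom_lengths: dict[str, int],
              path, read_len: int = 50) -> None:
    """Write placed read pairs as SAM text (no sequences, CIGAR of Ms)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, r in enumerate(records):
            qname = f"frag{i:07d}"
            rl = min(read_len, r.fragment_len)
            left = r.pos + 1  # SAM is 1-based
            right = r.pos + r.fragment_len - rl + 1
            cigar = f"{rl}M"
            if r.mate1_orientation == "R":
                # mate1 reverse: read1 at the fragment's right edge
                m1_pos, m2_pos = right, left
                tlen1, tlen2 = -r.fragment_len, r.fragment_len
            else:
                m1_pos, m2_pos = left, right
                tlen1, tlen2 = r.fragment_len, -r.fragment_len
            fh.write(f"{qname}\t{r.flags_mate1}\t{r.chrom}\t{m1_pos}\t60\t"
                     f"{cigar}\t=\t{m2_pos}\t{tlen1}\t*\t*\n")
            fh.write(f"{qname}\t{r.flags_mate2}\t{r.chrom}\t{m2_pos}\t60\t"
                     f"{cigar}\t=\t{m1_pos}\t{tlen2}\t*\t*\n")


def read_sam(path) -> list[AlignmentRecord]:
    """Read placed pairs back from a SAM/BAM file (pysam).

    Only the first mate of each properly-paired fragment is consulted;
    single-end records with flags 0/16 are accepted as fragment-length-long
    singletons.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_paired and not aln.is_read1:
                continue
            if aln.is_paired:
                tlen = abs(aln.template_length)
                pos = min(aln.reference_start,
                          aln.next_reference_start)
                if aln.is_reverse:
                    flags = ("R", 83, 163)
                else:
                    flags = ("F", 99, 147)
            else:
                tlen = aln.query_length or (aln.reference_end - aln.reference_start)
                pos = aln.reference_start
                flags = ("R", 83, 163) if aln.is_reverse else ("F", 99, 147)
            records.append(AlignmentRecord(aln.reference_name, pos, tlen,
                                           *flags))
    return records


def write_truth_tsv(records: list[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("record\tchrom\tpos\tfragment_len\torigin_locus\tstrand\n")
        for i, r in enumerate(records):
            strand = "+" if r.mate1_orientation == "R" else "-"
            fh.write(f"frag{i:07d}\t{r.chrom}\t{r.pos}\t{r.fragment_len}\t"
                     f"{r.origin_locus}\t{strand}\n")
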