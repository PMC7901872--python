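"""Fragment release, the four chemistries, and SAM flag semantics."""

import numpy as np
import pytest

import rloopkit as rk
from rloopkit import chemistry as chem
from rloopkit.chemistry import StrandState as S
from rloopkit.genome import ParameterError, RLoopLocus


def make_rloop(hybrid="+", ssdna_free=False, seq="ACCGGTAT" * 5):
    """Hand-built R-loop fragment with cytosines on both strands."""
    top, bottom = chem._c_offsets(seq)
    other = S.ABSENT if ssdna_free else S.DNA_SSDNA
    return chem.MoleculeState(
        "chr1", 100, 100 + len(seq),
        top_state=S.DNA_PROTECTED if hybrid == "+" else other,
        bottom_state=S.DNA_PROTECTED if hybrid == "-" else other,
        rna_paired=hybrid, c_offsets_top=top, c_offsets_bottom=bottom,
        origin_locus="L")


def make_background(seq="ACCGGTAT" * 5):
    top, bottom = chem._c_offsets(seq)
    return chem.MoleculeState("chr1", 100, 100 + len(seq),
                              top_state=S.DNA_PROTECTED,
                              bottom_state=S.DNA_PROTECTED,
                              c_offsets_top=top, c_offsets_bottom=bottom)


def survivors_of(mols):
    return {(s.strand) for s in chem.udg_select(mols)}


class TestReleaseFragments:
    def test_poisson_fragment_count(self):
        g = rk.simulate_genome(1, 50_000, 0.42, seed=1)
        locus = RLoopLocus("L", "chr1", 20_000, 21_000, "+", 10.0,
                           "gene_sense", ssdna_free_fraction=0.0)
        counts = [len(chem.release_fragments(g, [locus], background_rate=0.0,
                                             seed=s))
                  for s in range(200)]
        assert np.mean(counts) == pytest.approx(10.0, abs=1.0)
        assert np.var(counts) == pytest.approx(10.0, rel=0.35)

    def test_hybrid_strand_protected_other_ssdna(self):
        g = rk.simulate_genome(1, 50_000, 0.42, seed=1)
        for hybrid, top, bottom in [("+", S.DNA_PROTECTED, S.DNA_SSDNA),
                                    ("-", S.DNA_SSDNA, S.DNA_PROTECTED)]:
            locus = RLoopLocus("L", "chr1", 20_000, 21_000, hybrid, 20.0,
                               "gene_sense", ssdna_free_fraction=0.0)
            mols = chem.release_fragments(g, [locus], background_rate=0.0,
                                          seed=2)
            assert mols
            for m in mols:
                assert (m.top_state, m.bottom_state) == (top, bottom)
                assert m.rna_paired == hybrid

    def test_ssdna_free_boundary(self):
        g = rk.simulate_genome(1, 50_000, 0.42, seed=1)
        locus = RLoopLocus("L", "chr1", 20_000, 21_000, "+", 30.0,
                           "gene_sense", ssdna_free_fraction=1.0)
        mols = chem.release_fragments(g, [locus], background_rate=0.0, seed=3)
        assert mols and all(m.bottom_state is S.ABSENT for m in mols)

    def test_background_is_duplex(self):
        g = rk.simulate_genome(1, 100_000, 0.42, seed=1)
        mols = chem.release_fragments(g, [], background_rate=1.0, seed=4)
        assert mols
        assert all(m.top_state is S.DNA_PROTECTED
                   and m.bottom_state is S.DNA_PROTECTED
                   and m.rna_paired is None for m in mols)


class TestBisulfiteConvert:
    def test_full_conversion_marks_all_ssdna_cytosines(self):
        m = make_rloop("+")
        n_c = len(m.c_offsets_bottom)
        chem.bisulfite_convert([m], 1.0, seed=0)
        assert len(m.converted_cytosines_bottom) == n_c > 0
        assert m.has_uracil_bottom and not m.has_uracil_top

    def test_zero_conversion_is_identity(self):
        m = make_rloop("+")
        chem.bisulfite_convert([m], 0.0, seed=0)
        assert not m.converted_cytosines_bottom and not m.has_uracil_bottom

    def test_protected_duplex_untouched(self):
        m = make_background()
        chem.bisulfite_convert([m], 1.0, seed=0)
        assert not m.has_uracil_top and not m.has_uracil_bottom

    def test_invalid_probability(self):
        with pytest.raises(ParameterError):
            chem.bisulfite_convert([], 1.5)


class TestRnaseADigest:
    def test_full_digestion_removes_all_rloops(self):
        mols = [make_rloop("+"), make_rloop("-"), make_rloop("+", True)]
        chem.rnase_a_digest(mols, 1.0, seed=0)
        assert all(m.rna_paired is None for m in mols)
        assert all(S.DNA_SSDNA not in (m.top_state, m.bottom_state)
                   or S.ABSENT in (m.top_state, m.bottom_state)
                   for m in mols)

    def test_zero_efficiency_is_identity(self):
        m = make_rloop("+")
        chem.rnase_a_digest([m], 0.0, seed=0)
        assert m.rna_paired == "+" and m.bottom_state is S.DNA_SSDNA

    def test_retained_count_binomial(self):
        # 1000 R-loops at efficiency 0.9: retained ~ Binomial(1000, 0.1);
        # 99.99% interval [64, 140]
        mols = [make_rloop("+") for _ in range(1000)]
        chem.rnase_a_digest(mols, 0.9, seed=1)
        retained = sum(m.rna_paired is not None for m in mols)
        assert 64 <= retained <= 140


class TestSecondStrandSynthesis:
    def test_rloop_gains_uracil_strand(self):
        m = make_rloop("+")
        chem.second_strand_synthesis([m])
        assert m.synth_strand == "-" and m.synth_has_uracil
        assert m.rna_paired is None

    def test_background_unchanged(self):
        m = make_background()
        chem.second_strand_synthesis([m])
        assert m.synth_strand is None

    def test_hybrid_only_becomes_duplex(self):
        m = make_rloop("-", ssdna_free=True)
        chem.second_strand_synthesis([m])
        assert m.synth_strand == "+" and m.synth_has_uracil


class TestUdgSelect:
    def test_bismapr_rloop_yields_only_hybrid_strand(self):
        for hybrid in "+-":
            m = make_rloop(hybrid)
            chem.bisulfite_convert([m], 1.0, seed=0)
            chem.second_strand_synthesis([m])
            assert survivors_of([m]) == {hybrid}

    def test_background_duplex_yields_both(self):
        assert survivors_of([make_background()]) == {"+", "-"}

    def test_nbss_rloop_keeps_hybrid_and_ssdna(self):
        m = make_rloop("+")  # no conversion
        chem.second_strand_synthesis([m])
        assert survivors_of([m]) == {"+", "-"}  # only the dU strand lost


class TestSequenceLibrary:
    def test_flag_orientation_rule(self):
        plus = chem.SurvivingStrand("chr1", 0, 100, "+", "L")
        minus = chem.SurvivingStrand("chr1", 0, 100, "-", "L")
        r_plus, r_minus = chem.sequence_library([plus, minus])
        assert (r_plus.flags_mate1, r_plus.flags_mate2) == (83, 163)
        assert r_plus.mate1_orientation == "R"
        assert (r_minus.flags_mate1, r_minus.flags_mate2) == (99, 147)
        assert r_minus.mate1_orientation == "F"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            chem.sequence_library([], mode="drip")

    def test_mapr_two_pairs_per_fragment(self):
        g = rk.simulate_genome(1, 50_000, 0.42, seed=1)
        locus = RLoopLocus("L", "chr1", 20_000, 21_000, "+", 20.0,
                           "gene_sense", ssdna_free_fraction=0.0)
        mols = chem.release_fragments(g, [locus], background_rate=0.0, seed=5)
        recs = rk.run_chemistry(g, [locus], "mapr", background_rate=0.0,
                                seed=5)
        assert len(recs) == 2 * len(mols)
        flags = sorted(r.flags_mate1 for r in recs)
        assert flags.count(83) == flags.count(99) == len(mols)


class TestConservation:
    """No strand is both uracil-marked and surviving, in any mode."""

    @pytest.mark.parametrize("mode", chem.MODES)
    def test_no_uracil_survivor(self, mode, specific_world):
        g, _, loci = specific_world
        mols = chem.release_fragments(g, loci[:20], background_rate=0.1,
                                      seed=11)
        import copy
        mols = copy.deepcopy(mols)
        if mode in ("bismapr", "bismapr_rnaseA"):
            if mode == "bismapr_rnaseA":
                chem.rnase_a_digest(mols, 0.9, seed=1)
            chem.bisulfite_convert(mols, 0.7, seed=2)
            chem.second_strand_synthesis(mols)
        elif mode == "mapr_nbss":
            chem.second_strand_synthesis(mols)
        else:
            chem.rnase_a_digest(mols, 1.0, seed=1)
            mols = chem.duplex_only(mols)
        by_pos = {}
        for m in mols:
            by_pos.setdefault((m.chrom, m.start, m.end), []).append(m)
        for s in chem.udg_select(mols):
            for m in by_pos[(s.chrom, s.start, s.end)]:
                if s.strand == "+" and m.top_state is not S.ABSENT:
                    assert not m.has_uracil_top
                if s.strand == "-" and m.bottom_state is not S.ABSENT:
                    assert not m.has_uracil_bottom


class TestSamIO:
    def test_roundtrip(self, tmp_path):
        g = rk.simulate_genome(1, 50_000, 0.42, seed=1)
        locus = RLoopLocus("L", "chr1", 20_000, 21_000, "+", 30.0,
                           "gene_sense")
        recs = rk.run_chemistry(g, [locus], "bismapr", p_conv=1.0,
                                background_rate=0.2, seed=6)
        path = tmp_path / "lib.sam"
        chem.write_sam(recs, g.lengths, path)
        back = chem.read_sam(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert (a.chrom, a.pos, a.fragment_len, a.mate1_orientation) == \
                   (b.chrom, b.pos, b.fragment_len, b.mate1_orientation)
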