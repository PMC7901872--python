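"""GC skew, motif scanning, clustering mechanics, hypergeometric test."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rloopkit as rk
from rloopkit import enhancers as en
from rloopkit.genome import MotifModel, ParameterError, reverse_complement
from rloopkit.promoters import SignalMatrix


def brute_force_skew(seq, window=100, step=10):
    out = []
    for i in range(0, len(seq) - window + 1, step):
        w = seq[i:i + window]
        g, c = w.count("G"), w.count("C")
        out.append((g - c) / (g + c) if g + c else 0.0)
    return np.array(out)


dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


class TestGcSkew:
    def test_extremes(self):
        assert en.gc_skew("G" * 100)[0] == 1.0
        assert en.gc_skew("C" * 100)[0] == -1.0
        assert en.gc_skew("A" * 100)[0] == 0.0  # no G or C -> null skew

    def test_short_sequence_empty(self):
        assert en.gc_skew("ACGT" * 10).size == 0

    @given(dna)
    def test_matches_brute_force(self, seq):
        np.testing.assert_array_equal(en.gc_skew(seq, 50, 7),
                                      brute_force_skew(seq, 50, 7))

    def test_antisymmetry_under_reverse_complement(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=600))
            fwd = en.gc_skew(seq, 100, 10)
            rc = en.gc_skew(reverse_complement(seq), 100, 10)
            np.testing.assert_array_equal(rc, -fwd[::-1])

    def test_minus_strand_equals_reverse_complement(self):
        seq = "GGGCATCGATCG" * 20
        np.testing.assert_array_equal(
            en.gc_skew(seq, 50, 10, strand="-"),
            en.gc_skew(reverse_complement(seq), 50, 10))


class TestScanMotif:
    def test_planted_at_center(self):
        seq = "A" * 496 + "GGGGCGGGG" + "A" * 495
        hits = en.scan_motif(seq, rk.KLF_MOTIF)
        assert (0, "+") in hits

    def test_reverse_complement_hit(self):
        motif = MotifModel("GGGGNGGGG")
        rc = reverse_complement("GGGGAGGGG")
        seq = "T" * 495 + rc + "T" * 496
        hits = en.scan_motif(seq, motif)
        assert hits and all(strand == "-" for _, strand in hits)

    def test_no_match_empty(self):
        assert en.scan_motif("AT" * 500, rk.KLF_MOTIF) == []

    def test_iupac_degeneracy(self):
        motif = MotifModel("GGRGG")
        seq = "T" * 500 + "GGAGG" + "T" * 500
        assert any(s == "+" for _, s in en.scan_motif(seq, motif))

    def test_outside_search_window_ignored(self):
        seq = "GGGGCGGGG" + "A" * 1000
        assert en.scan_motif(seq, rk.KLF_MOTIF, search_window=500) == []


class TestRecenter:
    def test_central_hit_keeps_midpoint(self):
        e = rk.Enhancer("e1", "chr1", 1000, 2000, 1)
        out = en.recenter_on_motif([e], {"e1": [(0, "+")]})
        assert out == [("e1", "chr1", 1500, "+")]

    def test_offset_shifts_anchor(self):
        e = rk.Enhancer("e1", "chr1", 1000, 2000, 1)
        out = en.recenter_on_motif([e], {"e1": [(120, "+")]})
        assert out[0][2] == 1620

    def test_no_hit_dropped_and_nearest_wins(self):
        e1 = rk.Enhancer("e1", "chr1", 1000, 2000, 1)
        e2 = rk.Enhancer("e2", "chr1", 5000, 6000, 2)
        out = en.recenter_on_motif(
            [e1, e2], {"e2": [(200, "+"), (-30, "-"), (90, "+")]})
        assert [o[0] for o in out] == ["e2"]
        assert out[0][2] == 5500 - 30  # nearest to midpoint

    def test_tie_goes_upstream(self):
        e = rk.Enhancer("e1", "chr1", 0, 1000, 1)
        out = en.recenter_on_motif([e], {"e1": [(50, "+"), (-50, "+")]})
        assert out[0][2] == 450


class TestUnidirectionality:
    def test_limits_and_arithmetic(self):
        assert en.unidirectionality_index(5.0, 0.0, pseudocount=1e-12) \
            == pytest.approx(1.0)
        assert en.unidirectionality_index(4.0, 4.0) == 0.0
        assert en.unidirectionality_index(3.0, 1.0, pseudocount=0.0) == 0.5

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounded_and_symmetric(self, f, r):
        u = en.unidirectionality_index(f, r)
        assert 0.0 <= u <= 1.0
        assert u == en.unidirectionality_index(r, f)


def exact_hypergeom_sf(N, K, n, k):
    """Upper tail by exact rational arithmetic (independent of scipy)."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


class TestHypergeom:
    def test_closed_form(self):
        res = en.hypergeom_enrichment(10, 5, 5, 5)
        assert res.p == pytest.approx(1 / 252, rel=1e-12)

    def test_fold_of_expected_overlap_is_one(self):
        res = en.hypergeom_enrichment(100, 20, 10, 2)  # k = n*K/N
        assert res.fold == pytest.approx(1.0)

    def test_degenerate_draws(self):
        res = en.hypergeom_enrichment(10, 0, 5, 0)
        assert np.isnan(res.fold) and res.p == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            en.hypergeom_enrichment(10, 5, 5, 6)

    def test_exact_oracle_small_grid(self):
        for N in (5, 8, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        res = en.hypergeom_enrichment(N, K, n, k)
                        assert abs(res.p - float(exact_hypergeom_sf(N, K, n, k))) \
                            < 1e-12

    def test_oracle_matches_full_draw_enumeration(self):
        # enumerate every C(N, n) draw at tiny N: the rational-arithmetic
        # oracle itself is validated against first principles
        N, K, n = 9, 4, 5
        pop = [1] * K + [0] * (N - K)
        for k in range(min(K, n) + 1):
            hits = sum(1 for draw in combinations(pop, n) if sum(draw) >= k)
            assert exact_hypergeom_sf(N, K, n, k) == Fraction(hits, comb(N, n))

    def test_p_monotone_in_overlap(self):
        ps = [en.hypergeom_enrichment(50, 20, 15, k).p for k in range(16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestClusterMechanics:
    def _matrices(self, rng, n=30, cols=40):
        vals = rng.random((n, cols))
        ids = [f"e{i}" for i in range(n)]
        m = lambda v: SignalMatrix(ids, v, 50, 1000, 1000, ["+"] * n)
        return m(vals), m(rng.random((n, cols)))

    def test_k1_single_label(self):
        fwd, rev = self._matrices(np.random.default_rng(0))
        grp = en.cluster_enhancers(fwd, rev, k=1, seed=0)
        assert set(grp.labels) == {1}

    def test_row_permutation_preserves_label_multiset(self):
        # three well-separated planted groups: the recovered partition must
        # not depend on row order
        rng = np.random.default_rng(1)
        n_per, cols = 10, 40
        blocks = [rng.random((n_per, cols)) + 20 * i for i in range(3)]
        vals = np.vstack(blocks)
        ids = [f"e{i}" for i in range(3 * n_per)]
        m = lambda v, idx: SignalMatrix([ids[i] for i in idx], v[idx], 50,
                                        1000, 1000, ["+"] * len(idx))
        ident = np.arange(3 * n_per)
        perm = rng.permutation(3 * n_per)
        grp = en.cluster_enhancers(m(vals, ident), m(vals, ident), k=3, seed=0)
        grp_p = en.cluster_enhancers(m(vals, perm), m(vals, perm), k=3, seed=0)
        assert sorted(grp.labels) == sorted(grp_p.labels)
        # same enhancers grouped together regardless of order
        part = lambda g: frozenset(frozenset(g.members(i + 1)) for i in range(3))
        assert part(grp) == part(grp_p)

    def test_too_few_rows_rejected(self):
        fwd, rev = self._matrices(np.random.default_rng(2), n=3)
        with pytest.raises(ParameterError):
            en.cluster_enhancers(fwd, rev, k=4)


class TestEnrichmentDirection:
    def test_coplanted_enriched_disjoint_depleted(self):
        """High-ssDNA and high-R-loop sets that share members show fold > 1;
        deliberately disjoint sets show fold < 1."""
        rng = np.random.default_rng(5)
        N = 400
        rloop_high = set(range(100))
        kas_coplanted = set(rng.choice(100, size=60, replace=False)) | \
            set(rng.integers(100, N, size=40))
        res = en.hypergeom_enrichment(N, len(rloop_high), len(kas_coplanted),
                                      len(rloop_high & kas_coplanted))
        assert res.fold > 1 and res.p < 1e-6
        kas_disjoint = set(range(100, 200))
        res2 = en.hypergeom_enrichment(N, len(rloop_high), len(kas_disjoint),
                                       len(rloop_high & kas_disjoint))
        assert res2.fold < 1
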