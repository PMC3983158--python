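"""Nei-Gojobori estimator checked against exhaustive genetic-code
enumeration and an independent library implementation."""

import math
from itertools import permutations, product

import numpy as np
import pytest

from famevo.kaks import (
    SENSE_CODONS,
    STOP_CODONS,
    analyze_pair,
    classify_selection,
    codon_align,
    count_differences,
    count_sites,
    divergence_time,
    jukes_cantor,
    nei_gojobori,
    translate_codon,
)
from famevo.simulate import simulate_codon_pair

# -- independent oracle: genetic code rebuilt from scratch ------------------

_ORACLE_CODE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES, _BASES, _BASES)):
    _ORACLE_CODE[_b1 + _b2 + _b3] = _AA[_i]


def oracle_sites(codon):
    s = n = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _ORACLE_CODE[mut] == "*":
                continue
            if _ORACLE_CODE[mut] == _ORACLE_CODE[codon]:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_differences(ca, cb):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in permutations(positions):
        cur, sd, nd = ca, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _ORACLE_CODE[nxt] == "*":
                ok = False
                break
            if _ORACLE_CODE[nxt] == _ORACLE_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not positions:
        return (0.0, 0.0)
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestSiteCounting:
    def test_phe_ttt(self):
        assert count_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_gly_ggg(self):
        assert count_sites("GGG") == pytest.approx((1.0, 2.0))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert count_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_site_conservation(self):
        # s + n = 3 exactly when no neighbor is a stop codon
        for codon in SENSE_CODONS:
            s, n = count_sites(codon)
            stop_neighbors = sum(
                1
                for pos in range(3)
                for base in "ACGT"
                if base != codon[pos]
                and codon[:pos] + base + codon[pos + 1 :] in STOP_CODONS
            )
            assert s + n == pytest.approx(3.0 - stop_neighbors / 3.0)


class TestDifferenceCounting:
    def test_single_synonymous(self):
        assert count_differences("TTT", "TTC") == pytest.approx((1.0, 0.0))

    def test_two_step_pathway_average(self):
        assert count_differences("TTT", "GTC") == pytest.approx((1.0, 1.0))

    def test_identical(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            ca, cb = rng.choice(SENSE_CODONS, size=2)
            got = count_differences(str(ca), str(cb))
            expected = oracle_differences(str(ca), str(cb))
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)

    def test_sum_equals_hamming_when_pathway_exists(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ca, cb = (str(c) for c in rng.choice(SENSE_CODONS, size=2))
            diffs = count_differences(ca, cb)
            if diffs is not None:
                hamming = sum(x != y for x, y in zip(ca, cb))
                assert diffs[0] + diffs[1] == pytest.approx(hamming)


class TestNeiGojobori:
    def test_worked_example(self):
        aln = codon_align(("FGG", "FGG"), "TTTGGGGGG", "TTCGGGGGG")
        r = nei_gojobori(aln)
        assert r.S == pytest.approx(7 / 3)
        assert r.sd == pytest.approx(1.0)
        assert r.pS == pytest.approx(3 / 7)
        assert r.Ks == pytest.approx(-0.75 * math.log(1 - 4 / 7), abs=1e-9)
        assert r.Ks == pytest.approx(0.6355, abs=1e-4)
        assert r.Ka == 0.0
        assert r.ratio == 0.0

    def test_identical_sequences_flagged(self):
        cds = "ATGGCTAAA"
        aln = codon_align(("MAK", "MAK"), cds, cds)
        r = nei_gojobori(aln)
        assert r.Ka == 0.0 and r.Ks == 0.0
        assert r.ratio is None
        assert "ratio_undefined_Ks_zero" in r.flags
        assert r.selection_class == "undetermined"

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b, _ = simulate_codon_pair(60, 0.5, 0.3, seed=5)
        prot = lambda c: "".join(
            translate_codon(c[i : i + 3]) for i in range(0, len(c), 3)
        )
        r1 = nei_gojobori(codon_align((prot(a), prot(b)), a, b))
        r2 = nei_gojobori(codon_align((prot(b), prot(a)), b, a))
        assert r1.Ks == pytest.approx(r2.Ks)
        assert r1.Ka == pytest.approx(r2.Ka)

    def test_site_total_bounded_by_three_per_codon(self):
        a, b, _ = simulate_codon_pair(100, 0.3, 0.2, seed=9)
        prot = lambda c: "".join(
            translate_codon(c[i : i + 3]) for i in range(0, len(c), 3)
        )
        r = nei_gojobori(codon_align((prot(a), prot(b)), a, b))
        assert r.S + r.N <= 3 * 100 + 1e-6

    def test_matches_independent_library_estimator(self):
        # Bio.codonalign implements NG86 independently; compare on
        # simulated pairs (moderate divergence, no saturation).
        from Bio.Align import MultipleSeqAlignment
        from Bio.codonalign.codonalignment import CodonAlignment as BioCodonAln
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord as BioRecord

        for seed in (1, 2, 3):
            a, b, _ = simulate_codon_pair(200, 0.3, 0.25, seed=seed)
            prot = lambda c: "".join(
                translate_codon(c[i : i + 3]) for i in range(0, len(c), 3)
            )
            mine = nei_gojobori(codon_align((prot(a), prot(b)), a, b))
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.Ka == pytest.approx(dn, abs=5e-3)
            assert mine.Ks == pytest.approx(ds, abs=5e-3)


class TestCodonAlign:
    def test_identical_cds(self):
        aln = codon_align(("MK", "MK"), "ATGAAA", "ATGAAA")
        assert aln.n_codons == 2

    def test_gap_column_removed(self):
        aln = codon_align(("MAK", "M-K"), "ATGGCTAAA", "ATGAAA")
        assert aln.n_codons == 2
        assert aln.columns[0] == ("ATG", "ATG")

    def test_ambiguous_codon_dropped_and_logged(self):
        aln = codon_align(("MXK", "MAK"), "ATGNNNAAA", "ATGGCTAAA")
        assert aln.n_codons == 2
        assert aln.dropped_columns == 1

    def test_translation_mismatch_rejected(self):
        with pytest.raises(ValueError, match="codon 1"):
            codon_align(("MK", "MK"), "ATGGCT", "ATGAAA")


class TestSelectionAndDating:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.25, "purifying"), (1.0, "neutral"), (2.3, "positive"),
         (None, "undetermined")],
    )
    def test_classification(self, ratio, expected):
        assert classify_selection(ratio) == expected

    def test_jc_closed_form(self):
        assert jukes_cantor(0.10) == pytest.approx(0.10733, abs=1e-5)
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.80) is None

    def test_divergence_times(self):
        assert divergence_time(0.152, 6.1e-9) == pytest.approx(12.459, abs=1e-3)
        assert divergence_time(0.289, 9.1e-9) == pytest.approx(15.879, abs=1e-3)
        assert divergence_time(0.0, 6.5e-9) == 0.0
        with pytest.raises(ValueError):
            divergence_time(0.1, 0.0)

    def test_small_divergence_limit(self):
        # Ks -> pS as pS -> 0
        for p in (0.001, 0.005, 0.01):
            assert jukes_cantor(p) == pytest.approx(p, rel=0.01)


def test_analyze_pair_dates_only_known_species():
    a, b, _ = simulate_codon_pair(120, 0.2, 0.2, seed=2)
    dated = analyze_pair(a, b, species_code="Gm")
    undated = analyze_pair(a, b, species_code="Gr")
    assert dated.T_mya == pytest.approx(
        divergence_time(dated.Ks, 6.1e-9)
    )
    assert undated.T_mya is None
    assert undated.Ks == pytest.approx(dated.Ks)
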