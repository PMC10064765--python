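"""Alignment, K2P and NG86 against independent oracles.

The brute-force oracles here are deliberately naive: exhaustive alignment
enumeration, direct neighbor enumeration for site counts, and explicit
pathway listing for codon differences.
"""

import itertools
import math

import numpy as np
import pytest
from Bio import Align

from mitocompare.seqevol import (
    Alignment,
    SaturationError,
    codon_align,
    global_align,
    jukes_cantor,
    k2p_distance,
    k2p_from_fractions,
    ng86_differences,
    ng86_kaks,
    ng86_sites,
    translate4,
)

GAP_OPEN, GAP_EXTEND = -5, -1
BASES = "ACGT"
STOPS = {"TAA", "TAG"}
NONSTOP = [a + b + c for a in BASES for b in BASES for c in BASES
           if a + b + c not in STOPS]


# ---------------------------------------------------------------------------
# Brute-force alignment score oracle


def _oracle_best_score(a, b, match=1, mismatch=-1):
    """Enumerate every global alignment recursively, scoring gap runs as
    open + (k-1)*extend, and return the best score."""
    best = [-(10 ** 9)]

    def go(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            go(i + 1, j + 1, score + s, "M")
        if j < len(b):  # gap in a
            s = GAP_EXTEND if prev == "X" else GAP_OPEN
            go(i, j + 1, score + s, "X")
        if i < len(a):  # gap in b
            s = GAP_EXTEND if prev == "Y" else GAP_OPEN
            go(i + 1, j, score + s, "Y")

    go(0, 0, 0, "start")
    return best[0]


class TestGlobalAlign:
    def test_identical_no_gaps(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 4
        assert "-" not in aln.seq_a + aln.seq_b

    def test_one_gap_column(self):
        aln = global_align("ACGT", "AGT")
        assert (aln.seq_a + aln.seq_b).count("-") == 1

    def test_matches_bruteforce_on_random_short_pairs(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            la, lb = rng.integers(1, 8, size=2)
            a = "".join(rng.choice(list(BASES), size=la))
            b = "".join(rng.choice(list(BASES), size=lb))
            aln = global_align(a, b)
            assert aln.score == _oracle_best_score(a, b), (a, b)

    def test_score_symmetry(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            a = "".join(rng.choice(list(BASES), size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(list(BASES), size=int(rng.integers(5, 40))))
            assert global_align(a, b).score == global_align(b, a).score

    def test_alignment_reconstructs_inputs(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            a = "".join(rng.choice(list(BASES), size=int(rng.integers(5, 60))))
            b = "".join(rng.choice(list(BASES), size=int(rng.integers(5, 60))))
            aln = global_align(a, b)
            assert aln.seq_a.replace("-", "") == a
            assert aln.seq_b.replace("-", "") == b
            assert not any(x == y == "-" for x, y in aln.columns())

    def test_score_matches_biopython_aligner(self):
        # independent C implementation with the same gap-cost convention
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = GAP_OPEN
        aligner.extend_gap_score = GAP_EXTEND
        rng = np.random.default_rng(37)
        for _ in range(30):
            a = "".join(rng.choice(list(BASES), size=int(rng.integers(10, 80))))
            b = "".join(rng.choice(list(BASES), size=int(rng.integers(10, 80))))
            assert global_align(a, b).score == aligner.score(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


class TestK2P:
    def test_identical_zero(self):
        aln = Alignment("ACGT" * 25, "ACGT" * 25, 0)
        assert k2p_distance(aln) == 0

    def test_closed_form_fixture(self):
        # 100 columns, 10 transitions (A<->G), 5 transversions (A<->C)
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        d = k2p_distance(Alignment(a, b, 0))
        expected = -0.5 * math.log(1 - 2 * 0.10 - 0.05) \
            - 0.25 * math.log(1 - 2 * 0.05)
        assert d == pytest.approx(expected, abs=1e-9)
        assert d == pytest.approx(0.17018, abs=1e-5)

    def test_row_swap_invariance(self):
        a, b = "ACGTACGTAC", "ACGTACTTAC"
        assert k2p_distance(Alignment(a, b, 0)) \
            == k2p_distance(Alignment(b, a, 0))

    def test_gapped_columns_excluded(self):
        aln = Alignment("AC-GT" + "A" * 95, "ACCGT" + "A" * 95, 0)
        assert k2p_distance(aln) == 0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(Alignment("A" * 10, "G" * 10, 0))

    def test_jc_limit_at_equal_rates(self):
        # equal per-site transition/transversion rates -> K2P ~ JC69
        rng = np.random.default_rng(41)
        n = 10_000
        a = rng.choice(list(BASES), size=n)
        b = a.copy()
        hit = rng.random(n) < 0.15
        b[hit] = [rng.choice([x for x in BASES if x != y])
                  for y in b[hit]]
        aln = Alignment("".join(a), "".join(b), 0)
        p = float(np.mean(a != b))
        jc = jukes_cantor(p)
        assert k2p_distance(aln) == pytest.approx(jc, rel=0.05)


# ---------------------------------------------------------------------------
# NG86 oracles


def _oracle_sites(codon):
    aa = translate4(codon)
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in STOPS and translate4(mut) == aa:
                syn += 1 / 3
    return syn, 3 - syn


def _oracle_differences(ca, cb):
    """Explicit pathway listing for pairs differing at <= 3 positions."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diffs):
        cur, steps, through_stop = ca, [], False
        for k, pos in enumerate(order):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if k < len(order) - 1 and nxt in STOPS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [p for p in paths if not p[0]] or paths

    def classify(cur, nxt):
        if cur in STOPS or nxt in STOPS:
            return "N"
        return "S" if translate4(cur) == translate4(nxt) else "N"

    sd = np.mean([[classify(c, n) for c, n in steps].count("S")
                  for _, steps in usable])
    nd = np.mean([[classify(c, n) for c, n in steps].count("N")
                  for _, steps in usable])
    return float(sd), float(nd)


class TestNG86Sites:
    def test_phe_ttt(self):
        assert ng86_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_met_atg_no_synonymous_sites(self):
        s, n = ng86_sites("ATG")
        assert s == 0 and n == 3

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")

    def test_all_codons_match_enumeration_oracle(self):
        for codon in NONSTOP:
            s, n = ng86_sites(codon)
            so, no = _oracle_sites(codon)
            assert s == pytest.approx(so) and n == pytest.approx(no), codon
            assert s + n == pytest.approx(3.0)


class TestNG86Differences:
    def test_all_pairs_up_to_two_differences(self):
        for ca in NONSTOP:
            for cb in NONSTOP:
                ndiff = sum(x != y for x, y in zip(ca, cb))
                if not 1 <= ndiff <= 2:
                    continue
                got = ng86_differences(ca, cb)
                exp = _oracle_differences(ca, cb)
                assert got == pytest.approx(exp), (ca, cb)

    def test_three_difference_sample_against_oracle(self):
        rng = np.random.default_rng(43)
        pairs = 0
        while pairs < 50:
            ca, cb = rng.choice(NONSTOP, size=2)
            if sum(x != y for x, y in zip(ca, cb)) != 3:
                continue
            assert ng86_differences(ca, cb) == pytest.approx(
                _oracle_differences(ca, cb)), (ca, cb)
            pairs += 1

    def test_difference_counts_conserve_hamming(self):
        for ca, cb in [("TTT", "GTA"), ("AAA", "CCC"), ("ATG", "ATA")]:
            sd, nd = ng86_differences(ca, cb)
            assert sd + nd == pytest.approx(
                sum(x != y for x, y in zip(ca, cb)))


class TestKaKs:
    def test_identical_cds(self):
        cds = "ATG" + "AAA" * 50 + "TAA"
        st = ng86_kaks(cds, cds)
        assert st.ka == 0 and st.ks == 0 and st.ka_ks is None

    def test_single_synonymous_change(self):
        a = "ATG" + "TTT" * 99 + "TAA"
        b = "ATG" + "TTC" + "TTT" * 98 + "TAA"  # TTT->TTC synonymous (Phe)
        st = ng86_kaks(a, b)
        assert st.ka == 0
        assert st.ks > 0

    def test_single_nonsynonymous_change(self):
        a = "ATG" + "TTT" * 99 + "TAA"
        b = "ATG" + "GTT" + "TTT" * 98 + "TAA"  # Phe->Val
        st = ng86_kaks(a, b)
        assert st.ks == 0
        assert st.ka > 0
        assert st.ka_ks is None  # undefined at Ks == 0

    def test_two_hit_codon_uses_pathway_average(self):
        a = "ATG" + "TTT" + "AAA" * 60 + "TAA"
        b = "ATG" + "GTA" + "AAA" * 60 + "TAA"
        st = ng86_kaks(a, b)
        sd, nd = _oracle_differences("TTT", "GTA")
        S = (ng86_sites("TTT")[0] + ng86_sites("GTA")[0]) / 2 \
            + 61 * (ng86_sites("AAA")[0] + ng86_sites("ATG")[0] * 0)
        # reconstruct expected Ks from first principles over the whole CDS
        codons_a = ["ATG", "TTT"] + ["AAA"] * 60
        codons_b = ["ATG", "GTA"] + ["AAA"] * 60
        S = sum((ng86_sites(x)[0] + ng86_sites(y)[0]) / 2
                for x, y in zip(codons_a, codons_b))
        N = 3 * len(codons_a) - S
        exp_ks = jukes_cantor(sd / S)
        exp_ka = jukes_cantor(nd / N)
        assert st.ks == pytest.approx(exp_ks)
        assert st.ka == pytest.approx(exp_ka)

    def test_internal_stop_excluded_with_warning(self):
        a = "ATG" + "TAA" + "TTT" * 50 + "TAA"  # internal stop codon
        b = "ATG" + "TAA" + "TTT" * 50 + "TAA"
        with pytest.warns(UserWarning, match="internal stop"):
            st = ng86_kaks(a, b, aligned=True)
        assert st.sites_used == 3 * 51  # stop pair dropped, trailing stop kept

    def test_codon_align_threads_nucleotides(self):
        a = "ATG" + "AAA" * 10 + "TAA"
        b = "ATG" + "AAA" * 9 + "TAA"  # one codon deleted
        aln = codon_align(a, b)
        assert len(aln.seq_a) == len(aln.seq_b)
        assert aln.seq_b.count("-") == 3
        assert aln.seq_a.replace("-", "") == "ATG" + "AAA" * 10


class TestK2PFractionHelper:
    def test_matches_distance_on_alignment(self):
        a = "A" * 200
        b = "G" * 20 + "T" * 10 + "A" * 170
        aln = Alignment(a, b, 0)
        assert k2p_distance(aln) == pytest.approx(
            k2p_from_fractions(0.10, 0.05))
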