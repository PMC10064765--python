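"""Pairwise alignment, K2P distance, and Nei–Gojobori (1986) Ka/Ks.

All coding-sequence arithmetic uses the mold/protozoan mitochondrial
genetic code (translation table 4, TGA = Trp).  Ka/Ks follows the classic
NG86 recipe: per-codon synonymous/nonsynonymous site counting, equal-weight
pathway averaging for multi-hit codons, and a Jukes–Cantor correction of
the proportions.

The global aligner is an affine-gap Needleman–Wunsch/Gotoh with a fixed,
documented tie-break (diagonal > gap-in-a > gap-in-b) so alignments are
bit-reproducible.  A gap run of length k costs ``gap_open + (k-1) *
gap_extend``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

NEG_INF = -(10 ** 9)

_TABLE4 = CodonTable.unambiguous_dna_by_id[4]
STOP_CODONS_4 = frozenset(_TABLE4.stop_codons)  # {'TAA', 'TAG'}


def translate4(codon: str) -> str:
    """Amino acid for a codon under table 4; '*' for a stop codon."""
    if codon in STOP_CODONS_4:
        return "*"
    return _TABLE4.forward_table[codon]


class SaturationError(ArithmeticError):
    """Distance correction undefined (log argument non-positive)."""


@dataclass
class Alignment:
    """A pairwise global alignment: equal-length gapped strings + score."""

    seq_a: str
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned strings differ in length")

    def columns(self):
        return zip(self.seq_a, self.seq_b)


# ---------------------------------------------------------------------------
# Global alignment (Gotoh, vectorized over columns)


def global_align(a: str, b: str, match: int = 1, mismatch: int = -1,
                 gap_open: int = -5, gap_extend: int = -1) -> Alignment:
    """Optimal global alignment of two strings under affine-gap scoring.

    Works on any alphabet (used for both DNA and protein sequences).
    Deterministic: ties resolve diagonal > gap-in-a > gap-in-b during
    traceback.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    bb = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)

    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # gap in a, consumes b
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # gap in b, consumes a
    M[0, 0] = 0
    js = np.arange(1, m + 1)
    X[0, 1:] = gap_open + (js - 1) * gap_extend
    for i in range(1, n + 1):
        Y[i, 0] = gap_open + (i - 1) * gap_extend

    idx = np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1].encode("latin-1")[0]
        s = np.where(bb == ai, match, mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = s + prev_best[:-1]
        Y[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], X[i - 1, 1:]) + gap_open,
            Y[i - 1, 1:] + gap_extend,
        )
        # X[i,j] = max over k<j of max(M,Y)[i,k] + open + (j-1-k)*extend
        base = np.maximum(M[i], Y[i]) - idx * gap_extend
        run = np.maximum.accumulate(base)
        X[i, 1:] = run[:-1] + gap_open + (js - 1) * gap_extend

    # traceback, preference M > X > Y
    i, j = n, m
    best = max(M[n, m], X[n, m], Y[n, m])
    state = "M"
    for st, mat in (("M", M), ("X", X), ("Y", Y)):
        if mat[n, m] == best:
            state = st
            break
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - (match if a[i - 1] == b[j - 1] else mismatch)
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i, j] == target:
                    state = st
                    break
        elif state == "X":
            out_a.append("-")
            out_b.append(b[j - 1])
            val = X[i, j]
            j -= 1
            if M[i, j] + gap_open == val:
                state = "M"
            elif Y[i, j] + gap_open == val:
                state = "Y"
            else:
                state = "X"
        else:  # Y
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Y[i, j]
            i -= 1
            if M[i, j] + gap_open == val:
                state = "M"
            elif X[i, j] + gap_open == val:
                state = "X"
            else:
                state = "Y"
        if i == 0 and j == 0:
            break
        if i == 0 and state != "X":
            state = "X"
        if j == 0 and state != "Y":
            state = "Y"
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     int(best))


def codon_align(cds_a: str, cds_b: str) -> Alignment:
    """Codon-aware alignment: align translated proteins, thread nucleotides.

    Trailing stop codons are removed before alignment.  Trailing partial
    codons are truncated with a warning.
    """
    a = _trim_cds(cds_a)
    b = _trim_cds(cds_b)
    prot_a = "".join(translate4(a[i:i + 3]) for i in range(0, len(a), 3))
    prot_b = "".join(translate4(b[i:i + 3]) for i in range(0, len(b), 3))
    paln = global_align(prot_a, prot_b, match=1, mismatch=-1,
                        gap_open=-5, gap_extend=-1)
    ga, gb = [], []
    ia = ib = 0
    for ca, cb in paln.columns():
        if ca == "-":
            ga.append("---")
        else:
            ga.append(a[3 * ia:3 * ia + 3])
            ia += 1
        if cb == "-":
            gb.append("---")
        else:
            gb.append(b[3 * ib:3 * ib + 3])
            ib += 1
    return Alignment("".join(ga), "".join(gb), paln.score)


def _trim_cds(cds: str) -> str:
    cds = cds.upper()
    if len(cds) % 3:
        warnings.warn(f"CDS length {len(cds)} not divisible by 3; "
                      "trailing partial codon dropped", stacklevel=3)
        cds = cds[: len(cds) - len(cds) % 3]
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS_4:
        cds = cds[:-3]
    return cds


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_distance(aln: Alignment) -> float:
    """K2P distance with pairwise deletion of gapped/ambiguous columns.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P/Q the transition and
    transversion fractions over usable columns.
    """
    p, q, sites = transition_transversion_counts(aln)
    if sites == 0:
        raise ValueError("no ungapped, unambiguous columns in alignment")
    P, Q = p / sites, q / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined at P={P:.4f}, Q={Q:.4f} (saturated)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def transition_transversion_counts(aln: Alignment) -> tuple[int, int, int]:
    """(transitions, transversions, usable sites) under pairwise deletion."""
    p = q = sites = 0
    for ca, cb in aln.columns():
        if ca not in "ACGT" or cb not in "ACGT":
            continue
        sites += 1
        if ca == cb:
            continue
        if (ca, cb) in _TRANSITIONS:
            p += 1
        else:
            q += 1
    return p, q, sites


def k2p_from_fractions(P: float, Q: float) -> float:
    """Closed-form K2P from transition/transversion fractions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined at P={P}, Q={Q}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986

_BASES = "ACGT"


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a codon under table 4.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous; changes to stop codons count as
    nonsynonymous.  S + N == 3 for every non-stop codon.
    """
    codon = codon.upper()
    if codon in STOP_CODONS_4:
        raise ValueError(f"{codon} is a stop codon under table 4")
    aa = translate4(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant not in STOP_CODONS_4 and translate4(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) observed differences between two codons.

    Multi-hit codon pairs average over all mutational pathways with equal
    weight; pathways passing through a stop codon are excluded unless every
    pathway does.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> Optional[tuple[float, float]]:
        sd = nd = 0.0
        cur = codon_a
        for k, pos in enumerate(order):
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            intermediate = k < len(order) - 1
            if intermediate and nxt in STOP_CODONS_4:
                return None
            if nxt in STOP_CODONS_4 or cur in STOP_CODONS_4:
                nd += 1.0  # step to/from a stop: nonsynonymous by convention
            elif translate4(cur) == translate4(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:  # all pathways pass through stops: include them all
        valid = [_walk_through(codon_a, codon_b, order)
                 for order in itertools.permutations(diff_pos)]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


def _walk_through(codon_a: str, codon_b: str, order: Sequence[int]):
    sd = nd = 0.0
    cur = codon_a
    for pos in order:
        nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
        if cur in STOP_CODONS_4 or nxt in STOP_CODONS_4:
            nd += 1.0
        elif translate4(cur) == translate4(nxt):
            sd += 1.0
        else:
            nd += 1.0
        cur = nxt
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 correction d = -3/4 ln(1 - 4/3 p)."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4, JC correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairwiseGeneStats:
    """Per-gene evolutionary rates for one species pair."""

    gene: str
    k2p: Optional[float]
    ka: Optional[float]
    ks: Optional[float]
    ka_ks: Optional[float]
    sites_used: int


def ng86_kaks(cds_a: str, cds_b: str, gene: str = "",
              aligned: bool = False) -> PairwiseGeneStats:
    """NG86 Ka/Ks for a CDS pair under translation table 4.

    Unless ``aligned`` is true, the pair is first codon-aligned (protein
    alignment, nucleotides threaded back).  Codon columns containing gaps
    or ambiguity are excluded; internal stop codons are excluded with a
    warning.  ``ka_ks`` is None when Ks == 0.
    """
    if aligned:
        if len(cds_a) != len(cds_b):
            raise ValueError("aligned CDS pair must have equal lengths")
        ga, gb = cds_a.upper(), cds_b.upper()
    else:
        aln = codon_align(cds_a, cds_b)
        ga, gb = aln.seq_a, aln.seq_b

    S = N = Sd = Nd = 0.0
    codons_used = 0
    for i in range(0, len(ga) - len(ga) % 3, 3):
        ca, cb = ga[i:i + 3], gb[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca in STOP_CODONS_4 or cb in STOP_CODONS_4:
            if i + 3 < len(ga):  # a trailing stop pair is silently skipped
                warnings.warn(f"internal stop codon at alignment position "
                              f"{i}; codon pair excluded", stacklevel=2)
            continue
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = ng86_differences(ca, cb)
        Sd += sd
        Nd += nd
        codons_used += 1

    if codons_used == 0:
        return PairwiseGeneStats(gene, None, None, None, None, 0)
    ks = jukes_cantor(Sd / S) if S > 0 else None
    ka = jukes_cantor(Nd / N) if N > 0 else None
    ka_ks = (ka / ks) if (ka is not None and ks is not None and ks > 0) else None
    k2p = None
    try:
        k2p = k2p_distance(Alignment(ga, gb, 0))
    except (ValueError, SaturationError):
        pass
    return PairwiseGeneStats(gene, k2p, ka, ks, ka_ks, codons_used * 3)


# ---------------------------------------------------------------------------
# Per-gene cross-species aggregation


def per_gene_matrix(records, gene: str) -> dict:
    """All-pairs K2P/Ka/Ks for one core gene across annotated records.

    Returns a dict with square labelled DataFrames ('k2p', 'ka', 'ks',
    'ka_ks') and a 'summary' dict holding the off-diagonal means plus a
    selection call (mean Ka/Ks > 1: positive; < 1: purifying).
    """
    from .mitio import spliced_cds

    taxa = [r.id for r in records]
    cds = {r.id: spliced_cds(r, gene) for r in records}
    mats = {key: pd.DataFrame(0.0, index=taxa, columns=taxa, dtype=float)
            for key in ("k2p", "ka", "ks", "ka_ks")}
    for key in mats:
        mats[key][:] = np.nan
        np.fill_diagonal(mats[key].values, 0.0)
    vals: dict[str, list[float]] = {k: [] for k in mats}
    for x, y in itertools.combinations(taxa, 2):
        st = ng86_kaks(cds[x], cds[y], gene=gene)
        for key, v in (("k2p", st.k2p), ("ka", st.ka), ("ks", st.ks),
                       ("ka_ks", st.ka_ks)):
            if v is not None:
                mats[key].loc[x, y] = mats[key].loc[y, x] = v
                vals[key].append(v)
    summary = {f"mean_{k}": (float(np.mean(v)) if v else None)
               for k, v in vals.items()}
    mk = summary["mean_ka_ks"]
    summary["selection"] = (None if mk is None
                            else "positive" if mk > 1 else "purifying")
    summary["gene"] = gene
    mats["summary"] = summary
    return mats


def per_gene_summary(records, genes) -> pd.DataFrame:
    """Tidy per-gene summary table over a list of core genes."""
    rows = [per_gene_matrix(records, g)["summary"] for g in genes]
    return pd.DataFrame(rows)[
        ["gene", "mean_k2p", "mean_ka", "mean_ks", "mean_ka_ks", "selection"]]
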