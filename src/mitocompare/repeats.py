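"""Intra-genomic repeat detection: interspersed (direct/inverted) repeats by
seeded self-comparison, and tandem repeats by period scanning.

The interspersed finder replaces an E-value-thresholded self-BLASTn with
explicit minimum-length / minimum-identity cutoffs (defaults admit every
hit of at least 40 bp at 85% identity, comfortably covering the 47-246 bp,
87-97% identity range typical of small fungal mitogenomes).  The tandem
finder reports arrays longer than 10 bp with at least two copies, at least
80% consensus agreement, and a Tandem-Repeats-Finder-style alignment score
of at least ``min_score`` (default 50, TRF's default threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mitio import MitogenomeRecord, revcomp


@dataclass
class RepeatHit:
    """A pair of similar intervals within one genome."""

    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    orientation: str  # {direct, inverted}
    length: int
    identity: float  # percent

    def __post_init__(self) -> None:
        if self.interval_a == self.interval_b:
            raise ValueError("self-identical hit (trivial diagonal)")


@dataclass
class TandemHit:
    """A tandem array: interval, repeat period, copy number, consensus."""

    interval: tuple[int, int]
    period: int
    copies: float
    consensus: str
    consensus_match: float  # fraction of positions agreeing with consensus


def _as_seq(record) -> str:
    if isinstance(record, MitogenomeRecord):
        return record.sequence
    return str(record).upper()


def _seed_diagonals(seq_a: str, seq_b: str, k: int, self_compare: bool,
                    max_kmer_hits: int = 100):
    """Map diagonal -> sorted seed starts (in seq_a) of shared k-mers.

    k-mers occurring more than ``max_kmer_hits`` times are dropped as
    low-complexity (they would explode the seed-pair count without adding
    resolvable repeats)."""
    index: dict[str, list[int]] = {}
    for j in range(len(seq_b) - k + 1):
        index.setdefault(seq_b[j:j + k], []).append(j)
    diags: dict[int, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        positions = index.get(seq_a[i:i + k], ())
        if len(positions) > max_kmer_hits:
            continue
        for j in positions:
            if self_compare and j <= i:
                continue  # self diagonal and mirror pairs
            diags.setdefault(j - i, []).append(i)
    return diags


def _extend(seq_a: str, seq_b: str, i0: int, i1: int, diag: int,
            x_drop: int = 8):
    """Greedy ungapped extension of seq_a[i0:i1] vs the diagonal-offset
    window of seq_b, X-drop controlled (match +1, mismatch -2)."""
    def run(start, step, limit):
        best = pos = start
        score = best_score = 0
        while 0 <= pos + step and pos + step < limit \
                and 0 <= pos + step + diag < len(seq_b):
            pos += step
            score += 1 if seq_a[pos] == seq_b[pos + diag] else -2
            if score > best_score:
                best_score, best = score, pos
            if score < best_score - x_drop:
                break
        return best

    left = run(i0, -1, len(seq_a))
    right = run(i1 - 1, +1, len(seq_a))
    return left, right + 1


def find_interspersed(record, min_len: int = 40, min_identity: float = 85.0,
                      k: int = 11) -> list[RepeatHit]:
    """Direct and inverted repeats within one genome by seeded self-comparison.

    Shared k-mers off the trivial self-diagonal are clustered per diagonal,
    extended without gaps under an X-drop rule, and reported when they are
    at least ``min_len`` long at ``min_identity`` percent identity.
    Overlapping hits are merged keeping the best identity.
    """
    seq = _as_seq(record)
    if len(seq) < k:
        return []
    hits: list[RepeatHit] = []
    for orientation, target in (("direct", seq), ("inverted", revcomp(seq))):
        self_compare = orientation == "direct"
        diags = _seed_diagonals(seq, target, k, self_compare)
        for diag, starts in diags.items():
            starts.sort()
            # cluster seeds separated by at most 2k on the same diagonal
            cluster = [starts[0]]
            clusters = []
            for s in starts[1:]:
                if s - cluster[-1] <= 2 * k:
                    cluster.append(s)
                else:
                    clusters.append(cluster)
                    cluster = [s]
            clusters.append(cluster)
            for cl in clusters:
                a0, a1 = _extend(seq, target, cl[0], cl[-1] + k, diag)
                length = a1 - a0
                if length < min_len:
                    continue
                frag_a = seq[a0:a1]
                frag_b = target[a0 + diag:a1 + diag]
                ident = 100.0 * sum(x == y for x, y in zip(frag_a, frag_b)) / length
                if ident < min_identity:
                    continue
                if orientation == "direct":
                    ia, ib = (a0, a1), (a0 + diag, a1 + diag)
                else:
                    n = len(seq)
                    ia, ib = sorted([(a0, a1), (n - (a1 + diag), n - (a0 + diag))])
                    if ia == ib:
                        continue  # a perfect palindrome on itself, trivial
                hits.append(RepeatHit(ia, ib, orientation, length, ident))
    return _dedup_hits(hits)


def _dedup_hits(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Merge hits whose interval pairs overlap, keeping the best identity."""
    hits = sorted(hits, key=lambda h: (-h.identity, -h.length,
                                       h.interval_a, h.interval_b))
    kept: list[RepeatHit] = []

    def overlaps(x, y):
        return x[0] < y[1] and y[0] < x[1]

    for h in hits:
        if any(overlaps(h.interval_a, k2.interval_a)
               and overlaps(h.interval_b, k2.interval_b)
               and h.orientation == k2.orientation for k2 in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.interval_a, h.interval_b))
    return kept


def find_tandem(record, min_total_len: int = 11, max_period: int = 500,
                min_score: int = 50, min_consensus: float = 0.8
                ) -> list[TandemHit]:
    """Tandem repeats by period scanning with consensus refinement.

    For each candidate period p, maximal runs where position i matches
    position i+p are located (short interruptions merged); a run of r
    matches spans an array of r+p bases with (r+p)/p copies.  An array is
    reported when its total length exceeds ``min_total_len - 1`` bases, it
    holds at least two copies, at least ``min_consensus`` of its positions
    agree with the column-majority consensus, and its score (+2 per
    consensus match, -7 per mismatch, the TRF weights) reaches
    ``min_score``.  Nested periodicities (p, 2p, ...) collapse onto the
    smallest period.
    """
    seq = _as_seq(record)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
    raw: list[TandemHit] = []
    for p in range(1, min(max_period, n // 2) + 1):
        eq = arr[:-p] == arr[p:]
        if not eq.any():
            continue
        for i0, i1 in _runs(eq, max_gap=3):
            r = i1 - i0
            total = r + p
            if total < max(min_total_len, 2 * p):
                continue
            hit = _refine_tandem(seq, i0, i0 + total, p,
                                 min_consensus, min_score)
            if hit is not None:
                raw.append(hit)
    return _dedup_tandem(raw)


def _runs(mask: np.ndarray, max_gap: int = 0):
    """Maximal (start, end) runs of True, merging gaps of <= max_gap."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e]) + 1


def _refine_tandem(seq: str, start: int, end: int, period: int,
                   min_consensus: float, min_score: int):
    frag = seq[start:end]
    copies = [frag[i:i + period] for i in range(0, len(frag), period)]
    consensus = "".join(
        max("ACGTN", key=lambda b: sum(c[i] == b for c in copies if i < len(c)))
        for i in range(period))
    matches = sum(ch == consensus[i % period] for i, ch in enumerate(frag))
    mismatches = len(frag) - matches
    frac = matches / len(frag)
    score = 2 * matches - 7 * mismatches
    if frac < min_consensus or score < min_score:
        return None
    return TandemHit(interval=(start, end), period=period,
                     copies=len(frag) / period, consensus=consensus,
                     consensus_match=frac)


def _dedup_tandem(hits: list[TandemHit]) -> list[TandemHit]:
    """Among overlapping arrays keep the smallest period (then longest)."""
    hits = sorted(hits, key=lambda h: (h.period, -(h.interval[1] - h.interval[0]),
                                       h.interval))
    kept: list[TandemHit] = []
    for h in hits:
        if any(h.interval[0] < k.interval[1] and k.interval[0] < h.interval[1]
               for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.interval)
    return kept


def repeat_fraction(hits, genome_length: int) -> float:
    """Percent of the genome covered by the union of all hit intervals."""
    intervals: list[tuple[int, int]] = []
    for h in hits:
        if isinstance(h, RepeatHit):
            intervals.extend([h.interval_a, h.interval_b])
        else:
            intervals.append(h.interval)
    for s, e in intervals:
        if not 0 <= s < e <= genome_length:
            raise ValueError(f"interval ({s}, {e}) outside genome bounds")
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return 100.0 * covered / genome_length


def repeats_table(hits: list[RepeatHit]):
    import pandas as pd

    return pd.DataFrame([{
        "start_a": h.interval_a[0], "end_a": h.interval_a[1],
        "start_b": h.interval_b[0], "end_b": h.interval_b[1],
        "orientation": h.orientation, "length": h.length,
        "identity": h.identity} for h in hits])


def tandems_table(hits: list[TandemHit]):
    import pandas as pd

    return pd.DataFrame([{
        "start": h.interval[0], "end": h.interval[1], "period": h.period,
        "copies": h.copies, "consensus": h.consensus,
        "consensus_match": h.consensus_match} for h in hits])
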