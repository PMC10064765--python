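"""Base composition, strand skews, region partitioning and contribution
rates, codon usage under translation table 4, start/stop codon tables,
intergenic/overlap bookkeeping, and tRNA variable-site counting.

Strand skews follow AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C);
N never enters a skew or GC denominator.  The contribution rate of a region
to a between-genome size difference is

    C_r = (region_bp(large) - region_bp(small)) / (size(large) - size(small)) * 100

which sums to exactly 100% over the four regions because every nucleotide
belongs to exactly one of protein-coding, intronic, intergenic, or RNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mitio import CORE_PCGS, MitogenomeRecord, spliced_cds
from .seqevol import STOP_CODONS_4, global_align, translate4


@dataclass
class CompositionStats:
    length: int
    countA: int
    countC: int
    countG: int
    countT: int
    countN: int
    gc_percent: float
    at_percent: float
    at_skew: Optional[float]  # None when A+T == 0
    gc_skew: Optional[float]  # None when G+C == 0


def base_composition(seq: str) -> CompositionStats:
    """Counts, GC/AT content and strand skews of a DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    a, c, g, t = (seq.count(b) for b in "ACGT")
    n = len(seq) - a - c - g - t
    acgt = a + c + g + t
    gc = 100.0 * (g + c) / acgt if acgt else float("nan")
    at = 100.0 * (a + t) / acgt if acgt else float("nan")
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionStats(len(seq), a, c, g, t, n, gc, at, at_skew, gc_skew)


def composition_table(records: list[MitogenomeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        st = base_composition(r.sequence)
        rows.append({"id": r.id, "length": st.length, "gc_percent": st.gc_percent,
                     "at_percent": st.at_percent, "at_skew": st.at_skew,
                     "gc_skew": st.gc_skew})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Region partition and contribution rates

REGIONS = ("coding", "intronic", "intergenic", "rna")


@dataclass
class RegionPartition:
    """Exhaustive, exclusive assignment of every nucleotide to one region."""

    size: int
    coding_bp: int
    intronic_bp: int
    intergenic_bp: int
    rna_bp: int

    def __post_init__(self) -> None:
        total = self.coding_bp + self.intronic_bp + self.intergenic_bp + self.rna_bp
        if total != self.size:
            raise ValueError(
                f"regions sum to {total}, expected genome size {self.size}")

    def region_bp(self, region: str) -> int:
        return getattr(self, f"{region.rstrip('_bp')}_bp")

    @property
    def proportions(self) -> dict[str, float]:
        return {r: 100.0 * self.region_bp(r) / self.size for r in REGIONS}


def region_partition(record: MitogenomeRecord,
                     include_orfs: bool = True) -> RegionPartition:
    """Per-nucleotide region labelling with precedence coding > rna > intron.

    Intron-encoded ORFs (homing endonucleases) count as intronic: an ORF
    whose every span lies inside an annotated intron is not painted as
    coding.  Free-standing ORFs count as coding unless ``include_orfs`` is
    false.
    """
    n = record.length
    # labels: 0 intergenic, 1 intron, 2 rna, 3 coding (ascending precedence)
    labels = np.zeros(n, dtype=np.int8)
    intron_mask = np.zeros(n, dtype=bool)
    for f in record.features:
        if f.category == "intron":
            for s, e in f.spans:
                intron_mask[s:e] = True
    labels[intron_mask] = 1
    for f in record.features:
        if f.category in ("rrna", "trna"):
            for s, e in f.spans:
                labels[s:e] = np.maximum(labels[s:e], 2)
    for f in record.features:
        if f.category == "core_pcg" or (f.category == "orf" and include_orfs):
            if f.category == "orf" and all(
                    intron_mask[s:e].all() for s, e in f.spans):
                continue  # intronic ORF stays intronic
            for s, e in f.spans:
                labels[s:e] = 3
    counts = np.bincount(labels, minlength=4)
    return RegionPartition(size=n, coding_bp=int(counts[3]),
                           intronic_bp=int(counts[1]),
                           intergenic_bp=int(counts[0]),
                           rna_bp=int(counts[2]))


@dataclass
class ContributionReport:
    """Per-region contribution rates to a between-genome size difference."""

    size_difference: int
    rates: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.rates.values())


def contribution_rates(part_small: RegionPartition,
                       part_large: RegionPartition) -> ContributionReport:
    """Contribution of each region to the size difference of two genomes.

    Rates are signed and may exceed 100%; they always sum to exactly 100%.
    The caller may pass the partitions in either order — the smaller genome
    is identified internally.  Equal genome sizes are an error.
    """
    if part_small.size == part_large.size:
        raise ValueError("contribution rates undefined for equal genome sizes")
    if part_small.size > part_large.size:
        part_small, part_large = part_large, part_small
    delta = part_large.size - part_small.size
    rates = {
        r: 100.0 * (part_large.region_bp(r) - part_small.region_bp(r)) / delta
        for r in REGIONS
    }
    return ContributionReport(size_difference=delta, rates=rates)


def partition_table(records: list[MitogenomeRecord], **kw) -> pd.DataFrame:
    rows = []
    for r in records:
        p = region_partition(r, **kw)
        row = {"id": r.id, "size": p.size}
        row.update({f"{reg}_bp": p.region_bp(reg) for reg in REGIONS})
        row.update({f"{reg}_pct": v for reg, v in p.proportions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Codon usage

_ALL_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]


@dataclass
class CodonUsageTable:
    """64-codon counts with per-1000 frequencies and RSCU under table 4."""

    counts: dict[str, int]
    ambiguous: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies_per_1000(self) -> dict[str, float]:
        tot = self.total
        return {c: (1000.0 * n / tot if tot else 0.0)
                for c, n in self.counts.items()}

    @property
    def rscu(self) -> dict[str, float]:
        by_aa: dict[str, list[str]] = {}
        for c in _ALL_CODONS:
            by_aa.setdefault(translate4(c), []).append(c)
        out: dict[str, float] = {}
        for aa, codons in by_aa.items():
            mean = sum(self.counts[c] for c in codons) / len(codons)
            for c in codons:
                out[c] = self.counts[c] / mean if mean else float("nan")
        return out

    def top_codons(self, k: int = 6) -> list[str]:
        return sorted(self.counts, key=lambda c: (-self.counts[c], c))[:k]

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies_per_1000
        rscu = self.rscu
        rows = [{"codon": c, "amino_acid": translate4(c),
                 "count": self.counts[c], "per_1000": freqs[c],
                 "rscu": rscu[c]} for c in _ALL_CODONS]
        return pd.DataFrame(rows)


def codon_usage(cds_list: list[str]) -> CodonUsageTable:
    """Frame-0 codon counts over a list of CDSs (table 4, TGA = Trp).

    Trailing partial codons are dropped with a warning; codons containing
    non-ACGT characters are tallied as ambiguous and excluded from
    frequencies.
    """
    counts = {c: 0 for c in _ALL_CODONS}
    ambiguous = 0
    for cds in cds_list:
        cds = cds.upper()
        if len(cds) < 3:
            raise ValueError("CDS shorter than one codon")
        if len(cds) % 3:
            warnings.warn(f"CDS length {len(cds)} not divisible by 3; "
                          "trailing partial codon dropped", stacklevel=2)
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                ambiguous += 1
    return CodonUsageTable(counts=counts, ambiguous=ambiguous)


def start_stop_table(records: list[MitogenomeRecord],
                     genes: tuple[str, ...] = CORE_PCGS) -> pd.DataFrame:
    """First and last codon of each spliced core-PCG, reported verbatim.

    For a CDS whose length is not a codon multiple the stop is taken from
    the final full codon (with a warning from the splicing layer).
    """
    rows = []
    for r in records:
        row: dict[str, object] = {"id": r.id}
        for g in genes:
            try:
                cds = spliced_cds(r, g)
            except KeyError:
                row[f"{g}_start"] = row[f"{g}_stop"] = None
                continue
            usable = len(cds) - len(cds) % 3
            row[f"{g}_start"] = cds[:3]
            row[f"{g}_stop"] = cds[usable - 3:usable] if usable >= 3 else None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Intergenic gaps / overlaps


def intergenic_and_overlaps(record: MitogenomeRecord
                            ) -> list[tuple[str, str, int]]:
    """Circular successor gaps between consecutive gene envelopes.

    Introns are not independent genes; all other features participate via
    their envelope (5'-most start to 3'-most end).  Negative gaps are
    overlaps.  On a circular record the last-to-first gap is modular.
    """
    feats = [f for f in record.features if f.category != "intron"]
    if len(feats) < 2:
        raise ValueError("need at least two non-intron features")
    feats.sort(key=lambda f: (f.start, f.end, f.name))
    out: list[tuple[str, str, int]] = []
    for cur, nxt in zip(feats, feats[1:]):
        out.append((cur.name, nxt.name, nxt.start - cur.end))
    if record.topology == "circular":
        last, first = feats[-1], feats[0]
        out.append((last.name, first.name,
                    first.start + record.length - last.end))
    return out


# ---------------------------------------------------------------------------
# tRNA variable sites


def trna_variable_sites(trna_a: str, trna_b: str) -> tuple[int, float]:
    """Variable sites between two homologous tRNA sequences.

    The pair is globally aligned; any column with differing residues or a
    gap counts as variable.  Returns (count, percent of alignment length).
    """
    aln = global_align(trna_a.upper(), trna_b.upper())
    variable = sum(1 for ca, cb in aln.columns() if ca != cb)
    return variable, 100.0 * variable / len(aln.seq_a)
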