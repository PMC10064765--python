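"""Intron position-class (Pcl) analysis for cox1 (or any host gene).

Group I introns insert between two specific nucleotides of their host
gene's coding sequence.  Introns from different species inserted at the
same position of a shared reference CDS form one position class (Pcl) and
are treated as orthologous.  Insertion offsets are projected onto the
reference through a codon-aware pairwise alignment at nucleotide
resolution, because introns need not sit at codon boundaries.

Pcls found in at least one fifth of the surveyed species are "common",
the rest "rare"; a strict more-than-one-fifth rule is selectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .seqevol import codon_align


@dataclass
class IntronRecord:
    """One intron: its species, host gene, and insertion offset.

    ``insertion_offset`` is the number of spliced-CDS nucleotides 5' of the
    intron in its own species (the intron sits after that many coding
    nucleotides); it must be strictly internal to the CDS.
    """

    species: str
    host_gene: str
    insertion_offset: int
    intron_length: int = 0
    group: str = "unknown"  # {I, II, unknown}
    orf_product: str = "none"  # {LAGLIDADG, GIY-YIG, other, none}

    def __post_init__(self) -> None:
        if self.insertion_offset <= 0:
            raise ValueError("insertion offset must be strictly internal")


@dataclass
class Pcl:
    """An intron position class on the reference CDS (named P<position>)."""

    reference_position: int  # 1-based nucleotide count in the reference CDS
    members: list[IntronRecord] = field(default_factory=list)
    status: str = "unclassified"  # {common, rare, unclassified}

    @property
    def name(self) -> str:
        return f"P{self.reference_position}"

    @property
    def species(self) -> list[str]:
        return sorted({m.species for m in self.members})


def bundled_reference_cox1() -> str:
    """The synthetic cox1 reference CDS shipped for tests and demos.

    This is a generated stand-in with the length and composition of a
    basidiomycete cox1; real analyses must pass the true reference CDS
    (e.g. from *Ganoderma calidophilum*) explicitly.
    """
    text = (resources.files("mitocompare") / "data"
            / "reference_cox1.fasta").read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


def map_offset_to_reference(species_cds: str, ref_cds: str, offset: int,
                            min_identity: float = 30.0) -> Optional[int]:
    """Project an insertion point from a species CDS onto the reference.

    The insertion point between species nucleotides ``offset`` and
    ``offset + 1`` maps to the count of reference nucleotides at or before
    that point in a codon-aware global alignment; a point falling inside a
    reference gap projects to the nearest reference nucleotide on the 5'
    side.  Returns None (with a warning) when alignment identity is below
    ``min_identity`` percent.
    """
    if not 0 < offset < len(species_cds):
        raise ValueError(
            f"offset {offset} not internal to a CDS of length {len(species_cds)}")
    if species_cds == ref_cds:
        return offset
    aln = codon_align(species_cds, ref_cds)
    ungapped = [(a, b) for a, b in aln.columns() if a != "-" and b != "-"]
    if ungapped:
        identity = 100.0 * sum(a == b for a, b in ungapped) / len(ungapped)
    else:
        identity = 0.0
    if identity < min_identity:
        warnings.warn(
            f"alignment identity {identity:.1f}% below {min_identity}%; "
            "insertion point left unmapped", stacklevel=2)
        return None
    consumed = ref_count = 0
    for ca, cb in aln.columns():
        if consumed >= offset:
            break
        if ca != "-":
            consumed += 1
        if cb != "-":
            ref_count += 1
    return ref_count


def classify_pcls(introns: list[IntronRecord], ref_cds: str,
                  species_cds_map: dict[str, str],
                  merge_window: int = 0) -> list[Pcl]:
    """Group introns into Pcls by projected reference position.

    Exact projected-position equality defines a class by default;
    ``merge_window`` > 0 merges classes whose positions differ by at most
    that many nucleotides (for noisy annotations).  Output is ordered by
    position.
    """
    projected: dict[int, list[IntronRecord]] = {}
    for intron in introns:
        cds = species_cds_map[intron.species]
        pos = map_offset_to_reference(cds, ref_cds, intron.insertion_offset)
        if pos is None:
            continue
        projected.setdefault(pos, []).append(intron)

    positions = sorted(projected)
    if merge_window > 0:
        merged: dict[int, list[IntronRecord]] = {}
        anchor = None
        for pos in positions:
            if anchor is None or pos - anchor > merge_window:
                anchor = pos
                merged[anchor] = []
            merged[anchor].extend(projected[pos])
        projected, positions = merged, sorted(merged)

    return [Pcl(reference_position=p, members=projected[p]) for p in positions]


def call_common_rare(pcls: list[Pcl], n_species: int,
                     rule: str = "at_least_fifth") -> list[Pcl]:
    """Annotate each Pcl as common or rare by species occupancy.

    ``at_least_fifth`` (default): common when present in >= ceil(n/5)
    distinct species.  ``strict``: common only when present in strictly
    more than n/5 species.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    for pcl in pcls:
        k = len(pcl.species)
        if rule == "at_least_fifth":
            common = k >= math.ceil(n_species / 5)
        elif rule == "strict":
            common = k * 5 > n_species
        else:
            raise ValueError(f"unknown rule {rule!r}")
        pcl.status = "common" if common else "rare"
    return pcls


def presence_matrix(pcls: list[Pcl], species: list[str]) -> pd.DataFrame:
    """Species x Pcl binary matrix with per-species intron counts.

    Row sums equal each species' intron count over the classified Pcls;
    column sums equal Pcl member counts.
    """
    mat = pd.DataFrame(0, index=list(species),
                       columns=[p.name for p in pcls], dtype=int)
    for p in pcls:
        for m in p.members:
            mat.loc[m.species, p.name] += 1
    mat["intron_count"] = mat.sum(axis=1)
    return mat


def introns_from_records(records, host_gene: str = "cox1") -> list[IntronRecord]:
    """Extract intron records (with spliced-CDS offsets) from annotations.

    The insertion offset is the number of exonic nucleotides 5' of the
    intron in transcription orientation.
    """
    out: list[IntronRecord] = []
    for rec in records:
        host = None
        for f in rec.features:
            if f.name == host_gene and f.category != "intron":
                host = f
                break
        if host is None:
            continue
        exons = host.spans if host.wraps_origin else sorted(host.spans)
        for f in rec.features:
            if f.category != "intron" or f.parent != host_gene:
                continue
            istart = f.start
            if host.strand == "+":
                offset = sum(min(e, istart) - s for s, e in exons
                             if s < istart)
            else:
                iend = f.end
                offset = sum(e - max(s, iend) for s, e in exons if e > iend)
            out.append(IntronRecord(species=rec.id, host_gene=host_gene,
                                    insertion_offset=offset,
                                    intron_length=f.length))
    return out


def pcl_summary(pcls: list[Pcl]) -> dict:
    return {
        "n_pcls": len(pcls),
        "n_common": sum(p.status == "common" for p in pcls),
        "n_rare": sum(p.status == "rare" for p in pcls),
        "n_introns": sum(len(p.members) for p in pcls),
    }
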