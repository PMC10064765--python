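"""Circular gene-order extraction and rearrangement comparison.

Arrangement analysis is restricted to the 17-gene set (15 core PCGs plus
rnl and rns).  Orders are canonicalized by rotating the circle so the
anchor gene (cox1 by default) comes first on the plus strand; comparison
uses signed circular adjacencies, with the breakpoint distance counting
adjacencies of one order absent from the other.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .mitio import ARRANGEMENT_GENES, MitogenomeRecord

SignedGene = tuple[str, str]  # (gene name, '+'/'-')


@dataclass
class GeneOrder:
    """Canonical circular order of the 17-gene arrangement set."""

    species: str
    order: list[SignedGene]
    anchor: str = "cox1"

    def __post_init__(self) -> None:
        names = [g for g, _ in self.order]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genes in order")
        self.order = canonicalize(self.order, self.anchor)

    @property
    def n(self) -> int:
        return len(self.order)

    def adjacency_set(self) -> frozenset:
        return frozenset(_adjacencies(self.order))

    def as_string(self) -> str:
        return ",".join(f"{'-' if s == '-' else ''}{g}" for g, s in self.order)


def _flip(sg: SignedGene) -> SignedGene:
    g, s = sg
    return g, "-" if s == "+" else "+"


def canonicalize(order: list[SignedGene], anchor: str) -> list[SignedGene]:
    """Rotate so the anchor is first; if the anchor is on '-', read the
    circle in the other direction (reverse and flip strands) so the anchor
    is '+'.  Idempotent."""
    names = [g for g, _ in order]
    if anchor not in names:
        raise ValueError(f"anchor gene {anchor!r} not in order")
    i = names.index(anchor)
    rotated = order[i:] + order[:i]
    if rotated[0][1] == "-":
        rotated = [rotated[0]] + [_flip(sg) for sg in reversed(rotated[1:])]
        rotated[0] = _flip(rotated[0])
    return rotated


def _adjacencies(order: list[SignedGene]):
    """Signed circular adjacencies, each normalized so that (x, y) and the
    reverse-reading (-y, -x) are the same adjacency."""
    n = len(order)
    for i in range(n):
        x, y = order[i], order[(i + 1) % n]
        alt = (_flip(y), _flip(x))
        yield min((x, y), alt)


def gene_order(record: MitogenomeRecord,
               gene_set: tuple[str, ...] = ARRANGEMENT_GENES,
               anchor: str = "cox1") -> GeneOrder:
    """Extract the canonical circular order of ``gene_set`` from a record.

    Genes are taken by their 5'-most start around the circle; each must be
    annotated exactly once (introns do not count as separate genes).
    """
    found: dict[str, list] = {g: [] for g in gene_set}
    for f in record.features:
        if f.name in found and f.category != "intron":
            found[f.name].append(f)
    missing = sorted(g for g, fs in found.items() if not fs)
    duplicated = sorted(g for g, fs in found.items() if len(fs) > 1)
    if missing or duplicated:
        parts = []
        if missing:
            parts.append(f"missing: {', '.join(missing)}")
        if duplicated:
            parts.append(f"duplicated: {', '.join(duplicated)}")
        raise ValueError(f"cannot build gene order for {record.id} "
                         f"({'; '.join(parts)})")
    feats = sorted((fs[0] for fs in found.values()),
                   key=lambda f: (f.start, f.name))
    order = [(f.name, f.strand) for f in feats]
    return GeneOrder(species=record.id, order=order, anchor=anchor)


@dataclass
class SyntenyReport:
    """Pairwise comparison of two canonical circular gene orders."""

    identical: bool
    breakpoint_distance: int
    conserved_adjacencies: int
    changed_genes: list[str] = field(default_factory=list)


def compare_orders(a: GeneOrder, b: GeneOrder) -> SyntenyReport:
    """Signed circular adjacency comparison of two 17-gene orders.

    ``breakpoint_distance`` counts adjacencies of ``a`` absent from ``b``
    (a symmetric quantity, since both orders carry the same number of
    adjacencies); ``changed_genes`` lists genes with any differing signed
    neighbor.
    """
    genes_a = {g for g, _ in a.order}
    genes_b = {g for g, _ in b.order}
    if genes_a != genes_b:
        raise ValueError("orders cover different gene sets")
    adj_a = a.adjacency_set()
    adj_b = b.adjacency_set()
    conserved = len(adj_a & adj_b)
    distance = len(adj_a) - conserved
    changed = sorted(
        g for g in genes_a
        if {ad for ad in adj_a if g in (ad[0][0], ad[1][0])}
        != {ad for ad in adj_b if g in (ad[0][0], ad[1][0])}
    )
    return SyntenyReport(identical=(distance == 0),
                         breakpoint_distance=distance,
                         conserved_adjacencies=conserved,
                         changed_genes=changed)


def arrangement_matrix(orders: list[GeneOrder]
                       ) -> tuple[pd.DataFrame, list[list[str]]]:
    """Pairwise breakpoint-distance matrix plus identical-arrangement groups."""
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    taxa = [o.species for o in orders]
    mat = pd.DataFrame(0, index=taxa, columns=taxa, dtype=int)
    for oa, ob in itertools.combinations(orders, 2):
        d = compare_orders(oa, ob).breakpoint_distance
        mat.loc[oa.species, ob.species] = d
        mat.loc[ob.species, oa.species] = d
    clusters: dict[tuple, list[str]] = {}
    for o in orders:
        clusters.setdefault(tuple(o.order), []).append(o.species)
    groups = sorted(clusters.values(), key=lambda g: (-len(g), g))
    return mat, groups


def orders_table(orders: list[GeneOrder]) -> pd.DataFrame:
    return pd.DataFrame([{"species": o.species, "order": o.as_string()}
                         for o in orders])
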