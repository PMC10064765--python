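"""Core-gene supermatrix construction, K2P distance matrices, and
neighbor-joining trees.

The supermatrix concatenates per-gene codon-aware multiple alignments
(center-star progressive alignment to the longest sequence) of the 15 core
protein-coding genes, intron-free by construction since it starts from
spliced CDSs.  The NJ implementation is the canonical Saitou-Nei
algorithm with deterministic tie-breaking by taxon label, a desk-scale
stand-in for full Bayesian/ML inference; NEXUS/PHYLIP and partition-file
writers let users run external inference on the same matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mitio import CORE_PCGS, spliced_cds
from .seqevol import Alignment, codon_align, k2p_distance, SaturationError


# ---------------------------------------------------------------------------
# Supermatrix


@dataclass
class Supermatrix:
    """Aligned, concatenated gene matrix with a partition table."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) half-open

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("rows differ in length")
        (n,) = lengths
        pos = 0
        for gene, s, e in self.partitions:
            if s != pos or e <= s:
                raise ValueError("partitions do not tile the column range")
            pos = e
        if pos != n:
            raise ValueError("partitions do not cover all columns")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


def _center_star_msa(seqs: dict[str, str]) -> dict[str, str]:
    """Codon-aware center-star MSA: align everything to the longest sequence.

    Gap columns introduced by successive pairwise alignments are merged by
    taking, between any two center residues, the maximum insert length seen.
    """
    center = max(seqs, key=lambda t: (len(seqs[t]), t))
    center_seq = seqs[center]
    others = [t for t in sorted(seqs) if t != center]
    if not others:
        return {center: center_seq}

    # per-taxon: list of insert segments before each center residue
    # (index 0..len(center)), plus the residue-aligned characters
    def decompose(gc: str, go: str):
        inserts: list[str] = [""]
        aligned: list[str] = []
        for cc, co in zip(gc, go):
            if cc == "-":
                inserts[-1] += co
            else:
                aligned.append(co)
                inserts.append("")
        return inserts, aligned

    parts: dict[str, tuple[list[str], list[str]]] = {}
    trimmed_center: Optional[str] = None
    for t in others:
        aln = codon_align(center_seq, seqs[t])
        cc_ungapped = aln.seq_a.replace("-", "")
        if trimmed_center is None:
            trimmed_center = cc_ungapped
        inserts, aligned = decompose(aln.seq_a, aln.seq_b)
        parts[t] = (inserts, aligned)
    assert trimmed_center is not None
    lc = len(trimmed_center)
    parts[center] = ([""] * (lc + 1), list(trimmed_center))

    widths = [max(len(parts[t][0][i]) for t in parts) for i in range(lc + 1)]
    out: dict[str, str] = {}
    for t, (inserts, aligned) in parts.items():
        pieces: list[str] = []
        for i in range(lc + 1):
            pieces.append(inserts[i].ljust(widths[i], "-"))
            if i < lc:
                pieces.append(aligned[i])
        out[t] = "".join(pieces)
    return out


def build_supermatrix(records, genes: tuple[str, ...] = CORE_PCGS
                      ) -> Supermatrix:
    """Intron-free concatenated supermatrix over the core genes.

    Taxa missing any requested gene are dropped with a warning naming the
    taxon and gene.
    """
    cds: dict[str, dict[str, str]] = {}
    kept = []
    for r in records:
        row = {}
        missing = None
        for g in genes:
            try:
                row[g] = spliced_cds(r, g)
            except KeyError:
                missing = g
                break
        if missing is not None:
            warnings.warn(f"taxon {r.id} dropped: gene {missing} missing",
                          stacklevel=2)
            continue
        cds[r.id] = row
        kept.append(r.id)
    if len(kept) < 2:
        raise ValueError("fewer than two taxa with a complete gene set")

    rows = {t: [] for t in kept}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for g in genes:
        msa = _center_star_msa({t: cds[t][g] for t in kept})
        width = len(next(iter(msa.values())))
        for t in kept:
            rows[t].append(msa[t])
        partitions.append((g, pos, pos + width))
        pos += width
    return Supermatrix(taxa=kept, rows={t: "".join(v) for t, v in rows.items()},
                       partitions=partitions)


def k2p_matrix(sm: Supermatrix) -> pd.DataFrame:
    """Pairwise K2P distances over the concatenated columns
    (pairwise deletion); saturated pairs are reported as NaN."""
    taxa = sm.taxa
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            try:
                d = k2p_distance(Alignment(sm.rows[a], sm.rows[b], 0))
            except SaturationError:
                d = float("nan")
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class Node:
    name: str = ""
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _min_leaf(self) -> str:
        return min(self.leaves())

    def newick(self, with_lengths: bool = True) -> str:
        if self.is_leaf:
            core = self.name
        else:
            kids = sorted(self.children, key=lambda c: c._min_leaf())
            core = "(" + ",".join(k.newick(with_lengths) for k in kids) + ")"
        if with_lengths:
            return f"{core}:{self.length:.6f}"
        return core


@dataclass
class PhyloTree:
    """An unrooted tree held at an internal node; branch lengths in
    substitutions/site, negative NJ estimates clamped to zero."""

    root: Node
    clamped: bool = False

    def leaves(self) -> list[str]:
        return sorted(self.root.leaves())

    def newick(self, with_lengths: bool = True) -> str:
        kids = sorted(self.root.children, key=lambda c: c._min_leaf())
        inner = ",".join(k.newick(with_lengths) for k in kids)
        return f"({inner});"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the frozenset of leaves on the
        child side of an internal edge."""
        all_leaves = frozenset(self.root.leaves())
        out: set[frozenset] = set()

        def visit(node: Node) -> None:
            for c in node.children:
                side = frozenset(c.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    other = all_leaves - side
                    out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
                visit(c)

        visit(self.root)
        return out


def nj_tree(distances: pd.DataFrame) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining with deterministic tie-breaks.

    ``distances`` must be a symmetric, zero-diagonal labelled matrix over at
    least 3 taxa.  Ties in the Q criterion resolve to the lexicographically
    smallest taxon-label pair; merged nodes inherit the smaller member
    label, so the result is invariant to input row order.
    """
    taxa = list(distances.index)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    vals = distances.values
    if not np.allclose(vals, vals.T) or not np.allclose(np.diag(vals), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    D: dict[frozenset, float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            D[frozenset((a, b))] = float(distances.loc[a, b])
    nodes: dict[str, Node] = {t: Node(name=t) for t in taxa}
    clamped = False

    def d(a: str, b: str) -> float:
        return D[frozenset((a, b))]

    while len(nodes) > 3:
        labels = sorted(nodes)
        r = len(labels)
        R = {a: sum(d(a, b) for b in labels if b != a) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                q = (r - 2) * d(a, b) - R[a] - R[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d(a, b)
        la = 0.5 * dab + (R[a] - R[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        new_label = min(a, b)
        for c in list(nodes):
            dac = D.pop(frozenset((a, c)))
            dbc = D.pop(frozenset((b, c)))
            D[frozenset((new_label, c))] = 0.5 * (dac + dbc - dab)
        D.pop(frozenset((a, b)))
        nodes[new_label] = Node(name="", children=[child_a, child_b])

    labels = sorted(nodes)
    if len(labels) == 3:
        a, b, c = labels
        la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
        lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        lens = [la, lb, lc]
        if any(x < 0 for x in lens):
            clamped = True
            lens = [max(x, 0.0) for x in lens]
        kids = []
        for lab, ln in zip(labels, lens):
            node = nodes[lab]
            node.length = ln
            kids.append(node)
        root = Node(children=kids)
    else:  # exactly 2 remain (can happen for 3-taxon input after no loop)
        a, b = labels
        na, nb = nodes[a], nodes[b]
        na.length = nb.length = 0.5 * d(a, b)
        root = Node(children=[na, nb])
    return PhyloTree(root=root, clamped=clamped)


def root_on(tree: PhyloTree, taxon: str) -> PhyloTree:
    """Convenience outgroup rooting: return a tree whose first child is the
    named leaf (topology unchanged; display aid only)."""
    kids = sorted(tree.root.children,
                  key=lambda c: (taxon not in c.leaves(), c._min_leaf()))
    return PhyloTree(root=Node(children=kids), clamped=tree.clamped)


# ---------------------------------------------------------------------------
# Writers


def write_phylip(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_columns}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def write_nexus(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.n_columns};\n")
        fh.write("FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")
        fh.write(";\nEND;\n\nBEGIN SETS;\n")
        for gene, s, e in sm.partitions:
            fh.write(f"CHARSET {gene} = {s + 1}-{e};\n")
        fh.write("END;\n")


def write_partitions(sm: Supermatrix, path) -> None:
    """RAxML-style partition file (1-based inclusive ranges)."""
    with open(path, "w") as fh:
        for gene, s, e in sm.partitions:
            fh.write(f"DNA, {gene} = {s + 1}-{e}\n")
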