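"""Synthetic annotated mitogenome clades with full ground truth.

The generator emulates the statistical structure of small fungal
mitochondrial genomes: a circular chromosome carrying the 15 core
protein-coding genes, two rRNAs and a bank of 23 tRNAs, AT-rich codon
usage, controllable gene order (per-branch inversions/transpositions),
codon-level divergence with per-gene target Ka/Ks, group-I-style introns
planted at chosen reference cox1 positions, and tandem/interspersed
repeats planted in intergenic DNA.  Every stochastic choice flows from a
single spec seed through named substreams, so outputs are
byte-deterministic.

The ancestral cox1 IS the bundled reference CDS, and coding sequences
evolve by substitutions only, so intron-plan offsets remain exact in every
descendant; Pcl projection is still exercised on genuinely diverged
(substituted) sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .introns import bundled_reference_cox1
from .mitio import CORE_PCGS, GeneFeature, MitogenomeRecord, revcomp
from .phylosupport import Node
from .seqevol import STOP_CODONS_4, translate4

_BASES = "TCAG"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_NONSTOP = [c for c in _ALL_CODONS if c not in STOP_CODONS_4]

#: spliced lengths (including stop codon) of the non-cox1 core genes
_GENE_LENGTHS = {
    "atp6": 762, "atp8": 153, "atp9": 225, "cob": 1155, "cox2": 753,
    "cox3": 813, "nad1": 963, "nad2": 1503, "nad3": 363, "nad4": 1473,
    "nad4L": 273, "nad5": 1998, "nad6": 603, "rps3": 1104,
}
_RRNA_LENGTHS = {"rnl": 2970, "rns": 1413}
_TRNA_NAMES = tuple(
    f"trn{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY") + ("trnM2", "trnL2", "trnS2")


_TOP_CODONS = ("ATT", "TTA", "TTT", "TAT", "AAA", "AAT")


def default_codon_weights() -> dict[str, float]:
    """AT-rich codon weights matching the compositional bias of
    basidiomycete yeast mitogenomes; the six workhorse codons
    ATT/TTA/TTT/TAT/AAA/AAT (Ile, Leu, Phe, Tyr, Lys, Asn) get an extra
    boost so they rank strictly first, as they do in real AT-rich
    mitogenomes."""
    weights = {c: 4.0 ** sum(ch in "AT" for ch in c) for c in _NONSTOP}
    for c in _TOP_CODONS:
        weights[c] *= 1.6
    return weights


@dataclass
class RepeatPlan:
    """One repeat to plant in a species' intergenic DNA."""

    species: str
    kind: str  # {tandem, direct, inverted}
    length: int = 120  # total array length (tandem) or copy length
    period: int = 5  # tandem only
    mismatches: int = 0  # planted differences between interspersed copies

    def __post_init__(self) -> None:
        if self.kind not in ("tandem", "direct", "inverted"):
            raise ValueError(f"unknown repeat kind {self.kind!r}")


@dataclass
class CladeSpec:
    """Declarative description of a synthetic clade.  ``seed`` is mandatory."""

    n_species: int
    seed: int
    tree: Optional[Node] = None  # random topology when None
    genome_size_target: int = 35000
    genome_size_targets: dict[str, int] = field(default_factory=dict)
    gc_target: float = 30.0  # percent
    branch_length: float = 0.05  # mean, for random trees
    gene_omega: dict[str, float] = field(default_factory=dict)
    gene_order_ops: dict[str, dict[str, int]] = field(default_factory=dict)
    intron_plan: dict[int, set[str]] = field(default_factory=dict)
    intron_length: int = 312
    repeat_plan: list[RepeatPlan] = field(default_factory=list)
    codon_weights: dict[str, float] = field(default_factory=default_codon_weights)

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if any(w < 0 for w in self.codon_weights.values()):
            raise ValueError("codon weights must be non-negative")
        ref_len = len(bundled_reference_cox1())
        for pos in self.intron_plan:
            if not 0 < pos < ref_len:
                raise ValueError(
                    f"intron position {pos} not internal to the {ref_len} nt "
                    "reference cox1")

    @classmethod
    def from_yaml(cls, path) -> "CladeSpec":
        """Load a spec from a declarative YAML file.

        Schema (all keys optional except ``n_species`` and ``seed``)::

            n_species: 5
            seed: 7
            genome_size_target: 35000
            genome_size_targets: {sp01: 34648}
            gc_target: 30.0
            branch_length: 0.05
            gene_omega: {cob: 1.3}
            gene_order_ops: {sp02: {inversions: 1}}
            intron_plan: {383: [sp01, sp02]}
            intron_length: 312
            repeat_plan:
              - {species: sp01, kind: direct, length: 246, mismatches: 9}

        The tree is always random under a YAML spec (pass a ``tree``
        programmatically for a fixed topology).
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["intron_plan"] = {int(k): set(v)
                              for k, v in (raw.get("intron_plan") or {}).items()}
        raw["repeat_plan"] = [RepeatPlan(**rp)
                              for rp in (raw.get("repeat_plan") or [])]
        return cls(**raw)

    def species_names(self) -> list[str]:
        if self.tree is not None:
            return sorted(self.tree.leaves())
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    def size_for(self, species: str) -> int:
        return self.genome_size_targets.get(species, self.genome_size_target)

    def omega_for(self, gene: str) -> float:
        return self.gene_omega.get(gene, 0.2)


@dataclass
class GroundTruth:
    """Everything the generator knows that analyses should recover."""

    tree: Node
    gene_omega: dict[str, float]
    pcl_plan: dict[int, set[str]]
    gene_orders: dict[str, list[tuple[str, str]]]
    repeats: dict[str, list[dict]]
    region_sizes: dict[str, dict[str, int]]


# ---------------------------------------------------------------------------
# Building blocks


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed % (2 ** 31), stream])


def random_cds(n_codons: int, weights: dict[str, float],
               rng: np.random.Generator) -> str:
    """ATG + weighted non-stop codons + TAA (n_codons total)."""
    codons = sorted(weights)
    p = np.array([weights[c] for c in codons], dtype=float)
    p /= p.sum()
    body = rng.choice(codons, size=n_codons - 2, p=p)
    return "ATG" + "".join(body) + "TAA"


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA at the given GC fraction (0..1)."""
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(rng.choice(["G", "C", "A", "T"], size=length, p=p))


def mutate_cds(cds: str, branch_length: float, omega: float,
               rng: np.random.Generator) -> str:
    """Evolve an in-frame, stop-free CDS along one branch.

    Single-nucleotide proposals arrive at rate ``branch_length`` per site
    (scaled up when omega > 1 so the nonsynonymous class is not starved);
    synonymous proposals are accepted with probability min(1, 1/omega),
    nonsynonymous ones with min(1, omega), so the realized Ka/Ks tracks
    ``omega``.  Start and stop codons are preserved and no internal stop is
    ever introduced.
    """
    if branch_length < 0:
        raise ValueError("negative branch length")
    if branch_length == 0 or len(cds) <= 6:
        return cds
    seq = list(cds)
    n = len(seq)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    n_prop = rng.poisson(branch_length * n * max(1.0, omega))
    for _ in range(n_prop):
        pos = int(rng.integers(3, n - 3))  # keep start/stop codons
        old = seq[pos]
        new = "ACGT"[int(rng.integers(4))]
        if new == old:
            continue
        c0 = pos - pos % 3
        codon_old = "".join(seq[c0:c0 + 3])
        codon_new = codon_old[:pos - c0] + new + codon_old[pos - c0 + 1:]
        if codon_new in STOP_CODONS_4:
            continue
        synonymous = translate4(codon_old) == translate4(codon_new)
        if rng.random() < (p_syn if synonymous else p_non):
            seq[pos] = new
    return "".join(seq)


def _mutate_neutral(seq: str, branch_length: float,
                    rng: np.random.Generator) -> str:
    """Per-site substitution of a non-coding sequence."""
    if branch_length <= 0:
        return seq
    p = min(branch_length, 0.7)
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if hit.any():
        arr[hit] = rng.choice(list("ACGT"), size=int(hit.sum()))
    return "".join(arr)


def random_tree(names: list[str], mean_branch: float,
                rng: np.random.Generator) -> Node:
    """Random binary topology by sequential joining; exponential branches."""
    nodes = [Node(name=n, length=float(rng.exponential(mean_branch)))
             for n in sorted(names)]
    if len(nodes) == 1:
        return Node(children=nodes)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(Node(length=float(rng.exponential(mean_branch)),
                          children=[a, b]))
    return Node(children=nodes, length=0.0)


def _apply_order_ops(order: list[tuple[str, str]], n_inv: int, n_transp: int,
                     rng: np.random.Generator) -> list[tuple[str, str]]:
    order = list(order)
    n = len(order)
    for _ in range(n_inv):
        start = int(rng.integers(n))
        length = int(rng.integers(2, max(3, n // 2)))
        idx = [(start + k) % n for k in range(length)]
        seg = [(g, "-" if s == "+" else "+")
               for g, s in reversed([order[i] for i in idx])]
        for i, sg in zip(idx, seg):
            order[i] = sg
    for _ in range(n_transp):
        start = int(rng.integers(n))
        length = int(rng.integers(1, 3))
        idx = sorted(((start + k) % n for k in range(length)), reverse=True)
        seg = [order[i] for i in sorted(idx)]
        for i in idx:
            order.pop(i)
        dest = int(rng.integers(len(order) + 1))
        order[dest:dest] = seg
    return order


# ---------------------------------------------------------------------------
# Clade simulation


def simulate_clade(spec: CladeSpec
                   ) -> tuple[list[MitogenomeRecord], GroundTruth]:
    """Generate an annotated clade plus its ground truth.

    Deterministic given ``spec.seed``.  Raises before generation when the
    spec is infeasible (unknown species in a plan, or planted repeats that
    exceed the intergenic budget — the latter checked during assembly,
    before any record is emitted).
    """
    names = spec.species_names()
    planned: set[str] = {rp.species for rp in spec.repeat_plan}
    for members in spec.intron_plan.values():
        planned |= set(members)
    unknown = planned - set(names)
    if unknown:
        raise ValueError(f"plan references unknown species: {sorted(unknown)}")

    rng_seq = _rng(spec.seed, 0)
    rng_tree = _rng(spec.seed, 1)
    rng_order = _rng(spec.seed, 2)
    rng_rep = _rng(spec.seed, 3)
    rng_intron = _rng(spec.seed, 4)

    tree = spec.tree or random_tree(names, spec.branch_length, rng_tree)

    # ancestral gene content
    genes: dict[str, str] = {"cox1": bundled_reference_cox1()}
    for g in sorted(_GENE_LENGTHS):
        genes[g] = random_cds(_GENE_LENGTHS[g] // 3, spec.codon_weights,
                              rng_seq)
    rnas = {g: random_dna(n, spec.gc_target / 100.0, rng_seq)
            for g, n in sorted(_RRNA_LENGTHS.items())}
    trnas = {name: random_dna(int(rng_seq.integers(71, 89)),
                              spec.gc_target / 100.0, rng_seq)
             for name in _TRNA_NAMES}
    head = ("cox1", "rnl", "nad5", "cob", "rns")
    ancestral_order: list[tuple[str, str]] = [(g, "+") for g in head] + [
        (g, "+") for g in sorted(CORE_PCGS) if g not in head]

    # one intron sequence per planned position (orthologous introns similar)
    intron_seqs = {pos: random_dna(spec.intron_length, 0.18, rng_intron)
                   for pos in sorted(spec.intron_plan)}

    # evolve states down the tree (pre-order, deterministic child order)
    states: dict[str, dict] = {}

    def descend(node: Node, state: dict) -> None:
        new_state = {
            "genes": {g: mutate_cds(s, node.length, spec.omega_for(g), rng_seq)
                      for g, s in sorted(state["genes"].items())},
            "rnas": {g: _mutate_neutral(s, node.length, rng_seq)
                     for g, s in sorted(state["rnas"].items())},
            "trnas": {g: _mutate_neutral(s, node.length, rng_seq)
                      for g, s in sorted(state["trnas"].items())},
        }
        ops = spec.gene_order_ops.get(node.name or "", {})
        new_state["order"] = _apply_order_ops(
            state["order"], ops.get("inversions", 0),
            ops.get("transpositions", 0), rng_order)
        if node.is_leaf:
            states[node.name] = new_state
        for child in node.children:
            descend(child, new_state)

    root_state = {"genes": genes, "rnas": rnas, "trnas": trnas,
                  "order": ancestral_order}
    if tree.is_leaf:
        descend(tree, root_state)
    else:
        for child in tree.children:
            descend(child, root_state)

    records: list[MitogenomeRecord] = []
    truth = GroundTruth(
        tree=tree,
        gene_omega={g: spec.omega_for(g) for g in CORE_PCGS},
        pcl_plan={p: set(s) for p, s in spec.intron_plan.items()},
        gene_orders={}, repeats={}, region_sizes={})
    for sp in names:
        rec, regions, planted = _assemble(sp, spec, states[sp], intron_seqs,
                                          rng_seq, rng_rep)
        records.append(rec)
        truth.gene_orders[sp] = list(states[sp]["order"])
        truth.region_sizes[sp] = regions
        truth.repeats[sp] = planted
    return records, truth


# ---------------------------------------------------------------------------
# Genome assembly


def _cassette(gene: str, state: dict, spec: CladeSpec,
              intron_positions: list[int], intron_seqs: dict[int, str]):
    """(sequence in gene orientation, parts) for one placed gene.

    parts: list of (category, name, length) in gene orientation; exon parts
    share the gene name, intron parts get a per-position name.
    """
    if gene in state["genes"]:
        cds = state["genes"][gene]
        if gene == "cox1" and intron_positions:
            parts, chunks, prev = [], [], 0
            for pos in intron_positions:
                parts.append(("exon", gene, pos - prev))
                chunks.append(cds[prev:pos])
                iseq = intron_seqs[pos]
                parts.append(("intron", f"{gene}-P{pos}", len(iseq)))
                chunks.append(iseq)
                prev = pos
            parts.append(("exon", gene, len(cds) - prev))
            chunks.append(cds[prev:])
            return "".join(chunks), "core_pcg", parts
        return cds, "core_pcg", [("exon", gene, len(cds))]
    if gene in state["rnas"]:
        seq = state["rnas"][gene]
        return seq, "rrna", [("rna", gene, len(seq))]
    seq = state["trnas"][gene]
    return seq, "trna", [("rna", gene, len(seq))]


def _assemble(species: str, spec: CladeSpec, state: dict,
              intron_seqs: dict[int, str], rng_seq: np.random.Generator,
              rng_rep: np.random.Generator):
    intron_positions = sorted(
        p for p, members in spec.intron_plan.items() if species in members)

    # placement list: the 17 rearrangeable genes in species order, with the
    # 23 tRNAs distributed round-robin after successive gene slots
    placements: list[tuple[str, str]] = []  # (gene name, strand)
    trna_iter = list(_TRNA_NAMES)
    order = state["order"]
    per_slot = -(-len(trna_iter) // len(order))  # ceil
    ti = 0
    for gene, strand in order:
        placements.append((gene, strand))
        for _ in range(per_slot):
            if ti < len(trna_iter):
                placements.append((trna_iter[ti], "+"))
                ti += 1

    cassettes = []
    feature_bp = 0
    for gene, strand in placements:
        seq, category, parts = _cassette(gene, state, spec, intron_positions,
                                         intron_seqs)
        cassettes.append((gene, strand, category, seq, parts))
        feature_bp += len(seq)

    size = spec.size_for(species)
    n_gaps = len(placements)
    intergenic_total = size - feature_bp
    if intergenic_total < 3 * n_gaps:
        raise ValueError(
            f"{species}: genome size target {size} leaves {intergenic_total} "
            f"bp for {n_gaps} intergenic gaps (need >= {3 * n_gaps})")

    # solve the intergenic GC level so the genome lands on gc_target
    gc_feat = sum(s.count("G") + s.count("C") for _, _, _, s, _ in cassettes)
    gc_needed = spec.gc_target / 100.0 * size - gc_feat
    gi = min(0.95, max(0.02, gc_needed / intergenic_total))

    extra = intergenic_total - 3 * n_gaps
    split = rng_seq.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))
    gap_lens = [3 + int(x) for x in split]
    gaps = [random_dna(n, gi, rng_seq) for n in gap_lens]

    planted = _plant_repeats(species, spec, gaps, gi, rng_rep)

    # final assembly: gap[i] precedes cassette i
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    regions = {"coding": 0, "intronic": 0, "rna": 0}
    planted_abs: list[dict] = []
    gap_offsets: dict[int, int] = {}
    for i, (gene, strand, category, cseq, parts) in enumerate(cassettes):
        gap_offsets[i] = pos
        seq_parts.append(gaps[i])
        pos += len(gaps[i])
        cstart, clen = pos, len(cseq)
        placed = cseq if strand == "+" else revcomp(cseq)
        seq_parts.append(placed)

        # forward-strand span for a gene-orientation interval (u, v)
        def fwd(u: int, v: int) -> tuple[int, int]:
            if strand == "+":
                return cstart + u, cstart + v
            return cstart + clen - v, cstart + clen - u

        exon_spans: list[tuple[int, int]] = []
        u = 0
        for kind, pname, plen in parts:
            span = fwd(u, u + plen)
            if kind == "exon":
                exon_spans.append(span)
                regions["coding"] += plen
            elif kind == "intron":
                features.append(GeneFeature(name=pname, category="intron",
                                            strand=strand, spans=[span],
                                            parent=gene))
                regions["intronic"] += plen
            else:
                regions["rna"] += plen
            u += plen
        if category == "core_pcg":
            features.append(GeneFeature(name=gene, category="core_pcg",
                                        strand=strand,
                                        spans=sorted(exon_spans)))
        else:
            features.append(GeneFeature(name=gene, category=category,
                                        strand=strand,
                                        spans=[(cstart, cstart + clen)]))
        pos += clen

    for info in planted:
        abs_info = dict(info)
        gidx = info["gap_index"]
        abs_info["start"] = gap_offsets[gidx] + info["offset"]
        abs_info["end"] = abs_info["start"] + info["length"]
        if "gap_index_b" in info:
            abs_info["start_b"] = gap_offsets[info["gap_index_b"]] \
                + info["offset_b"]
            abs_info["end_b"] = abs_info["start_b"] + info["length"]
        planted_abs.append(abs_info)

    sequence = "".join(seq_parts)
    assert len(sequence) == size
    region_sizes = {
        "size": size,
        "coding_bp": regions["coding"],
        "intronic_bp": regions["intronic"],
        "rna_bp": regions["rna"],
        "intergenic_bp": size - sum(regions.values()),
    }
    record = MitogenomeRecord(id=species, sequence=sequence,
                              topology="circular", features=features,
                              source=f"mitocompare.simulate(seed={spec.seed})")
    return record, region_sizes, planted_abs


def _plant_repeats(species: str, spec: CladeSpec, gaps: list[str], gi: float,
                   rng_rep: np.random.Generator) -> list[dict]:
    """Overwrite intergenic gap content with planned repeats.

    Mutates ``gaps`` in place; returns per-repeat info with gap-relative
    coordinates.  Each gap hosts at most one planted element; 3 bp margins
    are kept at both ends.
    """
    plans = [rp for rp in spec.repeat_plan if rp.species == species]
    if not plans:
        return []
    free = sorted(range(len(gaps)), key=lambda i: -len(gaps[i]))
    used: set[int] = set()

    def take(min_len: int) -> int:
        for i in free:
            if i not in used and len(gaps[i]) >= min_len + 6:
                used.add(i)
                return i
        raise ValueError(
            f"{species}: no intergenic gap can host a {min_len} bp repeat; "
            "increase the genome size target or shrink the repeat plan")

    out: list[dict] = []
    for rp in plans:
        if rp.kind == "tandem":
            gidx = take(rp.length)
            unit = random_dna(rp.period, 0.5, rng_rep)
            array = (unit * (rp.length // rp.period + 1))[:rp.length]
            gaps[gidx] = _splice_into(gaps[gidx], array, 3)
            out.append({"species": species, "kind": "tandem",
                        "gap_index": gidx, "offset": 3,
                        "length": rp.length, "period": rp.period,
                        "unit": unit})
        else:
            copy_a = random_dna(rp.length, 0.5, rng_rep)
            copy_b = list(copy_a)
            if rp.mismatches:
                sites = rng_rep.choice(rp.length, size=rp.mismatches,
                                       replace=False)
                for s in sites:
                    choices = [b for b in "ACGT" if b != copy_b[s]]
                    copy_b[int(s)] = choices[int(rng_rep.integers(3))]
            copy_b = "".join(copy_b)
            if rp.kind == "inverted":
                copy_b = revcomp(copy_b)
            ga = take(rp.length)
            gb = take(rp.length)
            gaps[ga] = _splice_into(gaps[ga], copy_a, 3)
            gaps[gb] = _splice_into(gaps[gb], copy_b, 3)
            out.append({"species": species, "kind": rp.kind,
                        "gap_index": ga, "offset": 3,
                        "gap_index_b": gb, "offset_b": 3,
                        "length": rp.length, "mismatches": rp.mismatches})
    return out


def _splice_into(gap: str, payload: str, offset: int) -> str:
    return gap[:offset] + payload + gap[offset + len(payload):]


# ---------------------------------------------------------------------------
# A ready-made clade mirroring the study design


def apiotrichum_like_spec(seed: int = 1, n_background: int = 17,
                          focal_sizes: tuple[int, int] = (34648, 38096)
                          ) -> CladeSpec:
    """A 19-genome clade shaped like the study's comparison set.

    Two closely related focal species plus ``n_background`` deeper taxa;
    genome sizes spread between ~25 kb and ~178 kb; a shared orthologous
    cox1 intron in the focal pair plus common and rare intron classes in
    the background; purifying selection on most genes with cob and rps3
    near the positive-selection boundary.
    """
    names = [f"bg{i + 1:02d}" for i in range(n_background)]
    focal_a, focal_b = "focalA", "focalB"

    # focal pair on short branches, ladderized background
    pair = Node(length=0.30, children=[Node(name=focal_a, length=0.02),
                                       Node(name=focal_b, length=0.02)])
    node = pair
    for nm in names:
        node = Node(length=0.06,
                    children=[node, Node(name=nm, length=0.25)])
    tree = Node(children=node.children)

    sizes = {focal_a: focal_sizes[0], focal_b: focal_sizes[1]}
    rng = np.random.default_rng(seed)
    spread = np.linspace(25000, 178000, n_background)
    for nm, s in zip(names, spread):
        sizes[nm] = int(s)

    all_species = set(names) | {focal_a, focal_b}
    nine = {focal_a, focal_b} | set(names[:7])
    intron_plan: dict[int, set[str]] = {
        383: set(nine),
        706: set(names[:9]),
        166: {names[9]},
        900: {names[10]},
        237: {names[3], names[11]},
    }
    del rng, all_species

    gene_order_ops = {nm: {"inversions": 1, "transpositions": 1}
                      for nm in names[:8]}
    repeat_plan = [
        RepeatPlan(species=focal_a, kind="direct", length=246, mismatches=9),
        RepeatPlan(species=focal_a, kind="tandem", length=116, period=29),
        RepeatPlan(species=focal_b, kind="inverted", length=80, mismatches=4),
    ]
    omega = {g: 0.2 for g in CORE_PCGS}
    omega["cob"] = 1.3
    omega["rps3"] = 1.3
    omega["nad4L"] = 0.05
    return CladeSpec(n_species=n_background + 2, seed=seed, tree=tree,
                     genome_size_targets=sizes, gc_target=30.0,
                     gene_omega=omega, gene_order_ops=gene_order_ops,
                     intron_plan=intron_plan, repeat_plan=repeat_plan)
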