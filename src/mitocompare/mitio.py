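"""Coordinate-safe data model and I/O for annotated circular mitogenomes.

Internal coordinates are 0-based half-open on the forward strand; GenBank
I/O converts from/to 1-based inclusive.  Features whose span crosses the
circular origin are stored as two spans plus a ``wraps_origin`` flag, and
all downstream length arithmetic is modular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

#: The 15 protein-coding genes conserved across fungal mitogenomes.
CORE_PCGS: tuple[str, ...] = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
)

#: The 17-gene set used for gene-arrangement analysis (core PCGs + rRNAs).
ARRANGEMENT_GENES: tuple[str, ...] = CORE_PCGS + ("rnl", "rns")

CATEGORIES = ("core_pcg", "orf", "rrna", "trna", "intron", "exon")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Fatal problem while reading a sequence or annotation file."""


@dataclass
class GeneFeature:
    """One annotated feature on the forward strand of a mitogenome.

    ``spans`` are 0-based half-open intervals listed in transcription order
    (ascending starts for ``+`` strand features that do not wrap the origin).
    """

    name: str
    category: str
    strand: str
    spans: list[tuple[int, int]]
    parent: Optional[str] = None
    product: str = ""
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.spans:
            raise ValueError(f"feature {self.name!r} has no spans")
        for s, e in self.spans:
            if not 0 <= s < e:
                raise ValueError(f"bad span ({s}, {e}) on {self.name!r}")
        if not self.wraps_origin:
            for (_, e0), (s1, _) in zip(self.spans, self.spans[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping spans on {self.name!r}")

    @property
    def start(self) -> int:
        """5'-most forward-strand coordinate (start of the first span)."""
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)


@dataclass
class MitogenomeRecord:
    """A circular (or linear) annotated mitochondrial genome."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[GeneFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"feature {f.name!r} span exceeds genome length {n}"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def get(self, name: str, category: Optional[str] = None) -> GeneFeature:
        for f in self.features:
            if f.name == name and (category is None or f.category == category):
                return f
        raise KeyError(f"no feature {name!r} in record {self.id!r}")

    def by_category(self, *categories: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category in categories]

    def extract(self, span: tuple[int, int]) -> str:
        return self.sequence[span[0]:span[1]]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "sequence": self.sequence,
            "topology": self.topology,
            "source": self.source,
            "features": [
                {
                    "name": f.name, "category": f.category, "strand": f.strand,
                    "spans": [list(s) for s in f.spans], "parent": f.parent,
                    "product": f.product, "wraps_origin": f.wraps_origin,
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MitogenomeRecord":
        feats = [
            GeneFeature(
                name=f["name"], category=f["category"], strand=f["strand"],
                spans=[tuple(s) for s in f["spans"]], parent=f.get("parent"),
                product=f.get("product", ""),
                wraps_origin=f.get("wraps_origin", False),
            )
            for f in d.get("features", [])
        ]
        return cls(id=d["id"], sequence=d["sequence"],
                   topology=d.get("topology", "circular"),
                   features=feats, source=d.get("source", ""))


@dataclass
class GeneSetSpec:
    """Canonical gene names plus an alias map used during annotation import."""

    names: list[str]
    synonyms: dict[str, str]

    def __post_init__(self) -> None:
        # case-insensitive alias lookup; the map must be a function
        lowered: dict[str, str] = {}
        for alias, canon in self.synonyms.items():
            key = alias.lower()
            if key in lowered and lowered[key] != canon:
                raise ValueError(f"alias {alias!r} maps to two canonical names")
            lowered[key] = canon
        self._lookup = lowered

    def canonical(self, name: str) -> str:
        return self._lookup.get(name.lower(), name)


def default_gene_set() -> GeneSetSpec:
    """Gene-name canonicalization table shipped with the package."""
    text = (resources.files("mitocompare") / "data" / "gene_synonyms.tsv").read_text()
    synonyms: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canon = line.split("\t")
        synonyms[alias] = canon
    return GeneSetSpec(names=list(ARRANGEMENT_GENES), synonyms=synonyms)


# ---------------------------------------------------------------------------
# GenBank I/O


def _feature_name(bio_feature, spec: GeneSetSpec) -> str:
    q = bio_feature.qualifiers
    for key in ("gene", "product", "locus_tag", "note"):
        if key in q and q[key]:
            return spec.canonical(str(q[key][0]).replace(" ", "_"))
    return "unnamed"


def _category_for(feature_type: str, name: str) -> Optional[str]:
    if feature_type == "CDS":
        return "core_pcg" if name in CORE_PCGS else "orf"
    if feature_type == "rRNA":
        return "rrna"
    if feature_type == "tRNA":
        return "trna"
    if feature_type == "intron":
        return "intron"
    return None


def _spans_from_location(loc, genome_length: int) -> tuple[list[tuple[int, int]], bool]:
    """Sorted spans plus an origin-wrap flag from a Biopython location."""
    parts = sorted(((int(p.start), int(p.end)) for p in loc.parts))
    wraps = (
        len(parts) >= 2
        and parts[0][0] == 0
        and parts[-1][1] == genome_length
    )
    if wraps:
        # store in transcription order across the origin: (x, L) then (0, y)
        parts = parts[-1:] + parts[:-1]
    return parts, wraps


def read_genbank(path: str | Path, gene_set: Optional[GeneSetSpec] = None) -> MitogenomeRecord:
    """Read an annotated mitogenome from a GenBank flat file.

    Feature names are canonicalized through ``gene_set``; CDS join
    coordinates become multi-span features, and gaps between consecutive
    CDS spans of the same gene are materialized as intron features (explicit
    intron annotations take precedence).  Unknown feature keys are skipped.
    """
    spec = gene_set or default_gene_set()
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise ParseError(f"no GenBank records in {path}") from None
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise ParseError(f"record {rec.id} has no sequence")
    topology = rec.annotations.get("topology", "linear")
    n = len(seq)

    features: list[GeneFeature] = []
    explicit_introns: list[GeneFeature] = []
    for bf in rec.features:
        name = _feature_name(bf, spec)
        category = _category_for(bf.type, name)
        if category is None:
            continue
        spans, wraps = _spans_from_location(bf.location, n)
        strand = "-" if bf.location.strand == -1 else "+"
        product = str(bf.qualifiers.get("product", [""])[0])
        parent = None
        if category == "intron":
            parent = spec.canonical(str(bf.qualifiers.get("gene", ["unknown"])[0]))
            note = bf.qualifiers.get("note", [None])[0]
            name = str(note) if note else f"{parent}-intron"
        feat = GeneFeature(name=name, category=category, strand=strand,
                           spans=spans, parent=parent, product=product,
                           wraps_origin=wraps)
        (explicit_introns if category == "intron" else features).append(feat)

    # synthesize introns implied by multi-span CDS, explicit ones win
    synthesized: list[GeneFeature] = []
    for f in features:
        if f.category not in ("core_pcg", "orf") or len(f.spans) < 2 or f.wraps_origin:
            continue
        ordered = sorted(f.spans)
        for (s0, e0), (s1, e1) in zip(ordered, ordered[1:]):
            if s1 <= e0:
                continue
            covered = any(
                i.start <= e0 and i.end >= s1 for i in explicit_introns
                if i.parent == f.name
            )
            if not covered:
                synthesized.append(GeneFeature(
                    name=f"{f.name}-intron{len(synthesized) + 1}",
                    category="intron", strand=f.strand,
                    spans=[(e0, s1)], parent=f.name))
    features.extend(explicit_introns)
    features.extend(synthesized)

    return MitogenomeRecord(id=rec.id or rec.name, sequence=seq,
                            topology=topology, features=features,
                            source=str(path))


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Serialize a record back to a GenBank flat file."""
    type_for = {"core_pcg": "CDS", "orf": "CDS", "rrna": "rRNA",
                "trna": "tRNA", "intron": "intron", "exon": "exon"}
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.spans]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [f.name]}
        if f.product:
            qualifiers["product"] = [f.product]
        if f.category == "intron" and f.parent:
            qualifiers["gene"] = [f.parent]
            qualifiers["note"] = [f.name]
        rec.features.append(SeqFeature(loc, type=type_for[f.category],
                                       qualifiers=qualifiers))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA I/O


def write_fasta(record: MitogenomeRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        seq = record.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def read_fasta(path: str | Path) -> MitogenomeRecord:
    """Read a sequence-only record; non-ACGTN characters are rejected with
    their 1-based position reported."""
    header = None
    chunks: list[str] = []
    pos = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    break  # first record only
                header = line[1:].split()[0] if len(line) > 1 else "unnamed"
                continue
            for ch in line:
                pos += 1
                if ch.upper() not in "ACGTN":
                    raise ParseError(
                        f"non-ACGTN character {ch!r} at sequence position {pos}")
            chunks.append(line.upper())
    if header is None or not chunks:
        raise ParseError(f"no sequence in {path}")
    return MitogenomeRecord(id=header, sequence="".join(chunks),
                            topology="linear", source=str(path))


# ---------------------------------------------------------------------------
# Spliced CDS extraction


def spliced_cds(record: MitogenomeRecord, gene: str) -> str:
    """Concatenated exon sequence of ``gene`` in transcription order.

    Reverse-complemented for ``-`` strand features; spans crossing the
    circular origin are unwrapped.  A core-PCG whose spliced length is not
    divisible by 3 triggers a warning (the sequence is still returned).
    """
    feat = None
    for f in record.features:
        if f.name == gene and f.category != "intron":
            feat = f
            break
    if feat is None:
        raise KeyError(f"gene {gene!r} not annotated in {record.id!r}")
    spans = feat.spans if feat.wraps_origin else sorted(feat.spans)
    seq = "".join(record.sequence[s:e] for s, e in spans)
    if feat.strand == "-":
        seq = revcomp(seq)
    if feat.category == "core_pcg" and len(seq) % 3:
        warnings.warn(
            f"{record.id}:{gene} spliced CDS length {len(seq)} not divisible by 3",
            stacklevel=2)
    return seq


def features_table(record: MitogenomeRecord):
    """Feature annotation as a pandas DataFrame (TSV-exportable)."""
    import pandas as pd

    rows = []
    for f in record.features:
        rows.append({
            "id": record.id, "gene": f.name, "category": f.category,
            "strand": f.strand, "start": f.start, "end": f.end,
            "spans": ";".join(f"{s}-{e}" for s, e in f.spans),
            "parent": f.parent or "",
        })
    return pd.DataFrame(rows)


def unwrap(span: tuple[int, int], length: int) -> tuple[int, int]:
    """Normalize a possibly origin-crossing interval modulo the genome length."""
    s, e = span
    return s % length, ((e - 1) % length) + 1


def modular_length(start: int, end: int, length: int) -> int:
    """Length of the arc from start to end walking forward on a circle."""
    return (end - start) % length or (length if start != end else 0)
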