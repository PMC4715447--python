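"""Typed gene features on a (possibly circular) mitogenome.

Coordinates are stored the way they are serialized: 1-based, inclusive, on the
plus strand of the chosen linear representation. A feature that wraps the
origin of a circular genome has ``start > end`` (it runs ``start..L`` then
``1..end``). Internal helpers convert to 0-based half-open spans on a doubled
sequence where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control")

#: The 13 mitochondrial protein-coding genes, in the fixed concatenation order
#: used for supermatrix construction.
PCG_NAMES = (
    "nd1", "nd2", "nd3", "nd4", "nd5", "nd6", "nd4l",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cytb",
)

#: Canonical Lepidoptera mitogenome arrangement, beginning at trnM(cau).
#: Each entry: (name, strand, type, anticodon-or-None). Lepidoptera differ
#: from the ancestral insect order by the trnM-trnI-trnQ rearrangement at the
#: control-region boundary; everything else matches the typical insect plan.
LEPIDOPTERA_GENE_ORDER = (
    ("trnM", "+", "tRNA", "cau"),
    ("trnI", "+", "tRNA", "gau"),
    ("trnQ", "-", "tRNA", "uug"),
    ("nd2", "+", "PCG", None),
    ("trnW", "+", "tRNA", "uca"),
    ("trnC", "-", "tRNA", "gca"),
    ("trnY", "-", "tRNA", "gua"),
    ("cox1", "+", "PCG", None),
    ("trnL2", "+", "tRNA", "uaa"),
    ("cox2", "+", "PCG", None),
    ("trnK", "+", "tRNA", "cuu"),
    ("trnD", "+", "tRNA", "guc"),
    ("atp8", "+", "PCG", None),
    ("atp6", "+", "PCG", None),
    ("cox3", "+", "PCG", None),
    ("trnG", "+", "tRNA", "ucc"),
    ("nd3", "+", "PCG", None),
    ("trnA", "+", "tRNA", "ugc"),
    ("trnR", "+", "tRNA", "ucg"),
    ("trnN", "+", "tRNA", "guu"),
    ("trnS1", "+", "tRNA", "gcu"),
    ("trnE", "+", "tRNA", "uuc"),
    ("trnF", "-", "tRNA", "gaa"),
    ("nd5", "-", "PCG", None),
    ("trnH", "-", "tRNA", "gug"),
    ("nd4", "-", "PCG", None),
    ("nd4l", "-", "PCG", None),
    ("trnT", "+", "tRNA", "ugu"),
    ("trnP", "-", "tRNA", "ugg"),
    ("nd6", "+", "PCG", None),
    ("cytb", "+", "PCG", None),
    ("trnS2", "+", "tRNA", "uga"),
    ("nd1", "-", "PCG", None),
    ("trnL1", "-", "tRNA", "uag"),
    ("rrnL", "-", "rRNA", None),
    ("trnV", "-", "tRNA", "uac"),
    ("rrnS", "-", "rRNA", None),
)


@dataclass
class GeneFeature:
    """A stranded gene interval with codon metadata.

    ``start``/``end`` are 1-based inclusive plus-strand coordinates;
    ``start > end`` means the feature wraps the origin of a circular genome.
    ``stop_codon`` for PCGs is one of TAA/TAG (complete) or TA/T (incomplete,
    completed by polyadenylation of the mRNA) or None for non-coding features.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates are 1-based (got {self.start}..{self.end})")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def span0(self, genome_length: int) -> tuple[int, int]:
        """0-based half-open span on the doubled sequence (end may exceed L)."""
        s = self.start - 1
        e = self.end if not self.wraps else self.end + genome_length
        return s, e

    def extract(self, bases: str) -> str:
        """Sense-strand sequence of the feature from the genome string."""
        from ._dna import revcomp

        s, e = self.span0(len(bases))
        seq = (bases + bases)[s:e]
        return seq if self.strand == "+" else revcomp(seq)

    def shifted(self, offset: int, genome_length: int) -> "GeneFeature":
        """The same feature after rotating the genome left by ``offset`` bases."""
        s, e = self.span0(genome_length)
        ns = (s - offset) % genome_length
        ne = ns + (e - s)
        if ne <= genome_length:
            return replace(self, start=ns + 1, end=ne)
        return replace(self, start=ns + 1, end=ne - genome_length)


@dataclass
class AnnotationSet:
    """An ordered collection of features on one genome."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def add(self, feat: GeneFeature) -> None:
        self.features.append(feat)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def ordered(self) -> list[GeneFeature]:
        """Features in circular order of their start coordinate."""
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def rotated(self, offset: int) -> "AnnotationSet":
        return AnnotationSet(
            self.genome_length,
            [f.shifted(offset, self.genome_length) for f in self.features],
        )

    def sort_key(self) -> list[tuple]:
        return [
            (f.name, f.ftype, f.start, f.end, f.strand, f.start_codon, f.stop_codon)
            for f in self.ordered()
        ]
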