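"""Sequence I/O, quality trimming and mitochondrial translation.

FASTQ is Sanger/Phred+33 only (modern Illumina). Coordinates are 0-based
half-open internally and 1-based inclusive in every serialized format (GFF3,
GenBank). Translation uses the invertebrate mitochondrial code (NCBI table 5)
sourced from Biopython's codon tables, including the incomplete-stop
convention (a terminal T or TA completed to TAA by mRNA polyadenylation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from ._dna import revcomp, validate_dna
from .features import AnnotationSet, GeneFeature


class Library(str, enum.Enum):
    """Paired-end library of origin, by nominal insert size."""

    insert250 = "insert250"
    insert500 = "insert500"
    other = "other"


@dataclass
class ReadRecord:
    """One sequencing read: bases plus per-base Phred qualities."""

    id: str
    bases: str
    quals: Sequence[int]
    mate_id: Optional[str] = None
    library: Library = Library.other

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} qualities for {len(self.bases)} bases"
            )
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError(f"read {self.id!r}: Phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class GenomeSequence:
    """A named DNA sequence with linear or circular topology."""

    id: str
    bases: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"genome {self.id!r} is empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        validate_dna(self.bases, f"genome {self.id!r}")

    def __len__(self) -> int:
        return len(self.bases)


class StopStatus(str, enum.Enum):
    complete_TAA_TAG = "complete_TAA_TAG"
    incomplete_T = "incomplete_T"
    incomplete_TA = "incomplete_TA"
    none = "none"


class InternalStopError(ValueError):
    """A coding sequence translates with a stop codon before its end."""

    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        self.codon = codon
        super().__init__(f"internal stop codon {codon} at codon index {codon_index}")


@dataclass(frozen=True)
class CodonTable:
    """A translation table; the package default is NCBI table 5."""

    table_id: int
    codon_map: dict
    start_codons: frozenset
    stop_codons: frozenset


def _load_table5() -> CodonTable:
    t = _BioCodonTable.unambiguous_dna_by_id[5]
    return CodonTable(
        table_id=5,
        codon_map=dict(t.forward_table),
        start_codons=frozenset(t.start_codons),
        stop_codons=frozenset(t.stop_codons),
    )


#: Invertebrate mitochondrial code: ATA→M, TGA→W, AGA/AGG→S.
INVERTEBRATE_MITO = _load_table5()


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

class FastqParseError(ValueError):
    pass


def read_fastq(path, library: Library = Library.other) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a Phred+33 FASTQ file, preserving order."""
    path = Path(path)
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(qual) != len(seq):
                    raise FastqParseError(
                        f"{path.name}: record {title.split()[0]!r} has "
                        f"{len(qual)} quality characters for {len(seq)} bases"
                    )
                rid = title.split()[0]
                yield ReadRecord(
                    id=rid,
                    bases=seq.upper(),
                    quals=[ord(c) - 33 for c in qual],
                    library=library,
                )
        except ValueError as exc:
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(f"{path.name}: malformed FASTQ ({exc})") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(v + 33) for v in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{q}\n")


def read_fasta(path) -> list[GenomeSequence]:
    out = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            out.append(GenomeSequence(id=title.split()[0], bases=seq.upper()))
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def read_genbank(path) -> GenomeSequence:
    """Sequence (and topology) from a GenBank flat file."""
    rec = SeqIO.read(str(path), "genbank")
    topo = rec.annotations.get("topology", "linear")
    return GenomeSequence(id=rec.id, bases=str(rec.seq).upper(), topology=topo)


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

def trim_read(read: ReadRecord, qmin: int = 20) -> ReadRecord:
    """Remove the runs of sub-``qmin`` qualities at both read ends.

    Interior low-quality bases are kept; the result may be empty. The rule is
    the literal reading of end-trimming at quality < qmin (not a running-sum
    rule); it is idempotent.
    """
    q = read.quals
    n = len(q)
    lo = 0
    while lo < n and q[lo] < qmin:
        lo += 1
    hi = n
    while hi > lo and q[hi - 1] < qmin:
        hi -= 1
    if lo == 0 and hi == n:
        return read
    return replace(read, bases=read.bases[lo:hi], quals=list(q[lo:hi]))


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate_cds(
    cds: str,
    table: CodonTable = INVERTEBRATE_MITO,
    allow_incomplete_stop: bool = True,
) -> tuple[str, StopStatus]:
    """Translate a mitochondrial CDS; trailing T/TA is an incomplete stop.

    Returns (protein, stop_status). The start codon is translated by the
    codon map (an annotated non-ATG start such as cox1's CGA shows up as its
    table-5 amino acid; initiation still uses fMet in vivo). An internal stop
    raises :class:`InternalStopError` with the offending codon index.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    rem = len(cds) % 3
    if rem and not allow_incomplete_stop:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    body = cds[: len(cds) - rem]
    tail = cds[len(cds) - rem :]
    ncod = len(body) // 3
    protein = []
    for i in range(ncod):
        codon = body[3 * i : 3 * i + 3]
        if codon in table.stop_codons:
            if i == ncod - 1 and rem == 0:
                return "".join(protein), StopStatus.complete_TAA_TAG
            raise InternalStopError(i, codon)
        aa = table.codon_map.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at index {i}")
        protein.append(aa)
    if rem == 1:
        if tail != "T":
            raise ValueError(f"trailing base {tail!r} is not a valid incomplete stop")
        return "".join(protein), StopStatus.incomplete_T
    if rem == 2:
        if tail != "TA":
            raise ValueError(f"trailing bases {tail!r} are not a valid incomplete stop")
        return "".join(protein), StopStatus.incomplete_TA
    return "".join(protein), StopStatus.none


# ---------------------------------------------------------------------------
# Feature serialization (GFF3 + GenBank)
# ---------------------------------------------------------------------------

_GFF_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control": "D_loop"}
_GFF_TYPE_BACK = {v: k for k, v in _GFF_TYPE.items()}

_GB_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control": "D-loop"}
_GB_TYPE_BACK = {v: k for k, v in _GB_TYPE.items()}


def _check_bounds(genome: GenomeSequence, ann: AnnotationSet) -> None:
    L = len(genome)
    for f in ann:
        if f.start > L or f.end > L:
            raise ValueError(f"feature {f.name} exceeds genome bounds (length {L})")
        if f.wraps and genome.topology != "circular":
            raise ValueError(f"feature {f.name} wraps the origin of a linear genome")


def write_features(genome: GenomeSequence, ann: AnnotationSet, path, format: str = "gff3") -> None:
    """Write annotations as GFF3 or a GenBank flat file.

    Features wrapping the origin of a circular genome are emitted as two
    joined location segments; both formats round-trip exactly through
    :func:`read_features`.
    """
    _check_bounds(genome, ann)
    if format == "gff3":
        _write_gff3(genome, ann, path)
    elif format == "genbank_feature_table":
        _write_genbank(genome, ann, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _gff_attrs(f: GeneFeature) -> str:
    parts = [f"ID={f.name}", f"Name={f.name}", f"gene_type={f.ftype}"]
    if f.start_codon:
        parts.append(f"start_codon={f.start_codon}")
    if f.stop_codon:
        parts.append(f"stop_codon={f.stop_codon}")
    if f.anticodon:
        parts.append(f"anticodon={f.anticodon}")
    if f.notes:
        parts.append(f"note={f.notes.replace(';', '%3B')}")
    return ";".join(parts)


def _write_gff3(genome: GenomeSequence, ann: AnnotationSet, path) -> None:
    L = len(genome)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {L}\n")
        if genome.topology == "circular":
            fh.write(f"# {genome.id} is circular\n")
        for f in ann.ordered():
            ftype = _GFF_TYPE[f.ftype]
            attrs = _gff_attrs(f)
            segs = [(f.start, L), (1, f.end)] if f.wraps else [(f.start, f.end)]
            for s, e in segs:
                fh.write(
                    f"{genome.id}\tmitoforge\t{ftype}\t{s}\t{e}\t.\t{f.strand}\t.\t{attrs}\n"
                )


def _write_genbank(genome: GenomeSequence, ann: AnnotationSet, path) -> None:
    L = len(genome)
    rec = SeqRecord(Seq(genome.bases), id=genome.id, name=genome.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    for f in ann.ordered():
        strand = 1 if f.strand == "+" else -1
        if f.wraps:
            seg1 = FeatureLocation(f.start - 1, L, strand)
            seg2 = FeatureLocation(0, f.end, strand)
            loc = CompoundLocation([seg1, seg2] if strand == 1 else [seg2, seg1])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        quals = {"gene": [f.name], "mf_type": [f.ftype]}
        if f.start_codon:
            quals["mf_start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["mf_stop_codon"] = [f.stop_codon]
        if f.anticodon:
            quals["mf_anticodon"] = [f.anticodon]
        if f.notes:
            quals["note"] = [f.notes]
        rec.features.append(SeqFeature(loc, type=_GB_TYPE[f.ftype], qualifiers=quals))
    SeqIO.write(rec, str(path), "genbank")


def read_features(path, format: str = "gff3") -> tuple[Optional[GenomeSequence], AnnotationSet]:
    """Inverse of :func:`write_features`; GFF3 returns no sequence."""
    if format == "gff3":
        return _read_gff3(path)
    if format == "genbank_feature_table":
        return _read_genbank_features(path)
    raise ValueError(f"unknown format {format!r}")


def _read_gff3(path) -> tuple[Optional[GenomeSequence], AnnotationSet]:
    L = None
    segs: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                L = int(line.split()[-1])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            _, _, gtype, s, e, _, strand, _, attrs = cols
            ad = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            fid = ad["ID"]
            if fid not in segs:
                segs[fid] = []
                order.append(fid)
            segs[fid].append((int(s), int(e), strand, gtype, ad))
    if L is None:
        raise ValueError("GFF3 lacks a ##sequence-region pragma")
    ann = AnnotationSet(L)
    for fid in order:
        pieces = segs[fid]
        s1, e1, strand, gtype, ad = pieces[0]
        if len(pieces) == 1:
            start, end = s1, e1
        elif len(pieces) == 2:
            (sa, ea, *_), (sb, eb, *_) = pieces
            # wrapped feature: one segment ends at L, the other starts at 1
            if ea == L and sb == 1:
                start, end = sa, eb
            elif eb == L and sa == 1:
                start, end = sb, ea
            else:
                raise ValueError(f"feature {fid}: segments do not form an origin wrap")
        else:
            raise ValueError(f"feature {fid}: more than two segments")
        ann.add(
            GeneFeature(
                name=fid,
                ftype=_GFF_TYPE_BACK[gtype],
                start=start,
                end=end,
                strand=strand,
                start_codon=ad.get("start_codon"),
                stop_codon=ad.get("stop_codon"),
                anticodon=ad.get("anticodon"),
                notes=ad.get("note", "").replace("%3B", ";"),
            )
        )
    return None, ann


def _read_genbank_features(path) -> tuple[GenomeSequence, AnnotationSet]:
    rec = SeqIO.read(str(path), "genbank")
    genome = GenomeSequence(
        id=rec.id,
        bases=str(rec.seq).upper(),
        topology=rec.annotations.get("topology", "linear"),
    )
    L = len(genome)
    ann = AnnotationSet(L)
    for feat in rec.features:
        if feat.type not in _GB_TYPE_BACK:
            continue
        q = feat.qualifiers
        name = q.get("gene", [feat.type])[0]
        strand = "+" if (feat.location.strand or 1) >= 0 else "-"
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[1].end) == L and int(parts[0].start) == 0:
            start, end = int(parts[1].start) + 1, int(parts[0].end)
        else:
            start, end = int(feat.location.start) + 1, int(feat.location.end)
        ann.add(
            GeneFeature(
                name=name,
                ftype=q.get("mf_type", [_GB_TYPE_BACK[feat.type]])[0],
                start=start,
                end=end,
                strand=strand,
                start_codon=q.get("mf_start_codon", [None])[0],
                stop_codon=q.get("mf_stop_codon", [None])[0],
                anticodon=q.get("mf_anticodon", [None])[0],
                notes=q.get("note", [""])[0],
            )
        )
    return genome, ann
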