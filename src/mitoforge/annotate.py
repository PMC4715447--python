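"""Homology-based annotation of the 37 mitochondrial genes and the control region.

Gene placement is by reference similarity: each protein-coding gene's
reference protein is located in the six translated frames of the doubled
circle (exact match first, affine-gap local alignment with BLOSUM62 as the
fallback); tRNAs and rRNAs are located by nucleotide similarity on either
strand. Boundaries are then curated to mitogenome conventions: the start is
the nearest in-frame ATN within ±18 bp (CGA additionally accepted for cox1),
the end is the first in-frame TAA/TAG, truncated to an incomplete stop T/TA
when the downstream gene begins before a complete stop — the codon being
completed to TAA during mRNA maturation. Every accepted protein-coding gene
must translate without internal stops under the invertebrate mitochondrial
code.

The control region is defined by its bounding genes (the span connecting
rrnS to trnM(cau)), not by base composition; its report carries the features
used for QC of Lepidoptera mitogenomes: length, A+T fraction, the offset of
the first ATAGA motif downstream of rrnS, and the length of the poly-T
stretch that follows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._dna import at_fraction, revcomp
from .features import LEPIDOPTERA_GENE_ORDER, PCG_NAMES, AnnotationSet, GeneFeature
from .seqio import INVERTEBRATE_MITO, GenomeSequence, translate_cds

START_CODONS = ("ATG", "ATA", "ATT", "ATC")
_TRNA_LENGTH_WINDOW = (55, 80)
_MAX_GENE_OVERLAP = 10


class CurationError(ValueError):
    """Boundary curation could not produce a valid ORF."""


@dataclass
class GeneOrderReport:
    match: bool
    missing: list[str] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)
    strand_flipped: list[str] = field(default_factory=list)
    transposed: list[str] = field(default_factory=list)


@dataclass
class ControlRegionReport:
    start: int                     # 1-based inclusive, may wrap
    end: int
    length: int
    at_fraction: float
    motif_offset: Optional[int]    # bp between rrnS 3' boundary and ATAGA
    polyt_length: int


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _nuc_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _six_frames(doubled: str) -> list[tuple[str, int, str]]:
    """[(protein, frame offset, strand)] over the doubled circle."""
    out = []
    rc = revcomp(doubled)
    for strand, s in (("+", doubled), ("-", rc)):
        for f in range(3):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            out.append((str(Seq(sub).translate(table=5)), f, strand))
    return out


def _norm_span(a: int, b: int, L: int) -> tuple[int, int]:
    """Doubled-genome span [a,b) → 1-based inclusive, wrapping if needed."""
    s0 = a % L
    e0 = s0 + (b - a)
    if e0 <= L:
        return s0 + 1, e0
    return s0 + 1, e0 - L


def locate_pcgs(
    genome: GenomeSequence,
    reference_proteins: dict[str, str],
    score_floor_per_residue: float = 1.0,
) -> tuple[list[GeneFeature], list[str]]:
    """Best protein-similarity locus per PCG on the six frames of the circle.

    Located intervals cover start codon through last aligned codon (the stop
    is added by :func:`refine_boundaries`). Genes without a reference or
    without an alignment above the score floor are returned in the missing
    list.
    """
    L = len(genome)
    doubled = genome.bases + genome.bases
    frames = _six_frames(doubled)
    aligner = None
    features: list[GeneFeature] = []
    missing: list[str] = []
    for name in PCG_NAMES:
        ref = reference_proteins.get(name)
        if not ref:
            missing.append(name)
            continue
        hit = _find_protein_exact(ref, frames, L)
        if hit is None:
            if aligner is None:
                aligner = _protein_aligner()
            hit = _find_protein_aligned(
                ref, frames, L, aligner, score_floor_per_residue * len(ref)
            )
        if hit is None:
            missing.append(name)
            continue
        nt_a, nt_b, strand = hit
        if strand == "+":
            start, end = _norm_span(nt_a, nt_b, L)
        else:
            # reverse-frame coords index revcomp(doubled): map back to plus
            a_plus = 2 * L - nt_b
            b_plus = 2 * L - nt_a
            start, end = _norm_span(a_plus, b_plus, L)
        features.append(GeneFeature(name=name, ftype="PCG", start=start, end=end, strand=strand))
    return features, missing


def _find_protein_exact(ref: str, frames, L: int) -> Optional[tuple[int, int, str]]:
    for prot, f, strand in frames:
        p = prot.find(ref)
        if p != -1:
            nt_a = f + 3 * p
            return nt_a, nt_a + 3 * len(ref), strand
    return None


def _find_protein_aligned(
    ref: str, frames, L: int, aligner, floor: float
) -> Optional[tuple[int, int, str]]:
    best = None
    for prot, f, strand in frames:
        try:
            alns = aligner.align(prot, ref)
        except ValueError:
            continue
        if len(alns) == 0:
            continue
        a = alns[0]
        if best is None or a.score > best[0]:
            blocks = a.aligned[0]
            pa, pb = int(blocks[0][0]), int(blocks[-1][1])
            best = (a.score, f + 3 * pa, f + 3 * pb, strand)
    if best is None or best[0] < floor:
        return None
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# Boundary curation
# ---------------------------------------------------------------------------

def _sense_anchor(feature: GeneFeature, L: int) -> int:
    """Start of the feature along its own sense linearization of the circle."""
    a, b = feature.span0(L)
    if feature.strand == "+":
        return a % L
    return (L - b) % L


def _sense_interval_start(feature: GeneFeature, strand: str, L: int) -> int:
    """First base of ``feature``'s territory in the ``strand`` linearization."""
    a, b = feature.span0(L)
    if strand == "+":
        return a % L
    return (L - b) % L


def refine_boundaries(
    feature: GeneFeature,
    genome: GenomeSequence,
    downstream_feature: Optional[GeneFeature] = None,
    window: int = 18,
) -> GeneFeature:
    """Curate a PCG's start and stop to mitogenome conventions.

    The start moves to the nearest in-frame ATN within ±``window`` bp (ties
    prefer upstream, i.e. the longer ORF); CGA is additionally accepted for
    cox1. The end is the first in-frame TAA/TAG, or an incomplete T/TA stop
    abutting ``downstream_feature`` when a complete stop would overrun it.
    The resulting ORF is validated under the invertebrate mitochondrial code.
    """
    if feature.ftype != "PCG":
        raise ValueError("refine_boundaries applies to protein-coding genes")
    L = len(genome)
    sense = genome.bases if feature.strand == "+" else revcomp(genome.bases)
    T = sense * 3
    anchor = _sense_anchor(feature, L) + L

    allowed = START_CODONS + (("CGA",) if feature.name == "cox1" else ())
    shifts = sorted(range(-window, window + 1, 3), key=lambda d: (abs(d), d))
    start_pos = None
    for d in shifts:
        codon = T[anchor + d : anchor + d + 3]
        if codon in allowed:
            start_pos = anchor + d
            start_codon = codon
            break
    if start_pos is None:
        raise CurationError(
            f"{feature.name}: no valid start codon within ±{window} bp"
        )

    down_pos = None
    if downstream_feature is not None:
        off = (_sense_interval_start(downstream_feature, feature.strand, L)
               - (start_pos - L)) % L
        down_pos = start_pos + off

    stops = INVERTEBRATE_MITO.stop_codons
    stop_end = None
    stop_codon = None
    i = start_pos + 3
    limit = start_pos + L
    while i + 3 <= limit:
        codon = T[i : i + 3]
        if codon in stops:
            stop_end = i + 3
            stop_codon = codon
            break
        i += 3

    truncated = False
    if down_pos is not None and (stop_end is None or stop_end > down_pos):
        tail = down_pos - start_pos
        rem = tail % 3
        if rem == 1 and T[down_pos - 1] == "T":
            stop_end, stop_codon, truncated = down_pos, "T", True
        elif rem == 2 and T[down_pos - 2 : down_pos] == "TA":
            stop_end, stop_codon, truncated = down_pos, "TA", True
        elif stop_end is not None and stop_end <= down_pos + _MAX_GENE_OVERLAP:
            # genuine short gene overlap (atp8/atp6 style): keep the complete stop
            pass
        else:
            raise CurationError(
                f"{feature.name}: no complete stop before the downstream gene and "
                f"the boundary does not end in a valid incomplete stop"
            )
    if stop_end is None:
        raise CurationError(f"{feature.name}: no stop codon found")

    cds = T[start_pos:stop_end]
    translate_cds(cds)  # raises InternalStopError on a bad ORF

    # map sense interval back to plus-strand coordinates
    a_s, b_s = start_pos - L, stop_end - L
    if feature.strand == "+":
        start, end = _norm_span(a_s, b_s, L)
    else:
        start, end = _norm_span(L - b_s, L - a_s, L)

    notes = []
    if start_codon == "CGA":
        notes.append("non-ATN start codon CGA accepted")
    if truncated:
        notes.append("incomplete stop codon; completed to TAA by polyadenylation")
    if start_pos != anchor:
        notes.append(f"start shifted {start_pos - anchor:+d} bp during curation")
    return GeneFeature(
        name=feature.name,
        ftype="PCG",
        start=start,
        end=end,
        strand=feature.strand,
        start_codon=start_codon,
        stop_codon=stop_codon,
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# RNA genes
# ---------------------------------------------------------------------------

def locate_rnas(
    genome: GenomeSequence, reference_rna_seqs: dict[str, str]
) -> tuple[list[GeneFeature], list[str]]:
    """Best nucleotide-similarity locus per tRNA/rRNA reference, either strand."""
    L = len(genome)
    doubled = genome.bases + genome.bases
    aligner = None
    anticodons = {
        name: ac for name, _, ftype, ac in LEPIDOPTERA_GENE_ORDER if ftype == "tRNA"
    }
    features: list[GeneFeature] = []
    warnings: list[str] = []
    for name in sorted(reference_rna_seqs):
        ref = reference_rna_seqs[name]
        ftype = "rRNA" if name.startswith("rrn") else "tRNA"
        hits = []
        for strand, probe in (("+", ref), ("-", revcomp(ref))):
            for p in _occurrences(doubled, probe):
                if p < L:
                    hits.append((p, p + len(probe), strand))
        if hits:
            if len(hits) > 1:
                warnings.append(
                    f"{name}: {len(hits)} equal-scoring loci; lowest coordinate chosen"
                )
            hits.sort()
            a, b, strand = hits[0]
        else:
            if aligner is None:
                aligner = _nuc_aligner()
            best = None
            for strand, target in (("+", doubled), ("-", revcomp(doubled))):
                aln = aligner.align(target, ref)
                if len(aln) == 0:
                    continue
                top = aln[0]
                if best is None or top.score > best[0]:
                    blocks = top.aligned[0]
                    best = (top.score, int(blocks[0][0]), int(blocks[-1][1]), strand)
            if best is None:
                warnings.append(f"{name}: no alignment found; reported missing")
                continue
            _, ta, tb, strand = best
            if strand == "+":
                a, b = ta, tb
            else:
                a, b = 2 * L - tb, 2 * L - ta
        length = b - a
        if ftype == "tRNA" and not (_TRNA_LENGTH_WINDOW[0] <= length <= _TRNA_LENGTH_WINDOW[1]):
            warnings.append(
                f"{name}: best hit length {length} bp outside the "
                f"{_TRNA_LENGTH_WINDOW} tRNA window; unconstrained hit reported"
            )
        start, end = _norm_span(a, b, L)
        features.append(
            GeneFeature(
                name=name, ftype=ftype, start=start, end=end, strand=strand,
                anticodon=anticodons.get(name),
            )
        )
    return features, warnings


def _occurrences(seq: str, sub: str) -> list[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


# ---------------------------------------------------------------------------
# Gene order and control region
# ---------------------------------------------------------------------------

def check_gene_order(
    ann: AnnotationSet, template=LEPIDOPTERA_GENE_ORDER
) -> GeneOrderReport:
    """Circular comparison of the annotated order against the template."""
    observed = [(f.name, f.strand) for f in ann.ordered() if f.ftype != "control"]
    tnames = [name for name, *_ in template]
    tstrand = {name: strand for name, strand, *_ in template}
    onames = [n for n, _ in observed]
    missing = [n for n in tnames if n not in onames]
    extra = [n for n in onames if n not in tnames]
    flipped = [n for n, s in observed if n in tstrand and s != tstrand[n]]

    t_common = [n for n in tnames if n in onames]
    o_common = [n for n, _ in observed if n in tnames]
    transposed: list[str] = []
    if t_common:
        pivot = t_common[0]
        i = o_common.index(pivot)
        o_rot = o_common[i:] + o_common[:i]
        if o_rot != t_common:
            transposed = sorted(
                {a for a, b in zip(o_rot, t_common) if a != b}
            )
    match = not (missing or extra or flipped or transposed)
    return GeneOrderReport(
        match=match, missing=missing, extra=extra,
        strand_flipped=flipped, transposed=transposed,
    )


def analyze_control_region(
    genome: GenomeSequence, ann: AnnotationSet, motif: str = "ATAGA"
) -> ControlRegionReport:
    """Characterize the span strictly between rrnS and trnM(cau).

    The motif offset is the number of bases between the rrnS boundary and the
    first ATAGA occurrence; the poly-T length is the maximal T run starting
    immediately after the motif. An absent motif reports offset None.
    """
    rrns = ann.get("rrnS")
    trnm = ann.get("trnM")
    L = len(genome)
    _, rrns_end = rrns.span0(L)
    trnm_start, _ = trnm.span0(L)
    a = rrns_end % L
    length = (trnm_start - a) % L
    seq = (genome.bases + genome.bases)[a : a + length]
    idx = seq.find(motif)
    if idx == -1:
        offset, polyt = None, 0
    else:
        offset = idx
        j = idx + len(motif)
        polyt = 0
        while j + polyt < len(seq) and seq[j + polyt] == "T":
            polyt += 1
    start, end = _norm_span(a, a + length, L)
    return ControlRegionReport(
        start=start, end=end, length=length,
        at_fraction=at_fraction(seq), motif_offset=offset, polyt_length=polyt,
    )


# ---------------------------------------------------------------------------
# Whole-genome convenience
# ---------------------------------------------------------------------------

def annotate_genome(
    genome: GenomeSequence,
    reference_proteins: dict[str, str],
    reference_rna_seqs: dict[str, str],
) -> tuple[AnnotationSet, dict]:
    """Locate, curate and assemble the full annotation of a closed circle.

    Returns the AnnotationSet (PCGs with curated boundaries, RNAs, control
    region) and a report dict (missing genes, warnings, gene order, control
    region analysis).
    """
    L = len(genome)
    pcgs, missing = locate_pcgs(genome, reference_proteins)
    rnas, warnings = locate_rnas(genome, reference_rna_seqs)

    ann = AnnotationSet(L, list(pcgs) + list(rnas))
    ordered = ann.ordered()

    def downstream_of(f: GeneFeature) -> Optional[GeneFeature]:
        others = [g for g in ordered if g is not f]
        if not others:
            return None
        a, b = f.span0(L)
        if f.strand == "+":
            # nearest feature start after the gene end, going forward
            key = lambda g: (g.span0(L)[0] - (b % L)) % L
        else:
            key = lambda g: ((a % L) - g.span0(L)[1]) % L
        return min(others, key=key)

    refined = []
    for f in pcgs:
        refined.append(refine_boundaries(f, genome, downstream_of(f)))
    ann = AnnotationSet(L, refined + list(rnas))

    cr = None
    try:
        cr = analyze_control_region(genome, ann)
        ann.add(
            GeneFeature(name="d_loop", ftype="control", start=cr.start, end=cr.end, strand="+")
        )
    except KeyError:
        warnings.append("rrnS or trnM missing; control region not annotated")

    order = check_gene_order(ann)
    report = {
        "missing": missing,
        "warnings": warnings,
        "gene_order": order,
        "control_region": cr,
    }
    return ann, report
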