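"""Synthetic mitogenome and paired-end read simulation.

The generator emulates the data the assembly protocol assumes: a circular,
AT-rich (~80% genome-wide) molecule of ~15.4 kb carrying the canonical
37-gene Lepidoptera layout starting at trnM(cau), with an A+T-rich control
region between rrnS and trnM that contains an ATAGA motif 22 bp downstream of
rrnS followed by a 15 bp poly-T stretch. Reads are 150 bp paired-end from two
libraries (~250 and ~500 bp inserts) with substitution errors and a simple
quality model (errored bases Q≤15, correct bases Q 30–40) — enough structure
to exercise trimming, k-mer correction and junction-spanning closure.

Gene "stubs" are synthetic: protein-coding genes are real open reading frames
under the invertebrate mitochondrial code (cox1 starts with CGA; cox1, cox2
and nd4 end on an incomplete stop T abutting their downstream tRNA), tRNAs
and rRNAs are random sequences of realistic length. No real species'
sequence is embedded; real reference mitogenomes can be substituted
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._dna import revcomp
from .features import LEPIDOPTERA_GENE_ORDER, AnnotationSet, GeneFeature
from .seqio import INVERTEBRATE_MITO, GenomeSequence, Library, ReadRecord, translate_cds

#: Internal codon counts (between start and stop) per protein-coding gene,
#: close to typical Lepidoptera sizes.
_PCG_CODONS = {
    "nd2": 338, "cox1": 509, "cox2": 227, "atp8": 51, "atp6": 224,
    "cox3": 261, "nd3": 115, "nd5": 577, "nd4": 446, "nd4l": 95,
    "nd6": 175, "cytb": 378, "nd1": 312,
}

#: Genes ending on an incomplete stop codon T (completed by polyadenylation),
#: mirroring the usual Lepidoptera situation.
INCOMPLETE_STOP_GENES = ("cox1", "cox2", "nd4")

_RRN_BASE = {"rrnL": 1400, "rrnS": 780}


@dataclass
class RepeatInstability:
    """Length heterogeneity of one low-complexity tract across genome copies.

    ``region`` is the 0-based half-open tract span on the truth genome;
    ``variants`` maps tract length (bp) → probability (must sum to 1). Each
    simulated fragment is drawn from a genome copy whose tract length is
    sampled from this distribution.
    """

    region: tuple[int, int]
    variants: dict[int, float]


@dataclass
class SimConfig:
    genome_length: int = 15400
    at_fraction: float = 0.80
    control_region_length: int = 488
    cr_at_fraction: float = 0.947
    motif: str = "ATAGA"
    motif_offset: int = 22
    polyt_length: int = 15
    read_length: int = 150
    insert_means: Sequence[int] = (250, 500)
    insert_sd: float = 25.0
    coverage: float = 500.0
    sub_error_rate: float = 0.01
    repeat_instability: Optional[RepeatInstability] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.control_region_length <= 0:
            raise ValueError("lengths must be positive")
        if not (0 <= self.sub_error_rate < 1):
            raise ValueError("sub_error_rate must lie in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    if n <= 0:
        return ""
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_codons(rng: np.random.Generator, n: int, at: float, stops: frozenset) -> str:
    """n random codons, none of them a stop codon."""
    out = []
    while len(out) < n:
        c = _random_seq(rng, 3, at)
        if c not in stops:
            out.append(c)
    return "".join(out)


def _control_region(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Control region: [offset bases][ATAGA][poly-T][filler], AT-rich."""
    m = cfg.motif
    fixed = cfg.motif_offset + len(m) + cfg.polyt_length
    if cfg.control_region_length < fixed + 1:
        raise ValueError("control region too short for motif layout")
    while True:
        prefix = _random_seq(rng, cfg.motif_offset, cfg.cr_at_fraction)
        if m not in (prefix + m[:-1]):
            break
    rest_len = cfg.control_region_length - fixed
    while True:
        rest = _random_seq(rng, rest_len, cfg.cr_at_fraction)
        if rest[0] != "T" and m not in rest:
            break
    return prefix + m + "T" * cfg.polyt_length + rest


def simulate_mitogenome(cfg: SimConfig) -> tuple[GenomeSequence, AnnotationSet]:
    """Build the truth circle and its exact annotation, deterministically.

    The genome is laid out element-by-element in the canonical Lepidoptera
    order with small (2 bp) spacers, zero-length spacers where an incomplete
    stop abuts the downstream tRNA, and the control region closing the circle
    back to trnM. rrnL absorbs the slack so the total equals
    ``cfg.genome_length`` exactly.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    stops = INVERTEBRATE_MITO.stop_codons

    trna_len = {
        name: int(rng.integers(60, 71))
        for name, _, ftype, _ in LEPIDOPTERA_GENE_ORDER
        if ftype == "tRNA"
    }

    def planned_len(name: str, ftype: str) -> int:
        if ftype == "PCG":
            stop = 1 if name in INCOMPLETE_STOP_GENES else 3
            return 3 + 3 * _PCG_CODONS[name] + stop
        if ftype == "tRNA":
            return trna_len[name]
        return _RRN_BASE[name]

    # zero spacer *before* these elements (they abut the incomplete stop of
    # the element that precedes them in transcription direction)
    zero_before = {"trnL2", "trnK", "nd4"}

    total = 0
    spacers = []
    for i, (name, _, ftype, _) in enumerate(LEPIDOPTERA_GENE_ORDER):
        sp = 0 if (i == 0 or name in zero_before) else 2
        spacers.append(sp)
        total += sp + planned_len(name, ftype)
    total += cfg.control_region_length
    slack = cfg.genome_length - total
    rrnl_len = _RRN_BASE["rrnL"] + slack
    if rrnl_len < 600:
        raise ValueError(
            f"gene template ({total - _RRN_BASE['rrnL'] + 600} bp minimum) "
            f"longer than genome_length {cfg.genome_length}"
        )

    parts: list[str] = []
    feats: list[tuple] = []  # (name, ftype, strand, pos0, length, meta)
    pos = 0
    for i, (name, strand, ftype, anticodon) in enumerate(LEPIDOPTERA_GENE_ORDER):
        sp = spacers[i]
        if sp:
            parts.append(_random_seq(rng, sp, cfg.at_fraction))
            pos += sp
        meta = {"anticodon": anticodon}
        if ftype == "PCG":
            start_codon = "CGA" if name == "cox1" else "ATG"
            stop_codon = "T" if name in INCOMPLETE_STOP_GENES else "TAA"
            sense = start_codon + _random_codons(rng, _PCG_CODONS[name], cfg.at_fraction, stops) + stop_codon
            meta.update(start_codon=start_codon, stop_codon=stop_codon)
        elif ftype == "tRNA":
            sense = _random_seq(rng, trna_len[name], cfg.at_fraction)
        else:
            n = rrnl_len if name == "rrnL" else _RRN_BASE["rrnS"]
            sense = _random_seq(rng, n, cfg.at_fraction)
        parts.append(sense if strand == "+" else revcomp(sense))
        feats.append((name, ftype, strand, pos, len(sense), meta))
        pos += len(sense)

    cr = _control_region(rng, cfg)
    parts.append(cr)
    feats.append(("d_loop", "control", "+", pos, len(cr), {}))
    pos += len(cr)
    assert pos == cfg.genome_length

    genome = GenomeSequence(id="sim_mito", bases="".join(parts), topology="circular")
    ann = AnnotationSet(cfg.genome_length)
    for name, ftype, strand, p0, ln, meta in feats:
        ann.add(
            GeneFeature(
                name=name,
                ftype=ftype,
                start=p0 + 1,
                end=p0 + ln,
                strand=strand,
                start_codon=meta.get("start_codon"),
                stop_codon=meta.get("stop_codon"),
                anticodon=meta.get("anticodon"),
            )
        )
    return genome, ann


def truth_references(
    genome: GenomeSequence, ann: AnnotationSet
) -> tuple[dict[str, str], dict[str, str]]:
    """Per-gene reference sets taken from a truth genome.

    Returns (PCG protein references, RNA nucleotide references) — the inputs
    the annotation module expects, here derived from the simulation itself
    for self-recovery tests and desk-scale pipelines.
    """
    proteins: dict[str, str] = {}
    rnas: dict[str, str] = {}
    for f in ann:
        seq = f.extract(genome.bases)
        if f.ftype == "PCG":
            prot, _ = translate_cds(seq)
            proteins[f.name] = prot
        elif f.ftype in ("tRNA", "rRNA"):
            rnas[f.name] = seq
    return proteins, rnas


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _variant_genomes(genome: str, cfg: SimConfig) -> tuple[list[str], list[float]]:
    ri = cfg.repeat_instability
    if ri is None:
        return [genome], [1.0]
    s, e = ri.region
    tract = genome[s:e]
    if not tract:
        raise ValueError("repeat_instability region is empty")
    genomes, probs = [], []
    for length, p in sorted(ri.variants.items()):
        unit = tract * (length // len(tract) + 2)
        genomes.append(genome[:s] + unit[:length] + genome[e:])
        probs.append(p)
    total = sum(probs)
    return genomes, [p / total for p in probs]


def simulate_reads(
    genome: GenomeSequence, cfg: SimConfig
) -> dict[str, list[tuple[ReadRecord, ReadRecord]]]:
    """Paired-end reads per insert library, uniform around the circle.

    Fragments may wrap the origin; mates are inner-oriented (fragment ends
    read toward each other). Pair count per library is
    genome_length×coverage/(2×read_length×n_libraries), rounded.
    """
    rl = cfg.read_length
    L = len(genome)
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome length {L}")
    rng = np.random.default_rng([cfg.seed, 23])
    variants, vprobs = _variant_genomes(genome.bases, cfg)
    nlib = len(cfg.insert_means)
    pairs_per_lib = round(L * cfg.coverage / (2 * rl * nlib))
    lib_enum = {250: Library.insert250, 500: Library.insert500}

    out: dict[str, list[tuple[ReadRecord, ReadRecord]]] = {}
    for mean in cfg.insert_means:
        lib = lib_enum.get(mean, Library.other)
        key = f"insert{mean}"
        pairs: list[tuple[ReadRecord, ReadRecord]] = []
        for i in range(pairs_per_lib):
            vi = int(rng.choice(len(variants), p=vprobs)) if len(variants) > 1 else 0
            g = variants[vi]
            gl = len(g)
            insert = max(rl, int(round(rng.normal(mean, cfg.insert_sd))))
            insert = min(insert, gl)
            pos = int(rng.integers(0, gl))
            frag = (g + g)[pos : pos + insert]
            fwd = frag[:rl]
            rev = revcomp(frag[-rl:])
            if rng.random() < 0.5:
                s1, s2 = fwd, rev
            else:
                s1, s2 = rev, fwd
            r1 = _errorize(rng, s1, cfg.sub_error_rate)
            r2 = _errorize(rng, s2, cfg.sub_error_rate)
            id1 = f"sim.{key}.{i}/1"
            id2 = f"sim.{key}.{i}/2"
            pairs.append(
                (
                    ReadRecord(id=id1, bases=r1[0], quals=r1[1], mate_id=id2, library=lib),
                    ReadRecord(id=id2, bases=r2[0], quals=r2[1], mate_id=id1, library=lib),
                )
            )
        out[key] = pairs
    return out


_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


def _errorize(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list[int]]:
    n = len(seq)
    quals = rng.integers(30, 41, size=n)
    if rate > 0:
        err = np.nonzero(rng.random(n) < rate)[0]
        if err.size:
            chars = list(seq)
            subs = rng.integers(0, 3, size=err.size)
            lowq = rng.integers(2, 16, size=err.size)
            for j, (k, s) in enumerate(zip(err, subs)):
                chars[k] = _OTHER[chars[k]][s]
                quals[k] = lowq[j]
            seq = "".join(chars)
    return seq, quals.tolist()


def random_read_pool(
    n_reads: int, read_length: int = 150, seed: int = 0, at: float = 0.6
) -> list[ReadRecord]:
    """Unrelated random-sequence reads (e.g. a stand-in nuclear background)."""
    rng = np.random.default_rng([seed, 97])
    out = []
    for i in range(n_reads):
        seq = _random_seq(rng, read_length, at)
        quals = rng.integers(30, 41, size=read_length).tolist()
        out.append(ReadRecord(id=f"bg.{i}", bases=seq, quals=quals))
    return out
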