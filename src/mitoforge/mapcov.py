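"""Read mapping, per-base depth and assembly quality assessment.

The mapper is exact-seed / ungapped-extend: a read is placed at the best
locus (fewest mismatches, then lowest coordinate) reachable from an exact
seed k-mer on either strand, and rejected if its mismatch fraction exceeds a
cap. Indels leave a read unmapped rather than misplacing depth — the
conservative choice for a QC profile.

Because reads spanning the origin of a circular genome map to only one
terminus (or not at all) on the linear representation, naive depth
under-estimates coverage at both ends. ``wraparound_depth`` remaps all reads
to the half-rotated linearization and replaces the two terminal windows of
the profile with their images there, leaving interior positions untouched.

Low-coverage intervals are characterized the way AT-rich mitogenome QC needs:
dominant base fraction (poly-T tracts) and dinucleotide-repeat detection
(AT-repeat tracts), plus a read-level survey of tract-length heterogeneity
between unique flanking anchors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._dna import revcomp
from .seqio import GenomeSequence, ReadRecord

#: ratio of the low-coverage flag threshold to mean depth (1,000 at ~22,600×)
_FLAG_RATIO = 1000.0 / 22600.0


def estimate_coverage(
    n_reads: int, read_len: int, genome_len: int, paired: bool = True
) -> float:
    """Expected fold coverage: n_reads × read_len × (2 if paired) / genome_len."""
    return n_reads * read_len * (2 if paired else 1) / genome_len


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (22,616.9 → 22,600)."""
    if x == 0:
        return 0.0
    import math

    d = math.ceil(math.log10(abs(x)))
    return round(x, sig - d)


@dataclass
class ReadAlignment:
    read_id: str
    position: int          # 0-based start on the linear representation
    strand: str
    aligned_length: int
    mismatches: int


@dataclass
class DepthProfile:
    depth: np.ndarray
    provenance: str = "naive_linear"   # or wraparound_corrected

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def mean(self) -> float:
        return float(self.depth.mean())


@dataclass
class LowCoverageRegion:
    start: int                 # 0-based half-open interval
    end: int
    min_depth: int
    dominant_base: str
    dominant_fraction: float
    dinucleotide_repeat: bool = False
    repeat_unit: Optional[str] = None
    repeat_run_length: int = 0


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def _build_index(genome: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(genome) - k + 1):
        idx.setdefault(genome[i : i + k], []).append(i)
    return idx


def map_reads(
    reads: Iterable[ReadRecord],
    genome: GenomeSequence,
    seed_k: int = 21,
    max_mismatch_rate: float = 0.05,
    index: Optional[dict] = None,
) -> tuple[list[ReadAlignment], int]:
    """Place each read at its best exact-seed-then-extend locus.

    Returns (alignments, unmapped count). Ties break to the lowest
    coordinate, plus strand before minus — deterministic.
    """
    g = genome.bases
    L = len(g)
    idx = index if index is not None else _build_index(g, seed_k)
    alignments: list[ReadAlignment] = []
    unmapped = 0
    for r in reads:
        n = len(r.bases)
        if n < seed_k:
            unmapped += 1
            continue
        max_mm = int(max_mismatch_rate * n)
        best: Optional[tuple[int, int, int]] = None  # (mm, start, strand_rank)
        for strand_rank, s in enumerate((r.bases, revcomp(r.bases))):
            seen: set[int] = set()
            for off in range(0, n - seed_k + 1, seed_k):
                for p in idx.get(s[off : off + seed_k], ()):
                    start = p - off
                    if start < 0 or start + n > L or start in seen:
                        continue
                    seen.add(start)
                    mm = sum(a != b for a, b in zip(s, g[start : start + n]))
                    if mm <= max_mm:
                        cand = (mm, start, strand_rank)
                        if best is None or cand < best:
                            best = cand
        if best is None:
            unmapped += 1
        else:
            mm, start, sr = best
            alignments.append(
                ReadAlignment(
                    read_id=r.id,
                    position=start,
                    strand="+" if sr == 0 else "-",
                    aligned_length=n,
                    mismatches=mm,
                )
            )
    return alignments, unmapped


def depth_profile(alignments: Sequence[ReadAlignment], genome_len: int) -> DepthProfile:
    """depth[i] = number of alignments covering position i."""
    diff = np.zeros(genome_len + 1, dtype=np.int64)
    for a in alignments:
        if a.position + a.aligned_length > genome_len:
            raise ValueError(f"alignment of {a.read_id} exceeds genome length")
        diff[a.position] += 1
        diff[a.position + a.aligned_length] -= 1
    return DepthProfile(depth=np.cumsum(diff[:-1]), provenance="naive_linear")


def wraparound_depth(
    genome: GenomeSequence,
    reads: Sequence[ReadRecord],
    window: int = 1000,
    seed_k: int = 21,
    max_mismatch_rate: float = 0.05,
) -> DepthProfile:
    """Depth with the two terminal windows recomputed on the half-rotated circle.

    The rotated linearization joins the 5′-terminal half to the end of the
    3′-terminal half, so reads spanning the original origin map contiguously;
    positions inside the two ``window``-sized terminal segments take their
    depth from their images in that representation, interior positions keep
    the naive values.
    """
    L = len(genome)
    if window > L // 2:
        raise ValueError(f"window {window} exceeds half the genome length")
    aln, _ = map_reads(reads, genome, seed_k, max_mismatch_rate)
    naive = depth_profile(aln, L).depth
    if window == 0:
        return DepthProfile(depth=naive, provenance="wraparound_corrected")
    half = L // 2
    rotated = GenomeSequence(
        id=genome.id + "_rot", bases=genome.bases[half:] + genome.bases[:half],
        topology=genome.topology,
    )
    aln2, _ = map_reads(reads, rotated, seed_k, max_mismatch_rate)
    rot = depth_profile(aln2, L).depth
    corrected = naive.copy()
    for pos_block in (np.arange(0, window), np.arange(L - window, L)):
        images = (pos_block - half) % L
        corrected[pos_block] = rot[images]
    return DepthProfile(depth=corrected, provenance="wraparound_corrected")


# ---------------------------------------------------------------------------
# Low-coverage characterization
# ---------------------------------------------------------------------------

def auto_threshold(profile: DepthProfile) -> int:
    """Flag threshold scaled to mean depth (the 1,000 / 22,600 ratio)."""
    return max(1, int(round(_FLAG_RATIO * profile.mean)))


def _longest_period2_run(seq: str) -> tuple[str, int, bool]:
    """Longest run with period 2; returns (unit, run length, is dinucleotide)."""
    best_len, best_at = 0, 0
    n = len(seq)
    i = 0
    while i < n - 1:
        j = i + 2
        while j < n and seq[j] == seq[j - 2]:
            j += 1
        if j - i > best_len:
            best_len, best_at = j - i, i
        i = max(i + 1, j - 1)
    unit = seq[best_at : best_at + 2] if best_len >= 2 else seq[:1] * 2
    return unit, best_len, len(set(unit)) == 2


def flag_low_coverage(
    profile: DepthProfile, genome: GenomeSequence, threshold: Optional[int] = None
) -> list[LowCoverageRegion]:
    """Maximal sub-threshold intervals with base-composition diagnostics."""
    if threshold is None:
        threshold = auto_threshold(profile)
    d = profile.depth
    below = d < threshold
    regions: list[LowCoverageRegion] = []
    i = 0
    L = len(d)
    while i < L:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < L and below[j]:
            j += 1
        seq = genome.bases[i:j]
        counts = Counter(seq)
        base, cnt = counts.most_common(1)[0]
        unit, run, is_dinuc = _longest_period2_run(seq)
        dinuc = is_dinuc and run >= 0.9 * len(seq)
        regions.append(
            LowCoverageRegion(
                start=i,
                end=j,
                min_depth=int(d[i:j].min()),
                dominant_base=base,
                dominant_fraction=cnt / len(seq),
                dinucleotide_repeat=dinuc,
                repeat_unit=unit if dinuc else None,
                repeat_run_length=run if dinuc else 0,
            )
        )
        i = j
    return regions


def length_variant_survey(
    reads: Iterable[ReadRecord],
    genome: GenomeSequence,
    region: tuple[int, int],
    flank: int = 20,
) -> tuple[Counter, Optional[int], list[str]]:
    """Histogram of tract lengths observed between unique flanking anchors.

    ``region`` is 0-based half-open on the genome. Every read containing the
    left flank followed by the right flank votes for the intervening length.
    Returns (histogram, dominant length, warnings); the dominant form is
    compared with the genome's own tract length and a mismatch is warned.
    """
    s, e = region
    if s - flank < 0 or e + flank > len(genome):
        raise ValueError("region too close to the genome ends for the flank size")
    left = genome.bases[s - flank : s]
    right = genome.bases[e : e + flank]
    doubled = genome.bases + genome.bases if genome.topology == "circular" else genome.bases
    for anchor, label in ((left, "left"), (right, "right")):
        n_occ = len(_occ(doubled, anchor)) + len(_occ(doubled, revcomp(anchor)))
        limit = 2 if genome.topology == "circular" else 1
        if n_occ > limit:
            raise ValueError(f"{label} flank anchor is not unique in the genome")
    hist: Counter = Counter()
    for r in reads:
        for seq in (r.bases, revcomp(r.bases)):
            i = seq.find(left)
            if i == -1:
                continue
            j = seq.find(right, i + flank)
            if j == -1:
                continue
            hist[j - (i + flank)] += 1
            break
    warnings: list[str] = []
    if not hist:
        warnings.append("no reads span both flank anchors; histogram empty")
        return hist, None, warnings
    dominant = max(hist.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    if dominant != e - s:
        warnings.append(
            f"dominant tract length {dominant} differs from the assembled "
            f"genome's {e - s}; the assembly may not represent the dominant form"
        )
    return hist, dominant, warnings


def _occ(seq: str, sub: str) -> list[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


def write_sam(
    alignments: Sequence[ReadAlignment], genome: GenomeSequence, path
) -> None:
    """Minimal headered, unsorted SAM export of ungapped placements."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{genome.id}\tLN:{len(genome)}\n")
        fh.write("@PG\tID:mitoforge\tPN:mitoforge\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{genome.id}\t{a.position + 1}\t255\t"
                f"{a.aligned_length}M\t*\t0\t0\t*\t*\tNM:i:{a.mismatches}\n"
            )


def write_depth(profile: DepthProfile, path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(profile.depth, start=1):
            fh.write(f"{i}\t{int(d)}\n")


def write_bed(regions: Sequence[LowCoverageRegion], genome_id: str, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            label = f"{r.dominant_base}:{r.dominant_fraction:.2f}"
            if r.dinucleotide_repeat:
                label += f";{r.repeat_unit}x{r.repeat_run_length // 2}"
            fh.write(f"{genome_id}\t{r.start}\t{r.end}\t{label}\n")
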