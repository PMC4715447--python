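"""15-mer spectrum construction, frequency-guided error correction and read filtering.

At very high coverage of a single molecule, every true k-mer of the genome is
seen thousands of times while k-mers created by sequencing errors (or leaked
nuclear reads) stay rare. The protocol therefore counts 15-mers, corrects
reads whose k-mers fall below a frequency threshold by substitution search,
and excludes reads that cannot be lifted above the threshold.

The published threshold (1,000 at roughly 22,600-fold coverage) is a ratio of
~4.4% of expected coverage; :func:`scaled_min_freq` reproduces the absolute
value at publication-scale coverage while keeping desk-scale simulations
meaningful. Correction is a greedy quality-ranked substitution search: the
contract (every kept read's k-mers all reach the threshold, or the read is
excluded) is what the protocol requires of the corrector, not any particular
internal model.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from ._dna import canonical, canonical_kmers, revcomp
from .seqio import ReadRecord

#: ratio of the published threshold to the published expected coverage
_THRESHOLD_RATIO = 1000.0 / 22600.0


@dataclass
class KmerSpectrum:
    """Canonical k-mer → frequency map at fixed k."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_kmers(self) -> int:
        return sum(self.counts.values())

    def get(self, kmer: str) -> int:
        """Count of a k-mer in either orientation."""
        c = self.counts.get(kmer)
        if c is not None:
            return c
        return self.counts.get(revcomp(kmer), 0)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for km in sorted(self.counts):
                fh.write(f"{km}\t{self.counts[km]}\n")

    @classmethod
    def read(cls, path) -> "KmerSpectrum":
        counts: dict[str, int] = {}
        k = 0
        with open(path) as fh:
            for line in fh:
                km, c = line.split("\t")
                counts[km] = int(c)
                k = len(km)
        if not counts:
            raise ValueError(f"empty spectrum file {path}")
        return cls(k=k, counts=counts)


@dataclass
class CorrectionPolicy:
    min_freq: int = 1000
    max_edits_per_read: int = 3
    quality_guided: bool = True

    def __post_init__(self) -> None:
        if self.min_freq < 1:
            raise ValueError("min_freq must be >= 1")
        if self.max_edits_per_read < 0:
            raise ValueError("max_edits_per_read must be >= 0")


def scaled_min_freq(expected_coverage: float, absolute_floor: int = 3) -> int:
    """Coverage-scaled weak-k-mer threshold (~4.4% of expected coverage)."""
    return max(absolute_floor, math.ceil(_THRESHOLD_RATIO * expected_coverage))


def count_kmers(reads: Iterable[ReadRecord], k: int = 15) -> KmerSpectrum:
    """Count every N-free window of length k once, canonically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    any_window = False
    for r in reads:
        seq = r.bases if isinstance(r, ReadRecord) else r
        if len(seq) < k:
            continue
        any_window = True
        counts.update(canonical_kmers(seq, k))
    if not any_window:
        raise ValueError(f"k={k} exceeds every read length")
    return KmerSpectrum(k=k, counts=dict(counts))


# ---------------------------------------------------------------------------
# Correction
# ---------------------------------------------------------------------------

def _weak_positions(seq: str, spec: KmerSpectrum, min_freq: int) -> list[int]:
    """Indices of k-mer windows whose count is below the threshold."""
    k = spec.k
    n = len(seq)
    rc = revcomp(seq)
    weak = []
    counts = spec.counts
    for i in range(n - k + 1):
        w = seq[i : i + k]
        w2 = rc[n - i - k : n - i]
        km = w if w <= w2 else w2
        if counts.get(km, 0) < min_freq:
            weak.append(i)
    return weak


def _covering_min(seq: str, pos: int, spec: KmerSpectrum, n: int) -> int:
    """Minimum spectrum count over the k-mers covering position ``pos``."""
    k = spec.k
    lo = max(0, pos - k + 1)
    hi = min(pos, n - k)
    best = None
    for i in range(lo, hi + 1):
        c = spec.get(seq[i : i + k])
        if best is None or c < best:
            best = c
            if best == 0:
                pass
    return best if best is not None else 0


def _covering_weak(seq: str, pos: int, spec: KmerSpectrum, min_freq: int, n: int) -> int:
    k = spec.k
    lo = max(0, pos - k + 1)
    hi = min(pos, n - k)
    return sum(1 for i in range(lo, hi + 1) if spec.get(seq[i : i + k]) < min_freq)


_ALT = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def correct_read(
    read: ReadRecord, spec: KmerSpectrum, policy: CorrectionPolicy
) -> tuple[ReadRecord, str]:
    """Greedy quality-ranked substitution correction against the spectrum.

    Returns (read, status) with status in {"clean", "corrected",
    "uncorrectable"}. Candidate positions inside the weak-k-mer region are
    tried lowest quality first; a substitution is accepted when it lifts every
    k-mer covering the position to ``min_freq`` or, failing that, when it
    strictly reduces the number of weak covering k-mers (the case of several
    errors inside one k-mer span). At most ``max_edits_per_read`` bases are
    changed; a read still carrying a weak k-mer is returned unmodified as
    uncorrectable. Read length never changes.
    """
    seq = read.bases
    n = len(seq)
    if n < spec.k:
        # too short to carry any k-mer evidence: treat as uncorrectable
        return read, "uncorrectable"
    min_freq = policy.min_freq
    if not _weak_positions(seq, spec, min_freq):
        return read, "clean"

    work = list(seq)
    edits = 0
    while edits < policy.max_edits_per_read:
        cur = "".join(work)
        weak = _weak_positions(cur, spec, min_freq)
        if not weak:
            break
        region = sorted({p for i in weak for p in range(i, i + spec.k)})
        if policy.quality_guided:
            region.sort(key=lambda p: (read.quals[p], p))
        accepted = False
        fallback: Optional[tuple[int, int, str]] = None  # (weak_count, pos, base)
        for p in region:
            base = work[p]
            cur_weak = _covering_weak(cur, p, spec, min_freq, n)
            if cur_weak == 0:
                continue
            for alt in _ALT[base]:
                cand = cur[:p] + alt + cur[p + 1 :]
                w = _covering_weak(cand, p, spec, min_freq, n)
                if w == 0:
                    work[p] = alt
                    edits += 1
                    accepted = True
                    break
                if w < cur_weak and (fallback is None or w < fallback[0]):
                    fallback = (w, p, alt)
            if accepted:
                break
        if not accepted and fallback is not None:
            _, p, alt = fallback
            work[p] = alt
            edits += 1
            accepted = True
        if not accepted:
            break

    fixed = "".join(work)
    if _weak_positions(fixed, spec, min_freq):
        return read, "uncorrectable"
    if fixed == seq:
        return read, "clean"
    return replace(read, bases=fixed), "corrected"


@dataclass
class FilterReport:
    total: int
    clean: int
    corrected: int
    excluded: int

    @property
    def excluded_fraction(self) -> float:
        return self.excluded / self.total if self.total else 0.0


def filter_reads(
    reads: Sequence[ReadRecord], spec: KmerSpectrum, policy: CorrectionPolicy
) -> tuple[list[ReadRecord], list[ReadRecord], FilterReport]:
    """Correct every read; keep clean ∪ corrected, exclude uncorrectable."""
    kept: list[ReadRecord] = []
    excluded: list[ReadRecord] = []
    n_clean = n_corr = 0
    for r in reads:
        fixed, status = correct_read(r, spec, policy)
        if status == "uncorrectable":
            excluded.append(r)
        else:
            kept.append(fixed)
            if status == "clean":
                n_clean += 1
            else:
                n_corr += 1
    report = FilterReport(
        total=len(reads), clean=n_clean, corrected=n_corr, excluded=len(excluded)
    )
    return kept, excluded, report


def filter_read_pairs(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    spec: KmerSpectrum,
    policy: CorrectionPolicy,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord], list[ReadRecord], FilterReport]:
    """Pairwise filtering: an excluded read orphans its mate into singles."""
    kept_pairs = []
    singles = []
    excluded = []
    n_clean = n_corr = 0
    for r1, r2 in pairs:
        f1, s1 = correct_read(r1, spec, policy)
        f2, s2 = correct_read(r2, spec, policy)
        for s in (s1, s2):
            if s == "clean":
                n_clean += 1
            elif s == "corrected":
                n_corr += 1
        ok1 = s1 != "uncorrectable"
        ok2 = s2 != "uncorrectable"
        if ok1 and ok2:
            kept_pairs.append((f1, f2))
        elif ok1:
            singles.append(f1)
            excluded.append(r2)
        elif ok2:
            singles.append(f2)
            excluded.append(r1)
        else:
            excluded.extend((r1, r2))
    total = 2 * len(pairs)
    report = FilterReport(total=total, clean=n_clean, corrected=n_corr, excluded=len(excluded))
    return kept_pairs, singles, excluded, report
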