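"""Reference-seeded extraction of mitochondrial reads by iterative k-mer baiting.

Plays the role iterative bait-and-map tools fill in organelle assembly: seed a
k-mer set from one or more reference mitogenomes, select every read pair
sharing at least ``min_shared`` k-mers with the bait, fold the selected reads'
k-mers back into the bait, and iterate until the selection stops growing. The
iterative extension is what lets the bait cross regions where the sample has
diverged from the references: reads overlapping an already-selected read are
recruited even if they share nothing with the original references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ._dna import canonical, forward_kmers, revcomp
from .seqio import GenomeSequence, ReadRecord

DEFAULT_BAIT_K = 31


@dataclass
class BaitSet:
    """A growing k-mer bait.

    ``kmers`` holds both orientations of every bait k-mer so that membership
    tests against plain forward read k-mers need no per-window
    canonicalization; ``canonical_kmers`` exposes the strand-collapsed view.
    """

    k: int
    kmers: set[str] = field(default_factory=set)
    iteration: int = 0
    sources: list[str] = field(default_factory=list)

    def add_sequence(self, seq: str) -> None:
        for km in forward_kmers(seq, self.k):
            self.kmers.add(km)
            self.kmers.add(revcomp(km))

    def canonical_kmers(self) -> set[str]:
        return {km for km in self.kmers if km <= revcomp(km)}

    def __len__(self) -> int:
        return len(self.canonical_kmers())


@dataclass
class BaitReport:
    reads_in: int
    reads_selected: int
    iterations: int
    selected_fraction: float
    iteration_of_selection: dict[str, int] = field(default_factory=dict)


def build_bait(references: Sequence[GenomeSequence], k: int = DEFAULT_BAIT_K) -> BaitSet:
    """Seed a bait from reference mitogenomes (N-containing k-mers skipped)."""
    if not references:
        raise ValueError("at least one reference is required")
    shortest = min(len(r) for r in references)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest reference length {shortest}")
    bs = BaitSet(k=k, sources=[r.id for r in references])
    for ref in references:
        bs.add_sequence(ref.bases)
    return bs


def bait_reads(
    pairs: Sequence[tuple[ReadRecord, Optional[ReadRecord]]],
    baitset: BaitSet,
    min_shared: int = 1,
    max_iter: int = 30,
    pair_rescue: bool = True,
) -> tuple[set[str], BaitSet, BaitReport]:
    """Iteratively select read pairs sharing k-mers with the bait.

    Returns (selected read ids, final bait, report). A selected read's mate is
    always rescued when ``pair_rescue`` (whole pairs feed the assembler). The
    selected set and the bait only grow; the loop stops when an iteration
    selects nothing new or ``max_iter`` is reached. Zero selections is a valid
    outcome.
    """
    k = baitset.k
    bait = baitset.kmers
    selected: set[str] = set()
    iteration_of: dict[str, int] = {}
    remaining = list(range(len(pairs)))
    it = 0
    while remaining and it < max_iter:
        it += 1
        newly: list[int] = []
        still: list[int] = []
        for idx in remaining:
            r1, r2 = pairs[idx]
            hit = _shares(r1.bases, bait, k, min_shared) or (
                r2 is not None and _shares(r2.bases, bait, k, min_shared)
            )
            if hit:
                newly.append(idx)
            else:
                still.append(idx)
        if not newly:
            break
        for idx in newly:
            r1, r2 = pairs[idx]
            members = [r1] + ([r2] if (r2 is not None and pair_rescue) else [])
            for r in members:
                selected.add(r.id)
                iteration_of[r.id] = it
            for r in members:
                bs_add = baitset.add_sequence
                bs_add(r.bases)
        remaining = still
    baitset.iteration = it
    n_in = sum(1 + (1 if p[1] is not None else 0) for p in pairs)
    report = BaitReport(
        reads_in=n_in,
        reads_selected=len(selected),
        iterations=it,
        selected_fraction=len(selected) / n_in if n_in else 0.0,
        iteration_of_selection=iteration_of,
    )
    return selected, baitset, report


def _shares(seq: str, bait: set[str], k: int, min_shared: int) -> bool:
    n = 0
    for km in forward_kmers(seq, k):
        if km in bait:
            n += 1
            if n >= min_shared:
                return True
    return False
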