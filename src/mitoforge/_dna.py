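"""Low-level DNA string helpers shared across the toolkit.

Everything here operates on plain Python strings over {A,C,G,T,N}; the hot
loops (k-mer canonicalization in particular) are written to avoid per-k-mer
reverse-complement calls by reverse-complementing whole reads once.
"""

from __future__ import annotations

from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def canonical_kmers(seq: str, k: int, skip_n: bool = True) -> Iterator[str]:
    """Yield canonical k-mers over every window of ``seq``.

    Windows containing N are skipped when ``skip_n``. The reverse complement
    of the whole sequence is computed once so each window costs two slices.
    """
    n = len(seq)
    if k < 1 or n < k:
        return
    rc = seq.translate(_COMPLEMENT)[::-1]
    if skip_n and "N" in seq:
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            w2 = rc[n - i - k : n - i]
            yield w if w <= w2 else w2
    else:
        for i in range(n - k + 1):
            w = seq[i : i + k]
            w2 = rc[n - i - k : n - i]
            yield w if w <= w2 else w2


def forward_kmers(seq: str, k: int, skip_n: bool = True) -> Iterator[str]:
    """Yield plain forward-strand k-mers (N windows skipped when asked)."""
    n = len(seq)
    if k < 1 or n < k:
        return
    has_n = skip_n and "N" in seq
    for i in range(n - k + 1):
        w = seq[i : i + k]
        if has_n and "N" in w:
            continue
        yield w


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def validate_dna(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{context} contains non-DNA characters: {sorted(bad)}")
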