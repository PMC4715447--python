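"""Supermatrix preparation from annotated mitogenomes.

Covers the downstream steps between annotation and tree inference: per-taxon
cross-validation of mitogenome genes against independently sequenced copies
(keep only taxa whose lowest per-gene identity is above 95%), per-gene
protein alignment (MAFFT), masking of long-gap columns with their flanking
regions of uncertain alignment, concatenation into a partitioned supermatrix,
and a neighbor-joining sanity tree on p-distances. Maximum-likelihood and
Bayesian inference run in external engines; the module exports relaxed
PHYLIP plus a partition table for them.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align

from .features import PCG_NAMES

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass
class MSA:
    """A per-gene multiple protein alignment keyed by taxon."""

    gene: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.gene}: empty alignment")
        lens = {len(s) for s in self.rows.values()}
        if len(lens) != 1:
            raise ValueError(f"{self.gene}: ragged alignment rows {sorted(lens)}")
        bad = set("".join(self.rows.values())) - AA_ALPHABET - {GAP, "X", "*"}
        if bad:
            raise ValueError(f"{self.gene}: unexpected characters {sorted(bad)}")

    def column(self, j: int) -> str:
        return "".join(self.rows[t][j] for t in self.rows)


@dataclass
class SuperMatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]   # (gene, start col, end col) 1-based incl.

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class IdentityReport:
    taxon: str
    per_gene: dict[str, float]
    verdict: str                            # keep | exclude | n.a.

    @property
    def min_identity(self) -> Optional[float]:
        return min(self.per_gene.values()) if self.per_gene else None


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _global_identity(a: str, b: str) -> float:
    """Percent identity of the best global alignment, gap columns excluded."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = comparable = 0
    for x, y in zip(s1, s2):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        return 0.0
    return 100.0 * matches / comparable


def crossvalidate(
    mito_genes: dict[str, dict[str, str]],
    independent_seqs: dict[str, dict[str, str]],
    threshold: float = 95.0,
) -> list[IdentityReport]:
    """Validate each taxon's mitogenome genes against independent sequences.

    ``mito_genes`` and ``independent_seqs`` map taxon → {gene → nucleotide
    sequence}. A taxon is excluded iff its minimum per-gene identity falls
    below ``threshold``; a taxon with no independent sequence at all gets the
    verdict "n.a." and is kept with a warning (the usual situation for newly
    sequenced species). The single-gene case is the COI-barcode check.
    """
    reports = []
    for taxon in sorted(mito_genes):
        genes = mito_genes[taxon]
        indep = independent_seqs.get(taxon, {})
        shared = {g: indep[g] for g in genes if g in indep}
        if not shared:
            reports.append(IdentityReport(taxon=taxon, per_gene={}, verdict="n.a."))
            continue
        per_gene = {g: _global_identity(genes[g], ref) for g, ref in sorted(shared.items())}
        verdict = "exclude" if min(per_gene.values()) < threshold else "keep"
        reports.append(IdentityReport(taxon=taxon, per_gene=per_gene, verdict=verdict))
    return reports


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_gene(
    protein_seqs: dict[str, str], gene: str = "gene", mafft_path: Optional[str] = None
) -> MSA:
    """Multiple protein alignment via MAFFT (deterministic, --auto).

    Requires at least two sequences. To import a pre-computed alignment use
    :func:`msa_from_rows`, which validates it instead.
    """
    if len(protein_seqs) < 2:
        raise ValueError("alignment requires at least two sequences")
    exe = mafft_path or shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.faa"
        with open(fin, "w") as fh:
            for taxon in protein_seqs:
                fh.write(f">{taxon}\n{protein_seqs[taxon]}\n")
        proc = subprocess.run(
            [exe, "--auto", "--amino", "--quiet", str(fin)],
            capture_output=True, text=True, check=True,
        )
    rows: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = ""
        elif name is not None:
            rows[name] += line.strip().upper()
    return MSA(gene=gene, rows=rows)


def msa_from_rows(gene: str, rows: dict[str, str]) -> MSA:
    """Wrap (and validate) an externally computed alignment."""
    return MSA(gene=gene, rows=dict(rows))


def mask_alignment(
    msa: MSA, max_gap_fraction: float = 0.5, flank: int = 3
) -> tuple[MSA, list[int]]:
    """Remove long-gap columns and their flanking regions.

    A column whose gap fraction exceeds ``max_gap_fraction`` is removed
    together with ``flank`` columns on each side of every removed run — the
    flanks being the surrounding regions whose alignment is uncertain.
    Returns (masked MSA, removed column indices, 0-based).
    """
    n = msa.ncols
    ntax = len(msa.rows)
    gappy = [
        j for j in range(n)
        if msa.column(j).count(GAP) / ntax > max_gap_fraction
    ]
    removed: set[int] = set()
    # expand each maximal run of gappy columns by the flank
    i = 0
    while i < len(gappy):
        j = i
        while j + 1 < len(gappy) and gappy[j + 1] == gappy[j] + 1:
            j += 1
        lo = max(0, gappy[i] - flank)
        hi = min(n - 1, gappy[j] + flank)
        removed.update(range(lo, hi + 1))
        i = j + 1
    keep = [j for j in range(n) if j not in removed]
    if not keep:
        raise ValueError(f"{msa.gene}: masking removed every column")
    rows = {t: "".join(s[j] for j in keep) for t, s in msa.rows.items()}
    return MSA(gene=msa.gene, rows=rows), sorted(removed)


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate(msas: Sequence[MSA]) -> tuple[SuperMatrix, list[str]]:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    Genes follow the canonical PCG order; taxa missing a gene are filled with
    gaps and flagged. A taxon present in no gene is an error by construction
    (it would be an all-gap row).
    """
    if not msas:
        raise ValueError("no alignments to concatenate")
    order = {g: i for i, g in enumerate(PCG_NAMES)}
    msas = sorted(msas, key=lambda m: (order.get(m.gene, len(order)), m.gene))
    taxa = sorted({t for m in msas for t in m.rows})
    flags: list[str] = []
    rows = {t: [] for t in taxa}
    partitions = []
    col = 1
    for m in msas:
        w = m.ncols
        for t in taxa:
            if t in m.rows:
                rows[t].append(m.rows[t])
            else:
                rows[t].append(GAP * w)
                flags.append(f"{t}: {m.gene} missing, gap-filled")
        partitions.append((m.gene, col, col + w - 1))
        col += w
    joined = {t: "".join(parts) for t, parts in rows.items()}
    for t, s in joined.items():
        if set(s) == {GAP}:
            raise ValueError(f"taxon {t} is present in no gene")
    return SuperMatrix(taxa=taxa, rows=joined, partitions=partitions), flags


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def p_distance_matrix(matrix: SuperMatrix) -> tuple[list[str], list[list[float]]]:
    """Pairwise p-distances (fraction of differing non-gap-pair columns)."""
    taxa = list(matrix.taxa)
    rows = [matrix.rows[t] for t in taxa]
    n = len(taxa)
    d = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            diff = comp = 0
            for x, y in zip(rows[i], rows[j]):
                if x == GAP or y == GAP:
                    continue
                comp += 1
                if x != y:
                    diff += 1
            if comp == 0:
                raise ValueError(
                    f"taxa {taxa[i]} and {taxa[j]} share no comparable columns"
                )
            d[i][j] = d[j][i] = diff / comp
    return taxa, d


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, children=None, length=0.0):
        self.name = name
        self.children = children or []
        self.length = length

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        if self.length:
            return f"({inner}):{self.length:.6f}"
        return f"({inner})"

    def sort_name(self) -> str:
        if not self.children:
            return self.name
        return min(c.sort_name() for c in self.children)


def nj_tree(matrix: SuperMatrix) -> str:
    """Neighbor-joining tree (Newick, unrooted) from supermatrix p-distances.

    Saitou–Nei agglomeration with negative branch lengths clamped to zero and
    ties broken by taxon-name order, so the result is deterministic.
    """
    taxa, d = p_distance_matrix(matrix)
    return nj_from_distances(taxa, d)


def nj_from_distances(taxa: Sequence[str], d: Sequence[Sequence[float]]) -> str:
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [_Node(name=t) for t in taxa]
    D = [list(row) for row in d]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                key = (q, nodes[i].sort_name(), nodes[j].sort_name())
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i][j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = _Node(children=[ni, nj_])
        # distances to the new node
        D.append([0.0] * len(D))
        for row in D:
            row.append(0.0)
        k = len(D) - 1
        for x in active:
            if x in (i, j):
                continue
            D[k][x] = D[x][k] = max(0.0, 0.5 * (D[i][x] + D[j][x] - D[i][j]))
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = max(0.0, 0.5 * (D[i][j] + D[i][k] - D[j][k]))
    lj = max(0.0, 0.5 * (D[i][j] + D[j][k] - D[i][k]))
    lk = max(0.0, 0.5 * (D[i][k] + D[j][k] - D[i][j]))
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = ln
    children = sorted((nodes[i], nodes[j], nodes[k]), key=_Node.sort_name)
    root = _Node(children=children)
    return root.newick() + ";"


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_phylip(matrix: SuperMatrix, path) -> None:
    """Relaxed sequential PHYLIP (taxon names unpadded, space-separated)."""
    with open(path, "w") as fh:
        fh.write(f" {len(matrix.taxa)} {matrix.ncols}\n")
        for t in matrix.taxa:
            fh.write(f"{t}  {matrix.rows[t]}\n")


def write_partitions(matrix: SuperMatrix, path) -> None:
    with open(path, "w") as fh:
        for gene, a, b in matrix.partitions:
            fh.write(f"PROT, {gene} = {a}-{b}\n")


def write_alignment_fasta(msa_or_matrix, path) -> None:
    rows = msa_or_matrix.rows
    with open(path, "w") as fh:
        for t in rows:
            fh.write(f">{t}\n{rows[t]}\n")
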