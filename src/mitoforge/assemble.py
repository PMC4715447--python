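"""Compact de Bruijn assembly of filtered reads, plus paired-end scaffolding.

This is a deliberately small assembler adequate for a single ~15 kb clonal
molecule at high coverage: canonical k-mer nodes, (k+1)-mer edges, pruning of
low-count nodes/edges, short-tip removal and equal-length bubble collapsing,
then maximal non-branching paths as contigs. A pure cycle (the expected shape
for a circular mitogenome) is emitted as a linear contig of exactly one
period, opened at the lexicographically smallest oriented k-mer so assembly
is deterministic in both rotation and strand.

Scaffolding orders and orients contigs with read-pair links (all reads, the
pre-filter pool included) and estimates gaps from the implied insert spans.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Optional, Sequence

from ._dna import canonical, canonical_kmers, revcomp
from .seqio import Library, ReadRecord

DEFAULT_K_ASM = 31

#: nominal insert size by library tag, for gap estimation
_INSERT_BY_LIBRARY = {Library.insert250: 250, Library.insert500: 500}


class InsufficientCoverageError(RuntimeError):
    pass


@dataclass
class DeBruijnGraph:
    k: int
    nodes: dict[str, int] = field(default_factory=dict)   # canonical k-mer -> count
    edges: dict[str, int] = field(default_factory=dict)   # canonical (k+1)-mer -> count

    def has_node(self, kmer: str) -> bool:
        return kmer in self.nodes or revcomp(kmer) in self.nodes

    def node_count(self, kmer: str) -> int:
        c = self.nodes.get(kmer)
        if c is None:
            c = self.nodes.get(revcomp(kmer), 0)
        return c

    def has_edge(self, emer: str) -> bool:
        return emer in self.edges or revcomp(emer) in self.edges

    def successors(self, oriented: str) -> list[str]:
        out = []
        suffix = oriented[1:]
        for b in "ACGT":
            if self.has_edge(oriented + b) and self.has_node(suffix + b):
                out.append(suffix + b)
        return out

    def predecessors(self, oriented: str) -> list[str]:
        out = []
        prefix = oriented[:-1]
        for b in "ACGT":
            if self.has_edge(b + oriented) and self.has_node(b + prefix):
                out.append(b + prefix)
        return out

    def drop(self, kmers: Iterable[str]) -> None:
        """Remove nodes (canonical keys) and their incident edges."""
        for km in kmers:
            self.nodes.pop(km, None)
            self.nodes.pop(revcomp(km), None)
        dead = []
        for e in self.edges:
            u, v = e[:-1], e[1:]
            if not (self.has_node(u) and self.has_node(v)):
                dead.append(e)
        for e in dead:
            del self.edges[e]


@dataclass
class Contig:
    id: str
    bases: str
    mean_coverage: float
    cycle_opened: bool = False

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Scaffold:
    """Ordered, oriented contigs with estimated gaps (encoded as N runs)."""

    id: str
    members: list[tuple[str, str, int]]  # (contig id, orientation, gap after)
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(
    reads: Sequence[ReadRecord],
    k_asm: int = DEFAULT_K_ASM,
    min_node_count: int = 3,
    prune_tips: bool = True,
    pop_bubbles: bool = True,
) -> DeBruijnGraph:
    """Canonical de Bruijn graph over the reads, pruned.

    Nodes and edges below ``min_node_count`` are dropped; tip branches shorter
    than 2·k bases are pruned; bubbles of equal length collapse to the
    higher-coverage path.
    """
    nodes: Counter = Counter()
    edges: Counter = Counter()
    for r in reads:
        seq = r.bases if isinstance(r, ReadRecord) else r
        nodes.update(canonical_kmers(seq, k_asm))
        edges.update(canonical_kmers(seq, k_asm + 1))
    g = DeBruijnGraph(
        k=k_asm,
        nodes={km: c for km, c in nodes.items() if c >= min_node_count},
        edges={e: c for e, c in edges.items() if c >= min_node_count},
    )
    if not g.nodes:
        raise InsufficientCoverageError("insufficient coverage: no k-mer survives pruning")
    # drop edges whose endpoints vanished
    g.drop([])
    if prune_tips:
        _prune_tips(g)
    if pop_bubbles:
        _pop_bubbles(g)
    if not g.nodes:
        raise InsufficientCoverageError("insufficient coverage: graph emptied by pruning")
    return g


def _unitigs(g: DeBruijnGraph) -> tuple[list[list[str]], list[list[str]]]:
    """Maximal non-branching oriented paths and pure cycles.

    Each unitig/cycle is reported once (canonical node sets are disjoint and
    cover the graph).
    """
    visited: set[str] = set()
    paths: list[list[str]] = []

    def is_start(o: str) -> bool:
        preds = g.predecessors(o)
        if len(preds) != 1:
            return True
        return len(g.successors(preds[0])) != 1

    for c in sorted(g.nodes):
        if c in visited:
            continue
        for o in (c, revcomp(c)):
            if not is_start(o):
                continue
            path = [o]
            seen = {canonical(o)}
            cur = o
            while True:
                succ = g.successors(cur)
                if len(succ) != 1:
                    break
                nxt = succ[0]
                if len(g.predecessors(nxt)) != 1:
                    break
                if canonical(nxt) in seen:
                    break
                path.append(nxt)
                seen.add(canonical(nxt))
                cur = nxt
            visited.update(canonical(x) for x in path)
            paths.append(path)
            break

    cycles: list[list[str]] = []
    for c in sorted(g.nodes):
        if c in visited:
            continue
        path = [c]
        visited.add(c)
        cur = c
        while True:
            succ = g.successors(cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if canonical(nxt) == canonical(path[0]):
                break
            if canonical(nxt) in visited and canonical(nxt) != canonical(path[0]):
                break
            path.append(nxt)
            visited.add(canonical(nxt))
            cur = nxt
        cycles.append(path)
    return paths, cycles


def _spell(path: Sequence[str]) -> str:
    return path[0] + "".join(x[-1] for x in path[1:])


def _prune_tips(g: DeBruijnGraph, rounds: int = 3) -> None:
    k = g.k
    for _ in range(rounds):
        paths, _ = _unitigs(g)
        doomed: list[str] = []
        for path in paths:
            start, end = path[0], path[-1]
            free_start = len(g.predecessors(start)) == 0
            free_end = len(g.successors(end)) == 0
            attached = (not free_start) or (not free_end)
            if (free_start or free_end) and attached and len(_spell(path)) < 2 * k:
                doomed.extend(canonical(x) for x in path)
        if not doomed:
            return
        g.drop(doomed)


def _pop_bubbles(g: DeBruijnGraph) -> None:
    paths, _ = _unitigs(g)
    groups: dict[tuple, list] = defaultdict(list)
    for path in paths:
        preds = frozenset(canonical(x) for x in g.predecessors(path[0]))
        succs = frozenset(canonical(x) for x in g.successors(path[-1]))
        if not preds or not succs:
            continue
        cov = sum(g.node_count(x) for x in path) / len(path)
        # orientation-insensitive anchor key
        key = (frozenset((preds, succs)), len(path))
        groups[key].append((cov, path))
    doomed: list[str] = []
    for key, members in groups.items():
        if len(members) < 2:
            continue
        members.sort(key=lambda t: (-t[0], _spell(t[1])))
        for cov, path in members[1:]:
            doomed.extend(canonical(x) for x in path)
    if doomed:
        g.drop(doomed)


# ---------------------------------------------------------------------------
# Contig extraction
# ---------------------------------------------------------------------------

def assemble_contigs(graph: DeBruijnGraph) -> list[Contig]:
    """Maximal non-branching paths as contigs; pure cycles opened canonically.

    A cycle of M nodes spells a circular sequence of M bases; the emitted
    linear contig is that one period starting at the lexicographically
    smallest oriented k-mer over both traversal directions (``cycle_opened``
    set).
    """
    if not graph.nodes:
        return []
    paths, cycles = _unitigs(graph)
    contigs: list[Contig] = []
    n = 0
    for path in paths:
        seq = _spell(path)
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
        cov = sum(graph.node_count(x) for x in path) / len(path)
        n += 1
        contigs.append(Contig(id=f"contig_{n}", bases=seq, mean_coverage=cov))
    for path in cycles:
        fwd = path
        rev = [revcomp(x) for x in reversed(path)]
        best = None
        for direction in (fwd, rev):
            m = min(direction)
            i = direction.index(m)
            rotated = direction[i:] + direction[:i]
            if best is None or rotated[0] < best[0]:
                best = rotated
        seq = _spell(best)[: len(path)]
        cov = sum(graph.node_count(x) for x in path) / len(path)
        n += 1
        contigs.append(Contig(id=f"contig_{n}", bases=seq, mean_coverage=cov, cycle_opened=True))
    contigs.sort(key=lambda c: (-len(c.bases), c.id))
    return contigs


# ---------------------------------------------------------------------------
# Scaffolding
# ---------------------------------------------------------------------------

def _seed_index(contigs: Sequence[Contig], k: int) -> dict[str, tuple[str, int]]:
    idx: dict[str, tuple[str, int]] = {}
    for c in contigs:
        for i in range(len(c.bases) - k + 1):
            idx.setdefault(c.bases[i : i + k], (c.id, i))
    return idx


def _place(seq: str, idx: dict, k: int) -> Optional[tuple[str, int, str]]:
    """(contig id, read-start position on contig, strand) by exact seeding."""
    for s, strand in ((seq, "+"), (revcomp(seq), "-")):
        for off in range(0, max(1, len(s) - k + 1), k):
            hit = idx.get(s[off : off + k])
            if hit is not None:
                cid, pos = hit
                return cid, pos - off, strand
    return None


def scaffold(
    contigs: Sequence[Contig],
    read_pairs_all: Sequence[tuple[ReadRecord, ReadRecord]],
    min_links: int = 5,
    seed_k: Optional[int] = None,
    insert_by_library: Optional[dict] = None,
) -> tuple[list[Scaffold], list[str]]:
    """Order and orient contigs by consistent read-pair links.

    Uses ALL read pairs (the pre-filter pool included), as the protocol
    specifies for the scaffolding step. Returns (scaffolds, warnings); orphan
    contigs come back as single-member scaffolds. Gap estimates are medians
    of the per-pair implied gaps, floored at 0 and encoded as N runs.
    """
    warnings: list[str] = []
    if not contigs:
        return [], warnings
    by_id = {c.id: c for c in contigs}
    if len(contigs) == 1:
        c = contigs[0]
        return [Scaffold(id="scaffold_1", members=[(c.id, "+", 0)], bases=c.bases)], warnings

    insert_by_library = insert_by_library or _INSERT_BY_LIBRARY
    k = seed_k or min(DEFAULT_K_ASM, min(len(c.bases) for c in contigs))
    idx = _seed_index(contigs, k)

    links: dict[tuple, list[int]] = defaultdict(list)
    for r1, r2 in read_pairs_all:
        insert = insert_by_library.get(r1.library)
        if insert is None:
            continue
        p1 = _place(r1.bases, idx, k)
        p2 = _place(r2.bases, idx, k)
        if p1 is None or p2 is None or p1[0] == p2[0]:
            continue
        (ca, pa, sa), (cb, pb, sb) = p1, p2
        ra, rb = len(r1.bases), len(r2.bases)
        if cb < ca:
            (ca, pa, sa, ra), (cb, pb, sb, rb) = (cb, pb, sb, rb), (ca, pa, sa, ra)
        la, lb = len(by_id[ca].bases), len(by_id[cb].bases)
        oa = sa
        tail_a = la - pa if sa == "+" else pa + ra
        ob = "+" if sb == "-" else "-"   # B's scaffold orientation
        tail_b = pb + rb if sb == "-" else lb - pb
        gap = insert - tail_a - tail_b
        links[(ca, oa, cb, ob)].append(gap)

    # merge mirror-image link keys (A+ B+ observed from B's side is A- B-)
    merged: dict[tuple, list[int]] = {}
    for key, gaps in links.items():
        ca, oa, cb, ob = key
        mirror = (ca, _flip(oa), cb, _flip(ob))
        tgt = mirror if mirror in merged else key
        merged.setdefault(tgt, []).extend(gaps)
    accepted = {k_: v for k_, v in merged.items() if len(v) >= min_links}

    # port graph: each contig has ports L and R in its + orientation
    port_of: dict[tuple, tuple] = {}

    def port(cid: str, orient: str, side: str) -> tuple:
        # side: 'out' = right end in scaffold orientation
        if orient == "+":
            return (cid, "R" if side == "out" else "L")
        return (cid, "L" if side == "out" else "R")

    best_for_port: dict[tuple, tuple] = {}
    for key, gaps in sorted(accepted.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        ca, oa, cb, ob = key
        pa_ = port(ca, oa, "out")
        pb_ = port(cb, ob, "in")
        if pa_ in best_for_port or pb_ in best_for_port:
            warnings.append(
                f"conflicting link {key} ({len(gaps)} pairs) ignored; "
                "best-supported layout kept"
            )
            continue
        gap = max(0, int(round(median(gaps))))
        best_for_port[pa_] = (pb_, gap)
        best_for_port[pb_] = (pa_, gap)

    # walk chains
    used: set[str] = set()
    scaffolds: list[Scaffold] = []

    def other_side(p: tuple) -> tuple:
        return (p[0], "L" if p[1] == "R" else "R")

    def chain_from(cid: str, entry_port: tuple) -> list[tuple[str, str, int]]:
        members = []
        cur_id, cur_entry = cid, entry_port
        while True:
            orient = "+" if cur_entry[1] == "L" else "-"
            used.add(cur_id)
            exit_port = other_side(cur_entry)
            nxt = best_for_port.get(exit_port)
            if nxt is None:
                members.append((cur_id, orient, 0))
                break
            (nid, nside), gap = nxt[0], nxt[1]
            if nid in used:
                members.append((cur_id, orient, 0))
                break
            members.append((cur_id, orient, gap))
            cur_id, cur_entry = nid, (nid, nside)
        return members

    for c in sorted(contigs, key=lambda c: (-len(c.bases), c.id)):
        if c.id in used:
            continue
        # find the chain start: walk backwards from this contig
        entry = (c.id, "L")
        seen = {c.id}
        while True:
            back = best_for_port.get(entry)
            if back is None:
                break
            (pid, pside), _ = back[0], back[1]
            if pid in seen:
                break
            seen.add(pid)
            entry = other_side((pid, pside))
        start_id = entry[0]
        members = chain_from(start_id, entry)
        seq_parts = []
        for j, (cid, orient, gap) in enumerate(members):
            s = by_id[cid].bases
            seq_parts.append(s if orient == "+" else revcomp(s))
            if gap and j < len(members) - 1:
                seq_parts.append("N" * gap)
        scaffolds.append(
            Scaffold(
                id=f"scaffold_{len(scaffolds) + 1}",
                members=members,
                bases="".join(seq_parts),
            )
        )
    return scaffolds, warnings


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"
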