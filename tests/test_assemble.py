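"""De Bruijn graph construction, contig extraction and paired-end scaffolding."""

import numpy as np
import pytest

from mitoforge._dna import canonical, revcomp
from mitoforge.assemble import (
    InsufficientCoverageError,
    Contig,
    assemble_contigs,
    build_graph,
    scaffold,
)
from mitoforge.seqio import GenomeSequence, Library, ReadRecord
from mitoforge.simulate import SimConfig, simulate_reads


def _read(rid, seq, library=Library.other):
    return ReadRecord(rid, seq, [35] * len(seq), library=library)


def _tile(seq, read_len=60, step=2, prefix="t"):
    return [
        _read(f"{prefix}{i}", seq[i : i + read_len])
        for i in range(0, len(seq) - read_len + 1, step)
    ]


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestBuildGraph:
    def test_linear_sequence_gives_single_path(self):
        seq = _random_seq(2000, 0)
        g = build_graph(_tile(seq), k_asm=31, min_node_count=3)
        # one non-branching path: every interior node has in=out=1
        contigs = assemble_contigs(g)
        assert len(contigs) == 1
        assert not contigs[0].cycle_opened

    def test_single_read_path_length(self):
        seq = _random_seq(80, 1)
        g = build_graph([_read("r", seq)] * 3, k_asm=31, min_node_count=3)
        assert len(g.nodes) == len(seq) - 31 + 1

    def test_circular_genome_gives_single_cycle(self):
        circle = _random_seq(1200, 2)
        doubled = circle + circle
        reads = _tile(doubled[: 1200 + 60], prefix="c")
        g = build_graph(reads, k_asm=31, min_node_count=3)
        contigs = assemble_contigs(g)
        assert len(contigs) == 1
        assert contigs[0].cycle_opened
        assert len(contigs[0].bases) == 1200

    def test_no_surviving_kmer_errors(self):
        with pytest.raises(InsufficientCoverageError):
            build_graph([_read("r", _random_seq(60, 3))], k_asm=31, min_node_count=3)

    def test_low_count_noise_pruned(self):
        seq = _random_seq(500, 4)
        noise = _read("noise", _random_seq(60, 5))
        g = build_graph(_tile(seq) + [noise], k_asm=31, min_node_count=3)
        for km in (noise.bases[i : i + 31] for i in range(len(noise.bases) - 30)):
            assert not g.has_node(km)


class TestAssembleContigs:
    def test_reconstructs_sequence(self):
        """Single contig spelling the source, minus low-count terminal k-mers."""
        seq = _random_seq(2000, 6)
        contigs = assemble_contigs(build_graph(_tile(seq), k_asm=31))
        assert len(contigs) == 1
        got = contigs[0].bases
        assert got in seq or revcomp(got) in seq
        assert len(got) >= len(seq) - 10

    def test_circular_reconstruction_up_to_rotation(self):
        circle = _random_seq(1500, 7)
        reads = _tile(circle + circle[:60], prefix="c")
        contigs = assemble_contigs(build_graph(reads, k_asm=31))
        got = contigs[0].bases
        assert len(got) == 1500
        assert got in circle + circle or revcomp(got) in circle + circle

    def test_repeat_splits_into_three_contigs(self):
        """A genome s1-R-s2-R-s3 with |R| >= k breaks at the repeat."""
        s1, s2, s3 = _random_seq(300, 8), _random_seq(300, 9), _random_seq(300, 10)
        R = _random_seq(60, 11)
        seq = s1 + R + s2 + R + s3
        contigs = assemble_contigs(build_graph(_tile(seq), k_asm=31, prune_tips=False))
        # hand-derived path rule: unique segments split at the repeat node,
        # the repeat itself becomes one contig -> s1+, R, s2, s3-side pieces
        assert len(contigs) >= 3
        joined = "|".join(sorted(c.bases if c.bases < revcomp(c.bases) else revcomp(c.bases) for c in contigs))
        assert canonical(R[14 : 14 + 31]) in {
            canonical(c.bases[i : i + 31])
            for c in contigs
            for i in range(len(c.bases) - 30)
        }

    def test_matches_independent_unitig_oracle(self):
        """Contig set equals maximal non-branching paths found independently.

        Oracle: build the bidirected graph with networkx over oriented k-mers
        and extract maximal paths by the in/out-degree definition.
        """
        import networkx as nx

        seq = _random_seq(400, 12)
        R = _random_seq(45, 13)
        genome = seq[:150] + R + seq[150:300] + R + seq[300:]
        k = 31
        g = build_graph(_tile(genome), k_asm=k, prune_tips=False, pop_bubbles=False)

        dg = nx.DiGraph()
        oriented = set()
        for km in g.nodes:
            oriented.add(km)
            oriented.add(revcomp(km))
        for u in oriented:
            for v in (u[1:] + b for b in "ACGT"):
                if v in oriented and g.has_edge(u + v[-1]):
                    dg.add_edge(u, v)
        for u in oriented:
            dg.add_node(u)

        def starts():
            for u in dg.nodes:
                preds = list(dg.predecessors(u))
                if len(preds) != 1 or len(list(dg.successors(preds[0]))) != 1:
                    yield u

        oracle = set()
        for u in starts():
            path = [u]
            while True:
                succ = list(dg.successors(path[-1]))
                if len(succ) != 1:
                    break
                v = succ[0]
                if len(list(dg.predecessors(v))) != 1 or v == path[0]:
                    break
                path.append(v)
            seq_ = path[0] + "".join(x[-1] for x in path[1:])
            oracle.add(min(seq_, revcomp(seq_)))

        got = {min(c.bases, revcomp(c.bases)) for c in assemble_contigs(g)}
        assert got == oracle

    def test_empty_graph_gives_no_contigs(self):
        from mitoforge.assemble import DeBruijnGraph

        assert assemble_contigs(DeBruijnGraph(k=31)) == []

    def test_bubble_collapses_to_higher_coverage_path(self):
        seq = _random_seq(600, 14)
        alt = list(seq)
        alt[300] = [b for b in "ACGT" if b != alt[300]][0]
        alt = "".join(alt)
        reads = _tile(seq) * 3 + _tile(alt, prefix="alt")
        contigs = assemble_contigs(build_graph(reads, k_asm=31))
        assert len(contigs) == 1
        got = contigs[0].bases
        assert got == seq or got == revcomp(seq)


@pytest.fixture(scope="module")
def gapped_instance():
    """Two contigs from one genome separated by a 100 bp unassembled gap."""
    genome = GenomeSequence(
        id="g", bases=_random_seq(4000, 20), topology="circular"
    )
    cfg = SimConfig(seed=21, coverage=60, insert_means=(500,), sub_error_rate=0.0)
    pairs = simulate_reads(genome, cfg)["insert500"]
    a = genome.bases[0:1900]
    b = genome.bases[2000:3900]
    contigs = [
        Contig(id="A", bases=a, mean_coverage=60.0),
        Contig(id="B", bases=b, mean_coverage=60.0),
    ]
    return genome, contigs, pairs


class TestScaffold:

    def test_gap_estimate_within_20bp(self, gapped_instance):
        genome, contigs, pairs = gapped_instance
        scaffolds, warns = scaffold(contigs, pairs)
        assert len(scaffolds) == 1
        (c1, o1, gap1), (c2, o2, gap2) = scaffolds[0].members
        assert abs(gap1 - 100) <= 20
        n_run = scaffolds[0].bases.count("N")
        assert abs(n_run - 100) <= 20

    def test_order_and_orientation_recovered(self, gapped_instance):
        genome, contigs, pairs = gapped_instance
        scaffolds, _ = scaffold(contigs, pairs)
        members = scaffolds[0].members
        names = [m[0] for m in members]
        orients = [m[1] for m in members]
        assert names in (["A", "B"], ["B", "A"])
        if names == ["A", "B"]:
            assert orients == ["+", "+"]
        else:
            assert orients == ["-", "-"]

    def test_single_contig_identity(self):
        c = Contig(id="solo", bases=_random_seq(500, 22), mean_coverage=10.0)
        scaffolds, _ = scaffold([c], [])
        assert len(scaffolds) == 1 and scaffolds[0].bases == c.bases

    def test_unrelated_genomes_stay_separate(self):
        g1 = GenomeSequence(id="g1", bases=_random_seq(3000, 23), topology="circular")
        g2 = GenomeSequence(id="g2", bases=_random_seq(3000, 24), topology="circular")
        cfg = SimConfig(seed=25, coverage=40, insert_means=(250,), sub_error_rate=0.0)
        pairs = simulate_reads(g1, cfg)["insert250"] + simulate_reads(g2, cfg)["insert250"]
        contigs = [
            Contig(id="c1", bases=g1.bases[:2800], mean_coverage=40.0),
            Contig(id="c2", bases=g2.bases[:2800], mean_coverage=40.0),
        ]
        scaffolds, _ = scaffold(contigs, pairs)
        assert len(scaffolds) == 2


def test_contig_is_a_walk_in_the_graph(truth_genome):
    """Internal consistency: every adjacent k-mer pair of a contig is an edge."""
    reads = _tile(truth_genome.bases[:3000], read_len=100, step=3)
    g = build_graph(reads, k_asm=31)
    for c in assemble_contigs(g):
        k = g.k
        for i in range(len(c.bases) - k):
            assert g.has_node(c.bases[i : i + k])
            assert g.has_edge(c.bases[i : i + k + 1])
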