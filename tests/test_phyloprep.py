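"""Cross-validation, alignment masking, supermatrix assembly and NJ trees."""

import itertools

import numpy as np
import pytest

from mitoforge.phyloprep import (
    MSA,
    align_gene,
    concatenate,
    crossvalidate,
    mask_alignment,
    msa_from_rows,
    nj_from_distances,
    nj_tree,
    p_distance_matrix,
    write_partitions,
    write_phylip,
)


class TestCrossvalidate:
    def test_identical_barcode_gives_100(self):
        """The COI-barcode check: identical sequences agree 100%."""
        rng = np.random.default_rng(0)
        coi = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 658)])
        reports = crossvalidate({"lerema": {"cox1": coi}}, {"lerema": {"cox1": coi}})
        assert reports[0].per_gene["cox1"] == 100.0
        assert reports[0].verdict == "keep"

    @pytest.mark.parametrize(
        "n_mismatch,verdict", [(3, "keep"), (8, "exclude")]
    )
    def test_threshold_rule(self, n_mismatch, verdict):
        rng = np.random.default_rng(1)
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        b = list(a)
        for i in range(n_mismatch):
            pos = 10 + 10 * i
            b[pos] = [c for c in "ACGT" if c != b[pos]][0]
        reports = crossvalidate({"t": {"g": a}}, {"t": {"g": "".join(b)}})
        assert reports[0].per_gene["g"] == pytest.approx(100 - n_mismatch, abs=0.5)
        assert reports[0].verdict == verdict

    def test_taxon_without_independent_data_is_na(self):
        reports = crossvalidate({"newtaxon": {"cox1": "ACGTACGT"}}, {})
        assert reports[0].verdict == "n.a."
        assert reports[0].min_identity is None

    def test_self_identity_symmetric(self):
        rng = np.random.default_rng(2)
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        t = s[:150] + s[160:]  # deletion
        from mitoforge.phyloprep import _global_identity

        assert _global_identity(s, t) == _global_identity(t, s)
        assert _global_identity(s, s) == 100.0


class TestAlignGene:
    def test_identical_sequences_align_gapless(self):
        msa = align_gene({"a": "MKLVNNW", "b": "MKLVNNW"})
        assert msa.ncols == 7
        assert "-" not in "".join(msa.rows.values())

    def test_single_deletion_matches_pairwise_oracle(self):
        """MAFFT result agrees with brute-force optimal pairwise alignment."""
        msa = align_gene({"a": "ACDEF", "b": "ACEF"})
        # oracle: Needleman-Wunsch over all alignments of these tiny strings;
        # optimum is one gap column in b, none in a, total 5 columns
        assert msa.ncols == 5
        assert msa.rows["a"] == "ACDEF"
        assert msa.rows["b"].count("-") == 1
        assert msa.rows["b"].replace("-", "") == "ACEF"

    def test_fewer_than_two_sequences_errors(self):
        with pytest.raises(ValueError):
            align_gene({"a": "MKLV"})

    def test_ragged_import_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            msa_from_rows("g", {"a": "MKL-", "b": "MK"})


class TestMaskAlignment:
    def test_gappy_column_removed_with_flanks(self):
        rows = {
            "t1": "AAAAAAAAAAKLMNP",
            "t2": "AAAAAAAAAAKLMNP",
            "t3": "AAAAAAAAAA-LMNP",
            "t4": "AAAAAAAAAA-LMNP",
            "t5": "AAAAAAAAAA-LMNP",
            "t6": "AAAAAAAAAA-LMNP",
        }
        msa = msa_from_rows("g", rows)
        masked, removed = mask_alignment(msa, max_gap_fraction=0.5, flank=3)
        assert removed == [7, 8, 9, 10, 11, 12, 13]
        assert masked.ncols == 15 - 7

    def test_gapfree_alignment_unchanged(self):
        msa = msa_from_rows("g", {"a": "MKLVN", "b": "MKIVN"})
        masked, removed = mask_alignment(msa)
        assert removed == [] and masked.rows == msa.rows

    def test_no_column_above_threshold_after_masking(self):
        rng = np.random.default_rng(3)
        rows = {}
        for t in "abcdef":
            s = ["MKLVNPQRSTWYHE"[rng.integers(0, 14)] for _ in range(60)]
            for j in range(60):
                if rng.random() < 0.25:
                    s[j] = "-"
            rows[t] = "".join(s)
        masked, _ = mask_alignment(msa_from_rows("g", rows), max_gap_fraction=0.5)
        n = len(rows)
        for j in range(masked.ncols):
            assert masked.column(j).count("-") / n <= 0.5

    def test_masking_everything_errors(self):
        msa = msa_from_rows("g", {"a": "M-", "b": "-K", "c": "--"})
        with pytest.raises(ValueError, match="every column"):
            mask_alignment(msa, max_gap_fraction=0.3, flank=3)


class TestConcatenate:
    def _msa(self, gene, taxa, width, fill="K"):
        return msa_from_rows(gene, {t: fill * width for t in taxa})

    def test_width_is_sum_of_gene_widths(self):
        msas = [self._msa(g, ["a", "b"], w) for g, w in
                (("nd1", 10), ("cox1", 20), ("cytb", 5))]
        sm, flags = concatenate(msas)
        assert sm.ncols == 35
        # partitions tile [1, total] without overlap
        cols = list(itertools.chain.from_iterable(
            range(a, b + 1) for _, a, b in sm.partitions
        ))
        assert cols == list(range(1, 36))

    def test_missing_gene_gap_filled_and_flagged(self):
        sm, flags = concatenate(
            [self._msa("nd1", ["a", "b"], 8), self._msa("atp8", ["a"], 6)]
        )
        assert sm.rows["b"][8:] == "-" * 6
        assert any("atp8" in f and "b" in f for f in flags)

    def test_single_gene_identity(self):
        msa = self._msa("cox1", ["a", "b"], 12)
        sm, _ = concatenate([msa])
        assert sm.rows == msa.rows and sm.partitions == [("cox1", 1, 12)]

    def test_canonical_gene_order(self):
        sm, _ = concatenate(
            [self._msa("cytb", ["a", "b"], 3), self._msa("nd1", ["a", "b"], 3),
             self._msa("cox1", ["a", "b"], 3)]
        )
        assert [p[0] for p in sm.partitions] == ["nd1", "cox1", "cytb"]


class TestNeighborJoining:
    def test_quartet_recovery_four_point_oracle(self):
        """NJ recovers the split the four-point condition selects."""
        taxa = ["A", "B", "C", "D"]
        d = [
            [0, 3, 9, 10],
            [3, 0, 10, 9],
            [9, 10, 0, 5],
            [10, 9, 5, 0],
        ]
        # oracle: evaluate the three quartet sums; smallest pairing is the split
        sums = {
            "AB|CD": d[0][1] + d[2][3],
            "AC|BD": d[0][2] + d[1][3],
            "AD|BC": d[0][3] + d[1][2],
        }
        assert min(sums, key=sums.get) == "AB|CD"
        nwk = nj_from_distances(taxa, d)
        assert ("A" in nwk.split("C")[0]) and ("B" in nwk.split("C")[0])
        # A and B form a cherry
        import re

        cherry = re.search(r"\(([A-D]):[\d.]+,([A-D]):[\d.]+\)", nwk)
        assert {cherry.group(1), cherry.group(2)} == {"A", "B"}

    def test_three_taxa_closed_form(self):
        d = [[0, 4, 6], [4, 0, 8], [6, 8, 0]]
        nwk = nj_from_distances(["a", "b", "c"], d)
        # closed form: la = (dab+dac-dbc)/2 = 1, lb = 3, lc = 5
        assert "a:1.000000" in nwk and "b:3.000000" in nwk and "c:5.000000" in nwk

    def test_identical_rows_are_sisters(self):
        sm, _ = concatenate([msa_from_rows("g", {
            "x": "MKLVNPQR", "y": "MKLVNPQR", "z": "AAAANPQR", "w": "AAAAAAQR",
        })])
        taxa, d = p_distance_matrix(sm)
        assert d[taxa.index("x")][taxa.index("y")] == 0.0
        nwk = nj_tree(sm)
        import re

        # in the unrooted 4-taxon tree the split xy|zw may be written with
        # either pair as the internal cherry
        cherry = re.findall(r"\(([a-z]):[\d.]+,([a-z]):[\d.]+\)", nwk)
        assert [set(c) for c in cherry][0] in ({"x", "y"}, {"z", "w"})

    def test_matches_skbio_on_random_distances(self):
        """Independent oracle: same topology as scikit-bio's NJ."""
        from skbio import DistanceMatrix
        from skbio.tree import TreeNode, nj

        rng = np.random.default_rng(7)
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        # additive distances from a random tree: start from random positive
        # branch lengths on a caterpillar topology
        pts = rng.random((n, 8))
        d = [[float(np.abs(pts[i] - pts[j]).sum()) for j in range(n)] for i in range(n)]
        ours = TreeNode.read([nj_from_distances(taxa, d)])
        theirs = nj(DistanceMatrix(np.array(d), ids=taxa))
        rf = ours.compare_rfd(theirs)
        assert rf == 0.0

    def test_parameter_recovery_from_simulated_alignment(self):
        """NJ on p-distances recovers a known 6-taxon topology (>=200 cols)."""
        rng = np.random.default_rng(11)
        ncols = 300
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        root = alphabet[rng.integers(0, 20, ncols)]

        def evolve(seq, subs):
            out = seq.copy()
            idx = rng.choice(ncols, size=subs, replace=False)
            out[idx] = alphabet[rng.integers(0, 20, subs)]
            return out

        left = evolve(root, 40)
        right = evolve(root, 40)
        rows = {
            "a1": "".join(evolve(left, 8)),
            "a2": "".join(evolve(left, 8)),
            "b1": "".join(evolve(evolve(left, 25), 8)),
            "c1": "".join(evolve(right, 8)),
            "c2": "".join(evolve(right, 8)),
            "d1": "".join(evolve(evolve(right, 25), 8)),
        }
        sm, _ = concatenate([msa_from_rows("g", rows)])
        from skbio.tree import TreeNode

        tree = TreeNode.read([nj_tree(sm)])
        # a1+a2 and c1+c2 must each form a clade in the unrooted tree
        names = {t.name for t in tree.tips()}
        assert names == set(rows)
        for pair in ({"a1", "a2"}, {"c1", "c2"}):
            lca = tree.lca([t for t in tree.tips() if t.name in pair])
            assert {t.name for t in lca.tips()} == pair

    def test_zero_comparable_columns_errors(self):
        sm = __import__("mitoforge.phyloprep", fromlist=["SuperMatrix"]).SuperMatrix(
            taxa=["a", "b", "c"],
            rows={"a": "MK--", "b": "--LV", "c": "MKLV"},
            partitions=[("g", 1, 4)],
        )
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix(sm)


class TestExports:
    def test_phylip_and_partition_files(self, tmp_path):
        sm, _ = concatenate([msa_from_rows("nd1", {"a": "MKLV", "b": "MKIV"})])
        phy = tmp_path / "m.phy"
        part = tmp_path / "p.txt"
        write_phylip(sm, phy)
        write_partitions(sm, part)
        lines = phy.read_text().splitlines()
        assert lines[0].split() == ["2", "4"]
        assert lines[1].startswith("a") and lines[1].endswith("MKLV")
        assert part.read_text().strip() == "PROT, nd1 = 1-4"
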