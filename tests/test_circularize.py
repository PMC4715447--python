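"""Terminal-state detection, junction closure by read vote, and rotation."""

import numpy as np
import pytest

from mitoforge._dna import revcomp
from mitoforge.circularize import (
    AmbiguousAnchorError,
    ClosureTieError,
    close_circle,
    detect_terminal_state,
    rotate_to_gene,
)
from mitoforge.seqio import GenomeSequence


def _open_circle(circle: str, missing: int = 0) -> GenomeSequence:
    """Linear draft of a circle, optionally missing bases at the junction."""
    if missing:
        return GenomeSequence(id="draft", bases=circle[: len(circle) - missing])
    return GenomeSequence(id="draft", bases=circle)


class TestDetectTerminalState:
    def test_redundant_termini(self, truth_genome):
        circle = truth_genome.bases
        draft = GenomeSequence(id="d", bases=circle + circle[:40])
        state, overlap = detect_terminal_state(draft)
        assert state == "redundant" and overlap == 40

    def test_missing_fragment_is_gap_state(self, truth_genome):
        draft = _open_circle(truth_genome.bases, missing=6)
        assert detect_terminal_state(draft) == ("gap", None)

    def test_perfectly_opened_circle_is_gap_state(self, truth_genome):
        draft = _open_circle(truth_genome.bases)
        assert detect_terminal_state(draft) == ("gap", None)

    def test_short_draft_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_terminal_state(GenomeSequence(id="d", bases="ACGT" * 10))


class TestCloseCircle:
    def test_redundant_draft_trimmed(self, truth_genome, clean_read_pairs):
        circle = truth_genome.bases
        draft = GenomeSequence(id="d", bases=circle + circle[:40])
        closed, rep = close_circle(draft, [r for a, b in clean_read_pairs[:50] for r in (a, b)])
        assert rep.state == "redundant" and rep.trimmed_bp == 40
        assert closed.bases == circle

    def test_missing_fragment_recovered_errorfree(self, truth_genome, clean_read_pairs):
        """Error-free reads: the 6 bp insert is unanimous (majority = 1.0)."""
        draft = _open_circle(truth_genome.bases, missing=6)
        reads = [r for a, b in clean_read_pairs for r in (a, b)]
        closed, rep = close_circle(draft, reads)
        assert rep.state == "gap"
        assert rep.inserted_fragment == truth_genome.bases[-6:]
        assert rep.majority_fraction == 1.0
        assert closed.topology == "circular"
        assert closed.bases in truth_genome.bases * 2

    def test_missing_fragment_with_errors_majority_vote(self, truth_genome, read_pairs):
        """1% substitution errors: truth still wins with majority > 0.9."""
        draft = _open_circle(truth_genome.bases, missing=6)
        reads = [r for a, b in read_pairs for r in (a, b)]
        closed, rep = close_circle(draft, reads)
        assert rep.inserted_fragment == truth_genome.bases[-6:]
        assert rep.majority_fraction > 0.9
        assert rep.minor_variants  # error reads show up as minor variants

    def test_exact_draft_closes_with_empty_fragment(self, truth_genome, clean_read_pairs):
        draft = _open_circle(truth_genome.bases)
        reads = [r for a, b in clean_read_pairs for r in (a, b)]
        closed, rep = close_circle(draft, reads)
        assert rep.state == "exact" and rep.inserted_fragment == ""
        assert closed.bases == truth_genome.bases

    def test_vote_conservation(self, truth_genome, read_pairs):
        draft = _open_circle(truth_genome.bases, missing=6)
        reads = [r for a, b in read_pairs for r in (a, b)]
        _, rep = close_circle(draft, reads)
        top = round(rep.majority_fraction * rep.supporting_reads)
        assert top + sum(c for _, c in rep.minor_variants) == rep.supporting_reads
        assert 0 < rep.majority_fraction <= 1

    def test_length_accounting(self, truth_genome, clean_read_pairs):
        reads = [r for a, b in clean_read_pairs for r in (a, b)]
        for missing in (0, 6):
            draft = _open_circle(truth_genome.bases, missing=missing)
            closed, rep = close_circle(draft, reads)
            assert len(closed) == len(draft) - rep.trimmed_bp + len(rep.inserted_fragment)

    def test_no_junction_reads_returns_linear_draft(self, truth_genome):
        draft = _open_circle(truth_genome.bases, missing=6)
        closed, rep = close_circle(draft, [])
        assert not rep.closed and closed.topology == "linear"
        assert closed.bases == draft.bases

    def test_repeated_anchor_raises_ambiguity(self):
        rng = np.random.default_rng(0)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        anchor = core[:32]
        draft = GenomeSequence(id="d", bases=anchor + core[32:300] + anchor + core[300:])
        with pytest.raises(AmbiguousAnchorError):
            close_circle(draft, [])

    def test_tie_demands_manual_review(self, truth_genome):
        from mitoforge.seqio import ReadRecord

        circle = truth_genome.bases
        draft = _open_circle(circle, missing=6)
        a3, a5 = draft.bases[-32:], draft.bases[:32]
        r_true = ReadRecord("t", a3 + circle[-6:] + a5, [35] * 70)
        r_alt = ReadRecord("x", a3 + "AAAAAA" + a5, [35] * 70)
        with pytest.raises(ClosureTieError):
            close_circle(draft, [r_true, r_alt])


class TestRotateToGene:
    def test_rotation_starts_at_probe(self, truth_genome, truth_ann):
        # open the circle at an arbitrary rotation, then rotate to trnM
        circle = GenomeSequence(
            id="c", bases=truth_genome.bases[5000:] + truth_genome.bases[:5000],
            topology="circular",
        )
        probe = truth_ann.get("trnM").extract(truth_genome.bases)
        rotated = rotate_to_gene(circle, probe)
        assert rotated.bases == truth_genome.bases  # trnM is position 1 in truth
        assert len(rotated) == len(circle)

    def test_minus_strand_probe_flips(self, truth_genome, truth_ann):
        probe = truth_ann.get("trnM").extract(truth_genome.bases)
        flipped = GenomeSequence(
            id="c", bases=revcomp(truth_genome.bases), topology="circular"
        )
        rotated = rotate_to_gene(flipped, probe)
        assert rotated.bases == truth_genome.bases

    def test_idempotent(self, truth_genome, truth_ann):
        probe = truth_ann.get("trnM").extract(truth_genome.bases)
        once = rotate_to_gene(truth_genome, probe)
        assert rotate_to_gene(once, probe).bases == once.bases == truth_genome.bases

    def test_probe_absent_errors(self, truth_genome):
        with pytest.raises(ValueError, match="not found"):
            rotate_to_gene(truth_genome, "GC" * 20)

    def test_duplicated_probe_errors(self):
        rng = np.random.default_rng(1)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        probe = core[:40]
        circle = GenomeSequence(
            id="c", bases=core + probe + core[200:], topology="circular"
        )
        with pytest.raises(ValueError, match="ambiguous"):
            rotate_to_gene(circle, probe)


def test_rotation_invariance_of_assembly(truth_genome):
    """Assembly + closure of any rotation matches truth up to rotation/strand."""
    from mitoforge.assemble import assemble_contigs, build_graph
    from mitoforge.simulate import SimConfig, simulate_reads

    doubled = truth_genome.bases * 2
    for offset in (4000, 11000):
        rot = GenomeSequence(
            id="r", bases=truth_genome.bases[offset:] + truth_genome.bases[:offset],
            topology="circular",
        )
        cfg = SimConfig(seed=33, coverage=60, sub_error_rate=0.0)
        pairs = [p for lib in simulate_reads(rot, cfg).values() for p in lib]
        reads = [r for a, b in pairs for r in (a, b)]
        contigs = assemble_contigs(build_graph(reads, k_asm=31))
        assert len(contigs) == 1 and contigs[0].cycle_opened
        draft = GenomeSequence(id="d", bases=contigs[0].bases)
        closed, rep = close_circle(draft, reads)
        assert closed.bases in doubled or revcomp(closed.bases) in doubled
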