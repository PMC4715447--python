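"""End-to-end orchestration: reads → closed, rotated, annotated mitogenome.

Thin glue over the stage modules, in protocol order: quality trimming,
reference baiting, 15-mer spectrum correction/filtering, de Bruijn assembly,
paired-end scaffolding (all reads, pre-filter pool included), circular
closure by terminal-anchor vote, and rotation to trnM(cau) when a probe is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assemble import assemble_contigs, build_graph, scaffold
from .bait import build_bait, bait_reads
from .circularize import ClosureReport, close_circle, rotate_to_gene
from .kmer import CorrectionPolicy, count_kmers, filter_reads, scaled_min_freq
from .seqio import GenomeSequence, ReadRecord, trim_read


@dataclass
class PipelineResult:
    genome: GenomeSequence
    closure: ClosureReport
    n_pairs_in: int
    n_reads_baited: int
    bait_iterations: int
    n_reads_kept: int
    n_reads_excluded: int
    min_freq: int
    n_contigs: int
    warnings: list[str] = field(default_factory=list)


def assemble_mitogenome(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    references: Sequence[GenomeSequence],
    qmin: int = 20,
    bait_k: int = 31,
    spectrum_k: int = 15,
    k_asm: int = 31,
    min_freq: Optional[int] = None,
    expected_coverage: Optional[float] = None,
    anchor_len: int = 32,
    rotate_probe: Optional[str] = None,
) -> PipelineResult:
    """Run the full assembly protocol on a paired-end read pool.

    ``min_freq`` defaults to the coverage-scaled weak-k-mer threshold; pass
    ``expected_coverage`` (fold) to drive the scaling, otherwise it is
    estimated from the baited read mass and the mean reference length.
    """
    trimmed = [(trim_read(a, qmin), trim_read(b, qmin)) for a, b in pairs]
    baitset = build_bait(references, k=bait_k)
    selected_ids, _, bait_rep = bait_reads(trimmed, baitset)
    selected = [r for a, b in trimmed for r in (a, b) if r.id in selected_ids]

    if min_freq is None:
        if expected_coverage is None:
            ref_len = sum(len(r) for r in references) / len(references)
            mass = sum(len(r) for r in selected)
            expected_coverage = mass / ref_len
        min_freq = scaled_min_freq(expected_coverage)

    spectrum = count_kmers(selected, k=spectrum_k)
    policy = CorrectionPolicy(min_freq=min_freq)
    kept, excluded, filt_rep = filter_reads(selected, spectrum, policy)

    graph = build_graph(kept, k_asm=k_asm)
    contigs = assemble_contigs(graph)
    if len(contigs) > 10 and k_asm > 25:
        # AT-rich genomes can fragment at large k; retry once at k=25
        graph = build_graph(kept, k_asm=25)
        contigs = assemble_contigs(graph)
    scaffolds, warns = scaffold(contigs, pairs)
    scaffolds.sort(key=lambda s: -len(s.bases))
    draft = GenomeSequence(id="draft", bases=scaffolds[0].bases)

    all_reads = [r for a, b in pairs for r in (a, b)]
    circle, closure = close_circle(draft, all_reads, anchor_len=anchor_len)
    if rotate_probe is not None and closure.closed:
        circle = rotate_to_gene(circle, rotate_probe)

    return PipelineResult(
        genome=circle,
        closure=closure,
        n_pairs_in=len(pairs),
        n_reads_baited=bait_rep.reads_selected,
        bait_iterations=bait_rep.iterations,
        n_reads_kept=len(kept),
        n_reads_excluded=filt_rep.excluded,
        min_freq=min_freq,
        n_contigs=len(contigs),
        warnings=warns,
    )
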