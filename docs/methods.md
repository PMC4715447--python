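# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitoforge`, and what the simulation-based tests do and do not
demonstrate about real data.

## The problem setting

Insect mitogenomes are circular molecules of ~14–19 kb encoding 13 proteins,
22 tRNAs, 2 rRNAs and an A+T-rich control region. In a whole-genome shotgun
run the organelle is sequenced at a coverage several orders of magnitude above
the nuclear genome, which breaks the assumptions of general-purpose
assemblers in two ways: mitochondrial reads are a ~1% minority that must be
fished out of the pool, and at extreme coverage even rare sequencing errors
produce k-mers frequent enough to confuse a de Bruijn graph. The toolkit
implements the dedicated recovery protocol stage by stage, each stage behind
its own module surface so any one can be swapped or audited.

## Quality trimming

`trim_read` removes the maximal run of consecutive positions with quality
below `qmin` (default Q20) from each read end. This is the literal reading of
"trim low-quality regions at both ends"; a running-sum rule (BWA-style) is a
reasonable alternative and the function is small and isolated so it can be
swapped. Interior low-quality bases are kept — the k-mer correction stage,
not the trimmer, is responsible for them. The operation is idempotent, and an
empty result is valid rather than an error.

## Baiting

`build_bait` seeds a k-mer set (k = 31) from reference mitogenomes;
`bait_reads` iteratively selects every pair sharing ≥ 1 k-mer with the bait
and folds the selected reads' k-mers back in, until fixpoint or 30
iterations. Choices:

- **k = 31** (distinct from the 15-mer spectrum): long enough that random
  31-mer collisions are negligible at WGS scale, short enough that a 150 bp
  read from a ~5%-divergent taxon still usually carries an intact window.
- **min_shared = 1** mirrors the permissive intent of baiting; users with
  divergent references can raise it.
- **Pair rescue** (a selected read always recruits its mate) is on by
  default because whole pairs feed the assembler and the scaffolder.
- Internally the bait stores both orientations of each k-mer so that read
  scanning needs only forward slices; `canonical_kmers()` exposes the
  strand-collapsed set.

The iterative extension is what carries the bait across windows where the
sample differs from every reference: reads there are recruited via overlap
with already-selected flanking reads, observable as iteration-of-selection
greater than 1 in the report.

## 15-mer spectrum, correction and filtering

At high coverage every true genomic 15-mer is frequent and error 15-mers are
rare, so a frequency threshold separates them. The published operating point
— threshold 1,000 at an expected ~22,600-fold — is kept as a *ratio*:
`scaled_min_freq(C) = max(3, ceil(C × 1000/22600))`, which reproduces 1,000
at publication scale and stays meaningful at desk-scale coverage (23 at
500-fold).

Correction is a greedy, quality-ranked substitution search rather than a
full likelihood model: within the region covered by weak k-mers, candidate
positions are tried lowest quality first; a substitution is accepted if it
lifts every k-mer covering that position above the threshold, or — the
several-errors-in-one-span case — if it strictly reduces the number of weak
covering k-mers. Ties between equally good substitutions break by base order
A<C<G<T. At most `max_edits_per_read` (default 3) bases change; read length
never changes; a read still carrying a weak k-mer is returned unmodified and
excluded. The module's contract, asserted as an invariant test, is that no
kept read contains a sub-threshold k-mer when re-evaluated against the
original spectrum.

Under these rules the exclusion fraction on simulated data is governed by
the binomial tail P(errors > max_edits): with 150 bp reads at a 1% per-base
substitution rate that is ≈ 6.6%, and the test suite asserts agreement with
this analytic expectation rather than a looser ad-hoc bound. Whole pairs are
not discarded together: an excluded read orphans its mate into a singles
pool (`filter_read_pairs`).

## Assembly

`build_graph` builds a canonical de Bruijn graph (nodes = 31-mers, edges =
32-mers, both counted from the reads) and prunes nodes/edges below
`min_node_count` (default 3), then removes tip branches shorter than
2·k bases and collapses equal-length bubbles to the higher-coverage path.
This is deliberately a compact assembler for a single clonal ~15 kb molecule
at high coverage, not a general-purpose one; repeat resolution beyond
junction splitting and heterozygosity-aware bubble popping are out of scope.

Contigs are maximal non-branching paths. A pure cycle — the expected shape
for a complete circular mitogenome — is emitted as one period (M bases for a
cycle of M nodes) opened at the lexicographically smallest oriented k-mer
over both traversal directions, making assembly deterministic in rotation
and strand. k falls back from 31 to 25 if the graph fragments into more than
10 contigs (AT-rich genomes can break larger k).

`scaffold` orders and orients contigs using *all* read pairs (including the
excluded ones — the deliberate protocol choice, since excluded reads still
carry linking information), exact-k-mer seeding only, requiring ≥ 5
consistent links; the gap estimate is the median implied gap, floored at 0,
encoded as Ns. Conflicting link majorities keep the best-supported layout
and emit a warning rather than failing.

## Circular closure

A linear representation of a circle produced by an assembler either repeats
the junction at both termini or misses a fragment. `detect_terminal_state`
reports `redundant` iff a suffix of ≥ 32 bp equals a prefix (maximal overlap
trimmed directly); everything else is resolved by the read vote:
`close_circle` collects every read (either orientation) containing the 3′
terminal 32 bp anchor followed by the 5′ anchor within 2× read length, and
tallies the intervening fragments. The majority fragment is inserted; the
report carries the majority fraction and all minor variants, so statements
like "99.8% of junction reads agree" are outputs of the vote.

Conventions: anchor matching is exact (reads with errors inside an anchor
simply do not vote; a 1-mismatch mode exists for low coverage); an anchor
occurring twice in the draft raises an ambiguity error naming the loci; a
*tie* between top fragments raises an error demanding manual review — a tie
is precisely the situation automation must not silently decide. With zero
junction-spanning reads the draft is returned linear with `closed=False`.

`rotate_to_gene` performs the circular permutation so position 1 is the
first base of a probe (trnM(cau) by convention), reverse-complementing first
if the probe lies on the minus strand; it errors if the probe is absent or
duplicated, and is idempotent.

## Coverage assessment

The mapper is exact-seed (21-mers, staggered offsets) with ungapped
extension and a 5% mismatch cap; indels leave a read unmapped rather than
misplacing depth — conservative for a QC profile. Naive per-base depth
under-estimates the two termini because junction-spanning reads cannot map
contiguously; `wraparound_depth` remaps all reads to the half-rotated
linearization and substitutes the two terminal 1,000 bp windows with their
images there, leaving interior positions bit-identical (asserted as an
invariant).

Low-coverage flagging uses the same ratio logic as the k-mer threshold
(1,000/22,600 ≈ 4.4% of mean depth) unless an absolute threshold is given.
Flagged intervals are maximal runs below threshold, annotated with dominant
base fraction (poly-T tracts) and a dinucleotide-repeat detector (longest
period-2 run with two distinct bases covering ≥ 90% of the interval — the
AT-repeat case). `length_variant_survey` measures tract-length heterogeneity
directly from reads containing both unique 20 bp flank anchors and warns if
the assembled genome does not carry the dominant form.

## Annotation

Structural RNA models are not used; placement is reference similarity, which
matches how draft annotations are curated in practice against published
relatives. Proteins are located in the six translated frames of the doubled
circle (exact substring match first; BLOSUM62 local alignment, gap open −11
extend −1, as fallback with a score floor of 1.0/residue); RNAs by
nucleotide match/alignment on either strand, tRNAs constrained to 55–80 bp
with a warning when violated.

Boundary curation codifies the conventions: the start moves to the nearest
in-frame ATN within ±18 bp (6 codons — wide enough for typical curation
shifts, narrow enough to forbid silent relocations; ties prefer upstream,
the longer ORF), with CGA additionally accepted for cox1; the end is the
first in-frame TAA/TAG, truncated to an incomplete T/TA stop when the next
gene's territory begins before a complete stop (the codon is completed to
TAA by polyadenylation). A complete stop overlapping the downstream gene by
≤ 10 bp is kept only when no valid incomplete stop exists — the atp8/atp6
style of genuine overlap. Every accepted gene must translate with zero
internal stops under NCBI table 5 (ATA→M, TGA→W, AGA/AGG→S), sourced from
Biopython's codon tables.

The control region is defined by its bounding genes — the span strictly
between rrnS and trnM(cau) along the circle — not by AT content. Its report
gives length, A+T fraction, the offset of the first ATAGA occurrence from
the rrnS boundary, and the maximal poly-T run immediately after the motif.

Gene order is compared circularly against the canonical Lepidoptera
template starting at trnM, reporting missing, extra, strand-flipped and
transposed genes separately.

## Phylogenetic preparation

Cross-validation computes, per gene, the percent identity of the best global
nucleotide alignment (columns with a gap on either side excluded); a taxon
is excluded iff its minimum per-gene identity falls below 95 (strict `< 95`,
i.e. identity > 95% is the keep criterion), and a taxon with no independent
sequence is kept with the verdict "n.a.". The single-gene case is the
COI-barcode check.

Protein alignment shells out to MAFFT (`--auto`), the field-standard choice;
externally computed alignments can be imported and are validated. Masking
operationalizes "long gaps and their surrounding regions of uncertain
alignment" as: remove every column with gap fraction > 0.5 together with 3
flanking columns on each side of every removed run; both knobs are exposed,
since the manual equivalent is editorial judgment. Concatenation follows a
fixed canonical gene order, gap-fills missing genes with a flag, and
guarantees that partitions tile the matrix exactly.

Tree inference under mitochondrial ML/Bayesian models belongs to external
engines; the module exports relaxed sequential PHYLIP plus a partition
table for them. The built-in neighbor-joining tree is a sanity check only:
p-distances over comparable columns, Saitou–Nei agglomeration with negative
branch lengths clamped to zero and deterministic tie-breaking by taxon
name. It is implemented in-package (for the determinism guarantee) and
cross-checked in tests against an independent NJ implementation.

## The simulator: what it emulates and what it does not

`simulate_mitogenome` builds a circular genome of exactly the configured
length (default 15,400 bp, the mean size of the reference mitogenomes the
protocol assumes) at 80% A+T, laid out in the canonical 37-gene Lepidoptera
order starting at trnM(cau). Protein-coding genes are synthetic but *real*
ORFs under table 5 with typical per-gene codon counts; cox1 starts with CGA;
cox1, cox2 and nd4 end on an incomplete stop T abutting their downstream
tRNA — so the curation conventions are exercised, not just asserted. tRNAs
are random sequences of 60–70 bp, rRNAs ~780/~1,400 bp (rrnL absorbs the
length slack). The control region (488 bp at 94.7% A+T) plants the ATAGA
motif exactly 22 bp downstream of rrnS followed by exactly 15 T's. No real
species' sequence is embedded.

`simulate_reads` draws fragments uniformly on the circle (wrapping the
origin, guaranteeing junction-spanning reads for closure), inner-oriented
mates, two libraries at ~250/500 bp inserts (SD 25), pair count
L×coverage/(2×read length×libraries). Errors are i.i.d. substitutions
(default 1%) with a two-band quality model: errored bases Q 2–15, correct
bases Q 30–40. Optional `RepeatInstability` resamples the length of one
declared tract per fragment, emulating length heterogeneity among
mitochondrial DNA copies.

Not emulated: position- and cycle-dependent Illumina error profiles, indels
outside declared tracts, PCR duplicates, adapter read-through, GC/AT
library-preparation bias (so coverage is uniform and low-coverage flagging
is tested on constructed profiles), and nuclear mitochondrial insertions
(the background pool is random sequence, which is *easier* to reject than
real NUMTs). Passing tests therefore demonstrate the correctness of the
algorithms under the protocol's stated assumptions, not robustness to every
artifact of real libraries.

## Problem sizes and determinism

The test suite runs the shared simulated instance at 120-fold coverage and
the acceptance run at the protocol's nominal 500-fold (two libraries, 1%
errors, an equal mass of random background reads, a 5%-divergent baiting
reference) — sizes at which every stage's behavior is already asymptotic
(the bait converges, the spectrum separates cleanly, the graph is a single
cycle) while a full run stays around a minute on one CPU. All randomness
flows from explicit seeds (numpy `default_rng`); assembly output is
deterministic by construction (canonical cycle opening, lexicographic
tie-breaks), so identical seeds give byte-identical FASTQ, assemblies and
reports.

## Known limitations

- The baiting stage is k-mer set membership, not mapping-assembly; recall
  through highly diverged regions relies on iterative extension and may need
  more iterations at low coverage.
- The assembler does not resolve repeats longer than k beyond paired-link
  scaffolding; mitogenome-scale data rarely needs more, but a control-region
  macro-repeat would fragment the graph.
- The mapper is ungapped; indel-bearing reads are counted unmapped, which
  slightly depresses depth near true indel heterogeneity.
- Annotation requires references for every gene sought; there is no de novo
  gene finding, and tRNA secondary structure is not folded.
- The NJ tree is a sanity check, not an inference result; model-based
  phylogenetics happens downstream of the PHYLIP/partition exports.
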