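# Methods

## Model and assumptions

A superTranscript represents a gene as the shortest linear sequence through
which every member transcript can be read as an ordered chain of disjoint
intervals.  The construction treats transcripts as exact sequences — it
merges bases, it does not error-correct — and assumes the input clustering
(transcript → gene) is given.  Three construction routes share one output
model:

* **assembly route** (`assemble_cluster`): splice-graph assembly from
  pairwise transcript overlaps; works with any transcript set, including de
  novo contigs.
* **genome route** (`build_genome_st`): exon flattening + sequence
  concatenation when a genome and annotation exist; exact by construction,
  no alignment involved.
* **hybrid route** (`rebuild`): genome-based superTranscripts re-assembled
  together with de novo contigs assigned to them, so reference structure is
  kept while novel sequence is added.

The output contract, enforced by construction and checked by tests, is:

1. *Reconstruction*: concatenating `sequence[s:e]` over a transcript's path
   reproduces that transcript exactly (possibly reverse-complemented, if
   orientation normalization flipped it).
2. *Coverage*: every superTranscript base lies on at least one path.
3. *Determinism*: identical inputs give byte-identical outputs, independent
   of worker count.

## Pairwise alignment

The built-in aligner finds maximal exact gapless matches from exact k-mer
seeds (k = 11, clamped to the shorter sequence) and chains them by
dynamic programming under co-linearity, trimming overlaps between chained
blocks; the chain score is the number of matched bases.  Both orientations
are scored and the better one kept, `+` on ties.  On sequences ≤ 30 bp the
chain score provably equals the exhaustive optimum (tested against a
brute-force recursion).  Only gapless blocks are merged into the graph;
sequence between blocks (indels, diverged regions) stays unmerged, which
protects per-base identity at the cost of occasionally duplicating truly
shared bases.

The aligner reports a single best co-linear chain per pair.  A repeat
shared in *different* relative orders (the cycle-forming case) is not
co-linear and therefore needs two alignment records; those arrive either
from imported PSL (BLAT emits one line per local alignment) or from
fixture-supplied alignments.  This is a deliberate scope line: the internal
aligner covers the overwhelmingly common co-linear case, the PSL import
path covers the rest verbatim.

PSL minus-strand `qStarts` are kept in the frame PSL stores them in
(coordinates on the reverse-complemented query).  That frame keeps alignment
blocks strictly increasing on both sequences — the invariant the merge and
orientation machinery relies on — and is also the frame in which a flipped
transcript's coordinates are directly usable after orientation
normalization.

Defaults: `min_block_len = 20` within clusters (a merge-worthy overlap must
look like a shared exon, not a chance word), `min_identity = 0.98` and
`min matched bases = 200` for assignment-type decisions (contig → gene,
superTranscript → genome locus), mirroring common BLAT assignment settings.
All are exposed as CLI flags.

## Graph construction details

* **Merging** is union-find over (transcript, offset) base keys.  A block is
  applied atomically: if any union in it would place two distinct offsets of
  one transcript in a node, or join different letters, the whole block is
  rejected (counted and logged).  Greedy application in deterministic pair
  order plus whole-block rejection is what makes inconsistent alignment
  triangles safe: the reconstruction invariant can never be violated, only
  merging opportunities lost.
* **Compaction** collapses runs whose interior has in/out-degree 1 *and*
  identical member continuity — every transcript in the run must continue
  one base further.  Without the continuity condition a transcript ending
  mid-run would become unreadable.
* **Cycle breaking** repeatedly finds a cycle (DFS via networkx), orders its
  nodes by (base count, anchor) and duplicates the first node whose members
  can be separated by their entry edge: members arriving along the cycle's
  closing edge move to the duplicate, the rest stay.  Such a node always
  exists (transcript walks are finite, so not every member of every cycle
  node can have entered along the cycle), each split strictly reduces a
  potential function, and an iteration cap equal to the total base count
  guards pathological inputs.  In the canonical shared-repeat case this
  reduces exactly to "duplicate the smallest cycle node".
* **Ordering** is Kahn's algorithm with a priority queue keyed by each
  node's *anchor* — the minimal (input_rank, offset) over its members.
  Topological orders are not unique; the anchor makes the choice total,
  reproducible, and biased toward the input order of the earliest
  transcript, so a genome-based sequence placed at rank 0 keeps its
  original base order through hybrid re-assembly.  Disconnected components
  interleave by the same key, which for fully-compacted components means
  concatenation in input order.
* **Cap**: only the first 50 transcripts per cluster (by input order) are
  assembled, the rest are reported as skipped; graph processing cost grows
  quickly with redundant transcript count and the cap is the standard
  mitigation.  Exposed as `--max-transcripts`.

## Block annotation

Standard blocks cut at every path-interval endpoint.  Paths are the graph's
transcript walks, so this equals cutting at graph forks/divergences, but it
survives serialization — annotation can run on a written FASTA+GFF pair
without rebuilding the graph.  Dynamic blocks cut at read-derived junctions
(CIGAR `N`) with flanking matched segments ≥ `min_overhang` (default 12,
the usual aligner splice-overhang filter) and support ≥ `min_support`
(default 5 reads).  A read crossing two junctions contributes to both; a
record is counted once per junction it crosses.  Secondary, supplementary
and unmapped records are ignored.  Both annotations partition `[0, L)` by
construction.

## Genome mode and coordinate lifting

Flattening merges overlapping *and* book-ended exon intervals per gene.
Minus-strand genes concatenate union intervals in ascending genomic order
and reverse-complement the whole, so every superTranscript reads 5'→3' and
transcript paths ascend in transcript direction; this matches what exon
extraction tools produce for minus-strand features.  Chains store ungapped
(st_start, genome_start, length) segments; written chain files follow the
UCSC convention (minus-strand query coordinates counted from the chromosome
end).  Positions in no segment are reported unmapped rather than erroring —
for assembly-derived superTranscripts aligned back to a genome, novel
sequence legitimately has no genomic image, and indel-adjacent positions
are safer unmapped than misassigned.  Genes are processed independently; an
exon shared by two annotated genes is duplicated across their
superTranscripts.

## Hybrid merging

Contig assignment counts only qualifying hits (score and identity
thresholds) when deciding uniqueness, so a weak secondary hit does not turn
a good contig into a "chimera".  Unassigned contigs can be retried against
a secondary reference (homology rescue); contigs failing both passes are
dropped.  Re-assembly places the genome-based superTranscript at input rank
0 so its base order anchors the merged product, and the coverage report
measures, per labelled source, the fraction of merged bases its paths
cover, with `novel` counting bases covered by no labelled source.

## Synthetic data

The generator plants exons (default 50–300 bp, up to 5 per gene) in random
intergenic/intronic background and derives isoforms as exon subsets (first
and last exon always kept; every exon kept by at least one isoform, so the
exon union is recoverable).  Junction bases are sentineled: every possible
splice successor exon has a distinct first base and every possible
predecessor a distinct last base, so exact-match extension cannot cross a
splice boundary by chance and the exon-union length is an exact expectation
for the assembled superTranscript (the 4-letter alphabet is why genes cap
at 5 exons).  Spliced reads are emitted with exact per-junction support and
no errors.

What this does **not** emulate: sequencing errors and assembly artifacts
(mismatching copies of shared exons), alternative donor/acceptor sites
within an exon, expression-weighted isoform abundance, or paralogy between
genes.  Passing tests therefore demonstrate the correctness of the graph
machinery and coordinate arithmetic under clean input, not robustness to
assembly noise; on real data, merges lost to noise lengthen the
superTranscript (redundancy survives) rather than corrupt it, because the
rejection rules are one-sided.

## Problem sizes and numerical choices

The test suite and the acceptance script use 200 assembly-route genes
(1–8 isoforms each), 100 genome-route genes on both strands with full
per-base lift round-trips, and 150–300 enumerated micro-clusters (≤ 3
transcripts, ≤ 20 bp) checked against exhaustive oracles; these sizes keep
a full run in a few seconds while covering every branch point of the
algorithms.  All randomness flows from explicit seeds; ties are broken by
fixed total orders (anchor, lexicographic ids, `+` strand first), degenerate
inputs (empty clusters, empty sequences, zero-length exons, malformed
PSL/chain lines) raise typed data errors, and blocks/paths are validated as
partitions/chains at the API boundaries.

## Known limitations

* One co-linear chain per transcript pair from the internal aligner (see
  above); non-co-linear repeat structure requires imported alignments.
* Orientation normalization is breadth-first from the lowest-rank
  transcript; an inconsistent orientation cycle (rare, requires conflicting
  alignments) keeps the BFS assignment and drops alignments that remain
  minus-strand afterwards.
* The 50-transcript cap silently represents very deep clusters by their
  first 50 members; skipped transcripts are listed but not placed on the
  superTranscript.
* Genome mode requires exon features carrying gene and transcript
  attribution (GTF attributes or GFF3 Parent chains).
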