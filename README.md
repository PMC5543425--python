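# supertranscripts

Build **superTranscripts**: one linear reference sequence per gene that
contains every exonic base of the gene's transcripts exactly once, ordered
consistently with all of its isoforms.

RNA-seq analysis in organisms without a (good) reference genome usually
starts from a de novo transcriptome assembly, where each gene is represented
by many partially redundant contigs.  That redundancy breaks most
genome-style tooling: reads multi-map across isoforms, variant callers see
the same locus many times, and exon-level differential-usage tests have no
common coordinate system.  A superTranscript solves this by collapsing each
gene's transcripts (clustered e.g. by Corset) into a single non-redundant
sequence that every isoform reads through as an ordered chain of intervals —
so standard aligners, variant callers and counting tools work as if a genome
were available.

## The algorithm

For each cluster of transcripts:

1. **Pairwise alignment** — all transcript pairs are aligned with a built-in
   seed-and-extend chainer (exact 11-mer seeds extended to maximal gapless
   matches, best co-linear chain kept; score = matched bases), or with
   imported BLAT PSL alignments.  Opposite-orientation contigs are detected
   and reverse-complemented first.
2. **Splice graph** — a directed graph with one node per transcript base and
   an edge to the next base of the same transcript.  Aligned bases are
   merged (union-find); a whole alignment block is rejected if it would put
   two different positions of one transcript into one node or merge unequal
   letters — this guarantees every transcript remains readable from the
   result.
3. **Compaction** — maximal non-diverging base runs collapse into string
   nodes; forks and joins of the graph are exactly the splice boundaries.
4. **Cycle breaking** — a repeat shared in different contexts creates a
   directed cycle; the smallest node of the cycle is duplicated so the
   repeat appears twice and the graph becomes acyclic, with all transcript
   paths preserved.
5. **Topological sort** — Kahn's algorithm with a deterministic tie-break
   (earliest transcript-of-origin position) linearizes the DAG; the node
   sequences concatenate into the superTranscript and each transcript's
   node walk becomes its interval path.
6. **Block annotation** — *standard* blocks cut the superTranscript at every
   fork/divergence of the transcript paths; *dynamic* blocks instead cut at
   splice junctions observed in reads mapped back to the superTranscript
   (CIGAR `N` operations with ≥12 bp flanking overhang) supported by at
   least 5 reads.  Both are exon-analogue counting bins for differential
   isoform usage.

When a reference genome *is* available, superTranscripts are built directly
(`superT genome`): each gene's exons are flattened into disjoint intervals,
extracted and concatenated (reverse-complemented for minus-strand genes),
and a UCSC chain file is emitted so any superTranscript position (e.g. a
called SNP) can be lifted back to genome coordinates (`superT lift`).  A
genome-based superTranscriptome can also be *extended* with de novo contigs
(`superT hybrid`): contigs aligning to exactly one superTranscript join its
cluster, contigs matching two or more are discarded as likely chimeras, and
each cluster is re-assembled so novel sequence (e.g. missing from the
reference assembly) is incorporated.

## Worked example

```sh
$ superT fixtures --preset basic --seed 1 --out fx
wrote basic fixtures to fx
$ superT build --fasta fx/transcripts.fa --clusters fx/clusters.txt \
    --out-fasta st.fa --out-gff st.gff
built 5 superTranscripts; 0 transcripts skipped by the --max-transcripts cap
```

The 24 synthetic transcripts collapse into 5 superTranscripts (one per
gene).  The GFF names each gene, its blocks and each transcript's path:

```
##gff-version 3
##sequence-region g000 1 693
g000  superT    gene        1  693  .  +  .  ID=g000
g000  standard  exon        1  693  .  +  .  ID=g000:block:0:standard;Parent=g000
g000  superT    match       1  693  .  +  .  ID=g000:g000_iso0;Name=g000_iso0;Parent=g000
g000  superT    match_part  1  693  .  +  .  Parent=g000:g000_iso0;Name=g000_iso0
```

Gene `g000` yields a 693 bp superTranscript; its first isoform covers it in
a single interval (a full-length isoform), while skipped exons in other
genes appear as multiple `match_part` segments and extra `exon` blocks.

The repeat worked example from the library API:

```python
>>> from supertranscripts.simulate import repeat_fixture
>>> from supertranscripts.graph import build_graph
>>> cluster, alignments = repeat_fixture()     # GGGAAATTT / TTTAAACCC
>>> g = build_graph(cluster)
>>> for a in alignments: g.merge_alignment(a)
>>> st = g.compact().break_cycles().topo_sort()
>>> st.sequence
'GGGAAATTTAAACCC'
```

The shared `AAA`/`TTT` pair forms a cycle; the minimal node (`AAA`) is
duplicated, so both transcripts read through the 15 bp result intact.

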