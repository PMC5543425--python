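"""Genome-based superTranscript construction and coordinate lifting.

When a reference genome and annotation are available a superTranscript is
built directly, without graph assembly: each gene's transcript exons are
flattened into disjoint genomic intervals, their sequence extracted and
concatenated.  Minus-strand genes are reverse-complemented as a whole so
every superTranscript reads 5'→3'.  The genomic origin of each
superTranscript is recorded as a chain of ungapped segments (written in UCSC
chain format) through which any superTranscript position can be lifted back
to genome coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils

from .model import Block, DataError, PairwiseAlignment, SuperTranscript, revcomp

log = logging.getLogger(__name__)


@dataclass
class FlattenedGene:
    """A gene's transcripts merged into disjoint sorted exonic intervals."""

    gene_id: str
    chrom: str
    strand: str
    exon_union: list[tuple[int, int]]

    @property
    def st_length(self) -> int:
        return sum(e - s for s, e in self.exon_union)


@dataclass
class ChainRecord:
    """Ungapped alignment segments between a superTranscript and the genome.

    Segments are (st_start, genome_start, length) with genome_start the
    leftmost (plus-strand) genomic coordinate; on '−' the segment runs
    antiparallel: st position st_start+k maps to genome_start+length−1−k.
    """

    st_id: str
    st_size: int
    chrom: str
    chrom_size: int
    strand: str
    segments: list[tuple[int, int, int]]

    def lift(self, st_position: int) -> tuple[str, int, str] | None:
        """Map a superTranscript position to (chrom, genome_pos, strand).

        Positions covered by no segment return None ("unmapped") — possible
        for assembly-derived superTranscripts with novel sequence.
        """
        if not 0 <= st_position < self.st_size:
            raise DataError(f"position {st_position} outside [0,{self.st_size})")
        for st_start, g_start, ln in self.segments:
            if st_start <= st_position < st_start + ln:
                k = st_position - st_start
                g = g_start + k if self.strand == "+" else g_start + ln - 1 - k
                return self.chrom, g, self.strand
        return None

    def lift_genome(self, genome_position: int) -> int | None:
        """Inverse lift: genome position to superTranscript position."""
        for st_start, g_start, ln in self.segments:
            if g_start <= genome_position < g_start + ln:
                k = genome_position - g_start
                return st_start + k if self.strand == "+" else st_start + ln - 1 - k
        return None


def flatten_gene(
    gene_id: str,
    exons_by_transcript: dict[str, list[tuple[int, int]]],
    chrom: str,
    strand: str,
) -> FlattenedGene:
    """Merge all transcript exons of one gene into disjoint sorted intervals.

    Overlapping and book-ended (touching) intervals merge; the result is the
    per-gene flattened annotation.
    """
    if strand not in "+-":
        raise DataError(f"gene {gene_id!r}: bad strand {strand!r}")
    ivs = sorted(iv for exons in exons_by_transcript.values() for iv in exons)
    if not ivs:
        raise DataError(f"gene {gene_id!r} has no exons")
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return FlattenedGene(gene_id, chrom, strand, [(s, e) for s, e in merged])


def _st_coord(fg: FlattenedGene, g: int) -> int:
    """Genomic position (inside the union) → superTranscript position."""
    cum = 0
    for s, e in fg.exon_union:
        if s <= g < e:
            plus = cum + (g - s)
            return plus if fg.strand == "+" else fg.st_length - 1 - plus
        cum += e - s
    raise DataError(f"gene {fg.gene_id!r}: genomic position {g} outside the exon union")


def project_transcripts(
    fg: FlattenedGene, exons_by_transcript: dict[str, list[tuple[int, int]]]
) -> dict[str, list[tuple[int, int]]]:
    """Map each transcript's exons through the genomic→superTranscript function.

    Adjacent projected intervals merge; intervals are returned in ascending
    superTranscript order (5'→3' of the gene on both strands).
    """
    paths: dict[str, list[tuple[int, int]]] = {}
    for tid, exons in sorted(exons_by_transcript.items()):
        ivs = []
        for s, e in exons:
            if e <= s:
                raise DataError(f"transcript {tid!r}: empty exon [{s},{e})")
            a = _st_coord(fg, s)
            b = _st_coord(fg, e - 1)
            ivs.append((min(a, b), max(a, b) + 1))
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                if s < merged[-1][1]:
                    raise DataError(f"transcript {tid!r}: overlapping exons")
                merged[-1][1] = e
            else:
                merged.append([s, e])
        paths[tid] = [(s, e) for s, e in merged]
    return paths


def _genes_from_annotation(annotation_path: str | Path):
    """Yield (gene_id, chrom, strand, {transcript_id: [exon intervals]})."""
    db = gffutils.create_db(
        str(annotation_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        try:
            gid = exon.attributes["gene_id"][0]
            tid = exon.attributes["transcript_id"][0]
        except KeyError:
            parents = [p for p in db.parents(exon, level=1)]
            if not parents:
                raise DataError(f"exon at {exon.seqid}:{exon.start} lacks gene/transcript attribution")
            tid = parents[0].id
            gparents = [g for g in db.parents(parents[0], level=1)]
            gid = gparents[0].id if gparents else tid
        g = genes.setdefault(gid, {"chrom": exon.seqid, "strand": exon.strand, "tx": {}})
        if g["chrom"] != exon.seqid or g["strand"] != exon.strand:
            raise DataError(f"gene {gid!r} mixes chromosomes or strands")
        g["tx"].setdefault(tid, []).append((exon.start - 1, exon.end))
    for gid in sorted(genes):
        g = genes[gid]
        yield gid, g["chrom"], g["strand"], {t: sorted(iv) for t, iv in g["tx"].items()}


def build_genome_st(
    genome_fasta: str | Path, annotation_path: str | Path
) -> tuple[list[SuperTranscript], dict[str, list[Block]], list[ChainRecord]]:
    """Flatten every gene and extract+concatenate its exonic sequence.

    Returns the superTranscripts (with projected transcript paths), the
    union-interval block annotation in superTranscript coordinates, and one
    chain record per gene for lifting positions back to the genome.
    """
    from .io import read_fasta

    genome = read_fasta(genome_fasta)
    sts, blocks, chains = [], {}, []
    for gid, chrom, strand, tx in _genes_from_annotation(annotation_path):
        if chrom not in genome:
            raise DataError(f"gene {gid!r}: chromosome {chrom!r} absent from the genome FASTA")
        fg = flatten_gene(gid, tx, chrom, strand)
        chrom_seq = genome[chrom]
        if fg.exon_union[-1][1] > len(chrom_seq):
            raise DataError(f"gene {gid!r}: exon exceeds chromosome {chrom!r} length")
        seq = "".join(chrom_seq[s:e] for s, e in fg.exon_union)
        if strand == "-":
            seq = revcomp(seq)
        paths = project_transcripts(fg, tx)
        sts.append(SuperTranscript(gid, seq, paths, used_transcripts=sorted(tx)))
        blk = []
        segs = []
        cum = 0
        for s, e in fg.exon_union:
            ln = e - s
            if strand == "+":
                blk.append((cum, cum + ln))
                segs.append((cum, s, ln))
            else:
                blk.append((fg.st_length - cum - ln, fg.st_length - cum))
                segs.append((fg.st_length - cum - ln, s, ln))
            cum += ln
        blocks[gid] = [Block(s, e, "standard") for s, e in sorted(blk)]
        chains.append(ChainRecord(gid, fg.st_length, chrom, len(chrom_seq), strand, sorted(segs)))
    return sts, blocks, chains


# ------------------------------------------------------------------ chain IO


def write_chain(chains: list[ChainRecord], path: str | Path) -> None:
    """UCSC chain format; target = superTranscript, query = genome."""
    with open(path, "w") as fh:
        for i, c in enumerate(sorted(chains, key=lambda c: c.st_id), 1):
            if c.strand == "+":
                q_start, q_end = c.segments[0][1], c.segments[-1][1] + c.segments[-1][2]
            else:
                # minus-strand query coordinates count from the chromosome end
                q_start = c.chrom_size - (c.segments[0][1] + c.segments[0][2])
                q_end = c.chrom_size - c.segments[-1][1]
            t_start, t_end = c.segments[0][0], c.segments[-1][0] + c.segments[-1][2]
            score = sum(ln for _, _, ln in c.segments)
            fh.write(f"chain {score} {c.st_id} {c.st_size} + {t_start} {t_end} "
                     f"{c.chrom} {c.chrom_size} {c.strand} {q_start} {q_end} {i}\n")
            for j, (ts, gs, ln) in enumerate(c.segments):
                if j + 1 < len(c.segments):
                    nts, ngs, _ = c.segments[j + 1]
                    dt = nts - (ts + ln)
                    dq = (ngs - (gs + ln)) if c.strand == "+" else (gs - (ngs + c.segments[j + 1][2]))
                    fh.write(f"{ln} {dt} {dq}\n")
                else:
                    fh.write(f"{ln}\n")
            fh.write("\n")


def read_chain(path: str | Path) -> list[ChainRecord]:
    chains: list[ChainRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        f = lines[i].split()
        if len(f) != 13 or f[0] != "chain":
            raise DataError(f"{path}:{i + 1}: malformed chain header")
        st_id, st_size = f[2], int(f[3])
        chrom, chrom_size, strand = f[7], int(f[8]), f[9]
        t_pos = int(f[5])
        q_pos = int(f[10])
        segs: list[tuple[int, int, int]] = []
        i += 1
        while i < len(lines) and lines[i].strip():
            parts = lines[i].split()
            ln = int(parts[0])
            if strand == "+":
                segs.append((t_pos, q_pos, ln))
            else:
                segs.append((t_pos, chrom_size - (q_pos + ln), ln))
            t_pos += ln
            q_pos += ln
            if len(parts) == 3:
                t_pos += int(parts[1])
                q_pos += int(parts[2])
            elif len(parts) != 1:
                raise DataError(f"{path}:{i + 1}: malformed chain block line")
            i += 1
            if len(parts) == 1:
                break
        chains.append(ChainRecord(st_id, st_size, chrom, chrom_size, strand, sorted(segs)))
    return chains


def lift(chain: ChainRecord, st_position: int) -> tuple[str, int, str] | None:
    """Lift one superTranscript position to genome coordinates (or None)."""
    return chain.lift(st_position)


def chain_from_alignment(
    st_id: str,
    st_length: int,
    alignments: list[PairwiseAlignment],
    chrom_sizes: dict[str, int],
    exclude_suffix: str = "_alt",
) -> ChainRecord | None:
    """Build a chain from the best superTranscript-vs-genome alignment.

    Hits on alternative-haplotype contigs (target name ending in
    ``exclude_suffix``) are excluded before taking the highest score; with no
    qualifying hit the superTranscript is reported unmapped (None).
    """
    hits = [a for a in alignments if a.query_id == st_id
            and not a.target_id.endswith(exclude_suffix)]
    if not hits:
        return None
    best = max(hits, key=lambda a: (a.score, a.target_id))
    chrom = best.target_id
    segs = []
    for q, t, ln in best.blocks:
        if best.strand == "+":
            segs.append((q, t, ln))
        else:
            segs.append((st_length - q - ln, t, ln))
    return ChainRecord(st_id, st_length, chrom, chrom_sizes.get(chrom, 0),
                       best.strand, sorted(segs))
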