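"""Seeded synthetic data: gene models, isoforms, spliced reads, repeat cases.

Every generator is a pure function of its seed.  The truth objects returned
alongside the data are sufficient to compute expected outputs (exon-union
length, block boundaries, junction counts) without running the assembler.

Generated exons carry sentinel junction bases: every exon that can follow a
splice (exons 1..n−1) gets a distinct first base and every exon that can
precede one (exons 0..n−2) a distinct last base, so exact-match extension
can never run across a splice boundary by chance.  The exon-union length is
then an exact truth for the assembled superTranscript, not a statistical
one; the four-letter alphabet caps simulated genes at five exons.  Defaults
(exons of 50–300 bp, up to 8 isoforms) mimic compact vertebrate genes while
staying small enough for exhaustive oracles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .model import Cluster, DataError, PairwiseAlignment, Transcript

DEFAULT_EXON_LEN = (50, 300)
DEFAULT_INTRON_LEN = (60, 200)


@dataclass
class GeneModel:
    """A genomic segment with planted exons."""

    gene_id: str
    chrom: str
    sequence: str  # the genomic segment
    exons: list[tuple[int, int]]  # disjoint, sorted, 0-based half-open
    strand: str = "+"

    @property
    def union_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_union_sequence(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)


@dataclass
class IsoformTruth:
    """Which exons each isoform keeps, and its path on the exon-union axis."""

    kept_exons: dict[str, list[int]]
    union_paths: dict[str, list[tuple[int, int]]]
    union_length: int

    def boundaries(self) -> set[int]:
        b = {0, self.union_length}
        for path in self.union_paths.values():
            for s, e in path:
                b.update((s, e))
        return b


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def simulate_gene(
    n_exons: int,
    exon_len_range: tuple[int, int] = DEFAULT_EXON_LEN,
    intron_len_range: tuple[int, int] = DEFAULT_INTRON_LEN,
    seed: int = 0,
    gene_id: str = "gene",
    chrom: str = "chr1",
    strand: str = "+",
) -> GeneModel:
    """Random genomic segment with ``n_exons`` planted exons."""
    if n_exons < 1:
        raise DataError("n_exons must be >= 1")
    if min(exon_len_range) < 4 or min(intron_len_range) < 1:
        raise DataError("exon lengths must be >= 4 and intron lengths >= 1")
    rng = random.Random(seed)
    if n_exons > 5:
        raise DataError("at most 5 exons per simulated gene (sentinel bases)")
    # sentinel junction bases: distinct first base for every possible splice
    # successor (exons 1..n-1), distinct last base for every possible
    # predecessor (exons 0..n-2)
    firsts = [rng.choice("ACGT")] + rng.sample("ACGT", max(0, n_exons - 1))
    lasts = rng.sample("ACGT", max(1, n_exons - 1)) + [rng.choice("ACGT")]
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    lead = _random_dna(rng, rng.randint(*intron_len_range))
    parts.append(lead)
    pos += len(lead)
    for i in range(n_exons):
        ln = rng.randint(*exon_len_range)
        body = firsts[i] + _random_dna(rng, ln - 2) + lasts[i]
        parts.append(body)
        exons.append((pos, pos + ln))
        pos += ln
        intron = _random_dna(rng, rng.randint(*intron_len_range))
        parts.append(intron)
        pos += len(intron)
    return GeneModel(gene_id, chrom, "".join(parts), exons, strand)


def simulate_isoforms(
    gene: GeneModel,
    n_isoforms: int,
    keep_prob: float = 0.8,
    seed: int = 0,
) -> tuple[Cluster, IsoformTruth]:
    """Exon-subset isoforms of a gene, plus their truth on the union axis.

    The first and last exon are always kept; every exon is kept by at least
    one isoform so the exon union is recoverable from the isoform set.
    """
    if n_isoforms < 1:
        raise DataError("n_isoforms must be >= 1")
    rng = random.Random(seed)
    n = len(gene.exons)
    kept: list[list[int]] = []
    for _ in range(n_isoforms):
        if n_isoforms == 1:
            keep = list(range(n))
        else:
            keep = [i for i in range(n)
                    if i in (0, n - 1) or rng.random() < keep_prob]
        kept.append(keep)
    for exon in range(n):  # force full coverage of the union
        if not any(exon in k for k in kept):
            j = rng.randrange(n_isoforms)
            kept[j] = sorted(set(kept[j]) | {exon})

    exon_len = [e - s for s, e in gene.exons]
    cum = [0]
    for ln in exon_len:
        cum.append(cum[-1] + ln)
    transcripts = []
    union_paths: dict[str, list[tuple[int, int]]] = {}
    kept_map: dict[str, list[int]] = {}
    for iso, keep in enumerate(kept):
        tid = f"{gene.gene_id}_iso{iso}"
        seq = "".join(gene.sequence[gene.exons[i][0]:gene.exons[i][1]] for i in keep)
        transcripts.append(Transcript(tid, seq, gene.gene_id, iso))
        ivs = [(cum[i], cum[i + 1]) for i in keep]
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s == merged[-1][1]:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        union_paths[tid] = [(s, e) for s, e in merged]
        kept_map[tid] = keep
    cluster = Cluster(gene.gene_id, transcripts)
    return cluster, IsoformTruth(kept_map, union_paths, cum[-1])


def simulate_spliced_reads(
    st_id: str,
    st_length: int,
    junctions: list[tuple[int, int]],
    read_len: int = 76,
    per_junction_support: int = 5,
    overhang: int | None = None,
    n_unspliced: int = 10,
    seed: int = 0,
) -> str:
    """SAM text with exactly ``per_junction_support`` reads over each junction.

    Each spliced read has CIGAR <f>M<skip>N<g>M with f+g = read_len; the
    flank split is near-even unless ``overhang`` pins the left flank (used to
    exercise the junction overhang filter).  A few unspliced reads are added
    for realism.  Deterministic under ``seed``.
    """
    rng = random.Random(seed)
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{st_id}\tLN:{st_length}"]
    seq = "A" * read_len
    qual = "I" * read_len
    rid = 0
    for left, right in junctions:
        if not 0 < left < right <= st_length:
            raise DataError(f"junction [{left},{right}) outside [0,{st_length}]")
        for _ in range(per_junction_support):
            f = overhang if overhang is not None else read_len // 2 + rng.randint(-5, 5)
            f = max(1, min(read_len - 1, f, left))
            g = min(read_len - f, st_length - right)
            if g < 1:
                raise DataError("read does not fit right of the junction")
            pos = left - f  # 0-based start
            cigar = f"{f}M{right - left}N{g}M"
            lines.append(f"read{rid}\t0\t{st_id}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t"
                         f"{seq[:f + g]}\t{qual[:f + g]}")
            rid += 1
    for _ in range(n_unspliced):
        if st_length <= read_len:
            break
        pos = rng.randrange(0, st_length - read_len)
        lines.append(f"read{rid}\t0\t{st_id}\t{pos + 1}\t60\t{read_len}M\t*\t0\t0\t{seq}\t{qual}")
        rid += 1
    return "\n".join(lines) + "\n"


def repeat_fixture(unit_len: int = 3, cluster_id: str = "repeat") -> tuple[Cluster, list[PairwiseAlignment]]:
    """Two transcripts sharing a repeated pair of units that forces a cycle.

    t1 = G^u A^u T^u and t2 = T^u A^u C^u share both the A-run and the T-run,
    but in opposite relative order, so merging both (two separate local
    alignments, as a BLAT run would report) creates a cycle A⇄T in the
    splice graph.
    """
    if unit_len < 1:
        raise DataError("unit_len must be >= 1")
    u = unit_len
    t1 = Transcript("t1", "G" * u + "A" * u + "T" * u, cluster_id, 0)
    t2 = Transcript("t2", "T" * u + "A" * u + "C" * u, cluster_id, 1)
    alignments = [
        PairwiseAlignment("t1", "t2", "+", [(u, u, u)], 1.0, u),      # shared A-run
        PairwiseAlignment("t1", "t2", "+", [(2 * u, 0, u)], 1.0, u),  # shared T-run
    ]
    return Cluster(cluster_id, [t1, t2]), alignments


# ----------------------------------------------------------------- presets


def write_gtf(genes: list[GeneModel], isoform_exons: dict[str, dict[str, list[int]]],
              path: str | Path) -> None:
    """Minimal GTF for simulated genes (exon features with gene/transcript ids)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: g.gene_id):
            for tid in sorted(isoform_exons.get(gene.gene_id, {})):
                for i in isoform_exons[gene.gene_id][tid]:
                    s, e = gene.exons[i]
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                    fh.write(f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n")


def basic_preset(seed: int, n_genes: int = 5) -> list[tuple[GeneModel, Cluster, IsoformTruth]]:
    """A handful of multi-isoform genes for end-to-end runs."""
    rng = random.Random(seed)
    out = []
    for i in range(n_genes):
        gene = simulate_gene(rng.randint(2, 5), seed=rng.randrange(2**31), gene_id=f"g{i:03d}")
        cluster, truth = simulate_isoforms(gene, rng.randint(1, 8), seed=rng.randrange(2**31))
        out.append((gene, cluster, truth))
    return out
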