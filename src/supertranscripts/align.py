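"""Co-linear pairwise alignment of transcripts within a cluster.

The built-in aligner is a seed-and-extend chainer over exact k-mer seeds
(default k=11, the BLAT tile size): seeds are extended to maximal exact
gapless matches, and the highest-scoring strictly co-linear chain of such
blocks is kept (score = matched bases).  Both orientations are evaluated and
the better-scoring strand returned, '+' winning ties.  Alignments produced
externally (BLAT PSL) can be imported instead and used verbatim.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

from .model import Cluster, DataError, PairwiseAlignment, Transcript, revcomp

log = logging.getLogger(__name__)

DEFAULT_KMER = 11
DEFAULT_MIN_BLOCK_LEN = 20
DEFAULT_MIN_IDENTITY = 0.98


def _maximal_exact_matches(a: str, b: str, k: int, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact gapless matches of length >= min_len (via k-mer seeds)."""
    index: dict[str, list[int]] = defaultdict(list)
    for t in range(len(b) - k + 1):
        index[b[t:t + k]].append(t)
    seen_on_diag: dict[int, int] = {}  # diagonal -> q end of last extension
    out = []
    for q in range(len(a) - k + 1):
        for t in index.get(a[q:q + k], ()):
            diag = q - t
            if seen_on_diag.get(diag, -1) > q:
                continue
            qs, ts = q, t
            while qs > 0 and ts > 0 and a[qs - 1] == b[ts - 1]:
                qs -= 1
                ts -= 1
            qe, te = q + k, t + k
            while qe < len(a) and te < len(b) and a[qe] == b[te]:
                qe += 1
                te += 1
            seen_on_diag[diag] = qe
            if qe - qs >= min_len:
                out.append((qs, ts, qe - qs))
    return sorted(set(out))


def _best_chain(
    blocks: list[tuple[int, int, int]], min_block_len: int
) -> tuple[list[tuple[int, int, int]], int]:
    """Highest-scoring co-linear chain of (possibly start-trimmed) blocks.

    A successor block overlapping its predecessor on either sequence is
    trimmed at its start by the overlap (the trimmed part of a maximal exact
    match is still an exact match); a chain step is only allowed if the
    trimmed block still has min_block_len bases.  With maximal exact matches
    as input this reaches the true optimum over all exact gapless chains.
    Tie-breaking uses coordinate sums/extremes that are invariant under
    transposing query and target, so align_pair stays symmetric.
    """
    if not blocks:
        return [], 0
    n = len(blocks)
    score = [0] * n
    prev = [-1] * n
    start_trim = [0] * n  # bases cut from this block's start
    pred_end_trim = [0] * n  # bases cut from the chosen predecessor's end
    for i, (qi, ti, li) in enumerate(blocks):
        score[i] = li
        best_key = None
        for j in range(i):
            qj, tj, lj = blocks[j]
            if qj >= qi or tj >= ti or qj + lj >= qi + li or tj + lj >= ti + li:
                continue
            o = max(0, qj + lj - qi, tj + lj - ti)
            # overlap is absorbed by trimming the predecessor's end first
            # (its start is already fixed), then this block's start
            o_pred = min(o, max(0, lj - start_trim[j] - min_block_len))
            o_self = o - o_pred
            if li - o_self < min_block_len:
                continue
            cand = score[j] + li - o
            key = (-cand, qj + tj, min(qj, tj), max(qj, tj))
            if best_key is None or key < best_key:
                best_key = key
                prev[i] = j
                start_trim[i], pred_end_trim[i] = o_self, o_pred
                score[i] = cand
    best = min(range(n), key=lambda i: (-score[i], blocks[i][0] + blocks[i][1],
                                        min(blocks[i][0], blocks[i][1]),
                                        max(blocks[i][0], blocks[i][1])))
    chain = []
    i = best
    end_trim = 0
    while i >= 0:
        q, t, ln = blocks[i]
        s = start_trim[i]
        chain.append((q + s, t + s, ln - s - end_trim))
        end_trim = pred_end_trim[i]
        i = prev[i]
    return chain[::-1], score[best]


def align_pair(
    seq_a: str,
    seq_b: str,
    min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_KMER,
    query_id: str = "query",
    target_id: str = "target",
) -> PairwiseAlignment | None:
    """Align two sequences; return the best chain or None if nothing qualifies."""
    if not seq_a or not seq_b:
        raise DataError("align_pair requires non-empty sequences")
    k_eff = max(1, min(k, len(seq_a), len(seq_b)))
    best: PairwiseAlignment | None = None
    for strand, query in (("+", seq_a), ("-", revcomp(seq_a))):
        mems = _maximal_exact_matches(query, seq_b, k_eff, min_block_len)
        chain, score = _best_chain(mems, min_block_len)
        if not chain:
            continue
        if best is None or score > best.score:  # '+' wins ties
            best = PairwiseAlignment(query_id, target_id, strand, chain, 1.0, score)
    if best is None or best.identity < min_identity:
        return None
    return best


def cluster_alignments(
    cluster: Cluster,
    max_transcripts: int = 50,
    min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_KMER,
) -> tuple[list[PairwiseAlignment], list[str]]:
    """All-vs-all alignments among the first ``max_transcripts`` transcripts.

    Genes with very many transcripts dominate graph-processing time, so only
    the first ``max_transcripts`` (by input order, default 50) take part; the
    rest are reported as skipped.  Pair order is (rank_i, rank_j) ascending.
    """
    if not cluster.transcripts:
        raise DataError(f"cluster {cluster.cluster_id!r} is empty")
    used = cluster.transcripts[:max_transcripts]
    skipped = [t.id for t in cluster.transcripts[max_transcripts:]]
    alignments = []
    for i, ti in enumerate(used):
        for tj in used[i + 1:]:
            al = align_pair(ti.sequence, tj.sequence, min_block_len, min_identity, k,
                            query_id=ti.id, target_id=tj.id)
            if al is not None:
                alignments.append(al)
    return alignments, skipped


def orient_cluster(cluster: Cluster, alignments: list[PairwiseAlignment]) -> tuple[Cluster, set[str]]:
    """Reverse-complement transcripts so connected transcripts share a strand.

    Orientation propagates by breadth-first search from the lowest-rank
    transcript of each alignment-connected component; an edge on the '−'
    strand flips the far transcript relative to the near one.  Returns the
    re-oriented cluster and the set of flipped transcript ids.
    """
    rank = {t.id: t.input_rank for t in cluster.transcripts}
    adj: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for al in alignments:
        adj[al.query_id].append((al.target_id, al.strand))
        adj[al.target_id].append((al.query_id, al.strand))
    flip: dict[str, bool] = {}
    for t in sorted(cluster.transcripts, key=lambda t: t.input_rank):
        if t.id in flip:
            continue
        flip[t.id] = False
        queue = [t.id]
        while queue:
            cur = queue.pop(0)
            for other, strand in sorted(adj.get(cur, ()), key=lambda e: rank[e[0]]):
                if other not in flip:
                    flip[other] = flip[cur] ^ (strand == "-")
                    queue.append(other)
    flipped = {tid for tid, f in flip.items() if f}
    new = [
        Transcript(t.id, revcomp(t.sequence) if t.id in flipped else t.sequence,
                   cluster.cluster_id, t.input_rank)
        for t in cluster.transcripts
    ]
    return Cluster(cluster.cluster_id, new), flipped


def reorient_alignment(
    al: PairwiseAlignment, flip_q: bool, flip_t: bool, len_q: int, len_t: int
) -> PairwiseAlignment | None:
    """Express an alignment in the frame of re-oriented sequences.

    Returns None when the flips are inconsistent with the alignment strand
    (the pair would still align on '−' after orientation).
    """
    if (flip_q ^ flip_t) != (al.strand == "-"):
        return None
    if not flip_t:
        blocks = al.blocks
    else:
        blocks = sorted((len_q - q - ln, len_t - t - ln, ln) for q, t, ln in al.blocks)
    return PairwiseAlignment(al.query_id, al.target_id, "+", blocks, al.identity, al.score)


def read_psl(psl_path: str | Path, id_filter: set[str] | None = None) -> list[PairwiseAlignment]:
    """Import BLAT PSL alignments (21 columns, optional 5-line header).

    Minus-strand qStarts are kept in the frame PSL stores them in (positions
    on the reverse-complemented query), matching PairwiseAlignment's
    oriented-query convention; identity = matches/(matches+misMatches).
    """
    out = []
    with open(psl_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            first = line.split("\t")[0].split(" ")[0]
            if first in ("psLayout", "match", "") or set(line) <= {"-", "\t", " "}:
                continue  # header dialect
            f = line.split("\t")
            if len(f) != 21:
                raise DataError(f"{psl_path}:{lineno}: expected 21 PSL columns, got {len(f)}")
            matches, mismatches = int(f[0]), int(f[1])
            strand = f[8][0]
            qname, tname = f[9], f[13]
            if id_filter is not None and (qname not in id_filter or tname not in id_filter):
                continue
            sizes = [int(x) for x in f[18].rstrip(",").split(",")]
            qstarts = [int(x) for x in f[19].rstrip(",").split(",")]
            tstarts = [int(x) for x in f[20].rstrip(",").split(",")]
            if not len(sizes) == len(qstarts) == len(tstarts) == int(f[17]):
                raise DataError(f"{psl_path}:{lineno}: blockCount does not match block lists")
            blocks = sorted(zip(qstarts, tstarts, sizes))
            blocks = [(q, t, ln) for q, t, ln in blocks]
            identity = matches / (matches + mismatches) if matches + mismatches else 0.0
            out.append(PairwiseAlignment(qname, tname, strand, blocks, identity, matches))
    return out
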