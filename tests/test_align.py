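import random

import pytest

from helpers import oracle_best_chain_score, oracle_best_local_match
from supertranscripts.align import (
    align_pair,
    cluster_alignments,
    orient_cluster,
    read_psl,
    reorient_alignment,
)
from supertranscripts.model import Cluster, DataError, Transcript, revcomp


def test_identical_sequences_align_fully():
    al = align_pair("AAACCC", "AAACCC", min_block_len=3)
    assert al.strand == "+" and al.blocks == [(0, 0, 6)] and al.identity == 1.0


def test_disjoint_alphabets_do_not_align():
    assert align_pair("AAAAAA", "CCCCCC", min_block_len=3) is None


def test_unique_maximal_gapless_match():
    # cross-checked against full enumeration of gapless matches
    a, b = "ACGTACGTAA", "GTACGT"
    assert oracle_best_local_match(a, b) == (2, 0, 6)
    al = align_pair(a, b, min_block_len=6)
    assert al.blocks == [(2, 0, 6)] and al.strand == "+"


def test_reverse_complement_orientation_detected():
    rng = random.Random(1)
    s = "".join(rng.choice("ACGT") for _ in range(60))
    al = align_pair(revcomp(s), s)
    assert al is not None and al.strand == "-"
    # '-' blocks are in the reverse-complemented query frame
    q, t, ln = al.blocks[0]
    assert (q, t, ln) == (0, 0, 60)


@pytest.mark.parametrize("seed", range(12))
def test_alignment_is_symmetric_up_to_transposition(seed):
    rng = random.Random(seed)
    n = rng.randint(10, 40)
    a = "".join(rng.choice("ACG") for _ in range(n))
    b = "".join(rng.choice("ACG") for _ in range(rng.randint(10, 40)))
    ab = align_pair(a, b, min_block_len=4, k=4)
    ba = align_pair(b, a, min_block_len=4, k=4)
    if ab is None:
        assert ba is None
        return
    assert ab.score == ba.score and ab.strand == ba.strand
    if ab.strand == "+":
        assert [(t, q, ln) for q, t, ln in ab.blocks] == ba.blocks


@pytest.mark.parametrize("seed", range(40))
def test_chain_score_matches_exhaustive_oracle(seed):
    rng = random.Random(100 + seed)
    alpha = rng.choice(["AC", "ACG", "ACGT"])
    a = "".join(rng.choice(alpha) for _ in range(rng.randint(5, 30)))
    b = "".join(rng.choice(alpha) for _ in range(rng.randint(5, 30)))
    ml = rng.randint(2, 4)
    al = align_pair(a, b, min_block_len=ml, k=min(3, ml))
    exp = oracle_best_chain_score(a, b, ml)
    exp_rc = oracle_best_chain_score(revcomp(a), b, ml)
    if al is None:
        assert max(exp, exp_rc) == 0
    else:
        assert al.score == max(exp, exp_rc)
        if exp >= exp_rc:
            assert al.strand == "+"


def test_blocks_are_exact_matches_at_identity_one():
    rng = random.Random(7)
    a = "".join(rng.choice("ACGT") for _ in range(200))
    b = a[30:90] + "TTTT" + a[120:180]
    al = align_pair(a, b)
    assert al is not None and al.identity == 1.0
    for q, t, ln in al.blocks:
        assert a[q:q + ln] == b[t:t + ln]


def _cluster_of(n, length=30, seed=0):
    rng = random.Random(seed)
    txs = [Transcript(f"t{i}", "".join(rng.choice("ACGT") for _ in range(length)), "g", i)
           for i in range(n)]
    return Cluster("g", txs)


@pytest.mark.parametrize("n,pairs", [(1, 0), (2, 1), (3, 3)])
def test_pair_counts(n, pairs):
    # identical sequences so every attempted pair yields an alignment
    txs = [Transcript(f"t{i}", "ACGTACGTACGTACGTACGTACGT", "g", i) for i in range(n)]
    als, skipped = cluster_alignments(Cluster("g", txs), min_block_len=5, k=5)
    assert skipped == []
    assert len(als) == pairs


def test_transcript_cap_skips_beyond_fifty():
    cluster = _cluster_of(60, length=10)
    als, skipped = cluster_alignments(cluster, min_block_len=5, k=5)
    assert skipped == [f"t{i}" for i in range(50, 60)]


def test_orient_flips_reverse_complemented_transcript():
    rng = random.Random(3)
    s = "".join(rng.choice("ACGT") for _ in range(80))
    cluster = Cluster("g", [Transcript("t1", s, "g", 0),
                            Transcript("t2", revcomp(s), "g", 1)])
    als, _ = cluster_alignments(cluster)
    oriented, flipped = orient_cluster(cluster, als)
    assert flipped == {"t2"}
    assert oriented.transcripts[1].sequence == s
    al = align_pair(oriented.transcripts[0].sequence, oriented.transcripts[1].sequence)
    assert al.strand == "+" and al.blocks == [(0, 0, 80)]


def test_orient_identity_when_co_oriented():
    cluster = _cluster_of(3, length=50, seed=5)
    als, _ = cluster_alignments(cluster)
    oriented, flipped = orient_cluster(cluster, als)
    assert flipped == set()
    assert [t.sequence for t in oriented.transcripts] == [t.sequence for t in cluster.transcripts]


def test_orient_propagates_transitively():
    # t3 aligns only to t2 ('-'), t2 aligns to t1 ('-') -> flip t2, then t3
    rng = random.Random(11)
    left = "".join(rng.choice("ACGT") for _ in range(60))
    mid = "".join(rng.choice("ACGT") for _ in range(60))
    right = "".join(rng.choice("ACGT") for _ in range(60))
    t1 = left + mid[:30]
    t2 = revcomp(mid)
    t3 = revcomp(mid[30:] + right)
    cluster = Cluster("g", [Transcript("t1", t1, "g", 0),
                            Transcript("t2", t2, "g", 1),
                            Transcript("t3", t3, "g", 2)])
    als, _ = cluster_alignments(cluster)
    oriented, flipped = orient_cluster(cluster, als)
    assert flipped == {"t2", "t3"}
    # brute-force check: chosen orientation minimizes '-' strand alignments
    als2, _ = cluster_alignments(oriented)
    assert all(a.strand == "+" for a in als2)


def test_reorient_alignment_round_trip():
    rng = random.Random(13)
    a = "".join(rng.choice("ACGT") for _ in range(50))
    b = revcomp(a[10:40])
    al = align_pair(a, b, min_block_len=10)
    assert al.strand == "-"
    fixed = reorient_alignment(al, flip_q=False, flip_t=True, len_q=len(a), len_t=len(b))
    assert fixed is not None and fixed.strand == "+"
    bf = revcomp(b)
    for q, t, ln in fixed.blocks:
        assert a[q:q + ln] == bf[t:t + ln]


PSL_HEADER = (
    "psLayout version 3\n\nmatch\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\t"
    "strand\tQ        \tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     \tsize\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
    + "-" * 30 + "\n"
)


def _psl_line(matches, mismatches, strand, q, qsize, qs, qe, t, tsize, ts, te, sizes, qstarts, tstarts):
    f = [matches, mismatches, 0, 0, 0, 0, 0, 0, strand, q, qsize, qs, qe,
         t, tsize, ts, te, len(sizes),
         ",".join(map(str, sizes)) + ",", ",".join(map(str, qstarts)) + ",",
         ",".join(map(str, tstarts)) + ","]
    return "\t".join(str(x) for x in f) + "\n"


def test_read_psl_plus_strand_and_header(tmp_path):
    p = tmp_path / "a.psl"
    p.write_text(PSL_HEADER + _psl_line(6, 0, "+", "q1", 10, 0, 6, "t1", 10, 0, 6, [6], [0], [0]))
    als = read_psl(p)
    assert len(als) == 1
    assert als[0].blocks == [(0, 0, 6)] and als[0].identity == 1.0


def test_read_psl_minus_strand_frame(tmp_path):
    # construct a real '-' match and its PSL record, then verify the frame:
    # qStarts refer to the reverse-complemented query (PSL convention)
    rng = random.Random(17)
    t = "".join(rng.choice("ACGT") for _ in range(20))
    q = revcomp(t[5:15])  # 10 bp query matching t[5:15] on '-'
    # reverse-frame qStart of the full-query match is 0
    p = tmp_path / "m.psl"
    p.write_text(_psl_line(10, 0, "-", "q1", 10, 0, 10, "t1", 20, 5, 15, [10], [0], [5]))
    al = read_psl(p)[0]
    assert al.strand == "-"
    (qs, ts, ln), = al.blocks
    assert revcomp(q)[qs:qs + ln] == t[ts:ts + ln]


def test_read_psl_malformed_column_count(tmp_path):
    p = tmp_path / "bad.psl"
    p.write_text("1\t2\t3\n")
    with pytest.raises(DataError, match="1"):
        read_psl(p)
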