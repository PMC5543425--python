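import random

import networkx as nx
import pytest

from helpers import admits_interval_chain
from supertranscripts.graph import AssemblyOptions, assemble_cluster, build_graph
from supertranscripts.model import Cluster, DataError, PairwiseAlignment, Transcript, revcomp
from supertranscripts.simulate import repeat_fixture, simulate_gene, simulate_isoforms


def _cluster(*seqs, cid="g"):
    return Cluster(cid, [Transcript(f"t{i + 1}", s, cid, i) for i, s in enumerate(seqs)])


def test_build_single_transcript_chain():
    g = build_graph(_cluster("ACG"))
    assert g.node_count == 3 and g.edge_count == 2


def test_build_two_transcripts_disjoint_chains():
    g = build_graph(_cluster("ACGT", "ACGTAA"))
    assert g.node_count == 10 and g.edge_count == 8


def test_build_empty_cluster_rejected():
    with pytest.raises(DataError):
        build_graph(Cluster("g", []))


def test_merge_unifies_shared_prefix():
    # union-find oracle: 12 base classes minus 3 unions = 9
    g = build_graph(_cluster("AAACCC", "AAAGGG"))
    g.merge_alignment(PairwiseAlignment("t1", "t2", "+", [(0, 0, 3)], 1.0, 3))
    assert g.node_count == 9


def test_self_alignment_is_noop():
    g = build_graph(_cluster("AAACCC"))
    g.merge_alignment(PairwiseAlignment("t1", "t1", "+", [(0, 0, 6)], 1.0, 6))
    assert g.node_count == 6 and g.rejected_blocks == 0


def test_block_unifying_two_offsets_of_one_transcript_rejected():
    g = build_graph(_cluster("AAAAAA"))
    g.merge_alignment(PairwiseAlignment("t1", "t1", "+", [(0, 3, 3)], 1.0, 3))
    assert g.rejected_blocks == 1 and g.node_count == 6


def test_block_unifying_different_letters_rejected():
    g = build_graph(_cluster("AAACCC", "AAAGGG"))
    g.merge_alignment(PairwiseAlignment("t1", "t2", "+", [(3, 3, 3)], 1.0, 3))
    assert g.rejected_blocks == 1 and g.node_count == 12


def test_compact_unbranched_chain_to_single_node():
    g = build_graph(_cluster("ACG")).compact()
    assert g.node_count == 1 and next(iter(g.nodes.values())).bases == "ACG"


def test_compact_branch_point_yields_three_nodes():
    g = build_graph(_cluster("AAACCC", "AAAGGG"))
    g.merge_alignment(PairwiseAlignment("t1", "t2", "+", [(0, 0, 3)], 1.0, 3))
    g.compact()
    assert sorted(n.bases for n in g.nodes.values()) == ["AAA", "CCC", "GGG"]


def test_compact_fully_merged_identical_transcripts():
    g = build_graph(_cluster("ACGTAC", "ACGTAC"))
    g.merge_alignment(PairwiseAlignment("t1", "t2", "+", [(0, 0, 6)], 1.0, 6))
    g.compact()
    assert g.node_count == 1 and next(iter(g.nodes.values())).bases == "ACGTAC"


def test_break_cycles_identity_on_acyclic():
    g = build_graph(_cluster("AAACCC", "AAAGGG"))
    g.merge_alignment(PairwiseAlignment("t1", "t2", "+", [(0, 0, 3)], 1.0, 3))
    g.compact()
    before = {nid: (n.bases, dict(n.members)) for nid, n in g.nodes.items()}
    g.break_cycles()
    assert {nid: (n.bases, dict(n.members)) for nid, n in g.nodes.items()} == before


def test_shared_repeat_cycle_broken_by_duplicating_minimal_node():
    cluster, alignments = repeat_fixture()
    g = build_graph(cluster)
    for al in alignments:
        g.merge_alignment(al)
    g.compact()
    assert len(list(nx.simple_cycles(g.to_networkx()))) == 1
    sizes_in_cycle = {len(g.nodes[n].bases) for n in nx.find_cycle(g.to_networkx())[0]}
    g.break_cycles()
    assert nx.is_directed_acyclic_graph(g.to_networkx())
    # the duplicated node (same bases twice) has the minimal cycle-node size
    bases = sorted(n.bases for n in g.nodes.values())
    dup = [b for b in set(bases) if bases.count(b) == 2]
    assert len(dup) == 1 and len(dup[0]) == min(sizes_in_cycle)
    st = g.topo_sort()
    assert st.sequence == "GGGAAATTTAAACCC" and len(st) == 15
    assert st.extract("t1") == "GGGAAATTT" and st.extract("t2") == "TTTAAACCC"


def test_topo_sort_anchor_tiebreak():
    g = build_graph(_cluster("AAACCC", "AAAGGG"))
    g.merge_alignment(PairwiseAlignment("t1", "t2", "+", [(0, 0, 3)], 1.0, 3))
    g.compact()
    st = g.topo_sort()
    assert st.sequence == "AAACCCGGG"
    assert st.paths == {"t1": [(0, 6)], "t2": [(0, 3), (6, 9)]}


def test_disconnected_components_concatenate_by_anchor():
    st = assemble_cluster(_cluster("AAAATTTT", "CCCCGGGG"))
    assert st.sequence == "AAAATTTTCCCCGGGG"
    assert st.paths == {"t1": [(0, 8)], "t2": [(8, 16)]}


def test_assemble_single_transcript_identity():
    rng = random.Random(0)
    s = "".join(rng.choice("ACGT") for _ in range(120))
    st = assemble_cluster(_cluster(s))
    assert st.sequence == s and st.paths["t1"] == [(0, 120)]


def test_assemble_contained_transcript():
    rng = random.Random(1)
    s = "".join(rng.choice("ACGT") for _ in range(200))
    st = assemble_cluster(_cluster(s, s[40:150]))
    assert st.sequence == s
    assert st.paths["t2"] == [(40, 150)]


def test_assemble_sixty_transcript_cluster_uses_first_fifty():
    txs = [Transcript(f"t{i:02d}", "ACGT" * 10, "g", i) for i in range(60)]
    st = assemble_cluster(Cluster("g", txs))
    assert len(st.used_transcripts) == 50
    assert st.skipped_transcripts == [f"t{i:02d}" for i in range(50, 60)]


def test_output_invariant_to_transcript_relabeling():
    rng = random.Random(2)
    gene = simulate_gene(4, seed=33, gene_id="g")
    cluster, _ = simulate_isoforms(gene, 4, seed=44)
    st1 = assemble_cluster(cluster)
    renamed = Cluster("g", [Transcript(f"zz_{i}", t.sequence, "g", i)
                            for i, t in enumerate(cluster.transcripts)])
    st2 = assemble_cluster(renamed)
    assert st1.sequence == st2.sequence


def test_assemble_is_deterministic():
    gene = simulate_gene(5, seed=5, gene_id="g")
    cluster, _ = simulate_isoforms(gene, 6, seed=6)
    a, b = assemble_cluster(cluster), assemble_cluster(cluster)
    assert a.sequence == b.sequence and a.paths == b.paths


@pytest.mark.parametrize("seed", range(25))
def test_reconstruction_on_random_fixtures(seed):
    """Path-concatenation reproduces every input transcript exactly."""
    rng = random.Random(seed)
    gene = simulate_gene(rng.randint(2, 5), seed=500 + seed, gene_id="g")
    cluster, truth = simulate_isoforms(gene, rng.randint(1, 8), seed=600 + seed)
    st = assemble_cluster(cluster)
    for t in cluster.transcripts:
        assert st.extract(t.id) == t.sequence
        ivs = st.paths[t.id]
        assert all(e > s for s, e in ivs)
        assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))
    # every base covered by at least one path
    covered = bytearray(len(st))
    for path in st.paths.values():
        for s, e in path:
            for i in range(s, e):
                covered[i] = 1
    assert all(covered)


def test_tiny_clusters_admit_all_transcripts_as_interval_chains():
    """Seeded enumeration of <=3-transcript, <=20 bp clusters vs an
    independent subsequence oracle."""
    opts = AssemblyOptions(min_block_len=3, kmer=3)
    rng = random.Random(99)
    for _ in range(150):
        n = rng.randint(1, 3)
        base = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 20)))
        seqs = [base]
        for _ in range(n - 1):
            if rng.random() < 0.5:
                i = rng.randint(0, len(base) - 4)
                j = rng.randint(i + 4, len(base))
                seqs.append(base[i:j])
            else:
                seqs.append("".join(rng.choice("ACGT") for _ in range(rng.randint(4, 20))))
        st = assemble_cluster(_cluster(*seqs), opts)
        for i, s in enumerate(seqs):
            got = st.extract(f"t{i + 1}")
            assert got in (s, revcomp(s))  # orientation normalization may flip
            assert admits_interval_chain(got, st.sequence)
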