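"""The splice-graph core: build a base-level directed graph per cluster,
merge aligned bases, compact non-branching runs, break cycles by node
duplication, and topologically sort into a superTranscript.

The graph starts with one node per transcript base and a directed edge to
the next base of the same transcript.  Pairwise alignments merge bases of
overlapping sequence (union-find); a whole alignment block is rejected if it
would place two distinct offsets of one transcript in the same node or unify
different base letters — this is what guarantees that every transcript can
be read back off the final sequence exactly.  Compaction collapses maximal
non-diverging runs into string nodes.  Cycles (shared repeats) are broken by
duplicating the smallest node of the cycle; transcript walks are preserved.
Kahn's algorithm with a deterministic tie-break (the node "anchor": the
earliest (input_rank, offset) among its members) yields a reproducible
linear order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .align import cluster_alignments, orient_cluster, reorient_alignment
from .model import Cluster, DataError, PairwiseAlignment, SuperTranscript, Transcript

log = logging.getLogger(__name__)


@dataclass
class Node:
    """A run of bases and the transcript positions it represents.

    ``members`` maps transcript id to the offset of the node's FIRST base in
    that transcript; the run extends offset..offset+len(bases).
    """

    bases: str
    members: dict[str, int]


@dataclass
class AssemblyOptions:
    max_transcripts: int = 50
    min_block_len: int = 20
    min_identity: float = 0.98
    kmer: int = 11


class SpliceGraph:
    """Per-cluster splice graph; see module docstring for the life cycle."""

    def __init__(self, cluster: Cluster):
        if not cluster.transcripts:
            raise DataError("cannot build a splice graph from an empty cluster")
        self.cluster_id = cluster.cluster_id
        self._ids = [t.id for t in cluster.transcripts]
        self._seqs = {t.id: t.sequence for t in cluster.transcripts}
        self._ranks = {t.id: t.input_rank for t in cluster.transcripts}
        self._base0: dict[str, int] = {}
        n = 0
        letters = []
        for t in cluster.transcripts:
            self._base0[t.id] = n
            n += len(t.sequence)
            letters.append(t.sequence)
        self.total_bases = n
        self._letters = "".join(letters)
        self._parent = list(range(n))
        self._members: list[dict[str, int] | None] = [None] * n
        for tid in self._ids:
            b0 = self._base0[tid]
            for off in range(len(self._seqs[tid])):
                self._members[b0 + off] = {tid: off}
        self.rejected_blocks = 0
        self.compacted = False
        # set by compact():
        self.nodes: dict[int, Node] = {}
        self.walks: dict[str, list[int]] = {}

    # ---------------------------------------------------------------- base level

    def _find(self, i: int) -> int:
        p = self._parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def merge_alignment(self, alignment: PairwiseAlignment) -> None:
        """Unify aligned bases block by block (whole blocks are atomic)."""
        if self.compacted:
            raise DataError("merge_alignment must run before compaction")
        if alignment.strand != "+":
            raise DataError("alignments must be strand-normalized before merging")
        q0 = self._base0[alignment.query_id]
        t0 = self._base0[alignment.target_id]
        for q, t, ln in alignment.blocks:
            pairs = [(self._find(q0 + q + i), self._find(t0 + t + i)) for i in range(ln)]
            if self._block_consistent(pairs):
                for ra, rb in pairs:
                    self._union(ra, rb)
            else:
                self.rejected_blocks += 1
                log.debug("cluster %s: rejected inconsistent block (%d,%d,%d) %s/%s",
                          self.cluster_id, q, t, ln, alignment.query_id, alignment.target_id)

    def _block_consistent(self, pairs: list[tuple[int, int]]) -> bool:
        """Would applying all unions keep letters and per-transcript placement consistent?"""
        gparent: dict[int, int] = {}

        def gfind(r: int) -> int:
            while gparent.setdefault(r, r) != r:
                gparent[r] = gparent[gparent[r]]
                r = gparent[r]
            return r

        groups: dict[int, list[int]] = {}
        for ra, rb in pairs:
            ga, gb = gfind(ra), gfind(rb)
            if ga != gb:
                gparent[gb] = ga
        for r in gparent:
            groups.setdefault(gfind(r), []).append(r)
        for roots in groups.values():
            if len(roots) < 2:
                continue
            if len({self._letters[r] for r in roots}) > 1:
                return False
            seen: dict[str, int] = {}
            for r in roots:
                for tid, off in self._members[r].items():  # type: ignore[union-attr]
                    if seen.setdefault(tid, off) != off:
                        return False
        return True

    def _union(self, ra: int, rb: int) -> None:
        ra, rb = self._find(ra), self._find(rb)
        if ra == rb:
            return
        ma, mb = self._members[ra], self._members[rb]
        if len(ma) < len(mb):  # type: ignore[arg-type]
            ra, rb, ma, mb = rb, ra, mb, ma
        ma.update(mb)  # type: ignore[union-attr]
        self._members[rb] = None
        self._parent[rb] = ra

    # --------------------------------------------------------------- views

    def _base_walks(self) -> dict[str, list[int]]:
        return {
            tid: [self._find(self._base0[tid] + o) for o in range(len(self._seqs[tid]))]
            for tid in self._ids
        }

    def _current_walks(self) -> dict[str, list[int]]:
        if self.compacted:
            return self.walks
        walks = {}
        for tid, w in self._base_walks().items():
            walks[tid] = [n for n, _ in itertools.groupby(w)]
        return walks

    @property
    def node_count(self) -> int:
        if self.compacted:
            return len(self.nodes)
        return len({self._find(i) for i in range(self.total_bases)})

    def edges(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for w in self._current_walks().values():
            out.update(zip(w, w[1:]))
        return out

    @property
    def edge_count(self) -> int:
        return len(self.edges())

    def anchor(self, node_id: int) -> tuple[int, int]:
        """Minimal (input_rank, offset) among the node's members."""
        m = self.nodes[node_id].members
        return min((self._ranks[t], o) for t, o in m.items())

    def to_networkx(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        if self.compacted:
            g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    # ------------------------------------------------------------ compaction

    def compact(self) -> "SpliceGraph":
        """Collapse maximal non-diverging base runs into string nodes.

        Interior steps of a run must have in-degree 1 and out-degree 1 and
        carry exactly the same transcripts one base further, so every member
        spans the whole run.
        """
        if self.compacted:
            return self
        walks = self._base_walks()
        succ: dict[int, set[int]] = {}
        pred: dict[int, set[int]] = {}
        for w in walks.values():
            for u, v in zip(w, w[1:]):
                succ.setdefault(u, set()).add(v)
                pred.setdefault(v, set()).add(u)

        def mergeable(u: int, v: int) -> bool:
            if succ.get(u) != {v} or pred.get(v) != {u}:
                return False
            mu, mv = self._members[u], self._members[v]
            if len(mu) != len(mv):  # type: ignore[arg-type]
                return False
            return all(mv.get(t, -2) == o + 1 for t, o in mu.items())  # type: ignore[union-attr]

        absorbed = set()
        classes = {self._find(i) for i in range(self.total_bases)}
        for v in classes:
            p = pred.get(v)
            if p and len(p) == 1 and mergeable(next(iter(p)), v):
                absorbed.add(v)

        class_to_node: dict[int, int] = {}
        runs: list[list[int]] = []
        for c in sorted(classes, key=lambda c: min((self._ranks[t], o) for t, o in self._members[c].items())):
            if c in absorbed:
                continue
            run = [c]
            cur = c
            while True:
                s = succ.get(cur)
                if s and len(s) == 1 and next(iter(s)) in absorbed:
                    cur = next(iter(s))
                    run.append(cur)
                else:
                    break
            runs.append(run)
        self.nodes = {}
        for nid, run in enumerate(runs):
            self.nodes[nid] = Node("".join(self._letters[c] for c in run), dict(self._members[run[0]]))  # type: ignore[arg-type]
            for c in run:
                class_to_node[c] = nid
        self.walks = {
            tid: [n for n, _ in itertools.groupby(class_to_node[c] for c in w)]
            for tid, w in walks.items()
        }
        self.compacted = True
        return self

    # --------------------------------------------------------- cycle breaking

    def break_cycles(self) -> "SpliceGraph":
        """Duplicate the smallest node of each cycle until the graph is a DAG.

        Among a cycle's nodes the one with the fewest bases is selected (ties
        by smallest anchor) and duplicated; members entering it along the
        cycle's closing edge move to the duplicate, which inherits their
        outgoing continuations, so every transcript walk stays intact while
        the cycle's back edge disappears.
        """
        if not self.compacted:
            raise DataError("break_cycles requires a compacted graph")
        next_id = max(self.nodes, default=-1) + 1
        for _ in range(self.total_bases + 1):
            g = self.to_networkx()
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                return self
            cyc_pred = {v: u for u, v in cycle}
            sel = moved = None
            for n in sorted(cyc_pred, key=lambda n: (len(self.nodes[n].bases), self.anchor(n))):
                split: dict[str, int] = {}
                for tid, off in self.nodes[n].members.items():
                    w = self.walks[tid]
                    i = w.index(n)
                    if i > 0 and w[i - 1] == cyc_pred[n]:
                        split[tid] = off
                # a node whose members do not all arrive along the cycle must
                # exist (walks are finite); only such a split separates it
                if 0 < len(split) < len(self.nodes[n].members):
                    sel, moved = n, split
                    break
            if sel is None:
                raise DataError(f"cluster {self.cluster_id!r}: unexpected inseparable cycle")
            node = self.nodes[sel]
            dup = next_id
            next_id += 1
            self.nodes[dup] = Node(node.bases, moved)
            for tid in moved:
                del node.members[tid]
                w = self.walks[tid]
                w[w.index(sel)] = dup
            if not node.members:
                del self.nodes[sel]
        raise DataError(f"cluster {self.cluster_id!r}: cycle breaking did not converge")

    # ------------------------------------------------------------- topo sort

    def topo_sort(self) -> SuperTranscript:
        """Kahn's algorithm with anchor tie-breaking; emits the superTranscript."""
        import heapq

        if not self.compacted:
            raise DataError("topo_sort requires a compacted graph")
        indeg = {n: 0 for n in self.nodes}
        adj: dict[int, set[int]] = {n: set() for n in self.nodes}
        for u, v in self.edges():
            if v not in adj[u]:
                adj[u].add(v)
                indeg[v] += 1
        ready = [(self.anchor(n), n) for n in self.nodes if indeg[n] == 0]
        heapq.heapify(ready)
        pos: dict[int, tuple[int, int]] = {}
        cursor = 0
        order: list[int] = []
        while ready:
            _, n = heapq.heappop(ready)
            order.append(n)
            pos[n] = (cursor, cursor + len(self.nodes[n].bases))
            cursor = pos[n][1]
            for v in sorted(adj[n]):
                indeg[v] -= 1
                if indeg[v] == 0:
                    heapq.heappush(ready, (self.anchor(v), v))
        if len(order) != len(self.nodes):
            raise DataError(f"cluster {self.cluster_id!r}: graph still cyclic after break_cycles")
        sequence = "".join(self.nodes[n].bases for n in order)
        paths: dict[str, list[tuple[int, int]]] = {}
        for tid in self._ids:
            intervals: list[tuple[int, int]] = []
            for n in self.walks[tid]:
                s, e = pos[n]
                if intervals and intervals[-1][1] == s:
                    intervals[-1] = (intervals[-1][0], e)
                else:
                    intervals.append((s, e))
            paths[tid] = intervals
        return SuperTranscript(self.cluster_id, sequence, paths, used_transcripts=list(self._ids))


def build_graph(cluster: Cluster) -> SpliceGraph:
    """One node per transcript base, edges following each transcript."""
    return SpliceGraph(cluster)


def assemble_cluster(
    cluster: Cluster,
    options: AssemblyOptions | None = None,
    alignments: list[PairwiseAlignment] | None = None,
) -> SuperTranscript:
    """End-to-end assembly of one cluster into its superTranscript.

    Orientation normalization, all-vs-all alignment (or externally supplied
    alignments, e.g. from PSL), base merging, compaction, cycle breaking and
    topological sorting.  Only the first ``options.max_transcripts``
    transcripts take part; the remainder are reported as skipped.
    """
    opts = options or AssemblyOptions()
    used = [
        Transcript(t.id, t.sequence, cluster.cluster_id, i)
        for i, t in enumerate(cluster.transcripts[:opts.max_transcripts])
    ]
    skipped = [t.id for t in cluster.transcripts[opts.max_transcripts:]]
    sub = Cluster(cluster.cluster_id, used)
    used_ids = {t.id for t in used}
    lens = {t.id: len(t.sequence) for t in used}

    external = alignments is not None
    if external:
        als = [a for a in alignments if a.query_id in used_ids and a.target_id in used_ids]
    else:
        als, _ = cluster_alignments(sub, opts.max_transcripts, opts.min_block_len,
                                    opts.min_identity, opts.kmer)
    oriented, flipped = orient_cluster(sub, als)
    if flipped:
        if external:
            als = [
                a2 for a in als
                if (a2 := reorient_alignment(a, a.query_id in flipped, a.target_id in flipped,
                                             lens[a.query_id], lens[a.target_id])) is not None
            ]
        else:
            als, _ = cluster_alignments(oriented, opts.max_transcripts, opts.min_block_len,
                                        opts.min_identity, opts.kmer)
    als = [a for a in als if a.strand == "+"]

    graph = build_graph(oriented)
    for al in als:
        graph.merge_alignment(al)
    graph.compact()
    graph.break_cycles()
    st = graph.topo_sort()
    st.skipped_transcripts = skipped
    if graph.rejected_blocks:
        log.info("cluster %s: %d inconsistent alignment block(s) rejected",
                 cluster.cluster_id, graph.rejected_blocks)
    return st
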