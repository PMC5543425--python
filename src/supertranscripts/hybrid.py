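"""Merging a genome-based superTranscriptome with de novo contigs.

Contigs are assigned to genes by alignment against the genome-based
superTranscripts: a contig with exactly one qualifying hit joins that gene's
cluster, a contig matching two or more superTranscripts is discarded as a
likely chimera, and a contig with none can be retried against an optional
secondary reference (e.g. a related species' superTranscriptome) before
being dropped.  Each cluster — the genome-based superTranscript first, so it
anchors the ordering — is then re-assembled with the splice-graph core, and
per-source base coverage of the merged product is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import align_pair
from .graph import AssemblyOptions, assemble_cluster
from .model import Cluster, DataError, PairwiseAlignment, SuperTranscript, Transcript

log = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 200  # min matched bases for a qualifying assignment hit
DEFAULT_MIN_IDENTITY = 0.98


@dataclass
class ContigAssignment:
    assigned: dict[str, str] = field(default_factory=dict)  # contig -> superTranscript
    discarded_chimeric: list[str] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)


def assign_contigs(
    contig_ids: list[str],
    alignments: list[PairwiseAlignment],
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ContigAssignment:
    """Assign each contig to the single superTranscript it aligns to.

    Only qualifying hits (score >= min_score matched bases and identity >=
    min_identity) count; a contig with two or more qualifying targets is
    discarded as chimeric.
    """
    hits: dict[str, set[str]] = {cid: set() for cid in contig_ids}
    for al in alignments:
        if al.query_id not in hits:
            continue
        if al.score >= min_score and al.identity >= min_identity:
            hits[al.query_id].add(al.target_id)
    out = ContigAssignment()
    for cid in contig_ids:
        targets = sorted(hits[cid])
        if len(targets) == 1:
            out.assigned[cid] = targets[0]
        elif len(targets) >= 2:
            out.discarded_chimeric.append(cid)
        else:
            out.unassigned.append(cid)
    return out


def assign_with_secondary(
    contig_ids: list[str],
    primary_alignments: list[PairwiseAlignment],
    secondary_alignments: list[PairwiseAlignment] | None = None,
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[ContigAssignment, ContigAssignment | None]:
    """Primary assignment plus an optional homology-based rescue pass.

    Contigs unassigned against the primary reference are re-assigned against
    a secondary one; contigs failing both passes (or chimeric in either) are
    dropped.
    """
    primary = assign_contigs(contig_ids, primary_alignments, min_score, min_identity)
    if secondary_alignments is None or not primary.unassigned:
        return primary, None
    secondary = assign_contigs(primary.unassigned, secondary_alignments, min_score, min_identity)
    return primary, secondary


def align_contigs(
    contigs: dict[str, str],
    sts: list[SuperTranscript],
    min_block_len: int = 20,
    kmer: int = 11,
) -> list[PairwiseAlignment]:
    """All contig-vs-superTranscript alignments with the built-in aligner."""
    out = []
    for cid in sorted(contigs):
        for st in sorted(sts, key=lambda s: s.cluster_id):
            al = align_pair(contigs[cid], st.sequence, min_block_len=min_block_len,
                            k=kmer, query_id=cid, target_id=st.cluster_id)
            if al is not None:
                out.append(al)
    return out


def rebuild(
    sts: list[SuperTranscript],
    assignment: ContigAssignment,
    contigs: dict[str, str],
    options: AssemblyOptions | None = None,
) -> list[SuperTranscript]:
    """Re-assemble every cluster of {genome-based superTranscript + contigs}.

    The genome-based sequence enters at input rank 0, so shared sequence
    keeps its genome-based order and every genome-based base survives.
    """
    by_st: dict[str, list[str]] = {}
    for cid, st_id in sorted(assignment.assigned.items()):
        by_st.setdefault(st_id, []).append(cid)
    merged = []
    for st in sorted(sts, key=lambda s: s.cluster_id):
        members = [Transcript(st.cluster_id, st.sequence, st.cluster_id, 0)]
        for i, cid in enumerate(by_st.get(st.cluster_id, []), 1):
            members.append(Transcript(cid, contigs[cid], st.cluster_id, i))
        merged.append(assemble_cluster(Cluster(st.cluster_id, members), options))
    return merged


def coverage_report(
    st: SuperTranscript, source_of: dict[str, str]
) -> dict[str, float]:
    """Fraction of superTranscript bases covered by each source's paths.

    ``source_of`` labels every member transcript (e.g. "genome", "trinity").
    The extra key ``"novel"`` reports the fraction covered by none of the
    sources marked, i.e. candidate novel sequence when the map only labels
    genome-based inputs.
    """
    L = len(st)
    if L == 0:
        raise DataError("empty superTranscript")
    covered: dict[str, bytearray] = {}
    any_mask = bytearray(L)
    for tid, path in st.paths.items():
        src = source_of.get(tid)
        if src is None:
            continue
        mask = covered.setdefault(src, bytearray(L))
        for s, e in path:
            for i in range(s, e):
                mask[i] = 1
                any_mask[i] = 1
    report = {src: sum(mask) / L for src, mask in sorted(covered.items())}
    report["novel"] = (L - sum(any_mask)) / L
    return report
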