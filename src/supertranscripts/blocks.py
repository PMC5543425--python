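"""Block annotation of superTranscripts.

Standard blocks come from the splicing structure itself: every start or end
of a transcript path interval is a fork/divergence of the splice graph and
becomes a boundary.  Dynamic blocks come from the data instead: splice
junctions observed in reads mapped back to the superTranscript (CIGAR N
operations) that pass a support threshold define the boundaries.  Both
annotations partition [0, L).
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import pysam

from .model import Block, DataError, Junction, SuperTranscript, check_partition

log = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 5
DEFAULT_MIN_OVERHANG = 12

_REF_CONSUMES = {0, 2, 3, 7, 8}  # M, D, N, =, X
_MATCH_OPS = {0, 7, 8}


def _blocks_from_boundaries(boundaries: set[int], length: int, kind: str) -> list[Block]:
    cuts = sorted(boundaries | {0, length})
    cuts = [c for c in cuts if 0 <= c <= length]
    return [Block(s, e, kind) for s, e in zip(cuts, cuts[1:]) if s < e]


def standard_blocks(st: SuperTranscript) -> list[Block]:
    """Blocks delimited by every transcript-path interval endpoint."""
    bounds: set[int] = set()
    for path in st.paths.values():
        for s, e in path:
            bounds.update((s, e))
    blocks = _blocks_from_boundaries(bounds, len(st), "standard")
    check_partition(blocks, len(st))
    return blocks


def extract_junctions(
    alignment_path: str | Path,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> dict[str, list[Junction]]:
    """Splice junctions per superTranscript from a SAM/BAM of mapped reads.

    Each N operation in a primary mapped record yields one candidate
    junction (the skipped reference interval); candidates whose flanking
    matched stretches are shorter than ``min_overhang`` on either side are
    ignored, mirroring the usual aligner splice-junction overhang filter.
    """
    counts: dict[str, Counter[tuple[int, int]]] = {}
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                continue
            ref = rec.reference_name
            pos = rec.reference_start
            # split cigar into matched stretches separated by N skips
            segments: list[int] = [0]
            skips: list[tuple[int, int]] = []
            for op, ln in rec.cigartuples:
                if op == 3:
                    skips.append((pos, pos + ln))
                    segments.append(0)
                elif op in _MATCH_OPS:
                    segments[-1] += ln
                if op in _REF_CONSUMES:
                    pos += ln
            if ref in lengths and pos > lengths[ref]:
                log.warning("read %s: CIGAR extends past reference %s length; skipped", rec.query_name, ref)
                continue
            if not skips:
                continue
            for i, (left, right) in enumerate(skips):
                if segments[i] >= min_overhang and segments[i + 1] >= min_overhang:
                    counts.setdefault(ref, Counter())[(left, right)] += 1
    return {
        ref: [Junction(l, r, n) for (l, r), n in sorted(c.items())]
        for ref, c in counts.items()
    }


def dynamic_blocks(
    st_length: int,
    junctions: list[Junction],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[Block]:
    """Blocks bounded by junctions with support >= min_support (default 5)."""
    bounds: set[int] = set()
    for j in junctions:
        if j.right > st_length:
            raise DataError(f"junction [{j.left},{j.right}) outside superTranscript of length {st_length}")
        if j.support >= min_support:
            bounds.update((j.left, j.right))
    blocks = _blocks_from_boundaries(bounds, st_length, "dynamic")
    check_partition(blocks, st_length)
    return blocks


def annotate(
    sts: list[SuperTranscript],
    mode: str = "standard",
    junctions: dict[str, list[Junction]] | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> dict[str, list[Block]]:
    """Per-superTranscript block annotation in the requested mode."""
    if mode not in ("standard", "dynamic"):
        raise DataError(f"unknown annotation mode {mode!r}")
    out: dict[str, list[Block]] = {}
    for st in sts:
        if mode == "standard":
            out[st.cluster_id] = standard_blocks(st)
        else:
            juncs = (junctions or {}).get(st.cluster_id, [])
            out[st.cluster_id] = dynamic_blocks(len(st), juncs, min_support)
    return out
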