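"""Readers and writers: transcript FASTA + cluster TSV in, superTranscriptome
FASTA + GFF3 out, and a round-trip reader for the emitted pair.

The GFF3 layout is one ``gene`` feature per superTranscript, ``exon``
features for annotation blocks (the block kind in the source column), a
``match`` feature per member transcript and ``match_part`` features for its
path segments.  seqid is the cluster id and coordinates are 1-based
inclusive — the only place in the package where they are.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

from Bio import SeqIO

from .model import Block, Cluster, DataError, SuperTranscript, Transcript

log = logging.getLogger(__name__)

_HEADER_NAMES = {"transcript_id", "transcript", "contig", "cluster_id", "cluster", "gene_id", "gene"}


def _clean_sequence(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        warnings.warn(f"transcript {name!r}: non-ACGTN characters {bad} replaced by N")
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to an id→sequence dict; duplicate ids are a hard error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DataError(f"duplicate transcript id {rec.id!r} in {path}")
        seqs[rec.id] = _clean_sequence(str(rec.seq), rec.id)
    return seqs


def read_clusters_table(path: str | Path) -> list[tuple[str, str]]:
    """Two-column (transcript_id, cluster_id) TSV, Corset style.

    Blank lines are ignored; an optional single header line (starting with
    '#' or made of canonical column names) is skipped.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}")
            if not rows and (line.startswith("#") or {f.strip().lower() for f in fields} <= _HEADER_NAMES):
                continue
            rows.append((fields[0].strip(), fields[1].strip()))
    return rows


def read_transcripts(fasta_path: str | Path, cluster_path: str | Path) -> list[Cluster]:
    """Load transcripts grouped into clusters, input order preserved.

    A transcript named in the cluster table but absent from the FASTA is a
    hard error; a FASTA record absent from the table is dropped with a
    warning.
    """
    seqs = read_fasta(fasta_path)
    rows = read_clusters_table(cluster_path)
    seen: set[str] = set()
    order: list[str] = []
    members: dict[str, list[Transcript]] = {}
    for tid, cid in rows:
        if tid in seen:
            raise DataError(f"transcript {tid!r} listed twice in {cluster_path}")
        seen.add(tid)
        if tid not in seqs:
            raise DataError(f"transcript {tid!r} in cluster file is absent from the FASTA")
        if cid not in members:
            members[cid] = []
            order.append(cid)
        members[cid].append(Transcript(tid, seqs[tid], cid, len(members[cid])))
    unused = set(seqs) - seen
    if unused:
        warnings.warn(f"{len(unused)} FASTA record(s) not in the cluster file were dropped "
                      f"(e.g. {sorted(unused)[0]!r})")
    return [Cluster(cid, members[cid]) for cid in order]


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_supertranscriptome(
    sts: list[SuperTranscript],
    annotations: dict[str, list[Block]],
    fasta_out: str | Path,
    gff_out: str | Path,
) -> None:
    """Write the superTranscriptome FASTA and its GFF3 annotation.

    Record order is lexicographic by cluster id, then coordinate, so two
    runs on identical input are byte-identical.
    """
    sts_sorted = sorted(sts, key=lambda s: s.cluster_id)
    by_id = {s.cluster_id: s for s in sts_sorted}
    for cid, blocks in annotations.items():
        if cid not in by_id:
            raise DataError(f"annotation references unknown superTranscript {cid!r}")
        for b in blocks:
            if b.st_end > len(by_id[cid]):
                raise DataError(f"block [{b.st_start},{b.st_end}) exceeds {cid!r} length {len(by_id[cid])}")

    write_fasta([(s.cluster_id, s.sequence) for s in sts_sorted], fasta_out)

    with open(gff_out, "w") as fh:
        fh.write("##gff-version 3\n")
        for st in sts_sorted:
            cid, L = st.cluster_id, len(st)
            fh.write(f"##sequence-region {cid} 1 {L}\n")
            fh.write(_line(cid, "superT", "gene", 0, L, f"ID={cid}"))
            for i, b in enumerate(sorted(annotations.get(cid, []), key=lambda b: (b.st_start, b.st_end))):
                fh.write(_line(cid, b.kind, "exon", b.st_start, b.st_end,
                               f"ID={cid}:block:{i}:{b.kind};Parent={cid}"))
            for tid in sorted(st.paths):
                path = st.paths[tid]
                span = (min(s for s, _ in path), max(e for _, e in path))
                fh.write(_line(cid, "superT", "match", span[0], span[1],
                               f"ID={cid}:{tid};Name={tid};Parent={cid}"))
                for s, e in path:
                    fh.write(_line(cid, "superT", "match_part", s, e,
                                   f"Parent={cid}:{tid};Name={tid}"))


def _line(seqid: str, source: str, ftype: str, start0: int, end0: int, attrs: str) -> str:
    # 0-based half-open -> 1-based inclusive happens here and only here
    return f"{seqid}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t+\t.\t{attrs}\n"


def read_supertranscriptome(
    fasta_path: str | Path, gff_path: str | Path
) -> tuple[list[SuperTranscript], dict[str, list[Block]]]:
    """Round-trip reader for the files written by write_supertranscriptome."""
    seqs = read_fasta(fasta_path)
    paths: dict[str, dict[str, list[tuple[int, int]]]] = {cid: {} for cid in seqs}
    blocks: dict[str, list[Block]] = {cid: [] for cid in seqs}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise DataError(f"{gff_path}:{lineno}: expected 9 GFF columns")
            seqid, source, ftype, start, end = f[0], f[1], f[2], int(f[3]) - 1, int(f[4])
            if seqid not in seqs:
                raise DataError(f"{gff_path}:{lineno}: unknown seqid {seqid!r}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if ftype == "exon":
                blocks[seqid].append(Block(start, end, source))
            elif ftype == "match_part":
                paths[seqid].setdefault(attrs["Name"], []).append((start, end))
    sts = [
        SuperTranscript(cid, seqs[cid], {t: sorted(iv) for t, iv in paths[cid].items()},
                        used_transcripts=sorted(paths[cid]))
        for cid in sorted(seqs)
    ]
    return sts, blocks
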