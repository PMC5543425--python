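"""Domain types shared across the package.

All coordinates are 0-based half-open; conversion to 1-based inclusive
happens only when writing GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 2)."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    """One input cDNA/contig sequence and its gene-cluster membership."""

    id: str
    sequence: str
    cluster_id: str
    input_rank: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"transcript {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Cluster:
    """An ordered set of transcripts assigned to one gene."""

    cluster_id: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        for rank, t in enumerate(self.transcripts):
            t.input_rank = rank
            t.cluster_id = self.cluster_id

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass
class PairwiseAlignment:
    """Co-linear gapless block pairs linking two transcripts.

    ``blocks`` are (q_start, t_start, length) triples, 0-based half-open,
    strictly increasing and non-overlapping on both sequences.  For a '−'
    strand alignment the query coordinates refer to the reverse-complemented
    query (the orientation in which it matches the target forward), which is
    also the frame PSL uses for minus-strand qStarts.
    """

    query_id: str
    target_id: str
    strand: str
    blocks: list[tuple[int, int, int]]
    identity: float
    score: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError(f"bad strand {self.strand!r}")
        prev_q = prev_t = -1
        for q, t, ln in self.blocks:
            if ln < 1:
                raise DataError("alignment block length < 1")
            if q < prev_q or t < prev_t:
                raise DataError("alignment blocks not co-linear")
            prev_q, prev_t = q + ln, t + ln

    @property
    def matched(self) -> int:
        return sum(ln for _, _, ln in self.blocks)


@dataclass
class SuperTranscript:
    """The sorted linear sequence for one cluster plus per-transcript paths.

    ``paths`` maps transcript id to an ordered list of half-open
    (st_start, st_end) intervals; concatenating ``sequence[s:e]`` over the
    path reproduces the (possibly re-oriented) transcript exactly.
    """

    cluster_id: str
    sequence: str
    paths: dict[str, list[tuple[int, int]]]
    used_transcripts: list[str] = field(default_factory=list)
    skipped_transcripts: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def extract(self, transcript_id: str) -> str:
        """Sequence spelled by a transcript's path."""
        return "".join(self.sequence[s:e] for s, e in self.paths[transcript_id])


@dataclass(frozen=True)
class Block:
    """A half-open superTranscript interval used as a counting bin."""

    st_start: int
    st_end: int
    kind: str = "standard"

    def __post_init__(self) -> None:
        if not 0 <= self.st_start < self.st_end:
            raise DataError(f"bad block [{self.st_start},{self.st_end})")

    def __len__(self) -> int:
        return self.st_end - self.st_start


@dataclass(frozen=True)
class Junction:
    """A read-supported splice junction: the skip covers [left, right)."""

    left: int
    right: int
    support: int

    def __post_init__(self) -> None:
        if not 0 <= self.left < self.right:
            raise DataError(f"bad junction [{self.left},{self.right})")
        if self.support < 1:
            raise DataError("junction support must be >= 1")


def check_partition(blocks: list[Block], length: int) -> None:
    """Raise unless ``blocks`` exactly partition [0, length)."""
    pos = 0
    for b in sorted(blocks, key=lambda b: b.st_start):
        if b.st_start != pos:
            raise DataError(f"blocks do not partition [0,{length}): gap/overlap at {pos}")
        pos = b.st_end
    if pos != length:
        raise DataError(f"blocks end at {pos}, expected {length}")
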