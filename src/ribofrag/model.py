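"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` regardless of
the on-disk format they came from; format readers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STRANDS = frozenset({"+", "-", "."})

#: feature biotypes the pipeline distinguishes
BIOTYPES = frozenset(
    {"ncRNA", "CDS", "ORF_candidate", "CRISPR_repeat", "CRISPR_spacer", "other"}
)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A strand-aware span on a contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.contig}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap (>= 1 nt) under the half-open convention; strand-agnostic."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One aligned read/fragment.

    ``interval`` is the reference span (leftmost to rightmost aligned base);
    ``query_length`` is the aligned query length.  For the ungapped alignments
    this pipeline consumes the two lengths coincide.
    """

    interval: GenomicInterval
    query_length: int
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.query_length <= 0:
            raise ValueError("query_length must be positive")


@dataclass(frozen=True, slots=True)
class Feature:
    """An annotated genomic feature (ncRNA, CDS, CRISPR repeat, ...)."""

    id: str
    interval: GenomicInterval
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for feature {self.id}")


@dataclass(frozen=True, slots=True)
class ProdigalScore:
    """Start-site and coding-potential scores for one candidate ORF.

    Mirrors the per-ORF rows of Prodigal's ``-s`` intermediate table; the
    scores are unitless log-odds-style values where > 0 means support.
    """

    orf_id: str
    interval: GenomicInterval
    start_score: float
    coding_score: float
    rbs_motif: str = ""


class StructureAnnotation:
    """An RNA sequence with its secondary structure in dot-bracket notation.

    Parentheses mark paired positions, dots unpaired ones.  The annotation
    validates itself on construction: sequence and structure must have equal
    length, the alphabet is {A, C, G, T, U, N}, and the brackets must balance.
    """

    __slots__ = ("feature_id", "sequence", "dotbracket", "_paired_mask")

    def __init__(self, feature_id: str, sequence: str, dotbracket: str):
        sequence = sequence.upper()
        if len(sequence) != len(dotbracket):
            raise ValueError(
                f"{feature_id}: sequence length {len(sequence)} != "
                f"structure length {len(dotbracket)}"
            )
        bad = set(sequence) - set("ACGTUN")
        if bad:
            raise ValueError(f"{feature_id}: invalid sequence characters {sorted(bad)}")
        depth = 0
        for i, c in enumerate(dotbracket):
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(
                        f"{feature_id}: unbalanced ')' at position {i}"
                    )
            elif c != ".":
                raise ValueError(
                    f"{feature_id}: invalid structure character {c!r} at position {i}"
                )
        if depth != 0:
            raise ValueError(f"{feature_id}: {depth} unclosed '(' in structure")
        self.feature_id = feature_id
        self.sequence = sequence
        self.dotbracket = dotbracket
        self._paired_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def paired_mask(self) -> np.ndarray:
        """Boolean array, True where the position is base-paired."""
        if self._paired_mask is None:
            arr = np.frombuffer(self.dotbracket.encode("ascii"), dtype=np.uint8)
            self._paired_mask = (arr == ord("(")) | (arr == ord(")"))
        return self._paired_mask

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureAnnotation):
            return NotImplemented
        return (
            self.feature_id == other.feature_id
            and self.sequence == other.sequence
            and self.dotbracket == other.dotbracket
        )

    def __repr__(self) -> str:
        return (
            f"StructureAnnotation({self.feature_id!r}, length={len(self)}, "
            f"paired={int(self.paired_mask.sum())})"
        )


@dataclass(frozen=True, slots=True)
class CrisprArray:
    """An ordered CRISPR array: alternating direct repeats and spacers.

    Repeats come from annotation rows (minCED-style); spacers are the gaps
    between consecutive repeats.  Repeats and spacers are disjoint and tile
    the span between the first and last repeat.
    """

    array_id: str
    span: GenomicInterval
    repeats: tuple[GenomicInterval, ...]
    spacers: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.repeats:
            raise ValueError(f"array {self.array_id} has no repeats")
        for a, b in zip(self.repeats, self.repeats[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"array {self.array_id}: overlapping repeats "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError(
                f"array {self.array_id}: {len(self.repeats)} repeats require "
                f"{len(self.repeats) - 1} spacers, got {len(self.spacers)}"
            )

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)
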