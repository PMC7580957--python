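"""Per-feature read counting and RPKM expression calls.

RPKM (reads per kilobase of feature per million mapped reads) is the
expression measure used throughout:

    rpkm = count / (length / 1e3) / (total_mapped / 1e6)

A feature is called "expressed" when its RPKM strictly exceeds the
threshold (default 10).  Counting is any-overlap (>= 1 nt) and, by default,
strand-agnostic — the behaviour of ``bedtools multicov`` without flags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import Feature, ReadAlignment

DEFAULT_RPKM_THRESHOLD = 10.0


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    feature_id: str
    read_count: int
    feature_length: int
    total_mapped: int
    rpkm: float
    expressed: bool


def compute_rpkm(read_count: int, feature_length: int, total_mapped: int) -> float:
    """RPKM for one feature; raises on an empty library or empty feature."""
    if total_mapped <= 0:
        raise ValueError("empty library: total_mapped must be > 0")
    if feature_length <= 0:
        raise ValueError("feature_length must be > 0")
    return read_count / (feature_length / 1e3) / (total_mapped / 1e6)


def count_overlapping_reads(
    reads: Sequence[ReadAlignment], feature: Feature, stranded: bool = False
) -> int:
    """Number of reads overlapping the feature by >= 1 nt (half-open).

    Abutting intervals ([100,120) vs [120,200)) do not overlap.  With
    ``stranded=True`` only reads on the feature's strand are counted.
    """
    iv = feature.interval
    n = 0
    for r in reads:
        if not r.interval.overlaps(iv):
            continue
        if stranded and r.interval.strand != iv.strand:
            continue
        n += 1
    return n


def build_expression_table(
    reads: Sequence[ReadAlignment],
    features: Sequence[Feature],
    total_mapped: int | None = None,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
    stranded: bool = False,
) -> list[ExpressionRecord]:
    """Count reads over each feature and compute RPKM expression calls.

    ``total_mapped`` defaults to the number of alignments in ``reads`` (all
    primary mapped alignments in the library, not just those over features).
    Uses an interval tree per contig so many features stay fast.
    """
    if total_mapped is None:
        total_mapped = len(reads)
    trees: dict[str, IntervalTree] = {}
    # data carries the read index: duplicate alignments are kept, not merged
    for i, r in enumerate(reads):
        trees.setdefault(r.interval.contig, IntervalTree()).addi(
            r.interval.start, r.interval.end, (i, r.interval.strand)
        )
    records = []
    for f in features:
        iv = f.interval
        tree = trees.get(iv.contig)
        hits = tree.overlap(iv.start, iv.end) if tree is not None else ()
        if stranded:
            count = sum(1 for h in hits if h.data[1] == iv.strand)
        else:
            count = len(hits)
        rpkm = compute_rpkm(count, iv.length, total_mapped)
        records.append(
            ExpressionRecord(
                f.id, count, iv.length, total_mapped, rpkm, rpkm > threshold
            )
        )
    return records


def classify_expression(
    records: Sequence[ExpressionRecord], threshold: float = DEFAULT_RPKM_THRESHOLD
) -> list[ExpressionRecord]:
    """Re-flag records against a threshold; strict ``rpkm > threshold``."""
    return [replace(r, expressed=r.rpkm > threshold) for r in records]


def expression_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "length": [r.feature_length for r in records],
            "count": [r.read_count for r in records],
            "total_mapped": [r.total_mapped for r in records],
            "rpkm": [r.rpkm for r in records],
            "expressed": [r.expressed for r in records],
        }
    )
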