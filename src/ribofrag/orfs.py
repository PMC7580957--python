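"""Exhaustive ORF enumeration, ribosome-binding-site detection, and
ncRNA/ORF overlap classification.

An ORF here is any span from a bacterial start codon (ATG, GTG, TTG) to the
nearest in-frame stop codon (TAA, TAG, TGA), stop included, on either strand.
Nested starts sharing a stop are distinct candidates.  With the default
15 nt length cutoff an ORF encodes at least 4 amino acids plus the stop.

An ncRNA's overlap status distinguishes three situations: no possible ORF
overlaps it at all; overlapping ORFs exist but none has any support; or at
least one overlapping ORF is supported by a positive start-site score, a
positive coding-potential score, a ribosome-binding site, or by being small
(< 50 aa), the size class where gene callers are unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .io import reverse_complement
from .model import Feature, GenomicInterval, ProdigalScore

logger = logging.getLogger(__name__)

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MIN_ORF_LEN = 15
DEFAULT_SMALL_ORF_AA = 50
DEFAULT_RBS_MOTIF = "AGGAGG"
DEFAULT_RBS_MAX_MISMATCH = 1
DEFAULT_RBS_SPACER_RANGE = (5, 13)

SUPPORT_KINDS = ("positive_start", "coding_potential", "rbs", "small_orf_lt50aa")


@dataclass(frozen=True, slots=True)
class OrfCandidate:
    """One candidate ORF: start codon through in-frame stop (stop included)."""

    interval: GenomicInterval
    frame: int  # (start offset on the strand's 5'->3' reading) mod 3
    start_codon: str
    length_nt: int
    start_score: float | None = None
    coding_score: float | None = None
    has_rbs: bool = False

    @property
    def length_aa(self) -> int:
        return self.length_nt // 3 - 1


@dataclass(frozen=True, slots=True)
class OverlapClassification:
    ncrna_id: str
    category: str  # no_possible_orf | possible_orf_only | orf_with_support
    supporting: frozenset[str]
    n_overlapping_orfs: int


def enumerate_orfs(
    genome: Mapping[str, str], min_len: int = DEFAULT_MIN_ORF_LEN
) -> list[OrfCandidate]:
    """Enumerate all possible ORFs on both strands and all three frames.

    ORFs shorter than ``min_len`` nt (stop codon included) are dropped; ORFs
    whose span contains an N are skipped with a log entry.  Sequence
    characters outside {A, C, G, T, N} raise ``ValueError``.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    orfs: list[OrfCandidate] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"contig {contig}: invalid nucleotide characters {sorted(bad)}"
            )
        length = len(seq)
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            for frame in range(3):
                pending_starts: list[int] = []
                for pos in range(frame, length - 2, 3):
                    codon = oriented[pos : pos + 3]
                    if codon in STOP_CODONS:
                        for s in pending_starts:
                            orf_len = pos + 3 - s
                            if orf_len < min_len:
                                continue
                            if "N" in oriented[s : pos + 3]:
                                logger.debug(
                                    "skipping ORF with N at %s:%d (%s)",
                                    contig, s, strand,
                                )
                                continue
                            if strand == "+":
                                g_start, g_end = s, pos + 3
                            else:
                                g_start, g_end = length - (pos + 3), length - s
                            orfs.append(
                                OrfCandidate(
                                    GenomicInterval(contig, g_start, g_end, strand),
                                    frame,
                                    oriented[s : s + 3],
                                    orf_len,
                                )
                            )
                        pending_starts.clear()
                    elif codon in START_CODONS:
                        pending_starts.append(pos)
    return orfs


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_rbs(
    genome: Mapping[str, str],
    orf: OrfCandidate,
    motif: str = DEFAULT_RBS_MOTIF,
    max_mismatch: int = DEFAULT_RBS_MAX_MISMATCH,
    spacer_range: tuple[int, int] = DEFAULT_RBS_SPACER_RANGE,
) -> bool:
    """Look for a Shine-Dalgarno-like motif upstream of the ORF start.

    True iff a window whose spacer (gap between motif end and start codon)
    lies in ``spacer_range`` matches ``motif`` with <= ``max_mismatch``
    mismatches, read 5'->3' on the ORF's strand.  ORFs with insufficient
    upstream sequence return False with a log entry.
    """
    seq = genome[orf.interval.contig].upper()
    lo, hi = spacer_range
    need = hi + len(motif)
    if orf.interval.strand == "+":
        start = orf.interval.start
        upstream = seq[max(0, start - need) : start]
    else:
        end = orf.interval.end
        upstream = reverse_complement(seq[end : end + need])
    if len(upstream) < lo + len(motif):
        logger.debug(
            "ORF at %s:%d has insufficient upstream sequence for RBS scan",
            orf.interval.contig, orf.interval.start,
        )
        return False
    # upstream is oriented 5'->3'; its right edge abuts the start codon
    for spacer in range(lo, hi + 1):
        win_end = len(upstream) - spacer
        win_start = win_end - len(motif)
        if win_start < 0:
            break
        if _mismatches(upstream[win_start:win_end], motif) <= max_mismatch:
            return True
    return False


def annotate_orfs(
    genome: Mapping[str, str],
    orfs: Sequence[OrfCandidate],
    scores: Sequence[ProdigalScore] | None = None,
    motif: str = DEFAULT_RBS_MOTIF,
    max_mismatch: int = DEFAULT_RBS_MAX_MISMATCH,
    spacer_range: tuple[int, int] = DEFAULT_RBS_SPACER_RANGE,
) -> list[OrfCandidate]:
    """Attach RBS flags and (optionally) Prodigal-style scores to ORFs.

    Scores join by exact (contig, start, end, strand); a score row whose
    coordinates match no enumerated ORF raises ``ValueError``.
    """
    by_coord: dict[tuple[str, int, int, str], float | None] = {}
    score_map: dict[tuple[str, int, int, str], ProdigalScore] = {}
    if scores:
        orf_keys = {
            (o.interval.contig, o.interval.start, o.interval.end, o.interval.strand)
            for o in orfs
        }
        for s in scores:
            key = (s.interval.contig, s.interval.start, s.interval.end, s.interval.strand)
            if key not in orf_keys:
                raise ValueError(
                    f"score record {s.orf_id} matches no enumerated ORF"
                )
            score_map[key] = s
    annotated = []
    for o in orfs:
        key = (o.interval.contig, o.interval.start, o.interval.end, o.interval.strand)
        s = score_map.get(key)
        annotated.append(
            replace(
                o,
                has_rbs=find_rbs(genome, o, motif, max_mismatch, spacer_range),
                start_score=s.start_score if s else None,
                coding_score=s.coding_score if s else None,
            )
        )
    return annotated


def classify_ncrna_overlap(
    ncrna: Feature,
    orfs: Sequence[OrfCandidate],
    small_orf_aa: int = DEFAULT_SMALL_ORF_AA,
) -> OverlapClassification:
    """Classify one ncRNA by the ORFs overlapping it (>= 1 nt, either strand).

    ``supporting`` lists every support criterion met by any overlapping ORF;
    the category is ``orf_with_support`` when that set is non-empty,
    ``possible_orf_only`` when ORFs overlap but none has support, and
    ``no_possible_orf`` when nothing overlaps.
    """
    overlapping = [o for o in orfs if o.interval.overlaps(ncrna.interval)]
    if not overlapping:
        return OverlapClassification(ncrna.id, "no_possible_orf", frozenset(), 0)
    supporting: set[str] = set()
    for o in overlapping:
        if o.start_score is not None and o.start_score > 0:
            supporting.add("positive_start")
        if o.coding_score is not None and o.coding_score > 0:
            supporting.add("coding_potential")
        if o.has_rbs:
            supporting.add("rbs")
        if o.length_aa < small_orf_aa:
            supporting.add("small_orf_lt50aa")
    category = "orf_with_support" if supporting else "possible_orf_only"
    return OverlapClassification(
        ncrna.id, category, frozenset(supporting), len(overlapping)
    )


def classify_all(
    ncrnas: Sequence[Feature],
    orfs: Sequence[OrfCandidate],
    small_orf_aa: int = DEFAULT_SMALL_ORF_AA,
) -> list[OverlapClassification]:
    return [classify_ncrna_overlap(n, orfs, small_orf_aa) for n in ncrnas]
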