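"""Readers and writers for every external format the pipeline touches.

Supported formats: BED6 and SAM/BAM alignments (via pysam), GFF3 annotations
(via gffutils), FASTA genomes (via Biopython), Vienna-style dot-bracket
structure files, Prodigal ``-s``-style score tables, and bedGraph tracks.

All coordinates are normalized to the internal 0-based half-open convention
on read and converted back on write.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

from .model import (
    Feature,
    GenomicInterval,
    ProdigalScore,
    ReadAlignment,
    StructureAnnotation,
)

logger = logging.getLogger(__name__)

# GFF3 "type" column -> internal biotype
_GFF_TYPE_MAP = {
    "ncRNA": "ncRNA",
    "CDS": "CDS",
    "ORF_candidate": "ORF_candidate",
    "repeat_region": "CRISPR_repeat",
    "direct_repeat": "CRISPR_repeat",
    "binding_site": "CRISPR_spacer",
}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a ``{contig: uppercase sequence}`` mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Alignments: BED6 and SAM/BAM
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    format: str | None = None,
    sample_id: str | None = None,
) -> list[ReadAlignment]:
    """Read aligned reads from a BED6 or SAM/BAM file.

    Unmapped, secondary, and supplementary SAM records are excluded.
    ``format`` may be ``"bed6"`` or ``"sam"``; when omitted it is inferred
    from the file suffix.  ``sample_id`` defaults to the file stem.

    Raises ``ValueError`` naming the line number on malformed records, and
    on BED rows whose strand column is missing.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            format = "bed6"
        elif suffix in (".sam", ".bam"):
            format = "sam"
        else:
            raise ValueError(f"cannot infer alignment format from {path.name!r}")
    sample_id = sample_id if sample_id is not None else path.stem
    if format == "bed6":
        return _read_bed6(path, sample_id)
    if format == "sam":
        return _read_sam(path, sample_id)
    raise ValueError(f"unknown alignment format {format!r}")


def _read_bed6(path: Path, sample_id: str) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED record has {len(fields)} fields, "
                    "need 6 (strand column is required)"
                )
            contig, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                interval = GenomicInterval(contig, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            reads.append(ReadAlignment(interval, end - start, sample_id))
    return reads


def _read_sam(path: Path, sample_id: str) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            qlen = rec.query_alignment_length or rec.reference_length
            if not qlen:
                raise ValueError(
                    f"{path}: read {rec.query_name!r} has no resolvable length"
                )
            interval = GenomicInterval(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
            reads.append(ReadAlignment(interval, qlen, sample_id))
    return reads


def write_bed6(reads: Sequence[ReadAlignment], path: str | Path) -> None:
    """Write alignments as BED6 (name = running read index, score = 0)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\tr{i}\t0\t{iv.strand}\n"
            )


def write_sam(
    reads: Sequence[ReadAlignment],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write ungapped alignments as headered SAM with placeholder sequence."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in contig_lengths.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as af:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(af.header)
            a.query_name = f"r{i}"
            a.reference_name = r.interval.contig
            a.reference_start = r.interval.start
            a.mapping_quality = 255
            a.flag = 16 if r.interval.strand == "-" else 0
            a.cigarstring = f"{r.query_length}M"
            a.query_sequence = "N" * r.query_length
            af.write(a)


# ---------------------------------------------------------------------------
# GFF3 features
# ---------------------------------------------------------------------------

def read_gff_features(
    path: str | Path,
    biotype_filter: set[str] | None = None,
) -> list[Feature]:
    """Read GFF3 rows as Features, converting 1-based inclusive coordinates
    to 0-based half-open.

    The ``ID`` attribute becomes ``Feature.id``; the GFF type column maps to
    the internal biotype vocabulary (unknown types become ``other``).
    Duplicate IDs raise ``ValueError`` listing the offenders.
    """
    features: list[Feature] = []
    seen: dict[str, int] = {}
    for rec in gffutils.DataIterator(str(path)):
        start0, end = rec.start - 1, rec.end
        if start0 >= end:
            raise ValueError(
                f"{path}: feature on {rec.seqid} has start {rec.start} > end {rec.end}"
            )
        fid = rec.attributes["ID"][0] if "ID" in rec.attributes else rec.id
        if not fid:
            raise ValueError(f"{path}: feature on {rec.seqid} has no ID attribute")
        seen[fid] = seen.get(fid, 0) + 1
        biotype = _GFF_TYPE_MAP.get(rec.featuretype, "other")
        features.append(
            Feature(fid, GenomicInterval(rec.seqid, start0, end, rec.strand), biotype)
        )
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate feature IDs: {', '.join(dupes)}")
    if biotype_filter is not None:
        features = [f for f in features if f.biotype in biotype_filter]
    return features


_BIOTYPE_TO_GFF = {
    "ncRNA": "ncRNA",
    "CDS": "CDS",
    "ORF_candidate": "ORF_candidate",
    "CRISPR_repeat": "repeat_region",
    "CRISPR_spacer": "binding_site",
    "other": "region",
}


def write_gff_features(features: Sequence[Feature], path: str | Path) -> None:
    """Write Features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        "ribofrag",
                        _BIOTYPE_TO_GFF.get(f.biotype, "region"),
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={f.id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Dot-bracket structures (Vienna style)
# ---------------------------------------------------------------------------

def read_dotbracket(path: str | Path) -> list[StructureAnnotation]:
    """Read a Vienna-style file of (``>header``, sequence, structure) triples.

    Validation (balanced brackets, equal lengths) happens in the
    ``StructureAnnotation`` constructor and raises ``ValueError``.
    """
    structures: list[StructureAnnotation] = []
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {lines[i]!r}")
        header = lines[i][1:].split()[0]
        structures.append(StructureAnnotation(header, lines[i + 1], lines[i + 2]))
        i += 3
    return structures


def write_dotbracket(
    structures: Iterable[StructureAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f">{s.feature_id}\n{s.sequence}\n{s.dotbracket}\n")


# ---------------------------------------------------------------------------
# Prodigal -s score tables
# ---------------------------------------------------------------------------

_PRODIGAL_COLUMNS = (
    "contig",
    "beg",
    "end",
    "strand",
    "start_score",
    "coding_score",
    "rbs_motif",
)


def read_prodigal_scores(path: str | Path) -> list[ProdigalScore]:
    """Read a Prodigal ``-s``-style tab-delimited score table.

    Expected data columns: contig, beg (1-based), end (inclusive), strand,
    start_score, coding_score, rbs_motif (optional).  Lines beginning with
    ``#`` are comments.  Non-numeric scores raise with the line number.
    """
    records: list[ProdigalScore] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields"
                )
            contig, beg_s, end_s, strand = fields[:4]
            try:
                beg, end = int(beg_s), int(end_s)
                start_score = float(fields[4])
                coding_score = float(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            rbs = fields[6] if len(fields) > 6 else ""
            interval = GenomicInterval(contig, beg - 1, end, strand)
            orf_id = f"{contig}:{beg - 1}-{end}({strand})"
            records.append(
                ProdigalScore(orf_id, interval, start_score, coding_score, rbs)
            )
    return records


def write_prodigal_scores(
    scores: Sequence[ProdigalScore], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(_PRODIGAL_COLUMNS) + "\n")
        for s in scores:
            iv = s.interval
            fh.write(
                f"{iv.contig}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t"
                f"{s.start_score:g}\t{s.coding_score:g}\t{s.rbs_motif}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_bedgraph(
    values: Sequence[int] | np.ndarray,
    interval: GenomicInterval,
    path: str | Path,
) -> None:
    """Write per-position values over ``interval`` as a bedGraph track.

    Runs of equal adjacent values are merged; a write-then-read round trip
    reproduces the vector exactly.
    """
    values = np.asarray(values)
    if len(values) != interval.length:
        raise ValueError(
            f"value vector length {len(values)} != interval length {interval.length}"
        )
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                fh.write(
                    f"{interval.contig}\t{interval.start + run_start}\t"
                    f"{interval.start + i}\t{values[run_start]:g}\n"
                )
                run_start = i


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph file into (contig, start, end, value) tuples."""
    out: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return out


def bedgraph_to_array(
    records: Iterable[tuple[str, int, int, float]], interval: GenomicInterval
) -> np.ndarray:
    """Densify bedGraph records over ``interval`` into a per-position vector."""
    values = np.zeros(interval.length)
    for contig, start, end, value in records:
        if contig != interval.contig:
            continue
        lo = max(start, interval.start) - interval.start
        hi = min(end, interval.end) - interval.start
        if lo < hi:
            values[lo:hi] = value
    return values
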