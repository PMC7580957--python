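"""Synthetic data with known ground truth: structure-protected digestion.

The generator emulates what a nuclease-digestion + size-selection protocol
does to a structured RNA.  Cut events live on the bonds *between*
nucleotides; a bond is protected (cut with the low probability
``p_cut_paired``) only when both flanking bases are base-paired, and cut
with the high probability ``p_cut_unpaired`` otherwise.  Junction bonds —
one paired flank, one unpaired — therefore cut at the high rate, which is
exactly what concentrates fragment ends at structure junctions.  Fragments
outside the size-selection window [15, 45] nt are discarded, and fragments
longer than the read length yield truncated reads whose 3' end is a
sequencer artifact (the downstream fragment filter must remove them).

Everything needed to verify downstream stages — junction positions, cut
coordinates, truncation flags, planted read counts, repeat/spacer layout —
is recorded as ground truth, so no stage ever has to trust another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as rf_io
from .model import CrisprArray, Feature, GenomicInterval, ReadAlignment, StructureAnnotation

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))

DEFAULT_P_CUT_UNPAIRED = 0.2
DEFAULT_P_CUT_PAIRED = 0.005
DEFAULT_SIZE_MIN = 15
DEFAULT_SIZE_MAX = 45
DEFAULT_READ_LEN = 36


@dataclass(frozen=True, slots=True)
class DigestionConfig:
    """Parameters of one simulated digestion + size selection."""

    p_cut_unpaired: float = DEFAULT_P_CUT_UNPAIRED
    p_cut_paired: float = DEFAULT_P_CUT_PAIRED
    size_min: int = DEFAULT_SIZE_MIN
    size_max: int = DEFAULT_SIZE_MAX
    n_molecules: int = 400
    read_len: int = DEFAULT_READ_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_cut_paired <= self.p_cut_unpaired <= 1:
            raise ValueError(
                "require 0 <= p_cut_paired <= p_cut_unpaired <= 1"
            )
        if self.size_min > self.size_max:
            raise ValueError("size_min must be <= size_max")
        if self.n_molecules < 1 or self.read_len < 1:
            raise ValueError("n_molecules and read_len must be positive")


@dataclass(slots=True)
class DigestionTruth:
    """Ground truth of one digest: everything downstream stages must recover."""

    junctions: tuple[int, ...]  # transcript-relative paired-state flips
    bond_cut_counts: np.ndarray  # cuts observed per bond over all molecules
    bond_protected: np.ndarray  # bool per bond: both flanks paired
    n_molecules: int
    n_fragments_total: int  # before size selection
    fragments: list[tuple[int, int]]  # surviving, transcript coords [a, b)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_structured_transcript(
    length: int,
    n_stems: int,
    seed: int = 0,
    loop_len: int = 4,
    stem_len: int | None = None,
    linker_len: int = 5,
) -> StructureAnnotation:
    """A transcript of hairpins separated by short unpaired linkers.

    Each hairpin is a paired arm, a ``loop_len`` unpaired loop, and the
    complementary closing arm.  The default geometry emulates a heavily
    base-paired regulatory RNA of the 6S-RNA kind: most of the molecule in
    stems, interrupted only by short (around ``linker_len``) unpaired
    interludes.  Arm and linker lengths are jittered per hairpin so the
    architecture is aperiodic, as real RNAs are — identical evenly spaced
    hairpins would make the molecule self-similar under rotation, which no
    natural structure is.  When ``stem_len`` is given every arm uses it
    exactly; otherwise arms grow up to 25 nt, so that a protected arm plus
    its short unpaired flanks — a linker-to-loop or loop-to-linker
    fragment — still fits under a typical sequencer read length and
    survives both size selection and the fragment-length filter.  Leftover
    length is spread across the linkers.  Raises when the geometry cannot
    fit.
    """
    rng = np.random.default_rng(seed)
    if n_stems == 0:
        return StructureAnnotation(
            f"sim_transcript_{seed}", _random_seq(rng, length), "." * length
        )
    if n_stems < 0 or loop_len < 3 or linker_len < 0:
        raise ValueError("need n_stems >= 0, loop_len >= 3, linker_len >= 0")
    n_linkers = n_stems + 1
    if linker_len >= 3:
        linker_lens = [
            int(rng.integers(3, 2 * linker_len - 2)) for _ in range(n_linkers)
        ]
    else:
        linker_lens = [linker_len] * n_linkers
    budget = length - sum(linker_lens) - n_stems * loop_len
    if stem_len is not None:
        arm_lens = [stem_len] * n_stems
    else:
        base = min(25, budget // (2 * n_stems)) if budget > 0 else 0
        # independent downward jitter desynchronizes the hairpins
        jitter_room = min(3, max(0, base - 10))
        arm_lens = [
            base - int(rng.integers(0, jitter_room + 1)) for _ in range(n_stems)
        ]
    remaining = length - sum(2 * a + loop_len for a in arm_lens) - sum(linker_lens)
    if min(arm_lens) < 2 or remaining < 0:
        raise ValueError(
            f"infeasible geometry: {n_stems} stems (arms {arm_lens}) + loop "
            f"{loop_len} + linkers {linker_lens} do not fit in {length} nt"
        )
    for i in range(remaining):
        linker_lens[i % n_linkers] += 1
    seq_parts: list[str] = []
    db_parts: list[str] = []
    for i in range(n_stems):
        seq_parts.append(_random_seq(rng, linker_lens[i]))
        db_parts.append("." * linker_lens[i])
        arm = _random_seq(rng, arm_lens[i])
        loop = _random_seq(rng, loop_len)
        seq_parts.extend([arm, loop, arm.translate(_COMPLEMENT)[::-1]])
        db_parts.extend(["(" * arm_lens[i], "." * loop_len, ")" * arm_lens[i]])
    seq_parts.append(_random_seq(rng, linker_lens[-1]))
    db_parts.append("." * linker_lens[-1])
    return StructureAnnotation(
        f"sim_transcript_{seed}", "".join(seq_parts), "".join(db_parts)
    )


def digest(
    structure: StructureAnnotation, config: DigestionConfig
) -> tuple[list[tuple[int, int]], DigestionTruth]:
    """Digest ``n_molecules`` copies of the transcript and size-select.

    Each inter-nucleotide bond i (between positions i and i+1) is cut
    independently per molecule; molecule ends count as cuts, so fragments
    are the runs between cuts.  Fragments outside
    [``size_min``, ``size_max``] are discarded.
    """
    rng = np.random.default_rng(config.seed)
    paired = structure.paired_mask
    L = len(structure)
    protected = paired[:-1] & paired[1:]
    p_bond = np.where(protected, config.p_cut_paired, config.p_cut_unpaired)
    mask = structure.paired_mask
    junctions = tuple(int(i) for i in np.flatnonzero(mask[1:] != mask[:-1]) + 1)
    cut_counts = np.zeros(L - 1, dtype=np.int64)
    kept: list[tuple[int, int]] = []
    n_total = 0
    for _ in range(config.n_molecules):
        cuts = np.flatnonzero(rng.random(L - 1) < p_bond)
        cut_counts[cuts] += 1
        bounds = np.concatenate(([0], cuts + 1, [L]))
        n_total += len(bounds) - 1
        sizes = np.diff(bounds)
        ok = (sizes >= config.size_min) & (sizes <= config.size_max)
        for k in np.flatnonzero(ok):
            kept.append((int(bounds[k]), int(bounds[k + 1])))
    truth = DigestionTruth(
        junctions, cut_counts, protected, config.n_molecules, n_total, kept
    )
    return kept, truth


def emit_reads(
    fragments: Sequence[tuple[int, int]],
    config: DigestionConfig,
    feature: Feature,
    sample_id: str = "sim",
) -> tuple[list[ReadAlignment], list[bool]]:
    """Turn transcript-coordinate fragments into genomic read alignments.

    Each fragment yields one error-free ungapped alignment on the feature's
    strand.  Fragments longer than ``read_len`` are truncated at ``read_len``
    from their 5' end and flagged True in the returned truncation list —
    these are precisely the reads the downstream fragment filter removes.
    """
    fiv = feature.interval
    reads: list[ReadAlignment] = []
    truncated: list[bool] = []
    for a, b in fragments:
        frag_len = b - a
        trunc = frag_len > config.read_len
        qlen = min(frag_len, config.read_len)
        if fiv.strand == "-":
            # transcript position a is genomic end-1-a; 5' truncation keeps
            # the genomic-right side of the fragment
            ge = fiv.end - a
            gs = ge - qlen
        else:
            gs = fiv.start + a
            ge = gs + qlen
        reads.append(
            ReadAlignment(
                GenomicInterval(fiv.contig, gs, ge, fiv.strand), qlen, sample_id
            )
        )
        truncated.append(trunc)
    return reads, truncated


def simulate_crispr_array(
    n_repeats: int,
    repeat_len: int = 30,
    spacer_len: int = 35,
    seed: int = 0,
    contig: str = "crispr_contig",
    array_start: int = 0,
    loop_len: int = 4,
) -> tuple[CrisprArray, StructureAnnotation, str]:
    """A CRISPR array whose repeats are hairpins and spacers are unstructured.

    Every repeat carries the same sequence folded as a hairpin (arm, loop,
    complementary arm); spacers are random unpaired sequence.  Returns the
    array layout, the structure annotation over the array span, and
    minCED-style GFF text whose repeat rows round-trip through
    ``parse_crispr_gff``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    arm = (repeat_len - loop_len) // 2
    pad = repeat_len - loop_len - 2 * arm
    if arm < 2:
        raise ValueError("repeat_len too short for a hairpin")
    arm_seq = _random_seq(rng, arm)
    repeat_seq = arm_seq + _random_seq(rng, loop_len) + arm_seq.translate(
        _COMPLEMENT
    )[::-1] + _random_seq(rng, pad)
    repeat_db = "(" * arm + "." * loop_len + ")" * arm + "." * pad
    seq_parts, db_parts = [], []
    repeats, spacers = [], []
    pos = array_start
    gff_lines = ["##gff-version 3"]
    for i in range(n_repeats):
        repeats.append(GenomicInterval(contig, pos, pos + repeat_len, "+"))
        gff_lines.append(
            f"{contig}\tminced:ribofrag-sim\trepeat_region\t{pos + 1}\t"
            f"{pos + repeat_len}\t.\t+\t.\tID={contig}_CRISPR_{i};rpt_family=CRISPR"
        )
        seq_parts.append(repeat_seq)
        db_parts.append(repeat_db)
        pos += repeat_len
        if i < n_repeats - 1:
            spacers.append(GenomicInterval(contig, pos, pos + spacer_len, "+"))
            seq_parts.append(_random_seq(rng, spacer_len))
            db_parts.append("." * spacer_len)
            pos += spacer_len
    span = GenomicInterval(contig, array_start, pos, "+")
    array = CrisprArray(f"{contig}_array", span, tuple(repeats), tuple(spacers))
    structure = StructureAnnotation(
        array.array_id, "".join(seq_parts), "".join(db_parts)
    )
    return array, structure, "\n".join(gff_lines) + "\n"


def simulate_riboseq_background(
    orf: Feature,
    n_footprints: int,
    footprint_len_range: tuple[int, int] = (15, 40),
    seed: int = 0,
    sample_id: str = "sim",
) -> list[ReadAlignment]:
    """Ribosome-footprint background: uniform placements inside one ORF.

    Footprint lengths are uniform over ``footprint_len_range`` and every
    footprint lies fully within the ORF, on the ORF's strand.
    """
    lo, hi = footprint_len_range
    fiv = orf.interval
    if fiv.length < hi:
        raise ValueError("ORF shorter than the maximum footprint length")
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(n_footprints):
        flen = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(fiv.start, fiv.end - flen + 1))
        reads.append(
            ReadAlignment(
                GenomicInterval(fiv.contig, start, start + flen, fiv.strand),
                flen,
                sample_id,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class Scenario:
    """A fully materialized simulation: inputs plus ground truth."""

    genome: dict[str, str]
    features: list[Feature]
    structures: list[StructureAnnotation]
    reads: list[ReadAlignment]
    truth: dict
    crispr_gff_text: str | None = None
    crispr_array: CrisprArray | None = None


def _uniform_feature_reads(
    rng: np.random.Generator, feature: Feature, n: int, read_len: int = 25
) -> list[ReadAlignment]:
    fiv = feature.interval
    reads = []
    for _ in range(n):
        start = int(rng.integers(fiv.start, fiv.end - read_len + 1))
        reads.append(
            ReadAlignment(
                GenomicInterval(fiv.contig, start, start + read_len, fiv.strand),
                read_len,
                "sim",
            )
        )
    return reads


def build_scenario(
    scenario: str,
    seed: int = 0,
    transcript_length: int = 300,
    n_stems: int = 4,
    n_molecules: int = 400,
    n_crispr_repeats: int = 18,
    n_ncrnas: int = 65,
    n_expressed: int = 61,
    config: DigestionConfig | None = None,
) -> Scenario:
    """Assemble a named simulation scenario with full ground truth.

    ``ssrs-like``: one structured 300-nt transcript (4 hairpins) digested
    under the default protection asymmetry, embedded in a genomic contig.
    ``crispr``: an 18-repeat array (30 nt repeats, 35 nt spacers) digested
    the same way.  ``mixed``: both, plus a panel of ncRNAs with planted
    read counts (61 of 65 expressed) and a coding ORF carrying uniform
    ribosome-footprint background.
    """
    if scenario not in ("ssrs-like", "crispr", "mixed"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    if config is None:
        config = DigestionConfig(n_molecules=n_molecules, seed=sub())
    genome: dict[str, str] = {}
    features: list[Feature] = []
    structures: list[StructureAnnotation] = []
    reads: list[ReadAlignment] = []
    truth: dict = {"scenario": scenario, "seed": seed}
    crispr_gff = None
    crispr_array = None

    if scenario in ("ssrs-like", "mixed"):
        contig = "contig_1"
        structure = simulate_structured_transcript(
            transcript_length, n_stems, seed=sub()
        )
        offset = 500
        feat = Feature(
            structure.feature_id,
            GenomicInterval(contig, offset, offset + len(structure), "+"),
            "ncRNA",
        )
        fragments, dig_truth = digest(structure, config)
        t_reads, truncated = emit_reads(fragments, config, feat)
        flank = _random_seq(rng, offset)
        tail = _random_seq(rng, 500)
        contig_seq = flank + structure.sequence + tail
        features.append(feat)
        structures.append(structure)
        reads.extend(t_reads)
        truth["structured_transcript"] = {
            "feature_id": feat.id,
            "junctions": list(dig_truth.junctions),
            "n_fragments_kept": len(fragments),
            "n_truncated_reads": int(sum(truncated)),
            "read_len": config.read_len,
        }
        truth["truncated_flags"] = [bool(t) for t in truncated]

        if scenario == "mixed":
            pieces = [contig_seq]
            pos = len(contig_seq)
            planted: dict[str, int] = {feat.id: len(t_reads)}
            ncrna_len, gap = 200, 100
            # the structured transcript is ncRNA #1 and is expressed by its
            # digest signal; the rest get planted uniform counts
            for i in range(1, n_ncrnas):
                pieces.append(_random_seq(rng, gap))
                start = pos + gap
                pieces.append(_random_seq(rng, ncrna_len))
                pos = start + ncrna_len
                f = Feature(
                    f"ncrna_{i:03d}",
                    GenomicInterval(contig, start, start + ncrna_len, "+"),
                    "ncRNA",
                )
                # at desk-scale library sizes any single read clears an
                # RPKM threshold of 10, so silent ncRNAs receive no reads
                n_planted = 100 if i < n_expressed else 0
                features.append(f)
                reads.extend(_uniform_feature_reads(rng, f, n_planted))
                planted[f.id] = n_planted
            # coding ORF with footprint background
            pieces.append(_random_seq(rng, gap))
            orf_start = pos + gap
            orf_len = 1200
            pieces.append(_random_seq(rng, orf_len))
            pos = orf_start + orf_len
            orf_feat = Feature(
                "cds_bg",
                GenomicInterval(contig, orf_start, orf_start + orf_len, "+"),
                "CDS",
            )
            features.append(orf_feat)
            bg = simulate_riboseq_background(orf_feat, 5000, seed=sub())
            reads.extend(bg)
            planted[orf_feat.id] = len(bg)
            pieces.append(_random_seq(rng, 200))
            contig_seq = "".join(pieces)
            truth["planted_counts"] = planted
            truth["n_ncrnas"] = n_ncrnas
            truth["n_expressed_truth"] = n_expressed
        genome[contig] = contig_seq

    if scenario in ("crispr", "mixed"):
        c_contig = "contig_2"
        array, c_structure, crispr_gff = simulate_crispr_array(
            n_crispr_repeats, seed=sub(), contig=c_contig, array_start=300
        )
        c_feat = Feature(array.array_id, array.span, "other")
        c_frags, c_truth = digest(c_structure, config)
        c_reads, c_trunc = emit_reads(c_frags, config, c_feat)
        genome[c_contig] = (
            _random_seq(rng, array.span.start)
            + c_structure.sequence
            + _random_seq(rng, 300)
        )
        structures.append(c_structure)
        reads.extend(c_reads)
        crispr_array = array
        truth["crispr"] = {
            "array_id": array.array_id,
            "n_repeats": array.n_repeats,
            "repeats": [[r.start, r.end] for r in array.repeats],
            "spacers": [[s.start, s.end] for s in array.spacers],
            "span": [array.span.start, array.span.end],
            "n_fragments_kept": len(c_frags),
        }

    return Scenario(
        genome, features, structures, reads, truth, crispr_gff, crispr_array
    )


def write_scenario(scn: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a scenario to disk (FASTA/GFF3/dot-bracket/BED6/SAM/JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "features": out / "features.gff3",
        "structures": out / "structures.txt",
        "alignments_bed": out / "alignments.bed",
        "alignments_sam": out / "alignments.sam",
        "truth": out / "ground_truth.json",
    }
    rf_io.write_fasta(scn.genome, paths["genome"])
    rf_io.write_gff_features(scn.features, paths["features"])
    rf_io.write_dotbracket(scn.structures, paths["structures"])
    rf_io.write_bed6(scn.reads, paths["alignments_bed"])
    rf_io.write_sam(
        scn.reads, {c: len(s) for c, s in scn.genome.items()}, paths["alignments_sam"]
    )
    paths["truth"].write_text(json.dumps(scn.truth, indent=1, sort_keys=True))
    if scn.crispr_gff_text is not None:
        paths["crispr_gff"] = out / "crispr.gff3"
        paths["crispr_gff"].write_text(scn.crispr_gff_text)
    return paths
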