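"""Stage orchestration: run the analysis end to end with one config.

Stages run in order — expression (RPKM) → ORF scan → end profiles →
junction enrichment → CRISPR partition — and any stage whose inputs are
absent is skipped and noted in the run manifest.  All tabular output is
headered TSV; every parameter that affects any output is recorded in
``manifest.json``, so two runs with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import enrichment, expression, io, orfs
from .end_profiles import (
    compute_end_profile,
    filter_fragment_truncated,
    profile_to_frame,
    profile_to_tracks,
)
from .model import Feature, GenomicInterval, ReadAlignment


@dataclass(slots=True)
class RunConfig:
    """Paths, thresholds, and seeds for one pipeline run."""

    alignments: str | None = None
    genome: str | None = None
    features: str | None = None
    structures: str | None = None
    crispr_gff: str | None = None
    prodigal_scores: str | None = None
    out_dir: str = "ribofrag_out"

    rpkm_threshold: float = expression.DEFAULT_RPKM_THRESHOLD
    min_orf_len: int = orfs.DEFAULT_MIN_ORF_LEN
    small_orf_aa: int = orfs.DEFAULT_SMALL_ORF_AA
    max_read_len: int | None = None  # mandatory for end profiling
    tolerance: int = enrichment.DEFAULT_TOLERANCE
    min_count: int = enrichment.DEFAULT_MIN_COUNT
    peak_window: int = enrichment.DEFAULT_PEAK_WINDOW
    n_perm: int = enrichment.DEFAULT_N_PERM
    seed: int = enrichment.DEFAULT_SEED
    stranded: bool = False

    def validate(self) -> None:
        if not 0 <= self.rpkm_threshold:
            raise ValueError("rpkm_threshold must be >= 0")
        if self.min_orf_len < 3:
            raise ValueError("min_orf_len must be >= 3")
        if self.max_read_len is not None and self.max_read_len <= 0:
            raise ValueError("max_read_len must be positive")
        for p in (self.alignments, self.genome, self.features,
                  self.structures, self.crispr_gff, self.prodigal_scores):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def coverage_over_interval(
    reads: Sequence[ReadAlignment], interval: GenomicInterval
) -> np.ndarray:
    """Per-position coverage over ``interval`` from overlapping reads,
    clipped to the span (strand-agnostic)."""
    depth = np.zeros(interval.length, dtype=np.int64)
    for r in reads:
        if not r.interval.overlaps(interval):
            continue
        lo = max(r.interval.start, interval.start) - interval.start
        hi = min(r.interval.end, interval.end) - interval.start
        depth[lo:hi] += 1
    return depth


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage whose inputs are present; return the summary.

    Writes one TSV per stage plus ``summary.tsv`` and ``manifest.json``
    under ``config.out_dir``.  A failing stage aborts with the stage name
    prefixed to the error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v for k, v in asdict(config).items()
        },
        "stages": {},
    }
    summary: dict[str, float | int | str] = {}

    reads = features = ncrnas = None
    if config.alignments:
        reads = io.read_alignments(config.alignments)
        summary["n_alignments"] = len(reads)
    if config.features:
        features = io.read_gff_features(config.features)
        ncrnas = [f for f in features if f.biotype == "ncRNA"]
        summary["n_features"] = len(features)
        summary["n_ncrnas"] = len(ncrnas)

    # --- expression -------------------------------------------------------
    if reads is not None and features is not None:
        try:
            records = expression.build_expression_table(
                reads, features, threshold=config.rpkm_threshold,
                stranded=config.stranded,
            )
        except Exception as exc:
            raise RuntimeError(f"stage rpkm: {exc}") from exc
        frame = expression.expression_to_frame(records)
        _write_tsv(frame, out / "expression.tsv")
        by_id = {r.feature_id: r for r in records}
        expressed_nc = [n for n in (ncrnas or []) if by_id[n.id].expressed]
        summary["n_ncrnas_expressed"] = len(expressed_nc)
        manifest["stages"]["rpkm"] = "run"
    else:
        manifest["stages"]["rpkm"] = "skipped (needs alignments + features)"

    # --- ORF scan ---------------------------------------------------------
    if config.genome and ncrnas:
        try:
            genome = io.read_fasta(config.genome)
            all_orfs = orfs.enumerate_orfs(genome, config.min_orf_len)
            scores = (
                io.read_prodigal_scores(config.prodigal_scores)
                if config.prodigal_scores
                else None
            )
            annotated = orfs.annotate_orfs(genome, all_orfs, scores)
            classes = orfs.classify_all(ncrnas, annotated, config.small_orf_aa)
        except Exception as exc:
            raise RuntimeError(f"stage orfscan: {exc}") from exc
        frame = pd.DataFrame(
            {
                "ncrna_id": [c.ncrna_id for c in classes],
                "category": [c.category for c in classes],
                "n_overlapping_orfs": [c.n_overlapping_orfs for c in classes],
                "supporting": [
                    ",".join(sorted(c.supporting)) for c in classes
                ],
            }
        )
        _write_tsv(frame, out / "orf_overlap.tsv")
        for cat in ("no_possible_orf", "possible_orf_only", "orf_with_support"):
            summary[f"n_{cat}"] = sum(1 for c in classes if c.category == cat)
        manifest["stages"]["orfscan"] = "run"
    else:
        manifest["stages"]["orfscan"] = "skipped (needs genome + ncRNA features)"

    # --- end profiles + junction enrichment -------------------------------
    profiles = {}
    if reads is not None and ncrnas and config.max_read_len:
        try:
            kept, removed = filter_fragment_truncated(reads, config.max_read_len)
            summary["n_reads_fragment_filtered"] = len(removed)
            track_dir = out / "tracks"
            for f in ncrnas:
                prof = compute_end_profile(kept, f)
                profiles[f.id] = prof
                _write_tsv(profile_to_frame(prof), out / f"profile_{f.id}.tsv")
                profile_to_tracks(prof, f, track_dir)
        except Exception as exc:
            raise RuntimeError(f"stage endprofile: {exc}") from exc
        manifest["stages"]["endprofile"] = "run"
    else:
        manifest["stages"]["endprofile"] = (
            "skipped (needs alignments + ncRNA features + max_read_len)"
        )

    if profiles and config.structures:
        try:
            structures = {
                s.feature_id: s for s in io.read_dotbracket(config.structures)
            }
            rows = []
            for fid, prof in profiles.items():
                if fid not in structures:
                    continue
                juncs = enrichment.junctions_from_dotbracket(structures[fid])
                for end_type in ("five_prime", "three_prime"):
                    peaks = enrichment.call_peaks(
                        prof, end_type, config.min_count, config.peak_window
                    )
                    if not peaks.positions or not juncs.positions:
                        continue
                    res = enrichment.junction_enrichment(
                        peaks, juncs, prof.length, config.tolerance,
                        config.n_perm, config.seed,
                    )
                    rows.append(
                        {
                            "feature_id": fid,
                            "end_type": end_type,
                            "n_peaks": len(peaks.positions),
                            "n_junctions": len(juncs.positions),
                            "statistic": res.statistic,
                            "null_mean": res.null_mean,
                            "p_value": res.p_value,
                        }
                    )
        except Exception as exc:
            raise RuntimeError(f"stage junctions: {exc}") from exc
        frame = pd.DataFrame(
            rows,
            columns=[
                "feature_id", "end_type", "n_peaks", "n_junctions",
                "statistic", "null_mean", "p_value",
            ],
        )
        _write_tsv(frame, out / "junction_enrichment.tsv")
        if rows:
            summary["min_junction_p"] = min(r["p_value"] for r in rows)
        manifest["stages"]["junctions"] = "run"
    else:
        manifest["stages"]["junctions"] = (
            "skipped (needs end profiles + structures)"
        )

    # --- CRISPR repeat/spacer partition -----------------------------------
    if reads is not None and config.crispr_gff:
        try:
            arrays = enrichment.parse_crispr_gff(config.crispr_gff)
            rows, repeat_frames = [], []
            for arr in arrays:
                depth = coverage_over_interval(reads, arr.span)
                if depth.sum() == 0:
                    continue
                res, table = enrichment.repeat_spacer_partition(
                    depth, arr, config.n_perm, config.seed
                )
                table.insert(0, "array_id", arr.array_id)
                repeat_frames.append(table)
                repeat_len = sum(r.length for r in arr.repeats)
                rows.append(
                    {
                        "array_id": arr.array_id,
                        "n_repeats": arr.n_repeats,
                        "repeat_signal_fraction": res.statistic,
                        "repeat_length_fraction": repeat_len / arr.span.length,
                        "null_mean": res.null_mean,
                        "p_value": res.p_value,
                        "n_signal_positive": int(
                            table["signal_positive"].sum()
                        ),
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"stage crispr: {exc}") from exc
        _write_tsv(
            pd.DataFrame(
                rows,
                columns=[
                    "array_id", "n_repeats", "repeat_signal_fraction",
                    "repeat_length_fraction", "null_mean", "p_value",
                    "n_signal_positive",
                ],
            ),
            out / "crispr_partition.tsv",
        )
        if repeat_frames:
            _write_tsv(
                pd.concat(repeat_frames, ignore_index=True),
                out / "crispr_repeats.tsv",
            )
        if rows:
            summary["n_crispr_arrays"] = len(rows)
            summary["crispr_min_p"] = min(r["p_value"] for r in rows)
            summary["crispr_signal_positive_repeats"] = sum(
                r["n_signal_positive"] for r in rows
            )
        manifest["stages"]["crispr"] = "run"
    else:
        manifest["stages"]["crispr"] = "skipped (needs alignments + crispr_gff)"

    _write_tsv(
        pd.DataFrame(
            {"key": list(summary), "value": [summary[k] for k in summary]}
        ),
        out / "summary.tsv",
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return summary
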