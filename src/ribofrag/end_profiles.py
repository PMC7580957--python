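"""Strand-aware 5'/3' read-end profiles over individual features.

The 5' and 3' ends of an aligned fragment mark where the nuclease cut the
molecule, so per-position end counts over a feature are its fragmentation
profile.  Two conventions matter:

* For a ``+`` read spanning ``[s, e)`` the 5' end is ``s`` and the 3' end is
  ``e - 1`` (the last aligned base — the cut abuts it; the half-open ``e``
  is a coordinate-convention artifact, not a position on the molecule).
  For a ``-`` read the roles swap.
* Profiles are indexed 5'->3' along the *feature's* strand, so plots read
  the same way regardless of genomic orientation.

Reads whose fragment was longer than the sequencer read length must be
removed first (``filter_fragment_truncated``): their 3' end is where the
sequencer stopped, not where the nuclease cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import write_bedgraph
from .model import Feature, ReadAlignment


@dataclass(slots=True)
class EndProfile:
    """Per-position 5'/3' end counts and coverage over one feature."""

    feature_id: str
    length: int
    five_prime: np.ndarray  # int counts, feature-relative, 5'->3'
    three_prime: np.ndarray
    depth: np.ndarray
    n_reads_used: int
    n_reads_filtered: int

    def __post_init__(self) -> None:
        for name in ("five_prime", "three_prime", "depth"):
            arr = getattr(self, name)
            if len(arr) != self.length:
                raise ValueError(f"{name} has {len(arr)} entries, expected {self.length}")


def filter_fragment_truncated(
    reads: Sequence[ReadAlignment], max_read_len: int
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Partition reads into (kept, removed) by the fragment-length filter.

    Reads with ``query_length >= max_read_len`` are removed: a read at the
    machine length cannot certify that its fragment actually ended there, so
    its 3' end would be a sequencer artifact.  The boundary is inclusive.
    """
    if max_read_len <= 0:
        raise ValueError("max_read_len must be positive")
    kept, removed = [], []
    for r in reads:
        (removed if r.query_length >= max_read_len else kept).append(r)
    return kept, removed


def compute_end_profile(
    reads: Sequence[ReadAlignment], feature: Feature, partial: bool = False
) -> EndProfile:
    """Tally 5'/3' read ends and coverage over one oriented feature.

    By default only reads fully contained in the feature interval contribute
    (boundary-straddling reads would attribute end positions from
    neighbouring loci); ``partial=True`` admits any overlapping read, in
    which case ends falling outside the feature are silently dropped and
    the end-sum conservation invariant no longer holds.

    Reads on strand ``"."`` raise: end assignment needs an orientation.
    """
    fiv = feature.interval
    if fiv.strand == ".":
        raise ValueError(
            f"end profiling requires oriented feature (feature {feature.id})"
        )
    L = fiv.length
    five = np.zeros(L, dtype=np.int64)
    three = np.zeros(L, dtype=np.int64)
    depth = np.zeros(L, dtype=np.int64)
    n_used = n_filtered = 0
    for r in reads:
        riv = r.interval
        ok = fiv.contains(riv) if not partial else fiv.overlaps(riv)
        if not ok:
            n_filtered += 1
            continue
        if riv.strand == ".":
            raise ValueError("end profiling requires strand-resolved reads")
        n_used += 1
        if riv.strand == "+":
            g5, g3 = riv.start, riv.end - 1
        else:
            g5, g3 = riv.end - 1, riv.start
        if fiv.strand == "+":
            p5, p3 = g5 - fiv.start, g3 - fiv.start
            lo, hi = riv.start - fiv.start, riv.end - fiv.start
        else:
            p5, p3 = fiv.end - 1 - g5, fiv.end - 1 - g3
            lo, hi = fiv.end - riv.end, fiv.end - riv.start
        if 0 <= p5 < L:
            five[p5] += 1
        if 0 <= p3 < L:
            three[p3] += 1
        depth[max(lo, 0) : min(hi, L)] += 1
    return EndProfile(feature.id, L, five, three, depth, n_used, n_filtered)


def profile_to_tracks(
    profile: EndProfile, feature: Feature, out_dir: str | Path
) -> dict[str, Path]:
    """Write 5'-end, 3'-end, and depth bedGraph tracks in genomic coordinates.

    Feature-relative arrays are mapped back to the genome (reversed for
    ``-`` features) so the tracks line up with any annotation browser.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind, values in (
        ("five_prime", profile.five_prime),
        ("three_prime", profile.three_prime),
        ("depth", profile.depth),
    ):
        genomic = values if feature.interval.strand == "+" else values[::-1]
        path = out_dir / f"{profile.feature_id}.{kind}.bedgraph"
        write_bedgraph(genomic, feature.interval, path)
        paths[kind] = path
    return paths


def profile_to_frame(profile: EndProfile):
    import pandas as pd

    return pd.DataFrame(
        {
            "position": np.arange(profile.length),
            "five_prime": profile.five_prime,
            "three_prime": profile.three_prime,
            "depth": profile.depth,
        }
    )
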