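"""Independent brute-force reference implementations.

Deliberately naive (nested loops, no shared code with the package) so they
can serve as oracles for the optimized implementations.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

STARTS = {"ATG", "GTG", "TTG"}
STOPS = {"TAA", "TAG", "TGA"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_count_overlaps(reads, feature, stranded=False) -> int:
    n = 0
    fiv = feature.interval
    for r in reads:
        riv = r.interval
        if riv.contig != fiv.contig:
            continue
        if stranded and riv.strand != fiv.strand:
            continue
        # any shared base under the half-open convention
        shared = min(riv.end, fiv.end) - max(riv.start, fiv.start)
        if shared >= 1:
            n += 1
    return n


def naive_orf_scan(contig: str, seq: str, min_len: int):
    """Three-nested-loop six-frame ORF scan; returns (contig,start,end,strand) set."""
    seq = seq.upper()
    out = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else naive_revcomp(seq)
        L = len(s)
        for i in range(L - 2):
            if s[i : i + 3] not in STARTS:
                continue
            j = i + 3
            while j + 3 <= L:
                if s[j : j + 3] in STOPS:
                    if j + 3 - i >= min_len and "N" not in s[i : j + 3]:
                        if strand == "+":
                            out.add((contig, i, j + 3, "+"))
                        else:
                            out.add((contig, L - (j + 3), L - i, "-"))
                    break
                j += 3
    return out


def naive_end_profile(reads, feature):
    """Per-read tally of 5'/3' ends over a contained-read feature profile."""
    fiv = feature.interval
    L = fiv.end - fiv.start
    five = [0] * L
    three = [0] * L
    depth = [0] * L
    used = 0
    for r in reads:
        riv = r.interval
        if riv.contig != fiv.contig or riv.start < fiv.start or riv.end > fiv.end:
            continue
        used += 1
        g5 = riv.start if riv.strand == "+" else riv.end - 1
        g3 = riv.end - 1 if riv.strand == "+" else riv.start
        if fiv.strand == "+":
            p5, p3 = g5 - fiv.start, g3 - fiv.start
        else:
            p5, p3 = fiv.end - 1 - g5, fiv.end - 1 - g3
        five[p5] += 1
        three[p3] += 1
        for g in range(riv.start, riv.end):
            rel = g - fiv.start if fiv.strand == "+" else fiv.end - 1 - g
            depth[rel] += 1
    return five, three, depth, used


def naive_junctions(dotbracket: str):
    paired = [c in "()" for c in dotbracket]
    return [i for i in range(1, len(paired)) if paired[i] != paired[i - 1]]


def naive_peaks(counts, min_count, window):
    """Definition check at every position plus the leftmost-tie rule."""
    counts = list(counts)
    n = len(counts)
    candidates = []
    for i in range(n):
        if counts[i] < min_count:
            continue
        lo, hi = max(0, i - window), min(n - 1, i + window)
        if all(counts[i] >= counts[j] for j in range(lo, hi + 1)):
            candidates.append(i)
    # among ties within a window, keep the leftmost
    result = []
    for i in candidates:
        if any(j in result and counts[j] == counts[i] for j in range(i - window, i)):
            continue
        result.append(i)
    return result


def exact_enrichment_tail(peak_positions, junction_positions, length, tolerance):
    """Enumerate all circular offsets; return (observed stat, #offsets with
    null stat >= observed)."""
    mask = [False] * length
    for j in junction_positions:
        for d in range(-tolerance, tolerance + 1):
            mask[(j + d) % length] = True

    def stat(offset):
        hits = sum(mask[(p + offset) % length] for p in peak_positions)
        return hits / len(peak_positions)

    observed = stat(0)
    ge = sum(1 for d in range(length) if stat(d) >= observed)
    return observed, ge
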