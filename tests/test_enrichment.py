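"""Junction extraction, peak calling, and permutation enrichment tests."""

import numpy as np
import pytest

from oracles import exact_enrichment_tail, naive_junctions, naive_peaks
from ribofrag import enrichment
from ribofrag.end_profiles import EndProfile
from ribofrag.enrichment import (
    JunctionSet,
    PeakSet,
    call_peaks,
    junction_enrichment,
    junctions_from_dotbracket,
    parse_crispr_gff,
    repeat_spacer_partition,
)
from ribofrag.model import CrisprArray, GenomicInterval, StructureAnnotation


def _profile(counts, end_type="five_prime"):
    counts = np.asarray(counts, dtype=np.int64)
    zeros = np.zeros_like(counts)
    five = counts if end_type == "five_prime" else zeros
    three = counts if end_type == "three_prime" else zeros
    return EndProfile("f", len(counts), five, three, zeros, int(counts.sum()), 0)


def _balanced(db):
    return StructureAnnotation("s", "A" * len(db), db)


class TestJunctions:
    def test_two_state_transitions(self):
        js = junctions_from_dotbracket(_balanced("((((....))))"))
        assert js.positions == (4, 8)

    def test_unstructured_has_no_junctions(self):
        assert junctions_from_dotbracket(_balanced("." * 12)).positions == ()

    def test_random_structures_match_adjacent_pair_scan(self, rng):
        for _ in range(200):
            db, depth = [], 0
            for _ in range(int(rng.integers(5, 60))):
                c = "(.)"[int(rng.integers(0, 3))]
                if c == ")" and depth == 0:
                    c = "."
                depth += {"(": 1, ")": -1, ".": 0}[c]
                db.append(c)
            db.append(")" * depth)
            db = "".join(db)
            got = junctions_from_dotbracket(_balanced(db)).positions
            assert list(got) == naive_junctions(db)


class TestCallPeaks:
    def test_single_spike(self):
        ps = call_peaks(_profile([0, 0, 9, 0, 0]), "five_prime")
        assert ps.positions == (2,) and ps.heights == (9,)

    def test_tie_breaks_leftmost(self):
        ps = call_peaks(_profile([0, 7, 7, 0]), "five_prime", window=2)
        assert ps.positions == (1,)

    def test_min_count_validation(self):
        with pytest.raises(ValueError):
            call_peaks(_profile([1]), "five_prime", min_count=0)

    def test_random_profiles_match_definition_check(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 12, size=int(rng.integers(5, 80)))
            for window in (1, 2, 3):
                got = call_peaks(
                    _profile(counts), "five_prime", min_count=5, window=window
                )
                assert list(got.positions) == naive_peaks(counts, 5, window)


class TestJunctionEnrichment:
    def test_perfect_association(self):
        peaks = PeakSet("f", "five_prime", (10, 20, 30), (9, 9, 9))
        juncs = JunctionSet("f", (10, 20, 30))
        res = junction_enrichment(peaks, juncs, length=100, tolerance=0)
        assert res.statistic == 1.0
        assert res.p_value >= 1 / (res.n_perm + 1)

    def test_maximally_distant_peaks(self):
        peaks = PeakSet("f", "five_prime", (50,), (9,))
        juncs = JunctionSet("f", (0,))
        res = junction_enrichment(peaks, juncs, length=100, tolerance=0)
        assert res.statistic == 0.0
        assert res.p_value > 0.9

    def test_no_peaks_is_error(self):
        with pytest.raises(ValueError, match="no peaks"):
            junction_enrichment(
                PeakSet("f", "five_prime", (), ()), JunctionSet("f", (3,)), 20
            )

    def test_matches_exact_offset_enumeration(self):
        peaks = PeakSet("f", "five_prime", (7,), (9,))
        juncs = JunctionSet("f", (6, 13))
        L, tol, n_perm = 20, 1, 2000
        res = junction_enrichment(peaks, juncs, L, tolerance=tol, n_perm=n_perm, seed=5)
        observed, ge = exact_enrichment_tail((7,), (6, 13), L, tol)
        assert res.statistic == observed
        exact_p = ge / L
        se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert abs(res.p_value - exact_p) < 4 * se + 2 / n_perm

    def test_p_value_bounds(self, rng):
        for _ in range(20):
            L = int(rng.integers(20, 200))
            k = int(rng.integers(1, 8))
            peaks = PeakSet(
                "f", "five_prime",
                tuple(sorted(int(x) for x in rng.choice(L, k, replace=False))),
                tuple([5] * k),
            )
            juncs = JunctionSet(
                "f", tuple(sorted(int(x) for x in rng.choice(np.arange(1, L), 3, replace=False)))
            )
            res = junction_enrichment(peaks, juncs, L, n_perm=200, seed=int(rng.integers(1000)))
            assert 1 / 201 <= res.p_value <= 1.0

    def test_joint_translation_invariance(self):
        peaks = (3, 11, 17)
        juncs = (4, 12)
        L = 40
        a = junction_enrichment(
            PeakSet("f", "five_prime", peaks, (5, 5, 5)), JunctionSet("f", juncs), L
        )
        for shift in (1, 7, 23):
            b = junction_enrichment(
                PeakSet("f", "five_prime", tuple((p + shift) % L for p in peaks), (5, 5, 5)),
                JunctionSet("f", tuple((j + shift) % L for j in juncs)),
                L,
            )
            assert b.statistic == a.statistic


class TestParseCrisprGff:
    def _write(self, tmp_path, spans, contig="c1"):
        rows = ["##gff-version 3\n"]
        for i, (s, e) in enumerate(spans):
            rows.append(
                f"{contig}\tminced:2.0\trepeat_region\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID=CRISPR{i};rpt_family=CRISPR\n"
            )
        p = tmp_path / "crispr.gff3"
        p.write_text("".join(rows))
        return p

    def test_three_repeats_two_spacers(self, tmp_path):
        spans = [(0, 30), (65, 95), (130, 160)]
        (arr,) = parse_crispr_gff(self._write(tmp_path, spans))
        assert arr.n_repeats == 3
        assert [s.length for s in arr.spacers] == [35, 35]
        assert (arr.span.start, arr.span.end) == (0, 160)

    def test_empty_gff(self, tmp_path):
        p = tmp_path / "e.gff3"
        p.write_text("##gff-version 3\n")
        assert parse_crispr_gff(p) == []

    def test_overlapping_repeats_error(self, tmp_path):
        with pytest.raises(ValueError, match="overlap"):
            parse_crispr_gff(self._write(tmp_path, [(0, 30), (20, 50)]))

    def test_single_repeat_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="single-repeat"):
            (arr,) = parse_crispr_gff(self._write(tmp_path, [(0, 30)]))
        assert arr.spacers == ()

    def test_prokka_style_18_repeat_fixture(self, tmp_path):
        spans = [(i * 65, i * 65 + 30) for i in range(18)]
        (arr,) = parse_crispr_gff(self._write(tmp_path, spans))
        assert arr.n_repeats == 18
        # repeats and derived spacers tile the span without gaps
        tiles = sorted(
            [(r.start, r.end) for r in arr.repeats]
            + [(s.start, s.end) for s in arr.spacers]
        )
        assert tiles[0][0] == arr.span.start and tiles[-1][1] == arr.span.end
        assert all(a[1] == b[0] for a, b in zip(tiles, tiles[1:]))


def _toy_array(n_repeats=3, repeat_len=10, spacer_len=10):
    repeats, spacers = [], []
    pos = 0
    for i in range(n_repeats):
        repeats.append(GenomicInterval("c", pos, pos + repeat_len, "+"))
        pos += repeat_len
        if i < n_repeats - 1:
            spacers.append(GenomicInterval("c", pos, pos + spacer_len, "+"))
            pos += spacer_len
    return CrisprArray(
        "arr", GenomicInterval("c", 0, pos, "+"), tuple(repeats), tuple(spacers)
    )


class TestRepeatSpacerPartition:
    def test_all_signal_in_repeats(self):
        arr = _toy_array()
        depth = np.zeros(arr.span.length)
        for r in arr.repeats:
            depth[r.start : r.end] = 4
        res, table = repeat_spacer_partition(depth, arr)
        assert res.statistic == 1.0
        assert table.signal_positive.all()

    def test_uniform_depth_equals_repeat_fraction(self):
        arr = _toy_array()
        depth = np.full(arr.span.length, 3.0)
        res, _ = repeat_spacer_partition(depth, arr)
        repeat_frac = sum(r.length for r in arr.repeats) / arr.span.length
        assert res.statistic == pytest.approx(repeat_frac)
        assert 0.2 < res.p_value  # nothing to detect

    def test_no_signal_is_error(self):
        arr = _toy_array()
        with pytest.raises(ValueError, match="no signal"):
            repeat_spacer_partition(np.zeros(arr.span.length), arr)

    def test_protected_repeats_detected(self):
        from ribofrag import simulate
        from ribofrag.end_profiles import filter_fragment_truncated
        from ribofrag.model import Feature
        from ribofrag.pipeline import coverage_over_interval

        arr, structure, _ = simulate.simulate_crispr_array(8, seed=3)
        frags, truth = simulate.digest(structure, simulate.DigestionConfig(seed=4))
        feat = Feature(arr.array_id, arr.span, "other")
        reads, _ = simulate.emit_reads(frags, simulate.DigestionConfig(seed=4), feat)
        depth = coverage_over_interval(reads, arr.span)
        res, table = repeat_spacer_partition(depth, arr)
        repeat_frac = sum(r.length for r in arr.repeats) / arr.span.length
        assert res.statistic > repeat_frac
        assert res.p_value <= 0.01
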