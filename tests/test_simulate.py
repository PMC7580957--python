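"""The digestion simulator: geometry, cut statistics, and ground truth."""

import numpy as np
import pytest

from ribofrag import io, simulate
from ribofrag.enrichment import junctions_from_dotbracket, parse_crispr_gff
from ribofrag.expression import compute_rpkm
from ribofrag.model import Feature, GenomicInterval, StructureAnnotation


class TestStructuredTranscript:
    def test_single_hairpin_anatomy(self):
        st = simulate.simulate_structured_transcript(40, 1, seed=1)
        assert len(st) == 40
        juncs = junctions_from_dotbracket(st).positions
        assert len(juncs) in (2, 4)
        assert st.dotbracket.count("(") == st.dotbracket.count(")") > 0

    def test_no_stems_is_all_unpaired(self):
        st = simulate.simulate_structured_transcript(50, 0, seed=2)
        assert st.dotbracket == "." * 50
        assert junctions_from_dotbracket(st).positions == ()

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate.simulate_structured_transcript(30, 3, seed=1)

    def test_random_configs_pass_structure_validation(self, rng, tmp_path):
        path = tmp_path / "structs.db"
        structs = []
        for i in range(50):
            length = int(rng.integers(60, 500))
            n_stems = int(rng.integers(0, max(1, length // 70) + 1))
            structs.append(
                simulate.simulate_structured_transcript(length, n_stems, seed=i)
            )
        io.write_dotbracket(structs, path)
        back = io.read_dotbracket(path)  # re-validates balance and lengths
        assert len(back) == 50
        for a, b in zip(structs, back):
            assert a == b and len(a.sequence) == len(a.dotbracket)

    def test_stem_arms_are_reverse_complementary(self):
        st = simulate.simulate_structured_transcript(80, 1, seed=3)
        db = st.dotbracket
        open_idx = [i for i, c in enumerate(db) if c == "("]
        close_idx = [i for i, c in enumerate(db) if c == ")"]
        comp = dict(zip("ACGT", "TGCA"))
        for i, j in zip(open_idx, reversed(close_idx)):
            assert st.sequence[j] == comp[st.sequence[i]]


class TestDigest:
    def test_no_cut_limit_yields_full_molecules(self):
        st = StructureAnnotation("s", "G" * 30 + "C" * 0, "(" * 15 + ")" * 15)
        cfg = simulate.DigestionConfig(
            p_cut_unpaired=0.5, p_cut_paired=0.0, n_molecules=50, seed=1
        )
        frags, truth = simulate.digest(st, cfg)
        # fully paired: never cut; every molecule is one 30-nt fragment
        assert len(frags) == 50
        assert all(f == (0, 30) for f in frags)

    def test_full_length_over_size_max_discarded(self):
        st = StructureAnnotation("s", "G" * 30 + "C" * 30, "(" * 30 + ")" * 30)
        cfg = simulate.DigestionConfig(
            p_cut_unpaired=0.5, p_cut_paired=0.0, n_molecules=20, seed=1
        )
        frags, truth = simulate.digest(st, cfg)
        assert frags == []  # 60 nt > size_max
        assert truth.n_fragments_total == 20

    def test_saturated_cutting_leaves_no_survivors(self):
        st = StructureAnnotation("s", "A" * 40, "." * 40)
        cfg = simulate.DigestionConfig(
            p_cut_unpaired=1.0, p_cut_paired=0.5, n_molecules=10, seed=1
        )
        frags, truth = simulate.digest(st, cfg)
        assert frags == []
        assert truth.n_fragments_total == 10 * 40

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate.DigestionConfig(p_cut_unpaired=0.1, p_cut_paired=0.2)
        with pytest.raises(ValueError):
            simulate.DigestionConfig(size_min=40, size_max=20)

    def test_cut_frequencies_match_configured_probabilities(self):
        st = simulate.simulate_structured_transcript(120, 2, seed=9)
        n = 10_000
        cfg = simulate.DigestionConfig(n_molecules=n, seed=10)
        _, truth = simulate.digest(st, cfg)
        for protected, p in ((True, cfg.p_cut_paired), (False, cfg.p_cut_unpaired)):
            sel = truth.bond_protected == protected
            freq = truth.bond_cut_counts[sel] / n
            se = np.sqrt(p * (1 - p) / n)
            assert np.all(np.abs(freq - p) < 3 * se + 1e-9), (
                protected, freq.min(), freq.max()
            )


class TestEmitReads:
    def _feat(self, strand="+"):
        return Feature("t", GenomicInterval("c", 500, 560, strand), "ncRNA")

    def test_short_fragment_passes_through(self):
        cfg = simulate.DigestionConfig(seed=0)
        (read,), (trunc,) = simulate.emit_reads([(10, 30)], cfg, self._feat())
        assert (read.interval.start, read.interval.end) == (510, 530)
        assert read.query_length == 20 and trunc is False

    def test_long_fragment_truncated_from_five_prime(self):
        cfg = simulate.DigestionConfig(seed=0)
        (read,), (trunc,) = simulate.emit_reads([(5, 49)], cfg, self._feat())
        assert trunc is True
        assert read.query_length == 36
        assert (read.interval.start, read.interval.end) == (505, 541)

    def test_minus_feature_keeps_five_prime_side(self):
        cfg = simulate.DigestionConfig(seed=0)
        (read,), (trunc,) = simulate.emit_reads([(5, 49)], cfg, self._feat("-"))
        # transcript 5' end is the genomic-right side of a minus feature
        assert trunc is True and read.query_length == 36
        assert (read.interval.start, read.interval.end) == (560 - 41, 560 - 5)
        assert read.interval.strand == "-"

    def test_downstream_filter_recovers_ground_truth(self, rng):
        from ribofrag.end_profiles import filter_fragment_truncated

        st = simulate.simulate_structured_transcript(300, 4, seed=21)
        cfg = simulate.DigestionConfig(seed=22)
        frags, truth = simulate.digest(st, cfg)
        feat = Feature("t", GenomicInterval("c", 0, 300, "+"), "ncRNA")
        reads, trunc_flags = simulate.emit_reads(frags, cfg, feat)
        kept, removed = filter_fragment_truncated(reads, cfg.read_len)
        # the filter removes exactly the truncated reads plus genuine
        # read-length fragments (both have query_length == read_len)
        n_at_machine_len = sum(r.query_length >= cfg.read_len for r in reads)
        assert len(removed) == n_at_machine_len
        assert sum(trunc_flags) <= n_at_machine_len
        assert all(r.query_length < cfg.read_len for r in kept)


class TestCrisprArraySim:
    def test_recovers_18_repeats_through_gff(self, tmp_path):
        arr, structure, gff_text = simulate.simulate_crispr_array(18, seed=5)
        p = tmp_path / "sim.gff3"
        p.write_text(gff_text)
        (parsed,) = parse_crispr_gff(p)
        assert parsed.n_repeats == 18
        assert [(r.start, r.end) for r in parsed.repeats] == [
            (r.start, r.end) for r in arr.repeats
        ]
        assert [(s.start, s.end) for s in parsed.spacers] == [
            (s.start, s.end) for s in arr.spacers
        ]

    def test_two_repeats_one_spacer(self):
        arr, _, _ = simulate.simulate_crispr_array(2, seed=1)
        assert arr.n_repeats == 2 and len(arr.spacers) == 1

    def test_repeats_structured_spacers_not(self):
        arr, st, _ = simulate.simulate_crispr_array(4, seed=2)
        mask = st.paired_mask
        off = arr.span.start
        for rep in arr.repeats:
            assert mask[rep.start - off : rep.end - off].any()
        for sp in arr.spacers:
            assert not mask[sp.start - off : sp.end - off].any()

    def test_surviving_signal_concentrates_in_repeats(self):
        arr, st, _ = simulate.simulate_crispr_array(6, seed=8)
        cfg = simulate.DigestionConfig(seed=9)
        frags, _ = simulate.digest(st, cfg)
        feat = Feature(arr.array_id, arr.span, "other")
        reads, _ = simulate.emit_reads(frags, cfg, feat)
        off = arr.span.start
        mask = np.zeros(arr.span.length, dtype=bool)
        for rep in arr.repeats:
            mask[rep.start - off : rep.end - off] = True
        in_repeat = total = 0
        for r in reads:
            for g in range(r.interval.start, r.interval.end):
                total += 1
                in_repeat += mask[g - off]
        repeat_frac = mask.mean()
        assert in_repeat / total > repeat_frac


class TestRiboseqBackground:
    def _orf(self):
        return Feature("orf", GenomicInterval("c", 100, 700, "+"), "CDS")

    def test_zero_footprints(self):
        assert simulate.simulate_riboseq_background(self._orf(), 0, seed=1) == []

    def test_footprints_contained_with_lengths_in_range(self):
        reads = simulate.simulate_riboseq_background(self._orf(), 500, seed=2)
        for r in reads:
            assert 100 <= r.interval.start and r.interval.end <= 700
            assert 15 <= r.query_length <= 40

    def test_planted_rpkm_matches_closed_form(self):
        orf = self._orf()
        n = 250
        reads = simulate.simulate_riboseq_background(orf, n, seed=3)
        total = 10 * n  # pretend library with 10x background
        rpkm = compute_rpkm(n, orf.interval.length, total)
        assert rpkm == pytest.approx(n / (600 / 1e3) / (total / 1e6))
        assert rpkm == pytest.approx(1e9 / 600 / 10)


class TestScenarioDeterminism:
    def test_same_seed_bit_identical_outputs(self, tmp_path):
        a = simulate.build_scenario("mixed", seed=11)
        b = simulate.build_scenario("mixed", seed=11)
        pa = simulate.write_scenario(a, tmp_path / "a")
        pb = simulate.write_scenario(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        a = simulate.build_scenario("ssrs-like", seed=1)
        b = simulate.build_scenario("ssrs-like", seed=2)
        assert a.genome != b.genome
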