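import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings, strategies as st

from ssrforge import mining, synthetic
from ssrforge.mining import MiningConfig, SSRLocus
from ssrforge.sequence_io import SequenceRecord

from _oracle import oracle_find_ssrs


class TestMotifLibrary:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(1, 1, 4), (2, 2, 12), (1, 3, 76)],
    )
    def test_library_sizes(self, lo, hi, expected):
        lib = mining.build_motif_library(lo, hi)
        assert len(lib) == expected
        assert all(mining.is_primitive(m) for m in lib)
        assert lib == sorted(lib, key=lambda m: (len(m), m))

    def test_non_primitive_excluded(self):
        lib = mining.build_motif_library(2, 4)
        assert "AA" not in lib and "ATAT" not in lib and "AT" in lib

    def test_invalid_bounds(self):
        with pytest.raises(mining.MiningError):
            mining.build_motif_library(0, 2)


class TestConfig:
    def test_min_repeats_must_be_at_least_two(self):
        with pytest.raises(mining.MiningError):
            MiningConfig(min_repeats={2: 1})

    def test_parse_min_repeats(self):
        assert mining.parse_min_repeats("1=12, 2=5") == {1: 12, 2: 5}
        assert mining.parse_min_repeats("2:5") == {2: 5}
        with pytest.raises(mining.MiningError):
            mining.parse_min_repeats("nonsense")


class TestFindSSRs:
    def test_dimer_tract_reported_with_copy_count(self):
        # a 12-base TA tract flanked by non-repeat bases
        loci = mining.find_ssrs("GG" + "TA" * 6 + "GG", MiningConfig())
        assert [(l.start, l.end, l.repetitions, l.motif) for l in loci] == [
            (3, 14, 6, "TA")
        ]

    def test_below_threshold_not_reported(self):
        assert mining.find_ssrs("TA" * 4, MiningConfig()) == []

    def test_motif_reported_in_phase_at_start(self):
        loci = mining.find_ssrs("C" + "AG" * 7, MiningConfig())
        (l,) = loci
        assert l.motif == "AG" and l.start == 2

    def test_partial_trailing_unit_excluded(self):
        # (GT)x6 plus a trailing G: whole-copy end stays at the 12th base
        loci = mining.find_ssrs("GT" * 6 + "G", MiningConfig())
        (l,) = loci
        assert (l.start, l.end, l.repetitions) == (1, 12, 6)

    def test_lowercase_and_n_handling(self):
        loci = mining.find_ssrs("nn" + "ta" * 6 + "NN", MiningConfig())
        (l,) = loci
        assert l.motif == "TA" and (l.start, l.end) == (3, 14)

    def test_homopolymer_opt_in(self):
        seq = "CG" + "A" * 13 + "CG"
        assert mining.find_ssrs(seq, MiningConfig()) == []
        cfg = MiningConfig(min_repeats={1: 12, 2: 5})
        (l,) = mining.find_ssrs(seq, cfg)
        assert (l.motif, l.repetitions) == ("A", 13)

    def test_empty_sequence(self):
        assert mining.find_ssrs("", MiningConfig()) == []

    def test_locus_substring_invariant(self, planted_genome, default_config):
        records, _ = planted_genome
        for rec in records:
            for l in mining.find_ssrs(rec.sequence, default_config):
                assert l.span == l.repetitions * l.unit
                tract = rec.sequence[l.start - 1 : l.end].upper()
                assert tract == l.motif * l.repetitions

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        cfg = MiningConfig(min_repeats={1: 8, 2: 3, 3: 3, 4: 2, 5: 2, 6: 2})
        got = mining.find_ssrs(seq, cfg)
        expected = oracle_find_ssrs(seq, dict(cfg.min_repeats))
        assert [(l.start, l.end, l.motif) for l in got] == [
            (l.start, l.end, l.motif) for l in expected
        ]

    @settings(max_examples=150, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_matches_oracle_property(self, seq):
        cfg = MiningConfig(min_repeats={1: 5, 2: 2, 3: 2})
        got = mining.find_ssrs(seq, cfg)
        expected = oracle_find_ssrs(seq, dict(cfg.min_repeats))
        assert [(l.start, l.end, l.motif) for l in got] == [
            (l.start, l.end, l.motif) for l in expected
        ]

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=150))
    def test_reverse_complement_symmetry(self, seq):
        cfg = MiningConfig(min_repeats={2: 3, 3: 3})
        fwd = mining.find_ssrs(seq, cfg)
        rev = mining.find_ssrs(reverse_complement(seq), cfg)
        n = len(seq)
        assert len(fwd) == len(rev)
        mirrored = sorted((n - l.end + 1, n - l.start + 1, l.unit) for l in rev)
        assert mirrored == sorted((l.start, l.end, l.unit) for l in fwd)


class TestContainment:
    def test_contained_locus_dropped(self):
        outer = SSRLocus("s", 100, 10, 33, 4, "AAATAA")
        inner = SSRLocus("s", 100, 12, 23, 6, "AT")
        assert mining.filter_contained([inner, outer]) == [outer]

    def test_equal_interval_keeps_shorter_period(self):
        a = SSRLocus("s", 100, 10, 21, 6, "AT")
        b = SSRLocus("s", 100, 10, 21, 4, "ATA")
        assert mining.filter_contained([a, b]) == [a]

    def test_partial_overlap_keeps_both(self):
        a = SSRLocus("s", 100, 10, 21, 6, "AT")
        b = SSRLocus("s", 100, 20, 31, 4, "TAG")
        assert len(mining.filter_contained([a, b])) == 2


class TestMergeAndMineGenome:
    def test_duplicate_chunk_reports_collapse(self):
        rec = SequenceRecord("s", "GG" + "TA" * 6 + "GG")
        locus = SSRLocus("s", rec.length, 3, 14, 6, "TA")
        merged = mining.merge_chunk_loci([locus, locus], {"s": rec})
        assert merged == [locus]

    def test_boundary_split_run_coalesces(self):
        # one (GT)x25 run; chunks split it into out-of-phase pieces
        seq = "CCA" + "GT" * 25 + "ACC"
        rec = SequenceRecord("s", seq)
        cfg = MiningConfig(chunk_size=30, overlap=8)
        loci, _ = mining.mine_genome([rec], cfg)
        assert [(l.start, l.end, l.repetitions, l.motif) for l in loci] == [
            (4, 53, 25, "GT")
        ]

    def test_runs_separated_by_one_base_not_merged(self):
        seq = "GT" * 6 + "C" + "GT" * 6
        loci, _ = mining.mine_genome([SequenceRecord("s", seq)], MiningConfig())
        assert len(loci) == 2

    def test_conflicting_seq_len_rejected(self):
        rec = SequenceRecord("s", "GG" + "TA" * 6 + "GG")
        bad = SSRLocus("s", 999, 3, 14, 6, "TA")
        with pytest.raises(mining.MiningError):
            mining.merge_chunk_loci([bad], {"s": rec})

    def test_planted_loci_recovered_exactly(self, planted_genome, mined_loci):
        _, truth = planted_genome
        loci, _ = mined_loci
        assert {(t.seq_id, t.start, t.end, t.motif, t.copies) for t in truth} == {
            (l.seq_id, l.start, l.end, l.motif, l.repetitions) for l in loci
        }

    def test_chunking_is_invisible(self, planted_genome):
        records, _ = planted_genome
        small = MiningConfig(chunk_size=10_000, overlap=20)
        big = MiningConfig(chunk_size=10**9, overlap=20)
        assert mining.mine_genome(records, small)[0] == mining.mine_genome(records, big)[0]

    def test_summary_counts(self):
        recs = [
            SequenceRecord("a", "GG" + "TA" * 6 + "GG" + "CAG" * 7 + "TT"),
            SequenceRecord("b", "AA" + "GT" * 8 + "CC"),
        ]
        loci, summary = mining.mine_genome(recs)
        assert summary == mining.MiningSummary(
            n_sequences=2,
            total_length=sum(r.length for r in recs),
            n_loci=len(loci),
        )
        assert summary.n_loci == 3


class TestSsrFiles:
    def test_ssr_roundtrip_and_layout(self, tmp_path, mined_loci):
        loci, summary = mined_loci
        path = tmp_path / "out.ssr"
        mining.write_ssr(loci, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == mining.SSR_HEADER
        assert all(line.startswith(">") for line in lines[1:])
        assert mining.read_ssr(path) == list(loci)

    def test_sat1_contents(self, tmp_path, mined_loci):
        _, summary = mined_loci
        path = tmp_path / "out.sat1"
        mining.write_sat1(summary, path)
        text = path.read_text()
        assert f"Total_sequences\t{summary.n_sequences}" in text
        assert f"Total_length_bp\t{summary.total_length}" in text

    def test_highlighted_fasta_case(self, tmp_path):
        rec = SequenceRecord("s", "gg" + "ta" * 6 + "gg")
        loci, _ = mining.mine_genome([rec])
        out = tmp_path / "hl.fa"
        mining.write_highlighted_fasta([rec], loci, out)
        body = "".join(out.read_text().splitlines()[1:])
        assert body == "gg" + "TA" * 6 + "gg"
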