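import numpy as np
import pytest
from Bio.Seq import reverse_complement

from ssrforge import epcr as ep
from ssrforge import markers as mk
from ssrforge import mining, synthetic
from ssrforge.sequence_io import SequenceRecord


def brute_force_sites(sequence, primer, budget, exact3):
    """Sliding-window re-derivation of primer binding sites."""
    out = []
    up, word = sequence.upper(), primer.upper()
    rc = reverse_complement(word)
    for p in range(len(up) - len(word) + 1):
        win = up[p : p + len(word)]
        mism = sum(a != b for a, b in zip(win, word))
        if mism <= budget and win[-exact3:] == word[-exact3:]:
            out.append((p, "+", mism))
        mism = sum(a != b for a, b in zip(win, rc))
        if mism <= budget and win[:exact3] == rc[:exact3]:
            out.append((p, "-", mism))
    return sorted(out)


@pytest.fixture(scope="module")
def marker_fixture():
    rng = np.random.default_rng(13)
    plants = synthetic.random_plants(8, rng, units=(2, 3), copies_range=(6, 10))
    spec = synthetic.PlantSpec(seq_lengths=[50_000], plants=plants, seed=13)
    records, truth = synthetic.generate_genome(
        spec, verify_config=mining.MiningConfig()
    )
    loci, _ = mining.mine_genome(records)
    designed, _ = mk.design_all(loci, records)
    markers = mk.deduplicate_markers(designed)
    return records, truth, loci, markers


class TestFindPrimerSites:
    def test_planted_primer_found_once(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        primer = "GATTACAGATTACAGATTAC"
        template = seq[:700] + primer + seq[700:]
        sites = ep.find_primer_sites(template, primer)
        fwd = [s for s in sites if s.strand == "+"]
        assert any(s.position == 700 for s in fwd)

    def test_mismatch_budget(self):
        primer = "GATTACAGATTACAGATTAC"
        mutated = primer[:10] + "C" + primer[11:]
        template = "ACGT" * 20 + mutated + "TGCA" * 20
        assert ep.find_primer_sites(template, primer, ep.EpcrParams()) == []
        sites = ep.find_primer_sites(template, primer, ep.EpcrParams(max_mismatches=1))
        assert len(sites) == 1 and sites[0].mismatches == 1

    def test_three_prime_mismatch_never_allowed(self):
        primer = "GATTACAGATTACAGATTAC"
        bad_end = primer[:-1] + "G"
        template = "ACGT" * 15 + bad_end + "TGCA" * 15
        assert ep.find_primer_sites(template, primer, ep.EpcrParams(max_mismatches=2)) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("ACGT"), size=5000))
        primer = "".join(rng.choice(list("ACGT"), size=12))
        params = ep.EpcrParams(max_mismatches=1)
        got = [(s.position, s.strand, s.mismatches)
               for s in ep.find_primer_sites(template, primer, params)]
        assert got == brute_force_sites(template, primer, 1, params.exact_3prime)

    def test_gapped_matching_unsupported(self):
        with pytest.raises(ep.EpcrError):
            ep.EpcrParams(max_gaps=1)


class TestEpcr:
    def test_source_mapping_recovers_declared_size(self, marker_fixture):
        records, _, _, markers = marker_fixture
        amps = ep.epcr(markers, records)
        for m in markers:
            own = [a for a in amps if a.marker_id == m.marker_id]
            assert any(a.size == m.product_size for a in own)
            for a in own:
                assert a.size == a.end - a.start + 1

    def test_deleted_region_gives_na(self, marker_fixture):
        records, truth, _, markers = marker_fixture
        # drop every tract and its surroundings from the target
        rec = records[0]
        keep = rec.sequence[: truth[0].start - 500]
        target = SequenceRecord("trimmed", keep)
        amps = ep.epcr(markers, [target])
        matrix, _ = ep.score_polymorphism(amps, markers, [target])
        assert (matrix["trimmed"] == "NA").any()

    def test_insertion_shifts_size_by_delta(self, marker_fixture):
        records, truth, _, markers = marker_fixture
        variants, vtruth = synthetic.mutate_alleles(records, truth, {0: 2}, seed=1)
        unit = len(truth[0].motif)
        amps_src = ep.epcr(markers, records)
        amps_var = ep.epcr(markers, variants)
        # the marker whose tract gained 2 copies grows by 2*unit
        target = next(
            m for m in markers
            if m.source_loci[0][1] == truth[0].start
        )
        src = [a.size for a in amps_src if a.marker_id == target.marker_id]
        var = [a.size for a in amps_var if a.marker_id == target.marker_id]
        assert sorted(v - s for s, v in zip(sorted(src), sorted(var))) == [2 * unit]

    def test_strand_symmetry(self, marker_fixture):
        records, _, _, markers = marker_fixture
        rc_records = [
            SequenceRecord(r.id, reverse_complement(r.sequence)) for r in records
        ]
        fwd = ep.epcr(markers, records)
        rev = ep.epcr(markers, rc_records)
        n = records[0].length
        assert sorted(a.size for a in fwd) == sorted(a.size for a in rev)
        mirrored = sorted((n - a.end + 1, n - a.start + 1) for a in rev)
        assert mirrored == sorted((a.start, a.end) for a in fwd)


class TestPolymorphism:
    def make(self, mid, size):
        pair = mk.PrimerPair("A" * 20, "C" * 20, size, 0, 0, 60, 60)
        return mk.Marker(mid, pair, size, "TA", [("s", 1, 12)], [size])

    def amp(self, mid, sid, size, start=100):
        return ep.Amplicon(mid, sid, start, start + size - 1, size, "+")

    def test_monomorphic_same_size_everywhere(self):
        m = self.make("NIX1", 338)
        recs = [SequenceRecord(s, "A" * 1000) for s in ("t1", "t2", "t3")]
        amps = [self.amp("NIX1", s, 338) for s in ("t1", "t2", "t3")]
        matrix, flags = ep.score_polymorphism(amps, [m], recs)
        assert not flags["NIX1"]
        assert matrix.loc[0, "t1"] == "338"

    def test_multiallele_cell_sorted_ascending(self):
        m = self.make("NIX101398", 200)
        recs = [SequenceRecord(s, "A" * 1000) for s in ("a", "b")]
        amps = [
            self.amp("NIX101398", "a", 204, start=100),
            self.amp("NIX101398", "a", 200, start=400),
            self.amp("NIX101398", "b", 202),
        ]
        matrix, flags = ep.score_polymorphism(amps, [m], recs)
        assert matrix.loc[0, "a"] == "200+204"
        assert flags["NIX101398"]

    def test_no_amplification_all_na_not_polymorphic(self):
        m = self.make("MK9", 150)
        recs = [SequenceRecord("x", "A" * 100)]
        matrix, flags = ep.score_polymorphism([], [m], recs)
        assert matrix.loc[0, "x"] == "NA" and not flags["MK9"]


class TestSummary:
    def test_mean_amplicons(self):
        ms = [TestPolymorphism().make(f"M{i}", 100 + i) for i in range(3)]
        recs = [SequenceRecord("t", "A" * 500)]
        amps = [TestPolymorphism().amp("M0", "t", 100, start=10 + 30 * i) for i in range(3)]
        amps += [TestPolymorphism().amp("M1", "t", 101, start=200 + 30 * i) for i in range(2)]
        s = ep.summarize_mapping(amps, ms, recs)
        assert s.n_markers_mapped == 2
        assert s.total_amplicons == 5
        assert s.mean_amplicons_per_mapped_marker == pytest.approx(2.5)

    def test_all_unmapped_zeros(self):
        ms = [TestPolymorphism().make("M1", 100)]
        s = ep.summarize_mapping([], ms, [SequenceRecord("t", "AC")])
        assert s.n_markers_mapped == 0 and s.mean_amplicons_per_mapped_marker == 0

    def test_fixture_totals(self, marker_fixture):
        records, _, _, markers = marker_fixture
        amps = ep.epcr(markers, records)
        s = ep.summarize_mapping(amps, markers, records)
        assert s.total_amplicons == len(amps)
        assert s.n_sequences_with_marker == len({a.seq_id for a in amps})
        assert sum(s.allele_distribution.values()) == len(markers)


class TestReportFiles:
    def test_amp_roundtrip(self, tmp_path, marker_fixture):
        records, _, _, markers = marker_fixture
        amps = ep.epcr(markers, records)
        path = tmp_path / "x.amp"
        ep.write_amp(amps, path)
        assert ep.read_amp(path) == amps

    def test_frg_and_emap_and_sat4_written(self, tmp_path, marker_fixture):
        records, _, _, markers = marker_fixture
        amps = ep.epcr(markers, records)
        matrix, _ = ep.score_polymorphism(amps, markers, records)
        ep.write_frg(matrix, tmp_path / "x.frg")
        ep.write_emap(amps, records, tmp_path / "x.emap")
        ep.write_sat4(ep.summarize_mapping(amps, markers, records), tmp_path / "x.sat4")
        assert (tmp_path / "x.frg").read_text().count("\n") == len(markers) + 1
        assert "Total_amplicons" in (tmp_path / "x.sat4").read_text()
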