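"""Domain types, dialect conversion and round-trip fidelity."""

import numpy as np
import pandas as pd
import pytest

import lncarray as la
from lncarray import io
from lncarray.core import parse_stage


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(la.LncArrayError):
            la.GenomicInterval("chr1", -1, 10, "+")
        with pytest.raises(la.LncArrayError):
            la.GenomicInterval("chr1", 10, 10, "+")
        with pytest.raises(la.LncArrayError):
            la.GenomicInterval("chr1", 0, 10, "x")

    @pytest.mark.parametrize("a,b,expected", [
        ((0, 10), (10, 20), 0),     # abutting
        ((0, 10), (5, 15), 0),      # overlapping
        ((0, 10), (20, 30), 10),
        ((20, 30), (0, 10), 10),    # symmetric
    ])
    def test_gap(self, a, b, expected):
        ia = la.GenomicInterval("c", *a)
        ib = la.GenomicInterval("c", *b)
        assert ia.gap_to(ib) == expected
        assert ib.gap_to(ia) == expected

    def test_strand_aware_overlap(self):
        plus = la.GenomicInterval("c", 0, 10, "+")
        minus = la.GenomicInterval("c", 5, 15, "-")
        assert plus.overlaps(minus)
        assert not plus.overlaps(minus, same_strand=True)


class TestStageParsing:
    @pytest.mark.parametrize("label,expected", [
        ("1", (1, False)), ("2a", (2, False)), ("2b", (2, False)),
        ("4", (4, False)), ("4s", (4, True)), (3, (3, False)),
    ])
    def test_labels(self, label, expected):
        assert parse_stage(label) == expected

    @pytest.mark.parametrize("label", ["5", "0", "x", "IV"])
    def test_out_of_domain(self, label):
        with pytest.raises(la.LncArrayError):
            parse_stage(label)


class TestTranscriptRecord:
    def test_length_is_exon_sum(self):
        iv = la.GenomicInterval("c", 100, 1000, "+")
        exons = (la.GenomicInterval("c", 100, 300, "+"),
                 la.GenomicInterval("c", 600, 1000, "+"))
        tx = la.TranscriptRecord("t", "g", iv, exons)
        assert tx.length_nt == 200 + 400

    def test_overlapping_exons_rejected(self):
        iv = la.GenomicInterval("c", 0, 100, "+")
        exons = (la.GenomicInterval("c", 0, 60, "+"),
                 la.GenomicInterval("c", 50, 100, "+"))
        with pytest.raises(la.LncArrayError):
            la.TranscriptRecord("t", "g", iv, exons)


class TestCohortMatrix:
    def test_stage_2b_collapses(self, tiny_matrix):
        assert tiny_matrix.metadata.loc["s2", "stage"] == 2

    def test_4s_excluded_from_staged(self):
        values = pd.DataFrame(np.zeros((1, 2)), index=["p"], columns=["a", "b"])
        meta = pd.DataFrame({"stage": ["4", "4s"]}, index=["a", "b"])
        cm = la.CohortMatrix(values, meta)
        assert cm.staged_samples() == ["a"]
        assert set(cm.staged_samples(include_4s=True)) == {"a", "b"}

    def test_missing_values_rejected(self):
        values = pd.DataFrame([[1.0, np.nan]], index=["p"], columns=["a", "b"])
        with pytest.raises(la.LncArrayError):
            la.CohortMatrix(values)

    def test_metadata_for_unknown_sample_rejected(self):
        values = pd.DataFrame([[1.0]], index=["p"], columns=["a"])
        meta = pd.DataFrame({"stage": ["1"]}, index=["ghost"])
        with pytest.raises(la.LncArrayError):
            la.CohortMatrix(values, meta)

    def test_restrict_non_mna(self):
        values = pd.DataFrame(np.zeros((1, 3)), index=["p"],
                              columns=["a", "b", "c"])
        meta = pd.DataFrame({"mycn_amplified": [True, False, None]},
                            index=["a", "b", "c"])
        cm = la.CohortMatrix(values, meta)
        assert cm.restrict_non_mna().sample_ids == ["b", "c"]


class TestIntervalIO:
    def test_bed_is_half_open_as_is(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr2\t100\t200\ttx1\t0\t+\n")
        (rec,) = io.read_intervals(path, "BED")
        assert (rec.interval.start, rec.interval.end, rec.interval.strand) == (100, 200, "+")

    def test_gff3_converts_to_half_open_once(self, tmp_path):
        path = tmp_path / "x.gff3"
        path.write_text(
            "chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tID=tx1;biotype=unannotated\n")
        first = io.read_intervals(path, "GFF3")
        second = io.read_intervals(path, "GFF3")
        assert first[0].interval.start == 100 and first[0].interval.end == 200
        assert first == second  # single application of the conversion

    def test_duplicate_transcript_id_rejected(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t0\t10\ttx1\t0\t+\nchr1\t20\t30\ttx1\t0\t+\n")
        with pytest.raises(la.LncArrayError, match="tx1"):
            io.read_intervals(path, "BED")

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t0\t10\ttx1\t0\t+\nchr1\tnope\t30\ttx2\t0\t+\n")
        with pytest.raises(la.LncArrayError, match=":2"):
            io.read_intervals(path, "BED")

    def test_unknown_strand_rejected(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t0\t10\ttx1\t0\t*\n")
        with pytest.raises(la.LncArrayError, match="strand"):
            io.read_intervals(path, "BED")

    def test_transcript_tsv_round_trip(self, tmp_path, genome_fixture):
        path = tmp_path / "tx.tsv"
        io.write_intervals(genome_fixture.transcripts, path, "TSV")
        back = io.read_intervals(path, "TSV")
        assert back == genome_fixture.transcripts


class TestCohortIO:
    def test_round_trip_identical(self, tmp_path, planted_cohort):
        cohort, _ = planted_cohort
        expr, meta = tmp_path / "e.tsv", tmp_path / "m.tsv"
        io.write_cohort(cohort, expr, meta)
        back = io.read_cohort(expr, meta)
        pd.testing.assert_frame_equal(back.values, cohort.values)
        assert list(back.metadata["stage"]) == list(cohort.metadata["stage"])
        assert back.probe_ids == cohort.probe_ids
        assert back.sample_ids == cohort.sample_ids

    def test_non_numeric_cell_located(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("probe_id\ts1\ts2\np1\t1.0\toops\n")
        with pytest.raises(la.LncArrayError, match="p1.*s2"):
            io.read_cohort(expr)

    def test_stage_five_rejected(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("probe_id\ts1\np1\t1.0\n")
        meta = tmp_path / "m.tsv"
        meta.write_text("sample_id\tstage\ns1\t5\n")
        with pytest.raises(la.LncArrayError):
            io.read_cohort(expr, meta)

    def test_samples_without_metadata_get_empty_records(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("probe_id\ts1\ts2\np1\t1.0\t2.0\n")
        meta = tmp_path / "m.tsv"
        meta.write_text("sample_id\tstage\ns1\t2\n")
        cohort = io.read_cohort(expr, meta)
        assert pd.isna(cohort.metadata.loc["s2", "stage"])


class TestProbeMappingIO:
    def test_multi_placement_probe_not_unique(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t0\t25\tpA\t0\t+\ttx1\n"
                        "chr1\t100\t125\tpA\t0\t+\ttx1\n"
                        "chr1\t200\t225\tpB\t0\t-\ttx2\n")
        probes = io.read_probe_mappings(path)
        by_id = {p.probe_set_id: p for p in probes}
        assert not by_id["pA"].unique_match and len(by_id["pA"].placements) == 2
        assert by_id["pB"].unique_match

    def test_round_trip(self, tmp_path, genome_fixture):
        path = tmp_path / "p.bed"
        io.write_probe_mappings(genome_fixture.probes, path)
        back = io.read_probe_mappings(path)
        assert back == list(genome_fixture.probes)
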