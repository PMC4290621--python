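"""End-to-end pipeline runs and CLI plumbing."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import lncarray as la
from lncarray import io
from lncarray.cli import main
from lncarray.config import RunConfig
from lncarray.pipelines import run_annotation_pipeline, run_biomarker_pipeline


def _write_genome_inputs(fx, tmp_path):
    io.write_intervals(fx.transcripts, tmp_path / "transcripts.tsv", "TSV")
    io.write_probe_mappings(fx.probes, tmp_path / "probes.bed")
    with open(tmp_path / "protein_exons.bed", "w") as fh:
        for iv in fx.protein_exons:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\texon\t0\t{iv.strand}\n")
    io.write_intervals(fx.reference, tmp_path / "reference.tsv", "TSV")
    with open(tmp_path / "coding_calls.tsv", "w") as fh:
        fh.write("TX_ORF\tcoding\n")


@pytest.fixture()
def annotation_config(genome_fixture, tmp_path):
    _write_genome_inputs(genome_fixture, tmp_path)
    return RunConfig(
        cutoffs_nt=(386, 2345),  # toy genome is far too small to fit
        inputs={
            "probes": str(tmp_path / "probes.bed"),
            "transcripts": str(tmp_path / "transcripts.tsv"),
            "protein_exons": str(tmp_path / "protein_exons.bed"),
            "coding_calls": str(tmp_path / "coding_calls.tsv"),
            "reference": str(tmp_path / "reference.tsv"),
        },
        outdir=str(tmp_path / "out"))


class TestAnnotationPipeline:
    def test_toy_genome_end_to_end_matches_planted_tables(
            self, genome_fixture, annotation_config, tmp_path):
        out = run_annotation_pipeline(annotation_config)
        retained = set(out["candidates"]["probe_set_id"])
        assert retained == genome_fixture.expected_retained
        audit = out["audit"].set_index("probe_set_id")
        for probe, reasons in genome_fixture.expected_reasons.items():
            assert audit.loc[probe, "reasons"] == ";".join(reasons)
        hc = set(out["candidates"].loc[
            out["candidates"]["high_confidence"], "probe_set_id"])
        assert hc == genome_fixture.expected_high_confidence
        classes = out["classes"].set_index("probe_set_id")["length_class"]
        assert classes["probe_antisense"] == "class2"  # 500 nt
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["stage_counts"]["candidates"] == 2

    def test_rerun_is_byte_identical(self, annotation_config, tmp_path):
        run_annotation_pipeline(annotation_config)
        first = {p.name: p.read_bytes()
                 for p in (tmp_path / "out").iterdir()}
        run_annotation_pipeline(annotation_config)
        second = {p.name: p.read_bytes()
                  for p in (tmp_path / "out").iterdir()}
        assert first == second

    def test_empty_probe_input_yields_empty_outputs(self, annotation_config,
                                                    tmp_path):
        (tmp_path / "probes.bed").write_text("")
        out = run_annotation_pipeline(annotation_config)
        assert out["candidates"].empty and out["audit"].empty

    def test_neighbor_and_enrichment_stages(self, genome_fixture, tmp_path):
        _write_genome_inputs(genome_fixture, tmp_path)
        terms = tmp_path / "terms.gmt"
        terms.write_text("develop\t-\tPC1\nhousekeeping\t-\tOTHER\n")
        config = RunConfig(
            cutoffs_nt=(386, 2345),
            inputs={
                "probes": str(tmp_path / "probes.bed"),
                "transcripts": str(tmp_path / "transcripts.tsv"),
                "protein_exons": str(tmp_path / "protein_exons.bed"),
                "coding_calls": str(tmp_path / "coding_calls.tsv"),
                "terms": str(terms),
            },
            outdir=str(tmp_path / "out2"))
        out = run_annotation_pipeline(config)
        # the antisense lncRNA overlaps the coding gene body: distance 0
        pairs = out["neighbors"]
        assert ("TX_ANTI", "PC1", 0) in list(
            pairs.itertuples(index=False, name=None))
        assert not out["enrichment"].empty


class TestBiomarkerPipeline:
    def test_synthetic_cohort_full_run(self, planted_cohort, tmp_path):
        cohort, planted = planted_cohort
        io.write_cohort(cohort, tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        config = RunConfig(
            restrict="all", folds=5, delta_grid=(0.0, 3.0, 10), seed=1,
            inputs={"expr": str(tmp_path / "expr.tsv"),
                    "meta": str(tmp_path / "meta.tsv")},
            outdir=str(tmp_path / "bio"))
        out = run_biomarker_pipeline(config)
        selected = set(out["screen"].index[out["screen"]["selected"]])
        assert len(selected & set(planted.index)) >= 0.9 * len(planted)
        per_delta = out["signature_per_delta"]
        assert per_delta["cv_accuracy"].max() > 0.8
        assert "clusters" in out
        manifest = json.loads((tmp_path / "bio" / "manifest.json").read_text())
        assert manifest["stage_counts"]["selected"] == len(selected)

    def test_missing_eval_cohort_skips_evaluation(self, planted_cohort, tmp_path):
        cohort, _ = planted_cohort
        io.write_cohort(cohort, tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        config = RunConfig(
            restrict="all", folds=5, delta_grid=(0.0, 3.0, 5),
            inputs={"expr": str(tmp_path / "expr.tsv"),
                    "meta": str(tmp_path / "meta.tsv")},
            outdir=str(tmp_path / "bio2"))
        out = run_biomarker_pipeline(config)
        assert "evaluation" not in out

    def test_stage_trained_model_transfers_to_relapse_labels(
            self, planted_cohort, tmp_path):
        """Applying the stage signature unchanged to relapse outcomes gives
        above-chance discrimination (relapse is stage-linked by design)."""
        cohort, _ = planted_cohort
        result = la.screen_stage_markers(cohort)
        selected = list(result.index[result["selected"]])
        staged = cohort.subset(samples=cohort.staged_samples())
        stage = staged.metadata["stage"].astype(int)
        labels = pd.Series(np.where(stage.isin((1, 2)), "early", "late"),
                           index=stage.index)
        model, _ = la.nsc_train(staged.subset(probes=selected), labels,
                                np.linspace(0, 2, 8), folds=5, seed=0)
        pred, _ = la.nsc_predict(model, staged)
        relapse = staged.metadata["relapse"].astype(bool)
        late_rate_relapse = (pred[relapse] == "late").mean()
        late_rate_no = (pred[~relapse] == "late").mean()
        assert late_rate_relapse > late_rate_no


class TestCLI:
    def test_simulate_and_screen_round_trip(self, tmp_path):
        runner = CliRunner()
        expr, meta = str(tmp_path / "e.tsv"), str(tmp_path / "m.tsv")
        result = runner.invoke(main, [
            "simulate", "cohort", "--patients", "40", "--probes", "60",
            "--informative", "10", "--seed", "3",
            "--expr-out", expr, "--meta-out", meta])
        assert result.exit_code == 0, result.output
        out = str(tmp_path / "screen.tsv")
        result = runner.invoke(main, [
            "screen", "--expr", expr, "--meta", meta, "--out", out])
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out, sep="\t")
        assert {"p_mw", "p_t", "tau", "selected"} <= set(table.columns)

    def test_classify_lengths_command(self, tmp_path):
        runner = CliRunner()
        lengths = str(tmp_path / "lengths.tsv")
        runner.invoke(main, ["simulate", "lengths", "--n", "3000",
                             "--seed", "1", "--out", lengths])
        result = runner.invoke(main, [
            "classify-lengths", "--lengths", lengths,
            "--fit-out", str(tmp_path / "fit.tsv"),
            "--classes-out", str(tmp_path / "cls.tsv")])
        assert result.exit_code == 0, result.output
        fit = pd.read_csv(tmp_path / "fit.tsv", sep="\t")
        assert 300 < fit["cutoff1_nt"].iloc[0] < 500

    def test_input_error_exits_one(self, tmp_path):
        runner = CliRunner()
        expr = tmp_path / "bad.tsv"
        expr.write_text("probe_id\ts1\np1\tnot_a_number\n")
        result = runner.invoke(main, [
            "screen", "--expr", str(expr), "--meta", str(expr),
            "--out", str(tmp_path / "o.tsv")])
        assert result.exit_code == 1
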