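"""End-to-end pipelines: probe annotation and biomarker discovery.

Each run writes its tables plus a manifest (config hash, seed, stage
record counts) sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import annotation, io, length_classes, neighbors, nsc, screen
from .config import RunConfig
from .core import LncArrayError


class StageError(LncArrayError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage {stage}] {original}")
        self.stage = stage


def _run_stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except LncArrayError as exc:
        raise StageError(name, exc) from exc


def _write_manifest(outdir, config: RunConfig, counts: dict) -> None:
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stage_counts": counts}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_transcripts(path):
    fmt = "GFF3" if str(path).endswith((".gff", ".gff3")) else (
        "BED" if str(path).endswith(".bed") else "TSV")
    return io.read_intervals(path, format=fmt)


def run_annotation_pipeline(config: RunConfig) -> dict:
    """Filtration cascade -> length classes -> neighbors -> enrichment.

    Returns the output tables; also writes them under ``config.outdir``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    counts: dict[str, int] = {}
    out: dict[str, pd.DataFrame] = {}

    probes = _run_stage("read_probes", io.read_probe_mappings,
                        config.inputs["probes"]) if config.inputs.get("probes") else []
    transcripts = _run_stage("read_transcripts", _load_transcripts,
                             config.inputs["transcripts"])
    protein_path = config.inputs.get("protein_exons")
    protein_exons = io.read_bed_regions(protein_path) if protein_path else []
    counts["probes_in"] = len(probes)
    if not probes:
        io.kv_log("run_annotation", warning="empty probe input; writing empty outputs")

    coding_calls = {}
    if config.inputs.get("coding_calls"):
        coding_calls = {k: v[0] for k, v in io.read_two_column_tsv(
            config.inputs["coding_calls"], "coding calls").items()}
    evidence = annotation.CodingEvidence(external_calls=coding_calls)

    candidates, audits = _run_stage(
        "filter_candidates", annotation.filter_candidates,
        probes, transcripts, protein_exons, evidence, min_length=config.min_length)
    if config.inputs.get("reference"):
        reference = _load_transcripts(config.inputs["reference"])
        candidates = _run_stage("match_reference", annotation.match_reference,
                                candidates, reference)
    counts["candidates"] = len(candidates)
    counts["high_confidence"] = sum(c.high_confidence for c in candidates)

    out["candidates"] = pd.DataFrame(
        [{"probe_set_id": c.probe_set_id, "transcript_id": c.transcript.transcript_id,
          "length_nt": c.length_nt, "high_confidence": c.high_confidence}
         for c in candidates])
    out["audit"] = pd.DataFrame(
        [{"probe_set_id": a.probe_set_id, "outcome": a.outcome,
          "reasons": ";".join(a.reasons)} for a in audits])

    lengths = np.array([c.length_nt for c in candidates])
    cutoffs = config.cutoffs_nt
    fit_rows = []
    if cutoffs is None and np.unique(lengths).size >= 30:
        fit = _run_stage("fit_mixture", length_classes.fit_mixture,
                         lengths, n_components=config.n_components)
        cutoffs = fit.cutoffs_nt
        for comp, prop in zip(fit.components, fit.class_proportions):
            fit_rows.append({"a0": comp.a0, "a1": comp.a1, "a2": comp.a2,
                             "x_lo": comp.fit_range[0], "x_hi": comp.fit_range[1],
                             "proportion": prop})
        io.kv_log("fit_mixture", cutoffs=",".join(f"{c:.0f}" for c in cutoffs),
                  sse=f"{fit.sse:.4g}")
    elif cutoffs is None:
        io.kv_log("run_annotation",
                  warning="too few distinct lengths for mixture fit; classes skipped")
    out["fit_report"] = pd.DataFrame(fit_rows)
    if cutoffs is not None and len(candidates):
        labels = length_classes.classify_lengths(lengths, cutoffs, config.min_length)
        out["classes"] = pd.DataFrame({
            "probe_set_id": [c.probe_set_id for c in candidates],
            "length_nt": lengths, "length_class": labels})
    else:
        out["classes"] = pd.DataFrame(
            columns=["probe_set_id", "length_nt", "length_class"])
    counts["classified"] = len(out["classes"])

    lnc_tx = [c.transcript for c in candidates]
    coding_genes = [t for t in transcripts if t.biotype == "protein_coding"]
    pairs = _run_stage("find_neighbors", neighbors.find_neighbors,
                       lnc_tx, coding_genes, window=config.window)
    out["neighbors"] = neighbors.neighbors_to_frame(pairs)
    counts["neighbor_pairs"] = len(pairs)

    if config.inputs.get("terms") and pairs:
        mapping = io.read_gmt(config.inputs["terms"])
        selected = {p.gene_id for p in pairs} & mapping.universe
        _sig, full = _run_stage("enrich", neighbors.enrich, selected, mapping,
                                p_max=config.p_go,
                                min_enrichment=config.min_enrichment)
        out["enrichment"] = neighbors.enrichment_to_frame(full)
        counts["enriched_terms"] = len(_sig)
    else:
        out["enrichment"] = pd.DataFrame(
            columns=["term_id", "k", "n", "K", "N", "enrichment", "p"])

    for name, frame in out.items():
        frame.to_csv(os.path.join(config.outdir, f"{name}.tsv"),
                     sep="\t", index=False)
    _write_manifest(config.outdir, config, counts)
    io.kv_log("run_annotation_done", **counts)
    return out


def run_biomarker_pipeline(config: RunConfig) -> dict:
    """Stage screen -> NSC signature -> optional evaluation -> clustering."""
    os.makedirs(config.outdir, exist_ok=True)
    counts: dict[str, int] = {}
    out: dict = {}

    cohort = _run_stage("read_cohort", io.read_cohort,
                        config.inputs["expr"], config.inputs.get("meta"))
    counts["probes_in"] = cohort.n_probes
    counts["samples_in"] = cohort.n_samples

    result = _run_stage("screen", screen.screen_stage_markers, cohort,
                        p_screen=config.p_screen, tau_min=config.tau_min,
                        restrict=config.restrict, cut_on=config.cut_on)
    out["screen"] = result
    counts["pass_discrimination"] = int(result["pass_discrimination"].sum())
    counts["selected"] = int(result["selected"].sum())
    selected = list(result.index[result["selected"]])

    restricted = cohort.restrict_non_mna() if config.restrict == "non_mna" else cohort
    staged = restricted.subset(samples=restricted.staged_samples())
    stage = staged.metadata["stage"].astype(int)
    labels = pd.Series(np.where(stage.isin((1, 2)), "early", "late"),
                       index=stage.index)

    model = None
    if len(selected) >= 2:
        sig_cohort = staged.subset(probes=selected)
        lo, hi, num = config.delta_grid
        grid = np.linspace(float(lo), float(hi), int(num))
        folds = min(config.folds,
                    int(labels.value_counts().min() // 2))
        if folds >= 2:
            model, report = _run_stage("nsc_train", nsc.nsc_train, sig_cohort,
                                       labels, grid, folds=folds, seed=config.seed)
            out["signature_per_delta"] = report.per_delta
            out["signature_confusion"] = report.confusion
            out["signature_probes"] = pd.DataFrame({"probe_id": report.probes})
            counts["signature_probes"] = len(report.probes)
            io.kv_log("signature", delta=model.delta,
                      cv_accuracy=f"{report.cv_accuracy:.3f}")
        else:
            io.kv_log("run_biomarker", warning="too few samples per class for CV")
    else:
        io.kv_log("run_biomarker", warning="fewer than 2 selected probes; "
                  "signature training skipped")

    if model is not None and config.inputs.get("eval_expr"):
        eval_cohort = _run_stage("read_eval_cohort", io.read_cohort,
                                 config.inputs["eval_expr"],
                                 config.inputs.get("eval_meta"))
        pred, scores = _run_stage("nsc_predict", nsc.nsc_predict, model, eval_cohort)
        out["evaluation"] = pd.DataFrame({"predicted": pred}).join(scores)
        counts["evaluated_samples"] = len(pred)
    elif model is not None:
        io.kv_log("run_biomarker", notice="no evaluation cohort supplied; "
                  "evaluation skipped")

    if model is not None and len(model.surviving_features) >= 3:
        clusters, tau = _run_stage(
            "cluster_signature", nsc.cluster_signature,
            staged.subset(probes=model.surviving_features))
        out["clusters"] = pd.DataFrame({"cluster": clusters})
        out["tau_matrix"] = tau
        counts["clusters"] = int(clusters.nunique())

    for name, frame in out.items():
        frame.to_csv(os.path.join(config.outdir, f"{name}.tsv"), sep="\t",
                     index=True, index_label="id")
    _write_manifest(config.outdir, config, counts)
    io.kv_log("run_biomarker_done", **counts)
    return out
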