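"""Synthetic-data generators for every pipeline stage.

All generators are pure functions of (spec, seed): a toy annotated genome
with planted filter outcomes, transcript-length populations drawn from a
known three-component mixture (a log-normal body between 200 nt and the
first breakpoint plus two truncated-Pareto power-law tails), staged
patient cohorts with a planted subset of stage-monotone probes, and
siRNA knock-down replicate matrices with planted up/down genes.

Default conditions mirror the reference neuroblastoma study: length-class
shares of roughly 4% / 87% / 9% around breakpoints near 400 and 2,300 nt;
cohorts of 64 patients of whom ~14 are MYCN-amplified; planted stage
effects positive for ~80% of informative probes; knock-down designs of
two siRNA conditions x 4 replicates against one control x 4 replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import CodingEvidence, ProbeMapping
from .core import CohortMatrix, GenomicInterval, LncArrayError, TranscriptRecord

__all__ = [
    "LengthGenSpec", "CohortGenSpec", "GenomeFixture",
    "gen_lengths", "gen_cohort", "gen_knockdown", "gen_genome_fixture",
]


@dataclass(frozen=True)
class LengthGenSpec:
    """Generative twin of the three-class length mixture."""

    n: int = 1581
    proportions: tuple = (0.04, 0.87, 0.09)
    break1_nt: float = 400.0
    break2_nt: float = 2300.0
    body_mu: float = math.log(290.0)   # natural-log location of the short class
    body_sigma: float = 0.35
    tail_exponents: tuple = (-1.6, -2.6)  # log-log iCDF slopes of the two tails
    min_nt: int = 200

    def __post_init__(self):
        if len(self.proportions) != 3 or any(p < 0 for p in self.proportions):
            raise LncArrayError("proportions must be 3 non-negative reals")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise LncArrayError("proportions must sum to 1")
        if not self.min_nt < self.break1_nt < self.break2_nt:
            raise LncArrayError("require min_nt < break1_nt < break2_nt")
        if any(e >= 0 for e in self.tail_exponents):
            raise LncArrayError("tail exponents must be negative")


def _truncated_lognormal(rng, n, mu, sigma, lo, hi):
    """Inverse-CDF sampling of ln-normal(mu, sigma) truncated to [lo, hi]."""
    a = norm.cdf((math.log(lo) - mu) / sigma)
    b = norm.cdf((math.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=n)
    return np.exp(mu + sigma * norm.ppf(u))


def _truncated_pareto(rng, n, alpha, lo, hi=None):
    """Inverse-CDF sampling of Pareto with survival (L/lo)^-alpha on [lo, hi)."""
    u = rng.uniform(0.0, 1.0, size=n)
    if hi is None:
        return lo * (1.0 - u) ** (-1.0 / alpha)
    lo_a, hi_a = lo ** -alpha, hi ** -alpha
    return (lo_a - u * (lo_a - hi_a)) ** (-1.0 / alpha)


def gen_lengths(spec: LengthGenSpec, seed: int):
    """Draw n transcript lengths; returns (lengths array, class labels 1..3)."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=spec.n, p=np.asarray(spec.proportions)) + 1
    lengths = np.empty(spec.n)
    m1 = labels == 1
    m2 = labels == 2
    m3 = labels == 3
    lengths[m1] = _truncated_lognormal(
        rng, int(m1.sum()), spec.body_mu, spec.body_sigma, spec.min_nt, spec.break1_nt)
    lengths[m2] = _truncated_pareto(
        rng, int(m2.sum()), -spec.tail_exponents[0], spec.break1_nt, spec.break2_nt)
    lengths[m3] = _truncated_pareto(
        rng, int(m3.sum()), -spec.tail_exponents[1], spec.break2_nt)
    lengths = np.maximum(np.rint(lengths).astype(int), spec.min_nt)
    return lengths, labels


@dataclass(frozen=True)
class CohortGenSpec:
    """Staged expression cohort with planted stage-monotone probes."""

    n_patients: int = 64
    n_probes: int = 1000
    n_informative: int = 50
    effect_per_stage: float = 1.0   # mean log2 shift per stage step
    noise_sd: float = 0.5
    frac_mna: float = 14 / 64
    pos_frac: float = 0.8           # share of planted effects with positive sign
    relapse_intercept: float = -2.2  # logistic relapse model over stage
    relapse_slope: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_probes:
            raise LncArrayError("n_informative must be <= n_probes")
        if self.noise_sd <= 0:
            raise LncArrayError("noise_sd must be > 0")


def gen_cohort(spec: CohortGenSpec):
    """Simulate a staged cohort; returns (CohortMatrix, planted-marker frame).

    Informative probes have expectation baseline + sign * effect_per_stage
    * (stage - 1); all other probes are pure noise.  Stages are balanced
    across patients; relapse probability is logistic in stage.
    """
    rng = np.random.default_rng(spec.seed)
    stages = np.tile([1, 2, 3, 4], spec.n_patients // 4 + 1)[: spec.n_patients]
    rng.shuffle(stages)
    mna = rng.random(spec.n_patients) < spec.frac_mna
    relapse_p = 1.0 / (1.0 + np.exp(
        -(spec.relapse_intercept + spec.relapse_slope * (stages - 1))))
    relapse = rng.random(spec.n_patients) < relapse_p

    probe_ids = [f"P{i:05d}" for i in range(spec.n_probes)]
    sample_ids = [f"S{i:03d}" for i in range(spec.n_patients)]
    informative = rng.choice(spec.n_probes, size=spec.n_informative, replace=False)
    signs = np.where(rng.random(spec.n_informative) < spec.pos_frac, 1.0, -1.0)

    baseline = rng.normal(7.0, 1.0, size=spec.n_probes)
    values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_probes, spec.n_patients))
    values[informative] += (signs[:, None] * spec.effect_per_stage
                            * (stages[None, :] - 1))

    meta = pd.DataFrame({
        "stage": stages, "mycn_amplified": mna, "relapse": relapse}, index=sample_ids)
    cohort = CohortMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids), meta)
    planted = pd.DataFrame({
        "probe_id": [probe_ids[i] for i in informative],
        "sign": signs.astype(int)}).set_index("probe_id")
    return cohort, planted


def gen_knockdown(n_probes: int = 1000, de_up: int = 43, de_down: int = 53,
                  effect_log2: float = 2.0, reps: int = 4, seed: int = 0,
                  noise_sd: float = 0.1):
    """Simulate a knock-down array set (control + two siRNA conditions).

    Planted probes shift by +/- effect_log2 in BOTH siRNA conditions;
    replicate noise is i.i.d.  Returns (CohortMatrix with condition
    metadata, {'up': ids, 'down': ids}).
    """
    if reps < 3:
        raise LncArrayError("criterion 3 needs >= 3 replicates per condition")
    if de_up + de_down > n_probes:
        raise LncArrayError("de_up + de_down must be <= n_probes")
    rng = np.random.default_rng(seed)
    conditions = ["control", "siRNA_1", "siRNA_2"]
    sample_ids, cond_labels = [], []
    for cond in conditions:
        for r in range(1, reps + 1):
            sample_ids.append(f"{cond}_r{r}")
            cond_labels.append(cond)
    probe_ids = [f"G{i:05d}" for i in range(n_probes)]
    order = rng.permutation(n_probes)
    up_idx, down_idx = order[:de_up], order[de_up:de_up + de_down]

    baseline = rng.normal(7.0, 1.0, size=n_probes)
    values = baseline[:, None] + rng.normal(
        0.0, noise_sd, size=(n_probes, len(sample_ids)))
    treated = np.array([c != "control" for c in cond_labels])
    values[np.ix_(up_idx, treated)] += effect_log2
    values[np.ix_(down_idx, treated)] -= effect_log2

    meta = pd.DataFrame({"condition": cond_labels}, index=sample_ids)
    cohort = CohortMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids), meta)
    planted = {"up": sorted(probe_ids[i] for i in up_idx),
               "down": sorted(probe_ids[i] for i in down_idx)}
    return cohort, planted


# -- annotated toy genome -------------------------------------------------

@dataclass
class GenomeFixture:
    """A hand-enumerated toy genome exercising every filtration path."""

    transcripts: list
    protein_exons: list
    probes: list
    reference: list
    coding_evidence: CodingEvidence
    expected_retained: set
    expected_reasons: dict
    expected_high_confidence: set


def _orf_sequence(total_nt: int, orf_codons: int) -> str:
    """Deterministic sequence whose longest ORF has exactly orf_codons codons."""
    orf = "ATG" + "GGA" * (orf_codons - 1) + "TAA"
    pad = total_nt - len(orf)
    if pad < 0:
        raise LncArrayError("total_nt too small for requested ORF")
    return "C" * (pad // 2) + orf + "C" * (pad - pad // 2)


def gen_genome_fixture(seed: int = 0) -> GenomeFixture:
    """Toy genome with planted expected filter outcomes.

    The layout plants one probe per cascade path: a multi-locus probe, a
    sense overlap with a protein exon, an antisense overlap (which must
    survive, mirroring the HOXD-AS1 geometry), a probe on an annotated
    protein transcript, a coding-ORF transcript, a short (<200 nt)
    transcript, and a reference-matched high-confidence lncRNA.  The seed
    only permutes probe order; expectations are unchanged.
    """
    iv = GenomicInterval
    pc_exons = [iv("chr1", 1000, 1600, "+"), iv("chr1", 2200, 3000, "+")]
    tx_pc1 = TranscriptRecord("TX_PC1", "PC1", iv("chr1", 1000, 3000, "+"),
                              tuple(pc_exons), biotype="protein_coding")
    tx_multi = TranscriptRecord("TX_MULTI", "G_MULTI", iv("chr1", 5000, 5400, "+"))
    tx_sense = TranscriptRecord("TX_SENSE", "G_SENSE", iv("chr1", 1400, 1700, "+"))
    tx_anti = TranscriptRecord("TX_ANTI", "G_ANTI", iv("chr1", 1400, 1900, "-"))
    tx_orf = TranscriptRecord("TX_ORF", "G_ORF", iv("chr1", 20000, 20900, "+"))
    tx_short = TranscriptRecord("TX_SHORT", "G_SHORT", iv("chr1", 30000, 30150, "+"))
    tx_ref = TranscriptRecord("TX_REF", "G_REF", iv("chr1", 40000, 40800, "+"))
    transcripts = [tx_pc1, tx_multi, tx_sense, tx_anti, tx_orf, tx_short, tx_ref]

    probes = [
        ProbeMapping("probe_multi",
                     (iv("chr1", 5000, 5025, "+"), iv("chr1", 9000, 9025, "+")),
                     "TX_MULTI", unique_match=False),
        ProbeMapping("probe_sense", (iv("chr1", 1500, 1525, "+"),), "TX_SENSE"),
        ProbeMapping("probe_antisense", (iv("chr1", 1500, 1525, "-"),), "TX_ANTI"),
        ProbeMapping("probe_protein", (iv("chr1", 2300, 2325, "+"),), "TX_PC1"),
        ProbeMapping("probe_coding", (iv("chr1", 20100, 20125, "+"),), "TX_ORF"),
        ProbeMapping("probe_short", (iv("chr1", 30050, 30075, "+"),), "TX_SHORT"),
        ProbeMapping("probe_ref", (iv("chr1", 40100, 40125, "+"),), "TX_REF"),
    ]
    rng = np.random.default_rng(seed)
    probes = [probes[i] for i in rng.permutation(len(probes))]

    # TX_ORF: 100-codon ORF covering 303/900 nt = 33.7% -> coding
    evidence = CodingEvidence(sequences={"TX_ORF": _orf_sequence(900, 100)})
    reference = [TranscriptRecord("REF1", "REF1", iv("chr1", 40000, 40800, "+"))]

    expected_reasons = {
        "probe_multi": ("non_unique",),
        "probe_sense": ("same_strand_protein_exon_overlap",),
        "probe_antisense": (),
        "probe_protein": ("protein_annotated", "same_strand_protein_exon_overlap"),
        "probe_coding": ("coding_potential",),
        "probe_short": ("below_min_length",),
        "probe_ref": (),
    }
    return GenomeFixture(
        transcripts=transcripts, protein_exons=pc_exons, probes=probes,
        reference=reference, coding_evidence=evidence,
        expected_retained={"probe_antisense", "probe_ref"},
        expected_reasons=expected_reasons,
        expected_high_confidence={"probe_ref"})
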