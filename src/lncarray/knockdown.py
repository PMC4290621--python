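"""Triple-criterion differential-expression calling for siRNA knock-downs.

A probe is called differentially expressed in one siRNA condition when it
simultaneously satisfies (1) Student's t test treated vs control p < 0.05,
(2) |median fold change| beyond 1.3 (or 1.4), and (3) at least 3 treated
replicates beyond the control median in the fold-change direction.  The
consensus list keeps probes passing all three criteria in BOTH siRNA
conditions with the same direction.  Criterion 3 is direction-aware:
down-regulated probes must fall below the control median (the mirrored
condition), otherwise down-calls would be impossible.

Downstream helpers relate called targets to the anchoring lncRNA in
clinical cohorts (Kendall tau) and to binary outcomes such as relapse or
5-year survival (Mann-Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CohortMatrix, LncArrayError
from .screen import bh_fdr, kendall_tau_test, mann_whitney, students_t


@dataclass(frozen=True)
class DECall:
    probe_id: str
    condition: str
    fold_change: float  # linear-scale ratio of medians, treated / control
    p_t: float
    reps_beyond_control: int
    direction: str  # up | down
    passes: bool


def _condition_samples(cohort: CohortMatrix, condition: str):
    meta = cohort.metadata["condition"]
    ids = list(meta.index[meta == condition])
    if not ids:
        raise LncArrayError(f"no samples labelled condition {condition!r}")
    return ids


def call_de(cohort: CohortMatrix, p_de: float = 0.05, fc_min: float = 1.3,
            min_reps: int = 3, log_scale: bool = True,
            conditions=("siRNA_1", "siRNA_2"), control: str = "control"):
    """Call DE probes per siRNA condition and build the consensus list.

    ``log_scale`` declares the matrix to be log2; fold changes are then
    computed after exponentiation.  Returns (per-condition DataFrame,
    consensus DataFrame).
    """
    ctrl_ids = _condition_samples(cohort, control)
    cond_ids = {c: _condition_samples(cohort, c) for c in conditions}
    for c, ids in cond_ids.items():
        if len(ids) < min_reps:
            raise LncArrayError(
                f"condition {c!r} has {len(ids)} replicates < min_reps={min_reps}")
    if len(ctrl_ids) < 2:
        raise LncArrayError("control needs >= 2 replicates for the t test")

    calls = []
    for cond in conditions:
        treated = cohort.values[cond_ids[cond]].to_numpy()
        ctrl = cohort.values[ctrl_ids].to_numpy()
        lin_t = 2.0 ** treated if log_scale else treated
        lin_c = 2.0 ** ctrl if log_scale else ctrl
        med_t = np.median(lin_t, axis=1)
        med_c = np.median(lin_c, axis=1)
        ctrl_median = np.median(ctrl, axis=1)
        for i, probe in enumerate(cohort.probe_ids):
            if med_c[i] <= 0:
                raise LncArrayError(f"{probe}: non-positive control median on linear scale")
            fc = med_t[i] / med_c[i]
            direction = "up" if fc >= 1.0 else "down"
            _, p = students_t(treated[i], ctrl[i])
            if direction == "up":
                beyond = int((treated[i] > ctrl_median[i]).sum())
            else:
                beyond = int((treated[i] < ctrl_median[i]).sum())
            passes = (p < p_de
                      and max(fc, 1.0 / fc) > fc_min
                      and beyond >= min_reps)
            calls.append(DECall(probe, cond, float(fc), float(p), beyond,
                                direction, bool(passes)))

    per_condition = pd.DataFrame([c.__dict__ for c in calls])
    passed = per_condition[per_condition["passes"]]
    consensus_rows = []
    for probe, group in passed.groupby("probe_id", sort=False):
        if set(group["condition"]) == set(conditions) and group["direction"].nunique() == 1:
            consensus_rows.append({
                "probe_id": probe,
                "direction": group["direction"].iloc[0],
                "fold_change_min": float(group["fold_change"].min()),
                "fold_change_max": float(group["fold_change"].max()),
                "p_t_max": float(group["p_t"].max()),
            })
    consensus = pd.DataFrame(
        consensus_rows,
        columns=["probe_id", "direction", "fold_change_min", "fold_change_max", "p_t_max"])
    return per_condition, consensus


def collapse_to_genes(values: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Optional probe -> gene collapse keeping the max-variance probe per gene."""
    variances = values.var(axis=1)
    best = {}
    for probe in values.index:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or variances[probe] > variances[best[gene]]:
            best[gene] = probe
    out = values.loc[list(best.values())]
    out.index = list(best.keys())
    return out


def correlate_targets(cohort: CohortMatrix, anchor_probe: str, target_probes,
                      p_max: float = 0.05) -> pd.DataFrame:
    """Kendall tau-b of each target against the anchor lncRNA across samples."""
    if anchor_probe not in set(cohort.probe_ids):
        raise LncArrayError(f"anchor probe {anchor_probe!r} absent from cohort")
    anchor = cohort.values.loc[anchor_probe].to_numpy()
    if np.unique(anchor).size == 1:
        raise LncArrayError("anchor probe is constant: correlation undefined")
    rows = []
    for probe in target_probes:
        if probe not in set(cohort.probe_ids):
            raise LncArrayError(f"target probe {probe!r} absent from cohort")
        target = cohort.values.loc[probe].to_numpy()
        if np.unique(target).size == 1:
            rows.append({"probe_id": probe, "tau": np.nan, "p": np.nan,
                         "significant": False, "sign": 0})
            continue
        tau, p = kendall_tau_test(anchor, target)
        rows.append({"probe_id": probe, "tau": tau, "p": p,
                     "significant": bool(p < p_max), "sign": int(np.sign(tau))})
    return pd.DataFrame(rows).set_index("probe_id")


def binary_marker_test(cohort: CohortMatrix, outcome, probes=None,
                       p_max: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney test of each probe against a binary outcome.

    ``outcome`` is a metadata column name ('relapse' / 'survived_5y') or a
    per-sample boolean mapping.  Flags use raw p < p_max, matching the
    screening convention; BH q-values are reported alongside.
    """
    if isinstance(outcome, str):
        flags = cohort.metadata[outcome]
    else:
        flags = pd.Series(outcome).reindex(cohort.sample_ids)
    known = flags.notna()
    flags = flags[known].astype(bool)
    pos = list(flags.index[flags])
    neg = list(flags.index[~flags])
    if not pos or not neg:
        raise LncArrayError("binary_marker_test: both outcome groups must be non-empty")
    probes = list(probes) if probes is not None else cohort.probe_ids
    sub = cohort.subset(probes=probes)
    rows = []
    for probe in probes:
        x = sub.values.loc[probe, pos].to_numpy()
        y = sub.values.loc[probe, neg].to_numpy()
        U, p = mann_whitney(x, y)
        rows.append({"probe_id": probe, "U": U, "p": p})
    out = pd.DataFrame(rows).set_index("probe_id")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p"] < p_max
    return out
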