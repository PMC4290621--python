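"""Nearest-shrunken-centroid (PAM) signature modelling.

Per-feature standardized class-centroid differences
``d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0))`` are soft-thresholded by a
shrinkage amount delta; features whose differences vanish for every class
drop out of the signature, and classification uses the shrunken-centroid
discriminant with class priors.  Delta is chosen by stratified k-fold
cross-validation with the one-standard-error parsimony rule (the largest
delta whose CV error is within one SE of the minimum).

Here ``m_k = sqrt(1/n_k - 1/n)``, ``s_i`` is the pooled within-class
standard deviation and ``s0`` its median (the fudge constant guarding
against near-zero denominators), following the method's conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau
from sklearn.model_selection import StratifiedKFold

from .core import CohortMatrix, LncArrayError
from .io import kv_log


@dataclass
class NSCModel:
    feature_ids: list
    classes: tuple
    overall_centroid: np.ndarray
    class_centroids: np.ndarray
    shrunken_centroids: np.ndarray
    pooled_sd: np.ndarray
    s0: float
    delta: float
    priors: np.ndarray
    dik: np.ndarray

    @property
    def surviving_mask(self) -> np.ndarray:
        return (self.dik != 0).any(axis=0)

    @property
    def surviving_features(self) -> list:
        return [f for f, keep in zip(self.feature_ids, self.surviving_mask) if keep]


@dataclass
class SignatureReport:
    delta: float
    probes: list
    cv_accuracy: float
    confusion: pd.DataFrame
    per_class: pd.DataFrame
    per_delta: pd.DataFrame


def _centroid_stats(X: np.ndarray, y: np.ndarray, classes):
    n, p = X.shape
    k = len(classes)
    counts = np.array([(y == c).sum() for c in classes])
    overall = X.mean(axis=0)
    centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
    ss = np.zeros(p)
    for idx, c in enumerate(classes):
        ss += ((X[y == c] - centroids[idx]) ** 2).sum(axis=0)
    pooled_sd = np.sqrt(ss / (n - k))
    mk = np.sqrt(1.0 / counts - 1.0 / n)
    return overall, centroids, pooled_sd, mk, counts


def nsc_fit(X: np.ndarray, y: np.ndarray, delta: float,
            feature_ids=None, priors=None) -> NSCModel:
    """Fit a shrunken-centroid model at a fixed delta (samples x features)."""
    if delta < 0:
        raise LncArrayError("delta must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(np.unique(y))
    if len(classes) < 2:
        raise LncArrayError("nsc_fit needs >= 2 classes")
    overall, centroids, pooled_sd, mk, counts = _centroid_stats(X, y, classes)
    s0 = float(np.median(pooled_sd))
    denom = mk[:, None] * (pooled_sd + s0)[None, :]
    d = (centroids - overall) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall + denom * d_shrunk
    priors = (counts / len(y)) if priors is None else np.asarray(priors, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[1])]
    return NSCModel(
        feature_ids=list(feature_ids), classes=classes, overall_centroid=overall,
        class_centroids=centroids, shrunken_centroids=shrunken,
        pooled_sd=pooled_sd, s0=s0, delta=float(delta), priors=priors, dik=d_shrunk)


def _scores(model: NSCModel, X: np.ndarray) -> np.ndarray:
    scale = (model.pooled_sd + model.s0) ** 2
    out = np.empty((X.shape[0], len(model.classes)))
    for k in range(len(model.classes)):
        out[:, k] = (((X - model.shrunken_centroids[k]) ** 2) / scale).sum(axis=1)
        out[:, k] -= 2.0 * np.log(model.priors[k])
    return out


def nsc_predict(model: NSCModel, cohort: CohortMatrix):
    """Classify cohort samples; returns (labels Series, discriminant-score frame).

    The winning class minimises the shrunken-centroid discriminant; exact
    ties go to the first class in label order.
    """
    missing = [f for f in model.feature_ids if f not in set(cohort.probe_ids)]
    if missing:
        raise LncArrayError(f"cohort lacks model feature(s): {missing[:5]}")
    X = cohort.values.loc[model.feature_ids].to_numpy().T
    scores = _scores(model, X)
    ties = (scores == scores.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        kv_log("nsc_predict_ties", n=int(ties.sum()), rule="first class in label order")
    labels = pd.Series(
        [model.classes[i] for i in scores.argmin(axis=1)],
        index=cohort.sample_ids, name="predicted")
    frame = pd.DataFrame(scores, index=cohort.sample_ids, columns=list(model.classes))
    return labels, frame


def _predict_array(model: NSCModel, X: np.ndarray) -> np.ndarray:
    scores = _scores(model, X)
    return np.asarray(model.classes, dtype=object)[scores.argmin(axis=1)]


def nsc_train(cohort: CohortMatrix, labels, delta_grid, folds: int = 10,
              seed: int = 0):
    """Cross-validated shrunken-centroid training over a delta grid.

    ``labels`` is a per-sample mapping/Series of binary class labels.
    Returns (model fitted on all data at the chosen delta, SignatureReport).
    """
    delta_grid = sorted(float(d) for d in np.atleast_1d(np.asarray(delta_grid, dtype=float)))
    if not delta_grid:
        raise LncArrayError("delta_grid must not be empty")
    y = pd.Series(labels).reindex(cohort.sample_ids)
    if y.isna().any():
        raise LncArrayError("labels missing for some cohort samples")
    y = y.to_numpy()
    X = cohort.values.to_numpy().T
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2 * folds:
        raise LncArrayError(
            f"need >= 2 samples per class per fold: smallest class has "
            f"{counts.min()} samples for {folds} folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n_delta = len(delta_grid)
    fold_errors = np.zeros((n_delta, folds))
    held_out = {d: pd.Series(index=cohort.sample_ids, dtype=object) for d in range(n_delta)}
    sample_ids = np.asarray(cohort.sample_ids)
    for f, (train, test) in enumerate(skf.split(X, y)):
        fold_classes = tuple(np.unique(y[train]))
        overall, centroids, pooled_sd, mk, counts = _centroid_stats(
            X[train], y[train], fold_classes)
        s0 = float(np.median(pooled_sd))
        denom = mk[:, None] * (pooled_sd + s0)[None, :]
        d = (centroids - overall) / denom
        for di, delta in enumerate(delta_grid):
            shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
            model_d = NSCModel(
                feature_ids=cohort.probe_ids, classes=fold_classes,
                overall_centroid=overall, class_centroids=centroids,
                shrunken_centroids=overall + denom * shrunk,
                pooled_sd=pooled_sd, s0=s0, delta=delta,
                priors=counts / len(train), dik=shrunk)
            pred = _predict_array(model_d, X[test])
            fold_errors[di, f] = float(np.mean(pred != y[test]))
            held_out[di].loc[sample_ids[test]] = pred

    cv_err = fold_errors.mean(axis=1)
    cv_se = fold_errors.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(cv_err))
    threshold = cv_err[best] + cv_se[best]
    chosen = max(i for i in range(n_delta) if cv_err[i] <= threshold)
    delta = delta_grid[chosen]

    model = nsc_fit(X, y, delta=delta, feature_ids=cohort.probe_ids)
    per_delta = pd.DataFrame({
        "delta": delta_grid,
        "cv_accuracy": 1.0 - cv_err,
        "cv_se": cv_se,
        "n_surviving": [
            int(((np.abs(nsc_fit(X, y, d, feature_ids=cohort.probe_ids).dik) > 0)
                 .any(axis=0)).sum()) for d in delta_grid],
    })
    pred = held_out[chosen].reindex(cohort.sample_ids)
    confusion = pd.crosstab(pd.Series(y, index=cohort.sample_ids, name="true"),
                            pred.rename("predicted"), dropna=False)
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    per_class = {}
    total = confusion.to_numpy().sum()
    for c in classes:
        tp = confusion.loc[c, c]
        fn = confusion.loc[c].sum() - tp
        fp = confusion[c].sum() - tp
        tn = total - tp - fn - fp
        per_class[c] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
    report = SignatureReport(
        delta=delta, probes=model.surviving_features,
        cv_accuracy=float(1.0 - cv_err[chosen]), confusion=confusion,
        per_class=pd.DataFrame(per_class).T, per_delta=per_delta)
    kv_log("nsc_train", delta=delta, cv_accuracy=report.cv_accuracy,
           n_surviving=len(report.probes))
    return model, report


def cluster_signature(cohort: CohortMatrix):
    """Two-cluster grouping of signature probes by Kendall-tau correlation.

    Returns (cluster labels Series in {1, 2}, pairwise tau-b DataFrame).
    Average-linkage hierarchical clustering on distance 1 - tau; constant
    probes have undefined tau (NaN in the matrix) and enter at the maximum
    distance of 2.
    """
    if cohort.n_probes < 3:
        raise LncArrayError("cluster_signature needs >= 3 probes")
    X = cohort.values.to_numpy()
    p = X.shape[0]
    constant = np.array([np.unique(row).size == 1 for row in X])
    if constant.any():
        kv_log("cluster_signature_constant_probes", n=int(constant.sum()),
               handling="tau undefined, distance set to maximum")
    tau = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                tau[i, j] = tau[j, i] = np.nan
            else:
                tau[i, j] = tau[j, i] = kendalltau(X[i], X[j], variant="b").statistic
    dist = 1.0 - np.nan_to_num(tau, nan=-1.0)  # undefined -> max distance 2
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=2, criterion="maxclust")
    tau_df = pd.DataFrame(tau, index=cohort.probe_ids, columns=cohort.probe_ids)
    return pd.Series(labels, index=cohort.probe_ids, name="cluster"), tau_df
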