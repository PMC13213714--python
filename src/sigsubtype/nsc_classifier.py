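"""Nearest-shrunken-centroid (PAM-style) subtype classifier.

The classifier standardizes each class centroid's contrast with the
overall centroid by the pooled within-class dispersion (plus a fudge
constant s0, the median dispersion), soft-thresholds those contrasts by a
shrinkage amount Delta, and classifies new samples by the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k,

choosing the arg-min class. Shrinkage performs implicit feature
selection: a feature whose contrasts are fully thresholded for every
class carries no class information. Delta is chosen by stratified
cross-validation with the one-standard-error rule (the largest Delta
whose CV error is within one SE of the minimum — the most parsimonious
model that is statistically indistinguishable from the best).

The class-standardization factor is m_k = sqrt(1/n_k - 1/n), matching the
reference implementation of the method's canonical software; the
alternative sqrt(1/n_k + 1/n) published in the original article is
available via ``mk_variant="plus"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from sigsubtype.errors import SigsubtypeError, UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass
class ShrunkenCentroidModel:
    feature_names: list[str]
    class_labels: list[str]
    overall_centroid: np.ndarray  # (p,)
    class_centroids: np.ndarray  # (K, p)
    shrunken_centroids: np.ndarray  # (K, p)
    s: np.ndarray  # pooled within-class dispersions (p,)
    s0: float
    delta: float
    priors: np.ndarray  # (K,)
    mk: np.ndarray  # (K,)
    cv_curve: pd.DataFrame | None = None  # columns: delta, cv_error, cv_se, n_features
    metadata: dict = field(default_factory=dict)

    def n_surviving_features(self, delta: float | None = None) -> int:
        """Features with nonzero shrunken contrast in at least one class."""
        if delta is None:
            shrunk = self.shrunken_centroids
        else:
            shrunk = _shrink(self.class_centroids, self.overall_centroid, self.s, self.s0, self.mk, delta)
        contrast = shrunk - self.overall_centroid[None, :]
        return int((np.abs(contrast) > 0).any(axis=0).sum())

    def to_json(self, path) -> None:
        obj = {
            "feature_names": self.feature_names,
            "class_labels": self.class_labels,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "s": self.s.tolist(),
            "s0": self.s0,
            "delta": self.delta,
            "priors": self.priors.tolist(),
            "mk": self.mk.tolist(),
            "cv_curve": None if self.cv_curve is None else self.cv_curve.to_dict("list"),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ShrunkenCentroidModel":
        with open(path) as fh:
            obj = json.load(fh)
        cv = obj.pop("cv_curve")
        return cls(
            feature_names=obj["feature_names"],
            class_labels=obj["class_labels"],
            overall_centroid=np.array(obj["overall_centroid"]),
            class_centroids=np.array(obj["class_centroids"]),
            shrunken_centroids=np.array(obj["shrunken_centroids"]),
            s=np.array(obj["s"]),
            s0=obj["s0"],
            delta=obj["delta"],
            priors=np.array(obj["priors"]),
            mk=np.array(obj["mk"]),
            cv_curve=None if cv is None else pd.DataFrame(cv),
            metadata=obj.get("metadata", {}),
        )


def _shrink(centroids, overall, s, s0, mk, delta):
    """Soft-threshold standardized contrasts and rebuild centroids."""
    denom = mk[:, None] * (s + s0)[None, :]
    d = (centroids - overall[None, :]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    return overall[None, :] + denom * d_shrunk


def _fit_raw(X, y_idx, K, mk_variant):
    n, p = X.shape
    nk = np.bincount(y_idx, minlength=K).astype(float)
    overall = X.mean(axis=0)
    centroids = np.vstack([X[y_idx == k].mean(axis=0) for k in range(K)])
    # pooled within-class variance: sum_k sum_{i in k} (x - xbar_k)^2 / (n - K)
    ss = np.zeros(p)
    for k in range(K):
        ss += ((X[y_idx == k] - centroids[k][None, :]) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    if mk_variant == "minus":
        mk = np.sqrt(np.maximum(1.0 / nk - 1.0 / n, 0.0))
    elif mk_variant == "plus":
        mk = np.sqrt(1.0 / nk + 1.0 / n)
    else:
        raise SigsubtypeError(f"unknown mk_variant {mk_variant!r}")
    return overall, centroids, s, s0, mk, nk


def _discriminants(X, shrunken, s, s0, priors):
    dev = (X[:, None, :] - shrunken[None, :, :]) / (s + s0)[None, None, :]
    return (dev**2).sum(axis=2) - 2.0 * np.log(priors)[None, :]


def _stratified_folds(y_idx, n_folds, rng):
    """Per-class round-robin fold assignment after a seeded shuffle."""
    folds = np.empty(len(y_idx), dtype=int)
    for k in np.unique(y_idx):
        members = np.flatnonzero(y_idx == k)
        rng.shuffle(members)
        folds[members] = np.arange(len(members)) % n_folds
    return folds


def nsc_fit(
    X,
    y,
    delta_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    priors: str = "class",
    mk_variant: str = "minus",
    feature_names: list[str] | None = None,
) -> ShrunkenCentroidModel:
    """Fit a nearest-shrunken-centroid model with cross-validated shrinkage.

    ``X`` is samples x features (array or DataFrame; DataFrame column
    names become feature names), ``y`` the class labels. ``delta_grid``
    defaults to 30 points from 0 to the maximum absolute standardized
    contrast. ``priors="class"`` uses training proportions, ``"uniform"``
    equal priors.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise SigsubtypeError("features must be finite")
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    K = len(classes)
    if K < 2:
        raise SigsubtypeError("need at least 2 classes")
    nk = np.bincount(y_idx)
    if (nk < 2).any():
        raise SigsubtypeError("every class needs at least 2 samples")
    n = len(y)

    overall, centroids, s, s0, mk, nk_f = _fit_raw(X, y_idx, K, mk_variant)
    pri = nk_f / n if priors == "class" else np.full(K, 1.0 / K)

    if delta_grid is None:
        denom = mk[:, None] * (s + s0)[None, :]
        dmax = float(np.abs((centroids - overall[None, :]) / denom).max())
        delta_grid = np.linspace(0.0, dmax, 30)
    delta_grid = np.asarray(delta_grid, dtype=float)

    # stratified CV over the delta grid
    cv_folds_eff = min(cv_folds, int(nk.min()))
    if cv_folds_eff < 2:
        raise SigsubtypeError("cannot stratify: a class has too few samples for CV")
    if cv_folds_eff < cv_folds:
        logger.info("reducing CV folds to %d to keep every class in every fold", cv_folds_eff)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y_idx, cv_folds_eff, rng)
    fold_err = np.full((cv_folds_eff, len(delta_grid)), np.nan)
    for f in range(cv_folds_eff):
        tr, te = folds != f, folds == f
        if len(np.unique(y_idx[tr])) < K:
            raise SigsubtypeError(f"class vanished from CV training fold {f}")
        ov, cen, s_f, s0_f, mk_f, nk_tr = _fit_raw(X[tr], y_idx[tr], K, mk_variant)
        pri_f = nk_tr / tr.sum() if priors == "class" else np.full(K, 1.0 / K)
        for j, d in enumerate(delta_grid):
            shr = _shrink(cen, ov, s_f, s0_f, mk_f, d)
            pred = np.argmin(_discriminants(X[te], shr, s_f, s0_f, pri_f), axis=1)
            fold_err[f, j] = np.mean(pred != y_idx[te])
    cv_err = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(cv_folds_eff)

    # one-standard-error rule: largest delta within 1 SE of the minimum
    jmin = int(np.argmin(cv_err))
    threshold = cv_err[jmin] + cv_se[jmin]
    eligible = np.flatnonzero(cv_err <= threshold + 1e-12)
    jstar = int(eligible.max())
    delta = float(delta_grid[jstar])

    shrunken = _shrink(centroids, overall, s, s0, mk, delta)
    n_feat = [
        int(
            (np.abs(_shrink(centroids, overall, s, s0, mk, d) - overall[None, :]) > 0)
            .any(axis=0)
            .sum()
        )
        for d in delta_grid
    ]
    cv_curve = pd.DataFrame(
        {"delta": delta_grid, "cv_error": cv_err, "cv_se": cv_se, "n_features": n_feat}
    )
    return ShrunkenCentroidModel(
        feature_names=feature_names,
        class_labels=[str(c) for c in classes],
        overall_centroid=overall,
        class_centroids=centroids,
        shrunken_centroids=shrunken,
        s=s,
        s0=s0,
        delta=delta,
        priors=pri,
        mk=mk,
        cv_curve=cv_curve,
        metadata={
            "n": n,
            "cv_folds": cv_folds_eff,
            "seed": seed,
            "mk_variant": mk_variant,
            "priors": priors,
        },
    )


def nsc_predict(model: ShrunkenCentroidModel, X_new) -> pd.DataFrame:
    """Classify new samples; returns labels, discriminants and posteriors.

    DataFrame input is aligned to the model's features by name (missing
    features raise; extra features are ignored with a warning). Posterior
    probabilities are the softmax of -delta_k/2 (the Gaussian discriminant
    correspondence); ties break to the first class label.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X_new.columns]
        if missing:
            raise SigsubtypeError(f"prediction input lacks feature(s) {missing[:5]}")
        extra = [c for c in X_new.columns if c not in set(model.feature_names)]
        if extra:
            logger.warning("ignoring %d feature(s) unknown to the model", len(extra))
        index = X_new.index
        X = X_new[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X_new, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(model.feature_names):
            raise SigsubtypeError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}"
            )
        index = pd.RangeIndex(X.shape[0])
    if not np.all(np.isfinite(X)):
        raise SigsubtypeError("prediction input must be finite")
    disc = _discriminants(X, model.shrunken_centroids, model.s, model.s0, model.priors)
    # softmax of -delta/2, stabilized
    z = -0.5 * (disc - disc.min(axis=1, keepdims=True))
    post = np.exp(z)
    post /= post.sum(axis=1, keepdims=True)
    pred_idx = np.argmin(disc, axis=1)  # argmin ties -> first label
    out = pd.DataFrame(
        {"predicted": [model.class_labels[i] for i in pred_idx]}, index=index
    )
    for j, lab in enumerate(model.class_labels):
        out[f"score_{lab}"] = disc[:, j]
        out[f"posterior_{lab}"] = post[:, j]
    return out


def roc_auc(scores, truth) -> float:
    """Rank-based (Mann-Whitney) AUC of a continuous score against binary truth.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half (midranks).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = int(truth.sum())
    n_neg = int(len(truth) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
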