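"""Imagery-vs-rest classification: CSP+LDA, MDRM, gfMDRM, TS+LR.

All four methods consume the per-trial spatial covariance matrices
Sigma_i = X_i X_i^T / (T-1) of band-passed, channel-mean-centred epochs
X_i (C x T):

* ``csp_lda`` — Common Spatial Patterns spatial filters (first + last 4
  generalized eigenvectors, F = 8) with log-variance features and Fisher
  linear discriminant analysis;
* ``mdrm`` — minimum distance to the Riemannian (Fréchet) mean of each
  class under the affine-invariant metric;
* ``gfmdrm`` — MDRM after tangent-space Fisher (geodesic) filtering;
* ``tslr`` — projection to the tangent space at the training-set Fréchet
  mean followed by a regularized linear classifier.

``crossval_accuracy`` evaluates any of them under stratified k-fold
cross-validation (default k = 4) with every data-dependent step (CSP
filters, Fréchet means, geodesic filter, classifier weights) fit inside
the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import EpochSet
from .errors import ValidationError
from .riemann import (
    airm_distance,
    frechet_mean,
    geodesic_filter,
    regularize_spd,
    tangent_map,
    tangent_vectorize,
)

METHODS = ("csp_lda", "mdrm", "gfmdrm", "tslr")


def compute_covariances(epochs: EpochSet) -> np.ndarray:
    """Per-trial sample spatial covariance matrices, shape (n, C, C).

    Each epoch is channel-mean-centred; Sigma_i = X_i X_i^T / (T-1),
    regularized to strict positive definiteness when needed.
    """
    n, c, t = epochs.data.shape
    if t <= c:
        raise ValidationError(f"epoch length T={t} must exceed channel count C={c}")
    covs = np.empty((n, c, c))
    for i, x in enumerate(epochs.data):
        if not np.any(x):
            raise ValidationError(f"trial {i} is all zeros")
        xc = x - x.mean(axis=1, keepdims=True)
        covs[i] = regularize_spd(xc @ xc.T / (t - 1))
    return covs


def _class_split(labels: np.ndarray):
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 classes, got {list(classes)}")
    return classes


@dataclass
class CSPModel:
    """Common Spatial Patterns filters W (F x C) with their class order."""

    filters: np.ndarray
    classes: tuple
    eigenvalues: np.ndarray

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


def csp_fit(covs: np.ndarray, labels: np.ndarray, n_filters: int = 8) -> CSPModel:
    """Fit CSP from class-average covariances.

    Solves the generalized eigenproblem S1 w = lambda (S1 + S2) w on the
    class-mean covariances, sorts eigenvalues descending, and retains the
    first and last ``n_filters/2`` eigenvectors (the directions with the
    most extreme class variance ratios). Filter signs are fixed so each
    filter's largest-magnitude coefficient is positive (determinism).
    """
    classes = _class_split(labels)
    c = covs.shape[1]
    if n_filters > c or n_filters % 2:
        raise ValidationError(f"n_filters={n_filters} must be even and <= C={c}")
    s1 = covs[labels == classes[0]].mean(axis=0)
    s2 = covs[labels == classes[1]].mean(axis=0)
    evals, evecs = sla.eigh(s1, s1 + s2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    half = n_filters // 2
    keep = np.r_[np.arange(half), np.arange(c - half, c)]
    w = evecs[:, keep].T
    dom = np.argmax(np.abs(w), axis=1)
    signs = np.sign(w[np.arange(len(w)), dom])
    signs[signs == 0] = 1.0
    w = w * signs[:, None]
    return CSPModel(filters=w, classes=tuple(classes), eigenvalues=evals[keep])


def csp_features(model: CSPModel, epochs: EpochSet) -> np.ndarray:
    """Log of per-filter variance of W X_i; shape (n, F)."""
    feats = np.empty((epochs.n_epochs, model.n_filters))
    for i, x in enumerate(epochs.data):
        xc = x - x.mean(axis=1, keepdims=True)
        y = model.filters @ xc
        feats[i] = np.log(y.var(axis=1, ddof=1))
    return feats


def lda_fit(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Fisher LDA with equal priors (least-squares solver, ridge-stable)."""
    _class_split(labels)
    clf = LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5])
    clf.fit(features, labels)
    return clf


def lda_predict(model: LinearDiscriminantAnalysis, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


@dataclass
class MDRMModel:
    classes: tuple
    means: list


def mdrm_fit(covs: np.ndarray, labels: np.ndarray) -> MDRMModel:
    """Fréchet mean of each class's covariance matrices."""
    classes = _class_split(labels)
    means = [frechet_mean(covs[labels == cl]) for cl in classes]
    return MDRMModel(classes=tuple(classes), means=means)


def mdrm_predict(model: MDRMModel, covs: np.ndarray) -> np.ndarray:
    """Assign each matrix to the class of the nearest mean (AIRM distance).

    Ties go to the first class in the model's fixed class order.
    """
    out = []
    for s in covs:
        dists = [airm_distance(m, s) for m in model.means]
        out.append(model.classes[int(np.argmin(dists))])
    return np.array(out, dtype=object)


@dataclass
class GFMDRMModel:
    filter_model: object
    mdrm: MDRMModel


def gfmdrm_fit(covs: np.ndarray, labels: np.ndarray, d: int = 1) -> GFMDRMModel:
    """Geodesic (tangent-space Fisher) filtering followed by MDRM."""
    fmodel, filtered = geodesic_filter(list(covs), labels, d=d)
    mdrm = mdrm_fit(np.stack(filtered), labels)
    return GFMDRMModel(filter_model=fmodel, mdrm=mdrm)


def gfmdrm_predict(model: GFMDRMModel, covs: np.ndarray) -> np.ndarray:
    filtered = np.stack(model.filter_model.transform(list(covs)))
    return mdrm_predict(model.mdrm, filtered)


@dataclass
class TSLRModel:
    base: np.ndarray
    clf: object
    classes: tuple
    least_squares: bool = False


def _ts_features(base: np.ndarray, covs: np.ndarray) -> np.ndarray:
    return np.stack([tangent_vectorize(tangent_map(base, s)) for s in covs])


def tslr_fit(covs: np.ndarray, labels: np.ndarray, least_squares: bool = False) -> TSLRModel:
    """Tangent-space linear classification at the training Fréchet mean.

    The default linear model is L2-regularized logistic regression (the
    standard choice for tangent-space features); ``least_squares=True``
    switches to plain least-squares regression on +/-1 targets with a
    zero threshold for fidelity comparisons.
    """
    classes = _class_split(labels)
    for cl in classes:
        if np.sum(labels == cl) < 2:
            raise ValidationError(f"class {cl!r} has fewer than 2 training matrices")
    base = frechet_mean(covs)
    feats = _ts_features(base, covs)
    if least_squares:
        y = np.where(labels == classes[0], -1.0, 1.0)
        clf = LinearRegression().fit(feats, y)
    else:
        clf = LogisticRegression(C=1.0, max_iter=2000).fit(feats, labels.astype(str))
    return TSLRModel(base=base, clf=clf, classes=tuple(classes), least_squares=least_squares)


def tslr_predict(model: TSLRModel, covs: np.ndarray) -> np.ndarray:
    feats = _ts_features(model.base, covs)
    if model.least_squares:
        yhat = model.clf.predict(feats)
        return np.where(yhat < 0, model.classes[0], model.classes[1]).astype(object)
    return model.clf.predict(feats).astype(object)


@dataclass
class FoldResult:
    """Held-out performance of one cross-validation fold."""

    fold: int
    n_test: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_test

    def __post_init__(self):
        if not 0 <= self.n_correct <= self.n_test:
            raise ValidationError("n_correct must be within 0..n_test")


def _fit_predict(method: str, covs_tr, labels_tr, covs_te, epochs=None, tr=None, te=None):
    if method == "csp_lda":
        model = csp_fit(covs_tr, labels_tr)
        sub_tr = EpochSet(epochs.data[tr], epochs.labels[tr], epochs.fs, epochs.channel_labels)
        sub_te = EpochSet(epochs.data[te], epochs.labels[te], epochs.fs, epochs.channel_labels)
        lda = lda_fit(csp_features(model, sub_tr), labels_tr)
        return lda_predict(lda, csp_features(model, sub_te))
    if method == "mdrm":
        return mdrm_predict(mdrm_fit(covs_tr, labels_tr), covs_te)
    if method == "gfmdrm":
        return gfmdrm_predict(gfmdrm_fit(covs_tr, labels_tr), covs_te)
    if method == "tslr":
        return tslr_predict(tslr_fit(covs_tr, labels_tr), covs_te)
    raise ValidationError(f"unknown method {method!r}; choose from {list(METHODS)}")


def crossval_accuracy(
    epochs: EpochSet,
    method: str,
    k: int = 4,
    seed: int = 42,
    stratified: bool = True,
):
    """k-fold cross-validated accuracy of one method on one subject's epochs.

    Returns ``(fold_results, mean, min, max)`` where the mean is
    trial-weighted over folds. ``stratified=False`` uses chronological
    (unshuffled) folds instead of the default seeded stratified split.
    """
    labels = epochs.labels
    classes = _class_split(labels)
    for cl in classes:
        if np.sum(labels == cl) < k:
            raise ValidationError(f"class {cl!r} has fewer than k={k} trials")
    covs = compute_covariances(epochs)
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=False)
    results = []
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(labels)), labels.astype(str))):
        pred = _fit_predict(method, covs[tr], labels[tr], covs[te], epochs=epochs, tr=tr, te=te)
        results.append(FoldResult(fold=fold, n_test=len(te), n_correct=int(np.sum(pred == labels[te]))))
    n_total = sum(r.n_test for r in results)
    mean = sum(r.n_correct for r in results) / n_total
    accs = [r.accuracy for r in results]
    return results, mean, min(accs), max(accs)
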