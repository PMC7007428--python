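"""Two-class discriminant learners for preprocessed spectra.

PCA-LDA: the spectra matrix is reduced by PCA to ``k`` score dimensions, and
a linear discriminant classifier assigns each object to the class with the
smaller Mahalanobis distance to the class centroid under the pooled
within-class score covariance.  Class priors may enter the discriminant as
``-2 log(prior)`` (``priors="proportional"``); the default uses the observed
class frequencies, which is what makes the classifier track the majority
class when cohorts are imbalanced.

PLS-DA: NIPALS PLS1 regression of a +/-1-coded class response on the
spectra; objects are assigned by thresholding the predicted response (the
threshold is estimated, see :func:`fit_pls_da`).  Unlike PCA, the latent
variables are chosen to maximise covariance with the class coding, so far
fewer components carry the discriminant information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpectralDataset


class AxisMismatchError(ValueError):
    """Prediction input does not match the training wavenumber axis."""


def _check_two_classes(labels: np.ndarray, positive_class: str | None) -> tuple[str, str]:
    present = sorted(set(labels))
    if len(present) != 2:
        raise ValueError(f"need exactly two classes, got {present}")
    if positive_class is None:
        positive_class = present[1]
    if positive_class not in present:
        raise ValueError(f"positive class {positive_class!r} not among {present}")
    negative_class = next(c for c in present if c != positive_class)
    for c in present:
        if int((labels == c).sum()) < 2:
            raise ValueError(f"class {c} needs >= 2 objects")
    return negative_class, positive_class


# -- PCA -------------------------------------------------------------------

def fit_pca(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based PCA: returns (mean, loadings (p, k), eigenvalues, explained %)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > (s[0] * 1e-12 if s.size else 0)).sum())
    if not 1 <= k <= rank:
        raise ValueError(f"k={k} exceeds the data rank {rank}")
    eigs = s**2 / max(n - 1, 1)
    evr = 100.0 * eigs / eigs.sum()
    return mean, Vt[:k].T, eigs[:k], evr[:k]


@dataclass
class PcaLdaModel:
    wavenumbers: np.ndarray
    grand_mean: np.ndarray
    loadings: np.ndarray  # (p, k)
    eigenvalues: np.ndarray
    explained_variance: np.ndarray  # percent per PC
    n_pcs: int
    classes: tuple[str, str]  # (negative, positive)
    class_means_scores: dict[str, np.ndarray]
    pooled_covariance_scores: np.ndarray
    priors: dict[str, float]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.grand_mean) @ self.loadings


def fit_pca_lda(
    X: np.ndarray,
    labels: np.ndarray,
    k: int,
    wavenumbers: np.ndarray | None = None,
    positive_class: str | None = None,
    priors: str = "proportional",
) -> PcaLdaModel:
    """PCA reduction to ``k`` scores followed by a pooled-covariance LDA.

    ``priors``: "proportional" (observed class frequencies) or "equal".
    A near-singular pooled covariance is ridge-regularised with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    neg, pos = _check_two_classes(labels, positive_class)
    mean, loadings, eigs, evr = fit_pca(X, k)
    scores = (np.asarray(X, dtype=float) - mean) @ loadings
    n = scores.shape[0]

    class_means = {}
    pooled = np.zeros((k, k))
    counts = {}
    for c in (neg, pos):
        sc = scores[labels == c]
        counts[c] = sc.shape[0]
        class_means[c] = sc.mean(axis=0)
        dev = sc - class_means[c]
        pooled += dev.T @ dev
    pooled /= n - 2

    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-8 * np.trace(pooled) / k
        warnings.warn(
            f"pooled covariance near-singular (cond={cond:.2e}); "
            f"adding ridge {ridge:.2e}",
            stacklevel=2,
        )
        pooled = pooled + ridge * np.eye(k)

    if priors == "proportional":
        pri = {c: counts[c] / n for c in (neg, pos)}
    elif priors == "equal":
        pri = {neg: 0.5, pos: 0.5}
    else:
        raise ValueError("priors must be 'proportional' or 'equal'")

    return PcaLdaModel(
        wavenumbers=np.asarray(wavenumbers) if wavenumbers is not None else np.arange(X.shape[1], dtype=float),
        grand_mean=mean,
        loadings=loadings,
        eigenvalues=eigs,
        explained_variance=evr,
        n_pcs=k,
        classes=(neg, pos),
        class_means_scores=class_means,
        pooled_covariance_scores=pooled,
        priors=pri,
    )


def predict_pca_lda(
    model: PcaLdaModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assign to the class with the smaller prior-adjusted Mahalanobis
    distance; the signed score is g(neg) - g(pos) with
    g(c) = D2_Mahalanobis(c) - 2 log(prior_c), so larger means more
    positive-class-like.  Ties go to the positive class."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.grand_mean.size:
        raise AxisMismatchError(
            f"expected {model.grand_mean.size} columns, got {X.shape[1]}"
        )
    scores = model.transform(X)
    inv = np.linalg.inv(model.pooled_covariance_scores)
    neg, pos = model.classes
    g = {}
    for c in (neg, pos):
        dev = scores - model.class_means_scores[c]
        g[c] = np.einsum("ij,jk,ik->i", dev, inv, dev) - 2.0 * np.log(model.priors[c])
    signed = g[neg] - g[pos]
    labels = np.where(signed >= 0, pos, neg).astype(object)
    return labels, signed


# -- PLS-DA ----------------------------------------------------------------

@dataclass
class PlsDaModel:
    wavenumbers: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    regression_vector: np.ndarray  # (p,)
    n_lvs: int
    classes: tuple[str, str]  # (negative -> -1, positive -> +1)
    threshold: float
    x_explained_variance: np.ndarray  # percent per LV

    @property
    def coding(self) -> dict[str, float]:
        return {self.classes[0]: -1.0, self.classes[1]: +1.0}


def fit_pls_da(
    X: np.ndarray,
    labels: np.ndarray,
    n_lvs: int,
    wavenumbers: np.ndarray | None = None,
    positive_class: str | None = None,
    threshold: str | float = "midpoint",
) -> PlsDaModel:
    """NIPALS PLS1 on a +/-1 class coding.

    Each latent variable's weight vector is the (normalised) covariance
    between the deflated spectra and the deflated response; X is deflated by
    its loading projection, y by its fitted part.  The regression vector is
    ``W (P'W)^-1 q``.

    ``threshold`` places the dividing line on the predicted response:
    ``"midpoint"`` (default) estimates it as the midpoint of the two
    class-mean training responses, which keeps the error rates of the two
    classes consistent under class imbalance; a float fixes it explicitly
    (0 reproduces the naive coded-response cut).
    """
    labels = np.asarray(labels, dtype=object)
    neg, pos = _check_two_classes(labels, positive_class)
    y = np.where(labels == pos, 1.0, -1.0)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    if not 1 <= n_lvs <= min(n - 1, p):
        raise ValueError(f"n_lvs={n_lvs} out of range for {n}x{p} data")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    ss_x = float((E**2).sum())

    W = np.zeros((p, n_lvs))
    P = np.zeros((p, n_lvs))
    q = np.zeros(n_lvs)
    xvar = np.zeros(n_lvs)
    for a in range(n_lvs):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise ValueError(
                f"residual covariance vanished at component {a + 1}; "
                f"reduce n_lvs"
            )
        w /= nw
        t = E @ w
        tt = float(t @ t)
        p_a = E.T @ t / tt
        q_a = float(f @ t / tt)
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        xvar[a] = 100.0 * tt * float(p_a @ p_a) / ss_x

    B = W @ np.linalg.solve(P.T @ W, q)
    fitted = (X - x_mean) @ B + y_mean
    if threshold == "midpoint":
        thr = float((fitted[y > 0].mean() + fitted[y < 0].mean()) / 2.0)
    else:
        thr = float(threshold)
    return PlsDaModel(
        wavenumbers=np.asarray(wavenumbers) if wavenumbers is not None else np.arange(p, dtype=float),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=B,
        n_lvs=n_lvs,
        classes=(neg, pos),
        threshold=thr,
        x_explained_variance=xvar,
    )


def predict_pls_da(model: PlsDaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted response = centred spectrum . B + y_mean; the object is
    assigned to the positive class iff response >= threshold (ties positive)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.x_mean.size:
        raise AxisMismatchError(
            f"expected {model.x_mean.size} columns, got {X.shape[1]}"
        )
    response = (X - model.x_mean) @ model.regression_vector + model.y_mean
    neg, pos = model.classes
    labels = np.where(response >= model.threshold, pos, neg).astype(object)
    return labels, response


def model_to_dict(model: "PcaLdaModel | PlsDaModel") -> dict:
    """JSON-serialisable representation of a fitted model."""
    if isinstance(model, PcaLdaModel):
        return {
            "kind": "pcalda",
            "wavenumbers": model.wavenumbers.tolist(),
            "grand_mean": model.grand_mean.tolist(),
            "loadings": model.loadings.tolist(),
            "eigenvalues": model.eigenvalues.tolist(),
            "explained_variance": model.explained_variance.tolist(),
            "n_pcs": model.n_pcs,
            "classes": list(model.classes),
            "class_means_scores": {
                c: v.tolist() for c, v in model.class_means_scores.items()
            },
            "pooled_covariance_scores": model.pooled_covariance_scores.tolist(),
            "priors": dict(model.priors),
        }
    return {
        "kind": "plsda",
        "wavenumbers": model.wavenumbers.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "regression_vector": model.regression_vector.tolist(),
        "n_lvs": model.n_lvs,
        "classes": list(model.classes),
        "threshold": model.threshold,
        "x_explained_variance": model.x_explained_variance.tolist(),
    }


def model_from_dict(d: dict) -> "PcaLdaModel | PlsDaModel":
    kind = d.get("kind")
    if kind == "pcalda":
        return PcaLdaModel(
            wavenumbers=np.array(d["wavenumbers"]),
            grand_mean=np.array(d["grand_mean"]),
            loadings=np.array(d["loadings"]),
            eigenvalues=np.array(d["eigenvalues"]),
            explained_variance=np.array(d["explained_variance"]),
            n_pcs=int(d["n_pcs"]),
            classes=tuple(d["classes"]),
            class_means_scores={
                c: np.array(v) for c, v in d["class_means_scores"].items()
            },
            pooled_covariance_scores=np.array(d["pooled_covariance_scores"]),
            priors=dict(d["priors"]),
        )
    if kind == "plsda":
        return PlsDaModel(
            wavenumbers=np.array(d["wavenumbers"]),
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            weights=np.array(d["weights"]),
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            regression_vector=np.array(d["regression_vector"]),
            n_lvs=int(d["n_lvs"]),
            classes=tuple(d["classes"]),
            threshold=float(d["threshold"]),
            x_explained_variance=np.array(d["x_explained_variance"]),
        )
    raise ValueError(f"unknown model kind {kind!r}")


def pls_cv_threshold(
    X: np.ndarray,
    labels: np.ndarray,
    n_lvs: int,
    folds: list[np.ndarray],
    positive_class: str | None = None,
) -> float:
    """Decision threshold from cross-validated responses.

    Each fold's objects are predicted by a model fitted on the remaining
    folds; the threshold is the midpoint of the two classes' mean
    out-of-fold responses.  Unlike the fitted-response midpoint, this sees
    the shrinkage of unseen objects toward the majority class, so it keeps
    the two error rates consistent under class imbalance.
    """
    labels = np.asarray(labels, dtype=object)
    X = np.asarray(X, dtype=float)
    neg, pos = _check_two_classes(labels, positive_class)
    oof = np.full(len(labels), np.nan)
    for fold in folds:
        fold = np.asarray(fold)
        train_idx = np.setdiff1d(np.arange(len(labels)), fold)
        if len(set(labels[train_idx])) < 2 or len(fold) == 0:
            continue
        m = fit_pls_da(
            X[train_idx], labels[train_idx], n_lvs,
            positive_class=pos, threshold=0.0,
        )
        _, oof[fold] = predict_pls_da(m, X[fold])
    mask = ~np.isnan(oof)
    is_pos = labels == pos
    if not (mask & is_pos).any() or not (mask & ~is_pos).any():
        raise ValueError("cross-validated responses missing for one class")
    return float(
        (oof[mask & is_pos].mean() + oof[mask & ~is_pos].mean()) / 2.0
    )


# -- cross-validated component selection -----------------------------------

@dataclass
class FitReport:
    n_components_chosen: int
    cv_accuracy_by_k: pd.DataFrame  # columns: k, cv_accuracy, se
    model_kind: str
    training_residuals: np.ndarray | None = None


def select_components(
    X: np.ndarray,
    labels: np.ndarray,
    folds: list[np.ndarray],
    k_max: int,
    model_kind: str = "plsda",
    positive_class: str | None = None,
    **fit_kwargs,
) -> FitReport:
    """Venetian-blinds CV over component counts 1..k_max.

    Per k, each fold is predicted by a model fitted on the remaining folds;
    fold accuracies are averaged.  The chosen k is the smallest whose mean CV
    accuracy lies within one standard error of the best mean (1-SE rule).
    Folds whose training remainder lacks a class are skipped with a warning.
    """
    if model_kind not in ("pcalda", "plsda"):
        raise ValueError("model_kind must be 'pcalda' or 'plsda'")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    labels = np.asarray(labels, dtype=object)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    all_idx = np.arange(n)

    acc = np.full((k_max, len(folds)), np.nan)
    for j, fold in enumerate(folds):
        fold = np.asarray(fold)
        train_idx = np.setdiff1d(all_idx, fold)
        if len(set(labels[train_idx])) < 2 or len(fold) == 0:
            warnings.warn(f"fold {j} degenerate (single class); skipped", stacklevel=2)
            continue
        for k in range(1, k_max + 1):
            try:
                if model_kind == "pcalda":
                    m = fit_pca_lda(
                        X[train_idx], labels[train_idx], k,
                        positive_class=positive_class, **fit_kwargs,
                    )
                    pred, _ = predict_pca_lda(m, X[fold])
                else:
                    m = fit_pls_da(
                        X[train_idx], labels[train_idx], k,
                        positive_class=positive_class, **fit_kwargs,
                    )
                    pred, _ = predict_pls_da(m, X[fold])
            except ValueError:
                break  # k exceeded what this fold's training part supports
            acc[k - 1, j] = float(np.mean(pred == labels[fold]))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_acc = np.nanmean(acc, axis=1)
        n_eff = np.sum(~np.isnan(acc), axis=1)
        se = np.nanstd(acc, axis=1, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    if np.all(np.isnan(mean_acc)):
        raise ValueError("no usable folds")
    best = int(np.nanargmax(mean_acc))
    cut = mean_acc[best] - (se[best] if np.isfinite(se[best]) else 0.0)
    chosen = int(np.flatnonzero(mean_acc >= cut)[0]) + 1

    table = pd.DataFrame(
        {"k": np.arange(1, k_max + 1), "cv_accuracy": mean_acc, "se": se}
    )
    # training residuals of the final model on all data
    if model_kind == "pcalda":
        final = fit_pca_lda(X, labels, chosen, positive_class=positive_class, **fit_kwargs)
        recon = final.transform(X) @ final.loadings.T + final.grand_mean
        resid = np.sum((X - recon) ** 2, axis=1)
    else:
        final = fit_pls_da(X, labels, chosen, positive_class=positive_class, **fit_kwargs)
        T = (X - final.x_mean) @ final.weights @ np.linalg.inv(
            final.x_loadings.T @ final.weights
        )
        resid = np.sum((X - final.x_mean - T @ final.x_loadings.T) ** 2, axis=1)
    return FitReport(
        n_components_chosen=chosen,
        cv_accuracy_by_k=table,
        model_kind=model_kind,
        training_residuals=resid,
    )
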