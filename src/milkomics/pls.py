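"""Latent-variable core: NIPALS PLS2 / PLS-DA, PCA, VIP, cross-validation.

The models follow the usual estimator/results split: construct the model
from data, call :meth:`fit`, and read estimates off the returned results
object.  Matrices are centred internally (column means are stored so new
samples can be projected); any scaling is the caller's responsibility.

Sign convention: for every component the element of the X-loading vector
with the largest magnitude is made positive, which makes scores and
loadings platform-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_NIPALS_ITER = 500
NIPALS_TOL = 1e-12


def _as_matrix(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def dummy_matrix(labels) -> tuple[np.ndarray, list]:
    """One-hot class indicator matrix and the (sorted) class order."""
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    Y = np.zeros((labels.shape[0], len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, classes


@dataclass
class PLSResults:
    """Fitted PLS model.

    Attributes
    ----------
    x_weights_ : (p, A) array
        NIPALS weights W, unit-norm columns.
    x_scores_ : (n, A) array
        Scores T, mutually orthogonal columns.
    x_loadings_ : (p, A) array
        Loadings P.
    y_loadings_ : (m, A) array
        Y-loadings Q (regressions of Y on each score).
    r2x_, r2y_ : (A,) arrays
        Fraction of (centred) X- and Y-variance captured per component.
    """

    n_components: int
    x_weights_: np.ndarray
    x_scores_: np.ndarray
    x_loadings_: np.ndarray
    y_loadings_: np.ndarray
    r2x_: np.ndarray
    r2y_: np.ndarray
    ssy_: np.ndarray
    x_mean_: np.ndarray
    y_mean_: np.ndarray
    rotation_: np.ndarray
    feature_ids: list = field(default_factory=list)
    class_map: list = field(default_factory=list)
    class_centroids_: np.ndarray | None = None

    @property
    def cumulative_r2y_(self) -> float:
        return float(self.r2y_.sum())

    @property
    def cumulative_r2x_(self) -> float:
        return float(self.r2x_.sum())

    def transform(self, X) -> np.ndarray:
        """Project new samples into score space (uses the training means)."""
        Xc = _as_matrix(X) - self.x_mean_
        return Xc @ self.rotation_

    def vip(self) -> np.ndarray:
        """Variable importance in the projection.

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with
        unit-norm weight columns; mean squared VIP is 1 by construction.
        """
        ssy = self.ssy_
        total = ssy.sum()
        if total <= 0:
            raise ValueError("VIP undefined: model explains no Y-variance")
        p = self.x_weights_.shape[0]
        w2 = self.x_weights_ ** 2  # columns already unit norm
        return np.sqrt(p * (w2 @ ssy) / total)

    def predict(self, X) -> np.ndarray:
        """Discriminant prediction: nearest class centroid in score space.

        Score dimensions are weighted by the square root of the
        Y-variance each component explains, so noise-dominated trailing
        components do not drown the discriminant axis.
        """
        if not self.class_map:
            raise ValueError("predict requires a discriminant (PLS-DA) fit")
        scores = self.transform(X)
        total = self.ssy_.sum()
        w = np.sqrt(self.ssy_ / total) if total > 0 else np.ones_like(self.ssy_)
        diff = (scores[:, None, :] - self.class_centroids_[None, :, :]) * w
        d = (diff ** 2).sum(-1)
        return np.asarray(self.class_map, dtype=object)[np.argmin(d, axis=1)]

    def summary(self) -> str:
        lines = [
            f"PLS{'-DA' if self.class_map else '2'} model, "
            f"{self.n_components} component(s)",
            f"{'comp':>4} {'R2X':>8} {'R2Y':>8}",
        ]
        for a in range(self.n_components):
            lines.append(f"{a + 1:>4} {self.r2x_[a]:>8.4f} {self.r2y_[a]:>8.4f}")
        lines.append(f"cumulative R2X {self.cumulative_r2x_:.4f}, "
                     f"R2Y {self.cumulative_r2y_:.4f}")
        return "\n".join(lines)


class PLS:
    """NIPALS PLS2 with X-deflation.

    Parameters
    ----------
    X : (n, p) array-like
        Predictor matrix (pre-scaled; centred internally).
    Y : (n, m) array-like
        Response matrix (centred internally).
    n_components : int
        Number of latent components, at most ``min(n - 1, p)``.
    """

    def __init__(self, X, Y, n_components: int):
        self.X = _as_matrix(X)
        self.Y = _as_matrix(Y)
        self.n_components = int(n_components)
        n, p = self.X.shape
        if self.Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        if n < 3:
            raise ValueError("PLS needs at least 3 samples")
        if self.n_components < 1 or self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
            )

    def fit(self) -> PLSResults:
        X = self.X
        Y = self.Y
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xr = X - x_mean
        Yc = Y - y_mean
        ssx_tot = float((Xr ** 2).sum())
        ssy_tot = float((Yc ** 2).sum())
        if ssx_tot <= 0:
            raise ValueError("zero-variance X")
        n, p = Xr.shape
        A = self.n_components
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        Q = np.zeros((Yc.shape[1], A))
        ssy = np.zeros(A)
        r2x = np.zeros(A)
        fitted = 0
        for a in range(A):
            w, t = self._nipals_component(Xr, Yc)
            if w is None:
                warnings.warn(
                    f"PLS: residual exhausted after {a} component(s)")
                break
            tt = float(t @ t)
            pvec = Xr.T @ t / tt
            q = Yc.T @ t / tt
            # deterministic sign: largest-|loading| element positive
            j = int(np.argmax(np.abs(pvec)))
            if pvec[j] < 0:
                w, t, pvec, q = -w, -t, -pvec, -q
            W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pvec, q
            ssy[a] = tt * float(q @ q)
            r2x[a] = tt * float(pvec @ pvec) / ssx_tot
            Xr = Xr - np.outer(t, pvec)
            fitted = a + 1
        W, T, P, Q = W[:, :fitted], T[:, :fitted], P[:, :fitted], Q[:, :fitted]
        ssy, r2x = ssy[:fitted], r2x[:fitted]
        rotation = W @ np.linalg.pinv(P.T @ W)
        r2y = ssy / ssy_tot if ssy_tot > 0 else np.zeros(fitted)
        return PLSResults(
            n_components=fitted,
            x_weights_=W,
            x_scores_=T,
            x_loadings_=P,
            y_loadings_=Q,
            r2x_=r2x,
            r2y_=r2y,
            ssy_=ssy,
            x_mean_=x_mean,
            y_mean_=y_mean,
            rotation_=rotation,
        )

    @staticmethod
    def _nipals_component(Xr, Yc):
        """One NIPALS component on the residual matrices; returns (w, t)
        or (None, None) when the residual carries no usable variance."""
        # start from the Y column with the largest variance
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
        if not (u ** 2).sum() > 0:
            u = Xr[:, int(np.argmax(Xr.var(axis=0)))].copy()
        w_old = None
        w = t = None
        for _ in range(MAX_NIPALS_ITER):
            w = Xr.T @ u
            nw = float(np.linalg.norm(w))
            if nw <= 1e-300:
                return None, None
            w = w / nw
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 1e-300:
                return None, None
            q = Yc.T @ t / tt
            qq = float(q @ q)
            if qq <= 1e-300:
                break  # Y orthogonal to X residual: accept current direction
            u = Yc @ q / qq
            if w_old is not None and np.linalg.norm(w - w_old) < NIPALS_TOL:
                break
            w_old = w
        else:
            warnings.warn("NIPALS did not converge; using best iterate")
        return w, t


class PLSDA(PLS):
    """PLS discriminant analysis: PLS2 against a centred class indicator
    matrix; class prediction by nearest centroid in score space."""

    def __init__(self, X, labels, n_components: int):
        labels = np.asarray(labels)
        Y, classes = dummy_matrix(labels)
        if len(classes) < 2:
            raise ValueError("PLS-DA requires at least 2 classes")
        counts = [(labels == c).sum() for c in classes]
        if min(counts) < 2:
            raise ValueError("PLS-DA requires >=2 samples per class")
        super().__init__(X, Y, n_components)
        self.labels = labels
        self.classes = classes

    def fit(self) -> PLSResults:
        res = super().fit()
        res.class_map = list(self.classes)
        res.class_centroids_ = np.vstack([
            res.x_scores_[self.labels == c].mean(axis=0) for c in self.classes
        ])
        return res


# ------------------------------------------------------------- PCA


@dataclass
class PCAResults:
    n_components: int
    scores_: np.ndarray
    loadings_: np.ndarray  # (p, A), orthonormal columns
    explained_variance_ratio_: np.ndarray
    singular_values_: np.ndarray
    mean_: np.ndarray

    def transform(self, X) -> np.ndarray:
        return (_as_matrix(X) - self.mean_) @ self.loadings_


def fit_pca(X, n_components: int) -> PCAResults:
    """SVD-based PCA (mean-centred); variance fractions are squared
    singular-value shares of the total."""
    X = _as_matrix(X)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"fit_pca: n_components={n_components} exceeds rank {rank}; truncated"
        )
        n_components = rank
    total = float((s ** 2).sum())
    # deterministic sign per component
    V = Vt.T[:, :n_components].copy()
    Uc = U[:, :n_components].copy()
    for a in range(n_components):
        j = int(np.argmax(np.abs(V[:, a])))
        if V[j, a] < 0:
            V[:, a] *= -1
            Uc[:, a] *= -1
    scores = Uc * s[:n_components]
    evr = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAResults(n_components, scores, V, evr, s[:n_components], mean)


# --------------------------------------------------- cross-validation


@dataclass
class CVResult:
    error_rate: float
    predictions: pd.Series  # indexed by fold/sample position
    n_evaluated: int
    n_skipped: int


def loo_cv(X, labels, fit_predict, groups=None) -> CVResult:
    """Leave-one-out cross-validation of an arbitrary classifier chain.

    ``fit_predict(X_train, y_train, X_test)`` must refit the full chain
    (scaling statistics included, if any) on the training fold and return
    the predicted label(s) for ``X_test``.  Folds whose training labels
    collapse to a single class are skipped with a warning and removed
    from the denominator.

    When ``groups`` is given (e.g. the mother of each milk sample), all
    rows sharing a group are held out together — required when rows are
    duplicated or correlated within a group (twins share their mother's
    milk), otherwise the retained copy leaks the fold's profile into
    training.  The error is still counted per row.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 4:
        raise ValueError("loo_cv needs at least 4 samples")
    if groups is None:
        folds = [np.array([i]) for i in range(n)]
    else:
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("one group per sample required")
        folds = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    preds = {}
    skipped = 0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if len(np.unique(labels[mask])) < 2:
            warnings.warn(
                f"loo_cv: fold {fold.tolist()} left a single training class; "
                "skipped")
            skipped += len(fold)
            continue
        pred = np.asarray(fit_predict(X[mask], labels[mask], X[fold])).ravel()
        for j, i in enumerate(fold):
            preds[int(i)] = pred[j] if pred.size > 1 else pred[0]
    if not preds:
        raise ValueError("loo_cv: every fold was degenerate")
    errors = sum(1 for i, p in preds.items() if p != labels[i])
    return CVResult(
        error_rate=errors / len(preds),
        predictions=pd.Series(preds),
        n_evaluated=len(preds),
        n_skipped=skipped,
    )
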