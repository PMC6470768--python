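"""AoV-PLS + Fisher LDA discriminant workflow with VIP selection.

The feature matrix is first decomposed, feature by feature, into grand
mean + group effect + residual (one-way ANOVA with respect to the growth
factor).  PLS is then fitted on the factor-associated matrix
(effect + residual) against the centred group indicator; a Fisher linear
discriminant on the first few PLS score columns gives the canonical
axis, whose leave-one-out misclassification rate measures the
significance of the growth factor.  Features with VIP >= 1.5 on the PLS
model are retained as discriminant candidates.

In this single-factor design effect + residual equals the centred
matrix, so the PLS stage coincides with PLS-DA on centred data; the
decomposition is kept explicit so designs with nuisance factors (week,
secretor status) can sweep them out before the PLS stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLSDA, PLSResults, _as_matrix, loo_cv

VIP_THRESHOLD_DEFAULT = 1.5
LDA_RIDGE = 1e-8


def anova_decompose(X, factor):
    """One-way ANOVA decomposition of each feature.

    x_ij = grand_mean_j + (group_mean - grand_mean)_j + residual_ij.

    Returns ``(grand_mean, effect_matrix, residual_matrix)``; the three
    pieces reconstruct X exactly and the per-feature sums of squares are
    additive (SS_total = SS_effect + SS_residual).
    """
    X = _as_matrix(X)
    factor = np.asarray(factor)
    levels = pd.unique(factor)
    if len(levels) < 2:
        raise ValueError("anova_decompose needs >=2 groups")
    for g in levels:
        if (factor == g).sum() < 2:
            raise ValueError(f"group {g!r} has a single sample")
    grand = X.mean(axis=0)
    effect = np.zeros_like(X)
    for g in levels:
        mask = factor == g
        effect[mask] = X[mask].mean(axis=0) - grand
    residual = X - grand - effect
    return grand, effect, residual


def fisher_lda(scores, labels, ridge: float = LDA_RIDGE):
    """Fisher's linear discriminant on (PLS) score space, two classes.

    direction = S_within^-1 (mu_1 - mu_0), threshold = midpoint of the
    projected class means (equal priors).  Returns
    ``(direction, threshold, canonical_values, classes)`` where classes
    are sorted and the direction is oriented so the second class
    projects above the threshold.
    """
    S = _as_matrix(scores)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError("fisher_lda supports exactly 2 classes")
    m0 = S[labels == classes[0]].mean(axis=0)
    m1 = S[labels == classes[1]].mean(axis=0)
    Sw = np.zeros((S.shape[1], S.shape[1]))
    for c, m in ((classes[0], m0), (classes[1], m1)):
        D = S[labels == c] - m
        Sw += D.T @ D
    try:
        direction = np.linalg.solve(Sw, m1 - m0)
    except np.linalg.LinAlgError:
        warnings.warn("fisher_lda: singular within-class scatter; ridge added")
        direction = np.linalg.solve(Sw + ridge * np.eye(Sw.shape[0]), m1 - m0)
    norm = float(np.linalg.norm(direction))
    if norm > 0:
        direction = direction / norm
    proj0, proj1 = float(m0 @ direction), float(m1 @ direction)
    if proj1 < proj0:
        direction = -direction
        proj0, proj1 = -proj0, -proj1
    threshold = (proj0 + proj1) / 2.0
    return direction, threshold, S @ direction, classes


def _chain_fit_predict(n_pls: int, n_lda: int):
    """LOO fold worker: refit PLS on the centred training fold, LDA on
    its first ``n_lda`` score columns, classify the held-out sample."""

    def fit_predict(X_tr, y_tr, X_te):
        A = min(n_pls, X_tr.shape[0] - 1, X_tr.shape[1])
        model = PLSDA(X_tr, y_tr, A).fit()
        k = min(n_lda, model.n_components)
        direction, threshold, _, classes = fisher_lda(
            model.x_scores_[:, :k], y_tr)
        vals = model.transform(X_te)[:, :k] @ direction
        return np.where(vals > threshold, classes[1], classes[0])

    return fit_predict


def cv_error_chain(X, factor, n_components: int, lda_components: int,
                   groups=None):
    """Leave-one-out error of the whole decompose->PLS->LDA chain.

    Each fold re-centres (the decomposition's grand mean is the training
    fold's column mean), refits the PLS model and the LDA axis, and
    classifies the held-out sample against the refitted threshold.
    ``groups`` holds out correlated rows together (see
    :func:`milkomics.pls.loo_cv`).
    """
    return loo_cv(X, factor, _chain_fit_predict(n_components, lda_components),
                  groups=groups)


def select_vip_features(vip, feature_ids=None,
                        threshold: float = VIP_THRESHOLD_DEFAULT) -> list:
    """Feature ids with VIP >= threshold, sorted by VIP descending
    (ties broken by feature id)."""
    vip = np.asarray(vip, dtype=float)
    if feature_ids is None:
        feature_ids = [str(j) for j in range(vip.shape[0])]
    pairs = [(fid, v) for fid, v in zip(feature_ids, vip) if v >= threshold]
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return [fid for fid, _ in pairs]


@dataclass
class AovPlsLdaResults:
    """Fitted AoV-PLS/LDA discriminant model."""

    grand_mean: np.ndarray
    effect_matrix: np.ndarray
    residual_matrix: np.ndarray
    pls: PLSResults
    lda_direction: np.ndarray
    lda_threshold: float
    canonical_values: np.ndarray
    classes: list
    n_lda_components: int
    cv_error: float | None
    cv_errors_by_components: dict = field(default_factory=dict)
    vip_: np.ndarray | None = None
    selected_features: list = field(default_factory=list)
    vip_threshold: float = VIP_THRESHOLD_DEFAULT
    feature_ids: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "AoV-PLS / Fisher LDA discriminant model",
            f"  PLS components fitted : {self.pls.n_components}",
            f"  LDA score components  : {self.n_lda_components}",
            f"  cumulative R2X / R2Y  : {self.pls.cumulative_r2x_:.4f} / "
            f"{self.pls.cumulative_r2y_:.4f}",
        ]
        if self.cv_error is not None:
            lines.append(f"  LOO CV error          : {100 * self.cv_error:.2f}%")
        lines.append(
            f"  VIP >= {self.vip_threshold:g} features   : "
            f"{len(self.selected_features)} of {len(self.feature_ids)}"
        )
        return "\n".join(lines)


class AovPlsLda:
    """Growth-group discriminant model for one omics block.

    Parameters
    ----------
    X : (n, p) array-like
        Scaled feature matrix (observations x features).
    labels : array-like
        Two-level growth factor ("faster"/"slower").
    n_components : int
        PLS components to fit (LDA may consume fewer, see
        ``lda_components``).
    lda_components : int or None
        Number of leading PLS score columns the LDA consumes.  ``None``
        (default) selects it by minimising the leave-one-out error over
        1..min(5, n_components).
    feature_ids : sequence, optional
        Names used in VIP selection output.
    vip_threshold : float
        VIP cutoff for the discriminant feature list (default 1.5).
    """

    def __init__(self, X, labels, n_components: int = 5,
                 lda_components: int | None = None, feature_ids=None,
                 vip_threshold: float = VIP_THRESHOLD_DEFAULT):
        self.X = _as_matrix(X)
        self.labels = np.asarray(labels)
        n, p = self.X.shape
        self.n_components = int(min(n_components, n - 1, p))
        self.lda_components = lda_components
        self.feature_ids = (list(feature_ids) if feature_ids is not None
                            else [str(j) for j in range(p)])
        self.vip_threshold = float(vip_threshold)

    def fit(self, cv: bool = True) -> AovPlsLdaResults:
        grand, effect, residual = anova_decompose(self.X, self.labels)
        Xa = effect + residual  # factor-associated matrix (centred X, one-way)
        pls = PLSDA(Xa, self.labels, self.n_components).fit()

        cv_by_a: dict[int, float] = {}
        if self.lda_components is None:
            candidates = range(1, min(5, pls.n_components) + 1)
            for a in candidates:
                cv_by_a[a] = cv_error_chain(
                    self.X, self.labels, self.n_components, a).error_rate
            # smallest error; ties favour the simpler model
            n_lda = min(cv_by_a, key=lambda a: (cv_by_a[a], a))
        else:
            n_lda = int(min(self.lda_components, pls.n_components))

        direction, threshold, canonical, classes = fisher_lda(
            pls.x_scores_[:, :n_lda], self.labels)

        cv_error = None
        if cv:
            if n_lda in cv_by_a:
                cv_error = cv_by_a[n_lda]
            else:
                cv_error = cv_error_chain(
                    self.X, self.labels, self.n_components, n_lda).error_rate

        vip = pls.vip()
        selected = select_vip_features(vip, self.feature_ids, self.vip_threshold)
        return AovPlsLdaResults(
            grand_mean=grand,
            effect_matrix=effect,
            residual_matrix=residual,
            pls=pls,
            lda_direction=direction,
            lda_threshold=threshold,
            canonical_values=canonical,
            classes=classes,
            n_lda_components=n_lda,
            cv_error=cv_error,
            cv_errors_by_components=cv_by_a,
            vip_=vip,
            selected_features=selected,
            vip_threshold=self.vip_threshold,
            feature_ids=self.feature_ids,
        )
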