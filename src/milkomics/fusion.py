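"""Multi-block fusion: superblock assembly, unfold PCA, MB-PLS.

The scaled blocks (log-Pareto for metabolome/lipidome, autoscaled for
glycome/fatty acids/free amino acids, glycome secretor-centred) are
concatenated with per-block weights (default 1/sqrt(p_b), so no block
dominates by width).  The superblock feeds an unsupervised unfold PCA
and a supervised MB-PLS against the growth factor.  MB-PLS is fitted
block-wise with super-score deflation: per component each block
contributes a block score t_b, and the super score is
t = sum_b omega_b t_b with sum_b omega_b^2 = 1; omega_b^2 is the block's
importance on that component.  This variant coincides with ordinary PLS
on the weighted concatenated matrix, which the test suite verifies
against an independent route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PCAResults, _as_matrix, dummy_matrix, fit_pca
from .pls import MAX_NIPALS_ITER, NIPALS_TOL


@dataclass
class SuperBlock:
    """Weighted horizontal concatenation of scaled omics blocks."""

    block_names: list
    matrix: pd.DataFrame  # n x sum(p_b), weights already applied
    ranges: dict  # block -> slice into the columns
    weights: dict  # block -> applied scalar weight

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def block_view(self, name: str) -> pd.DataFrame:
        return self.matrix.iloc[:, self.ranges[name]]


def default_block_weights(blocks: dict) -> dict:
    return {name: 1.0 / np.sqrt(df.shape[1]) for name, df in blocks.items()}


def assemble_superblock(blocks: dict, weights: dict | None = None) -> SuperBlock:
    """Concatenate pre-scaled blocks with per-block weights.

    ``blocks`` maps block name -> samples x features DataFrame, all with
    identical row index (sample misalignment raises).  Column names are
    prefixed ``block::feature`` so provenance survives concatenation.
    """
    if not blocks:
        raise ValueError("assemble_superblock needs at least one block")
    names = list(blocks)
    frames = {n: pd.DataFrame(df) for n, df in blocks.items()}
    index = frames[names[0]].index
    for n in names[1:]:
        if not frames[n].index.equals(index):
            raise ValueError(f"sample misalignment between {names[0]!r} and {n!r}")
    if weights is None:
        weights = default_block_weights(frames)
    parts = []
    ranges = {}
    start = 0
    for n in names:
        df = frames[n]
        w = float(weights[n])
        if w <= 0:
            raise ValueError(f"block weight for {n!r} must be > 0")
        part = df * w
        part.columns = [f"{n}::{c}" for c in df.columns]
        parts.append(part)
        ranges[n] = slice(start, start + df.shape[1])
        start += df.shape[1]
    return SuperBlock(names, pd.concat(parts, axis=1),
                      ranges, {n: float(weights[n]) for n in names})


# ---------------------------------------------------------------- UPCA


def upca(data, n_components: int = 4) -> PCAResults:
    """Unfold PCA.

    ``data`` is either a 2-way samples x features matrix (used as-is;
    the analysis discards the lactation-week factor and works on a
    single week or a superblock) or a 3-way (samples, weeks, features)
    array which is mode-1 unfolded to samples x (weeks*features).  The
    unfolded matrix is mean-centred and decomposed by SVD.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 3:
        if not np.isfinite(arr).all():
            raise ValueError("upca: inconsistent week coverage "
                             "(non-finite cells in the tensor)")
        arr = arr.reshape(arr.shape[0], -1)
    elif arr.ndim != 2:
        raise ValueError("upca expects a 2-way or 3-way array")
    return fit_pca(arr, n_components)


# -------------------------------------------------------------- MB-PLS


@dataclass
class MBPLSResults:
    """Fitted multi-block PLS model.

    ``super_scores_`` are the common-component sample scores;
    ``block_scores_[b]`` the per-block scores; ``block_importance_``
    (blocks x components) the squared super-weights, which sum to 1 over
    blocks for every component.
    """

    block_names: list
    n_components: int
    super_scores_: np.ndarray  # (n, A)
    block_scores_: dict  # name -> (n, A)
    block_weights_: dict  # name -> (p_b, A) unit-norm block weight vectors
    block_loadings_: dict  # name -> (p_b, A)
    super_weights_: np.ndarray  # (B, A) omega, columns unit norm
    block_importance_: np.ndarray  # (B, A) = omega**2
    y_loadings_: np.ndarray
    r2y_: np.ndarray
    ssy_: np.ndarray
    r2x_block_: pd.DataFrame  # per-block variance explained per component
    x_means_: dict
    classes: list = field(default_factory=list)
    class_centroids_: np.ndarray | None = None
    feature_ids: dict = field(default_factory=dict)
    applied_weights: dict = field(default_factory=dict)

    def importance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.block_importance_,
            index=self.block_names,
            columns=[f"comp{a + 1}" for a in range(self.n_components)],
        )

    def transform(self, blocks: dict) -> np.ndarray:
        """Project new samples (dict of block matrices) to super scores."""
        scores = np.zeros((len(next(iter(blocks.values()))), self.n_components))
        Xc = {
            b: (np.asarray(blocks[b], dtype=float) * self.applied_weights[b]
                - self.x_means_[b])
            for b in self.block_names
        }
        for a in range(self.n_components):
            t = np.zeros(scores.shape[0])
            for i, b in enumerate(self.block_names):
                tb = Xc[b] @ self.block_weights_[b][:, a]
                t += self.super_weights_[i, a] * tb
            scores[:, a] = t
            for b in self.block_names:
                pb = self.block_loadings_[b][:, a]
                Xc[b] = Xc[b] - np.outer(t, pb)
        return scores

    def predict(self, blocks: dict) -> np.ndarray:
        """Nearest class centroid in super-score space, with components
        weighted by the Y-variance they explain (as in PLS-DA)."""
        if not self.classes:
            raise ValueError("predict requires a labelled (discriminant) fit")
        scores = self.transform(blocks)
        total = self.ssy_.sum()
        w = np.sqrt(self.ssy_ / total) if total > 0 else np.ones_like(self.ssy_)
        diff = (scores[:, None, :] - self.class_centroids_[None, :, :]) * w
        d = (diff ** 2).sum(-1)
        return np.asarray(self.classes, dtype=object)[np.argmin(d, axis=1)]

    def summary(self) -> str:
        lines = [
            f"MB-PLS model: {len(self.block_names)} blocks, "
            f"{self.n_components} component(s)",
            f"cumulative R2Y {float(self.r2y_.sum()):.4f}",
            "block importance per component:",
        ]
        lines.append(self.importance_frame().round(4).to_string())
        return "\n".join(lines)


class MBPLS:
    """Multi-block PLS discriminant model.

    Parameters
    ----------
    blocks : dict
        Block name -> samples x features DataFrame (pre-scaled, aligned
        rows).
    labels : array-like
        Two-level class factor; the response is the centred class
        indicator matrix.
    n_components : int
        Number of common components.
    block_weights : dict or None
        Scalar weight per block applied before fitting (default
        1/sqrt(p_b)).
    positive_class : str or None
        Orient each component so this class's mean super score is
        positive (default: second class in sorted order).
    """

    def __init__(self, blocks: dict, labels, n_components: int = 2,
                 block_weights: dict | None = None,
                 positive_class: str | None = None):
        if len(blocks) < 1:
            raise ValueError("MBPLS needs at least one block")
        self.blocks = {n: pd.DataFrame(df) for n, df in blocks.items()}
        index = next(iter(self.blocks.values())).index
        for n, df in self.blocks.items():
            if not df.index.equals(index):
                raise ValueError(f"sample misalignment in block {n!r}")
        self.labels = np.asarray(labels)
        self.n_components = int(n_components)
        self.block_weights = (default_block_weights(self.blocks)
                              if block_weights is None else dict(block_weights))
        self.positive_class = positive_class

    def fit(self) -> MBPLSResults:
        names = list(self.blocks)
        Y, classes = dummy_matrix(self.labels)
        if len(classes) < 2:
            raise ValueError("MBPLS requires 2 classes")
        Yc = Y - Y.mean(axis=0)
        ssy_tot = float((Yc ** 2).sum())
        Xw = {}
        x_means = {}
        ssx = {}
        for b in names:
            arr = self.blocks[b].to_numpy(dtype=float) * self.block_weights[b]
            x_means[b] = arr.mean(axis=0)
            Xw[b] = arr - x_means[b]
            ssx[b] = float((Xw[b] ** 2).sum())
        n = Yc.shape[0]
        A = self.n_components
        B = len(names)
        T = np.zeros((n, A))
        Tb = {b: np.zeros((n, A)) for b in names}
        Wb = {b: np.zeros((self.blocks[b].shape[1], A)) for b in names}
        Pb = {b: np.zeros((self.blocks[b].shape[1], A)) for b in names}
        Omega = np.zeros((B, A))
        Q = np.zeros((Yc.shape[1], A))
        ssy = np.zeros(A)
        r2x_block = np.zeros((B, A))
        pos = self.positive_class or classes[-1]
        pos_mask = self.labels == pos
        for a in range(A):
            u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
            w_global_old = None
            for _ in range(MAX_NIPALS_ITER):
                v = {b: Xw[b].T @ u for b in names}
                g = float(np.sqrt(sum(float(vb @ vb) for vb in v.values())))
                if g <= 1e-300:
                    raise ValueError("MBPLS: residual carries no variance")
                wb = {b: v[b] / g for b in names}  # global unit norm
                omega = np.array([float(np.linalg.norm(wb[b])) for b in names])
                t = np.zeros(n)
                tb = {}
                for i, b in enumerate(names):
                    if omega[i] > 0:
                        tb[b] = Xw[b] @ (wb[b] / omega[i])
                    else:
                        tb[b] = np.zeros(n)
                    t += omega[i] * tb[b]
                tt = float(t @ t)
                if tt <= 1e-300:
                    raise ValueError("MBPLS: degenerate super score")
                q = Yc.T @ t / tt
                qq = float(q @ q)
                if qq <= 1e-300:
                    break
                u_new = Yc @ q / qq
                w_global = np.concatenate([wb[b] for b in names])
                if (w_global_old is not None
                        and np.linalg.norm(w_global - w_global_old) < NIPALS_TOL):
                    u = u_new
                    break
                w_global_old = w_global
                u = u_new
            else:
                warnings.warn("MBPLS NIPALS did not converge; using best iterate")
            # orientation: positive class scores positive on every component
            if pos_mask.any() and t[pos_mask].mean() < t[~pos_mask].mean():
                t = -t
                q = -q
                for b in names:
                    wb[b] = -wb[b]
                    tb[b] = -tb[b]
            tt = float(t @ t)
            T[:, a] = t
            Q[:, a] = q
            ssy[a] = tt * float(q @ q)
            for i, b in enumerate(names):
                Omega[i, a] = float(np.linalg.norm(wb[b]))
                Tb[b][:, a] = tb[b]
                Wb[b][:, a] = (wb[b] / Omega[i, a]) if Omega[i, a] > 0 else wb[b]
                pb = Xw[b].T @ t / tt
                Pb[b][:, a] = pb
                r2x_block[i, a] = (tt * float(pb @ pb) / ssx[b]
                                   if ssx[b] > 0 else 0.0)
                Xw[b] = Xw[b] - np.outer(t, pb)
        centroids = np.vstack([T[self.labels == c].mean(axis=0) for c in classes])
        return MBPLSResults(
            block_names=names,
            n_components=A,
            super_scores_=T,
            block_scores_=Tb,
            block_weights_=Wb,
            block_loadings_=Pb,
            super_weights_=Omega,
            block_importance_=Omega ** 2,
            y_loadings_=Q,
            r2y_=ssy / ssy_tot if ssy_tot > 0 else np.zeros(A),
            ssy_=ssy,
            r2x_block_=pd.DataFrame(
                r2x_block, index=names,
                columns=[f"comp{a + 1}" for a in range(A)]),
            x_means_=x_means,
            classes=classes,
            class_centroids_=centroids,
            feature_ids={b: list(self.blocks[b].columns) for b in names},
            applied_weights=dict(self.block_weights),
        )


def select_by_loadings(result: MBPLSResults, components=(1, 2),
                       k: int | None = None,
                       quantile: float | None = None) -> pd.DataFrame:
    """Rank features by their loading norm on the chosen common components.

    Features (all blocks pooled) are ranked by the Euclidean norm of
    their loadings on the 1-based ``components``; the sign of the first
    chosen component's loading gives the direction of association (the
    components are oriented so the positive class — "faster" growth —
    scores positive).  Returns the top ``k`` (or top ``quantile``) rows
    with block provenance; both cut rules exposed, default all features.
    """
    comps = [c - 1 for c in components]
    records = []
    for b in result.block_names:
        P = result.block_loadings_[b][:, comps]
        norms = np.linalg.norm(P, axis=1)
        for j, fid in enumerate(result.feature_ids[b]):
            records.append({
                "feature_id": fid,
                "block": b,
                "loading_norm": float(norms[j]),
                "loading_c1": float(P[j, 0]),
                "direction": "positive" if P[j, 0] >= 0 else "negative",
            })
    df = pd.DataFrame(records).sort_values(
        ["loading_norm", "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if quantile is not None:
        cut = df["loading_norm"].quantile(quantile)
        df = df[df["loading_norm"] >= cut]
    if k is not None:
        df = df.head(int(k))
    return df
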