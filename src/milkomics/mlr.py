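"""Confounder-adjusted biomarker regressions.

One ordinary-least-squares model per candidate feature regresses the
infant's weight-Z-score change (discharge minus birth, SD units) on the
feature plus the clinical confounders; Benjamini-Hochberg FDR across the
screened candidates flags features with q < 0.1 as reliable biomarkers.

Milk is measured at the mother-week level while the response is one
value per infant, so feature values are collapsed to the mother's mean
over weeks 2-4 and duplicated to twins before the regression (a
week-3-only mode is available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_tables import CONFOUNDER_NAMES, CohortMetadata, FeatureTable
from .univariate import bh_fdr

logger = logging.getLogger(__name__)

RELIABLE_Q = 0.1


def fit_feature_mlr(feature_values, response, confounders=None):
    """OLS of the response on [intercept, feature, confounders].

    Rows with missing values in any regressor or the response are
    dropped (listwise deletion, logged).  Returns ``(coef, se, p)`` for
    the feature term (two-sided t-test).
    """
    f = np.asarray(feature_values, dtype=float)
    y = np.asarray(response, dtype=float)
    if confounders is None:
        C = np.empty((f.shape[0], 0))
        conf_names: list[str] = []
    else:
        Cdf = pd.DataFrame(confounders)
        conf_names = [str(c) for c in Cdf.columns]
        C = Cdf.to_numpy(dtype=float)
    design = np.column_stack([f, C])
    keep = np.isfinite(y) & np.isfinite(design).all(axis=1)
    if keep.sum() < design.shape[0]:
        logger.info("fit_feature_mlr: listwise deletion dropped %d rows",
                    int((~keep).sum()))
    y, design = y[keep], design[keep]
    n, k = design.shape
    if n <= k + 2:
        raise ValueError(f"too few complete cases (n={n}) for {k} regressors")
    if np.ptp(design[:, 0]) == 0:
        raise ValueError("constant feature: coefficient not identifiable")
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = ["intercept", "feature", *conf_names]
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns involved in a rank deficiency via the small
    diagonal entries of the pivoted QR factor."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[j] for j in np.where(diag <= tol)[0]] or names[1:]


@dataclass
class MlrScreenResults:
    """Results of a per-feature biomarker screen."""

    table: pd.DataFrame  # indexed by feature_id
    n_models: int
    reliable_q: float = RELIABLE_Q

    @property
    def reliable_features(self) -> list:
        return list(self.table.index[self.table["reliable"]])

    def summary(self) -> str:
        return (
            f"MLR biomarker screen: {self.n_models} model(s), "
            f"{len(self.reliable_features)} reliable at q < {self.reliable_q:g}"
        )


class MlrScreen:
    """Screen a candidate feature set as growth biomarkers.

    Parameters
    ----------
    candidates : pandas.DataFrame
        Infant x feature matrix (scaled abundance units), one row per
        infant, aligned with ``response``.
    response : array-like
        Weight-Z-score change per infant (SD units).
    confounders : pandas.DataFrame, optional
        Infant x confounder matrix; defaults to none.
    """

    def __init__(self, candidates: pd.DataFrame, response,
                 confounders: pd.DataFrame | None = None,
                 reliable_q: float = RELIABLE_Q):
        self.candidates = pd.DataFrame(candidates)
        self.response = np.asarray(response, dtype=float)
        self.confounders = confounders
        self.reliable_q = float(reliable_q)

    def fit(self) -> MlrScreenResults:
        if self.candidates.shape[1] == 0:
            warnings.warn("MlrScreen: empty candidate set")
            empty = pd.DataFrame(
                columns=["coef", "se", "mlr_p", "mlr_q", "reliable"],
                index=pd.Index([], name="feature_id"),
            )
            return MlrScreenResults(empty, 0, self.reliable_q)
        records = []
        for fid in self.candidates.columns:
            coef, se, p = fit_feature_mlr(
                self.candidates[fid], self.response, self.confounders)
            records.append({"feature_id": fid, "coef": coef, "se": se, "mlr_p": p})
        table = pd.DataFrame(records).set_index("feature_id")
        table["mlr_q"] = bh_fdr(table["mlr_p"].to_numpy())
        table["reliable"] = table["mlr_q"] < self.reliable_q
        return MlrScreenResults(table, len(table), self.reliable_q)


def collapse_to_infants(table, metadata: CohortMetadata,
                        mode: str = "mother_mean", weeks=(2, 3, 4)):
    """Collapse mother-week milk values to one row per infant.

    ``mode="mother_mean"`` averages each mother's weekly samples;
    ``mode="week3"`` takes the week-3 sample only.  Twins inherit their
    mother's (shared) milk values.  ``table`` may be a FeatureTable or a
    plain sample x feature DataFrame.  Returns ``(X_infant, infants)``
    aligned with ``metadata.infant_table()``.
    """
    values = table.values if isinstance(table, FeatureTable) else pd.DataFrame(table)
    bio = metadata.biological
    bio = bio[bio["sample_id"].isin(set(values.index))]
    if mode == "week3":
        bio = bio[bio["week"] == 3]
    elif mode == "mother_mean":
        bio = bio[bio["week"].isin(list(weeks))]
    else:
        raise ValueError(f"unknown collapse mode {mode!r}")
    pairs = bio.drop_duplicates(["mother_id", "sample_id"])
    per_mother = (
        values.loc[pairs["sample_id"]]
        .groupby(pairs["mother_id"].to_numpy())
        .mean()
    )
    infants = metadata.infant_table()
    infants = infants[infants["mother_id"].isin(per_mother.index)]
    X = per_mother.loc[infants["mother_id"]].copy()
    X.index = infants.index
    return X, infants


def run_mlr_screen(candidates, metadata: CohortMetadata,
                   confounder_names=CONFOUNDER_NAMES,
                   collapse: str = "mother_mean",
                   reliable_q: float = RELIABLE_Q) -> MlrScreenResults:
    """Screen the candidate features of one block against infant growth.

    Collapses milk values to infants (see :func:`collapse_to_infants`),
    takes the response and the nine clinical confounders from the
    metadata, and runs one OLS per feature with BH-FDR over the screen.
    """
    X, infants = collapse_to_infants(candidates, metadata, mode=collapse)
    response = infants["delta_weight_zscore"].to_numpy(dtype=float)
    conf = infants[list(confounder_names)].astype(float)
    # impute by group median only when listwise deletion would be too costly
    n_complete = int(conf.notna().all(axis=1).sum())
    if n_complete < 0.8 * len(conf):
        logger.info("run_mlr_screen: imputing confounders by group median "
                    "(%d/%d complete cases)", n_complete, len(conf))
        med = conf.groupby(infants["growth_group"].to_numpy()).transform("median")
        conf = conf.fillna(med)
    return MlrScreen(X, response, conf, reliable_q=reliable_q).fit()
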