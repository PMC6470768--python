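"""Feature filtering, scaling, and glycome-specific transforms.

Implements the preprocessing used ahead of the multivariate models:

* QC-based feature filtration (30% relative-SD cutoff over pooled-QC
  injections);
* log-Pareto scaling (log10 then mean-centring and division by the
  square root of the feature standard deviation) for the wide-dynamic-
  range metabolome/lipidome blocks, plain autoscaling (unit variance)
  for the narrower glycome / fatty-acid / free-amino-acid blocks;
* relative HMO abundances (percent of each sample's total HMO signal);
* HMO composition-code parsing (Hex/Fuc/HexNAc/NeuAc counts, e.g.
  ``"4230b"``);
* maternal secretor-status calling from 2'-fucosyllactose levels, and
  secretor-stratified mean-centring of the glycome.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)

FUCOSYLATION_CLASSES = {
    0: "neutral-unfucosylated",
    1: "mono",
    2: "di",
    3: "tri",
    4: "tetra",
}


# ------------------------------------------------------------ scaling


@dataclass
class ScalingSpec:
    """Fitted per-feature scaling statistics (retained for new data and
    for the inverse transform)."""

    method: str  # "log_pareto" | "autoscale" | "none"
    mean_: np.ndarray
    scale_: np.ndarray  # divisor actually applied
    sd_: np.ndarray  # pre-scaling per-feature standard deviation
    pseudocount: float = 0.0
    log_base: int = 10
    feature_ids: list = field(default_factory=list)

    def transform(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if self.method == "log_pareto":
            arr = np.log10(arr + self.pseudocount)
        return (arr - self.mean_) / self.scale_

    def inverse(self, Xs) -> np.ndarray:
        arr = np.asarray(Xs, dtype=float) * self.scale_ + self.mean_
        if self.method == "log_pareto":
            arr = np.power(10.0, arr) - self.pseudocount
        return arr


def _as_frame(block) -> pd.DataFrame:
    if isinstance(block, FeatureTable):
        return block.values
    return pd.DataFrame(block)


def default_pseudocount(values: pd.DataFrame) -> float:
    """Half the smallest nonzero abundance in the block (standard
    below-detection offset); 0 if the block has no zeros."""
    arr = np.asarray(values, dtype=float)
    if not (arr == 0).any():
        return 0.0
    nz = arr[arr > 0]
    if nz.size == 0:
        raise ValueError("all-zero block: cannot choose a pseudocount")
    return float(nz.min() / 2.0)


def _guarded_scale(raw: np.ndarray, what: str) -> np.ndarray:
    scale = raw.copy()
    zero = ~(scale > 0)
    if zero.any():
        warnings.warn(
            f"{what}: {int(zero.sum())} constant feature(s); scale set to 1",
            stacklevel=3,
        )
        scale[zero] = 1.0
    return scale


def log_pareto_scale(block, pseudocount: float | None = None):
    """log10 transform followed by Pareto scaling.

    Each feature x is mapped to ``(log10(x + c) - mean) / sqrt(sd)``
    where ``sd`` is the feature's post-log standard deviation and the
    pseudocount ``c`` defaults to half the block's smallest nonzero
    value (required whenever the block contains zeros).

    Returns ``(scaled, spec)`` with ``scaled`` a DataFrame matching the
    input layout and ``spec`` the fitted :class:`ScalingSpec`.
    """
    df = _as_frame(block)
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log_pareto_scale requires non-negative values")
    c = default_pseudocount(df) if pseudocount is None else float(pseudocount)
    if (arr == 0).any() and c <= 0:
        raise ValueError("pseudocount must be > 0 when the block contains zeros")
    logged = np.log10(arr + c)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    scale = _guarded_scale(np.sqrt(sd), "log_pareto_scale")
    spec = ScalingSpec("log_pareto", mean, scale, sd, pseudocount=c,
                       feature_ids=list(df.columns))
    out = pd.DataFrame((logged - mean) / scale, index=df.index, columns=df.columns)
    return out, spec


def autoscale(block):
    """Mean-centre and scale each feature to unit variance (no log)."""
    df = _as_frame(block)
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    scale = _guarded_scale(sd.copy(), "autoscale")
    spec = ScalingSpec("autoscale", mean, scale, sd, feature_ids=list(df.columns))
    out = pd.DataFrame((arr - mean) / scale, index=df.index, columns=df.columns)
    return out, spec


SCALERS = {"log_pareto": log_pareto_scale, "autoscale": autoscale}


def scale_block(block, method: str):
    if method == "none":
        df = _as_frame(block)
        p = df.shape[1]
        spec = ScalingSpec("none", np.zeros(p), np.ones(p),
                           df.to_numpy(dtype=float).std(axis=0, ddof=1),
                           feature_ids=list(df.columns))
        return df.copy(), spec
    try:
        return SCALERS[method](block)
    except KeyError:
        raise ValueError(f"unknown scaling method {method!r}") from None


# ------------------------------------------------------- QC filtering


def qc_rsd_filter(table: FeatureTable, metadata: CohortMetadata,
                  cutoff: float = 0.30) -> FeatureTable:
    """Drop features whose relative SD over pooled-QC injections exceeds
    ``cutoff`` (default 30%).

    RSD is sd/mean over the QC rows (sample sd, ddof=1).  Features with
    zero QC mean and any QC variation are treated as unstable and
    removed; an all-zero QC feature is likewise removed.
    """
    qc_ids = [s for s in metadata.qc_sample_ids if s in set(table.sample_ids)]
    if len(qc_ids) < 3:
        raise ValueError(
            f"{table.block_name}: QC RSD filter needs >=3 QC rows, found {len(qc_ids)}"
        )
    qc = table.values.loc[qc_ids].to_numpy(dtype=float)
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean, np.inf)
    rsd = np.where((mean == 0) & (sd == 0), np.inf, rsd)
    keep = rsd <= cutoff
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    if removed:
        logger.info("qc_rsd_filter(%s): removed %d/%d features (RSD > %.0f%%): %s",
                    table.block_name, len(removed), table.n_features,
                    cutoff * 100, removed[:8])
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.subset_features(kept)


# ----------------------------------------------------- glycome tools


def relative_hmo_abundance(glycome: FeatureTable) -> FeatureTable:
    """Rescale each sample's HMO peak areas to percent of the sample's
    total HMO signal (rows sum to 100)."""
    vals = glycome.values.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    bad = totals <= 0
    if bad.any():
        sample = glycome.sample_ids[int(np.argwhere(bad)[0][0])]
        raise ValueError(f"relative_hmo_abundance: all-zero sample {sample!r}")
    rel = 100.0 * vals / totals[:, None]
    return FeatureTable(
        glycome.block_name,
        pd.DataFrame(rel, index=glycome.values.index, columns=glycome.values.columns),
        glycome.feature_meta,
    )


@dataclass(frozen=True)
class HmoComposition:
    """Monosaccharide composition of an HMO.

    Codes are four digits (hexose, fucose, N-acetylhexosamine,
    N-acetylneuraminic acid counts) with an optional lower-case isomer
    letter, e.g. ``"3210"`` = 3 Hex / 2 Fuc / 1 HexNAc / 0 NeuAc and
    ``"4230b"`` = isomer b of 4 Hex / 2 Fuc / 3 HexNAc / 0 NeuAc.
    """

    hex: int
    fuc: int
    hexnac: int
    neuac: int
    isomer: str | None = None

    @property
    def fucosylation_class(self) -> str:
        return FUCOSYLATION_CLASSES.get(self.fuc, f"{self.fuc}-fucosylated")

    @property
    def sialylated(self) -> bool:
        return self.neuac > 0

    def format(self) -> str:
        return f"{self.hex}{self.fuc}{self.hexnac}{self.neuac}{self.isomer or ''}"


_HMO_RE = re.compile(r"^(\d)(\d)(\d)(\d)([a-z]?)$")


def parse_hmo_code(code: str) -> HmoComposition:
    m = _HMO_RE.match(str(code).strip())
    if not m:
        raise ValueError(f"malformed HMO composition code {code!r}")
    hexn, fuc, hexnac, neuac, isomer = m.groups()
    return HmoComposition(int(hexn), int(fuc), int(hexnac), int(neuac),
                          isomer or None)


# ------------------------------------------------ secretor machinery


def largest_gap_split(values: np.ndarray, min_ratio: float = 3.0,
                      min_range_fraction: float = 0.5):
    """1-D two-cluster split at the largest gap in the sorted values.

    The split is accepted only when the largest inter-point gap is
    decisive on both criteria: at least ``min_ratio`` times the median
    of the remaining (within-cluster) gaps, and at least
    ``min_range_fraction`` of the total range (the latter rejects the
    large tail gaps that unimodal skewed samples produce).  Otherwise
    the sample is considered homogeneous.  Returns
    ``(threshold or None, gap_ratio)``.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 3:
        raise ValueError("largest_gap_split needs >=3 values")
    gaps = np.diff(v)
    i = int(np.argmax(gaps))
    big = gaps[i]
    rng_v = float(v[-1] - v[0])
    others = np.delete(gaps, i)
    spread = float(np.median(others))
    if spread <= 0:
        spread = float(np.mean(others))
    if spread <= 0:
        # all duplicates except one jump: any positive gap is decisive
        ratio = np.inf if big > 0 else 0.0
    else:
        ratio = float(big / spread)
    accept = (big > 0 and ratio >= min_ratio
              and big >= min_range_fraction * rng_v)
    if accept:
        return float((v[i] + v[i + 1]) / 2.0), ratio
    return None, ratio


def classify_secretor(glycome: FeatureTable, metadata: CohortMetadata,
                      fl2_feature_id: str, floor: float = 1.0,
                      min_ratio: float = 3.0) -> pd.Series:
    """Call maternal secretor status from milk 2'-FL levels.

    Mothers are split into two clusters of mean relative 2'-FL abundance
    (percent of total HMO signal) at the largest gap; the low cluster is
    called non-secretor.  Regardless of the clustering, mothers below
    ``floor`` percent relative 2'-FL are non-secretor (non-secretor milk
    has very low or undetectable 2'-FL).  When the gap split is rejected
    (homogeneous cohort) only the floor applies.

    Returns a Series indexed by mother_id with values
    ``"secretor"`` / ``"non-secretor"``.
    """
    if fl2_feature_id not in set(glycome.feature_ids):
        raise ValueError(f"2'-FL feature {fl2_feature_id!r} not in glycome block")
    rel = relative_hmo_abundance(glycome)
    bio = metadata.biological
    bio = bio[bio["sample_id"].isin(rel.sample_ids)]
    per_sample = rel.values[fl2_feature_id]
    mothers = bio.drop_duplicates(["mother_id", "sample_id"])
    levels = (
        per_sample.loc[mothers["sample_id"]]
        .groupby(mothers["mother_id"].to_numpy())
        .mean()
    )
    if len(levels) < 3:
        raise ValueError("classify_secretor needs >=3 mothers")
    # split on the log scale: the secretor/non-secretor contrast spans
    # orders of magnitude while within-cluster spread is fractional
    arr = levels.to_numpy(dtype=float)
    eps = (arr[arr > 0].min() / 10.0) if (arr > 0).any() else 1e-6
    log_levels = np.log10(arr + eps)
    threshold, ratio = largest_gap_split(log_levels, min_ratio=min_ratio)
    status = pd.Series("secretor", index=levels.index, name="secretor_status")
    if threshold is not None:
        status[log_levels < threshold] = "non-secretor"
    status[levels < floor] = "non-secretor"
    logger.info("classify_secretor: %d/%d non-secretor (gap ratio %.2f)",
                int((status == "non-secretor").sum()), len(status), ratio)
    return status


def secretor_stratified_center(X, statuses) -> pd.DataFrame:
    """Mean-centre each feature within each secretor stratum.

    Removes the cross-stratum separation the FUT2 polymorphism imposes on
    fucosylated HMOs before the blocks are fused.  ``statuses`` gives the
    stratum of each row of ``X``.  A stratum of size 1 is centred on its
    own single value (that row becomes 0) with a warning.
    """
    df = pd.DataFrame(X).copy()
    statuses = np.asarray(statuses)
    if statuses.shape[0] != df.shape[0]:
        raise ValueError("one status per sample row required")
    for level in pd.unique(statuses):
        mask = statuses == level
        if mask.sum() < 2:
            warnings.warn(
                f"secretor stratum {level!r} has a single sample; centred to 0"
            )
        df.loc[mask] = df.loc[mask] - df.loc[mask].mean(axis=0)
    return df
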