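"""Tabular IO: feature tables, cohort metadata, result tables.

All artifacts are delimited text (comma or tab, auto-detected, UTF-8).
The canonical in-memory layout is samples in rows and features in columns
(the usual n x p multivariate convention); files that store features in
rows declare it by naming their first header column ``feature_id`` and
are transposed on load.

Missing abundances are written as 0 on disk.  MS peak tables rarely
distinguish "not detected" from a true zero, so zeros are carried through
and treated as below-detection values downstream (the scalers add a
pseudocount before taking logs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical block names used throughout the pipeline
BLOCK_NAMES = (
    "metabolome_pos",
    "metabolome_neg",
    "lipidome",
    "glycome",
    "faa",
    "fa",
)

#: clinical confounders entered in the biomarker regressions
CONFOUNDER_NAMES = (
    "maternal_bmi",
    "birth_weight",
    "gestational_age",
    "protein_intake",
    "lipid_intake",
    "energy_intake",
    "parenteral_days",
    "ventilation_days",
    "hospital_stay_days",
)

GROWTH_GROUPS = ("faster", "slower")


class TableValidationError(ValueError):
    """A tabular artifact violated one of its invariants."""


@dataclass
class FeatureTable:
    """One omics block: samples x features abundance matrix.

    Parameters
    ----------
    block_name : str
        Block identity, one of :data:`BLOCK_NAMES` (other names are
        allowed for ad-hoc tables but the pipeline only routes the
        canonical ones).
    values : pandas.DataFrame
        Non-negative abundance matrix, samples in rows (index =
        sample ids), features in columns (columns = feature ids).
        Units are arbitrary peak areas.
    feature_meta : pandas.DataFrame, optional
        Per-feature metadata indexed by feature id.  Recognised columns:
        ``mz`` (Daltons), ``rt`` (minutes), ``annotation_level``
        (1, 2 or "unannotated") and, for the glycome block, ``hmo_code``
        (monosaccharide composition string such as ``"4230b"``).
    """

    block_name: str
    values: pd.DataFrame
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise TableValidationError(
                f"{self.block_name}: duplicate sample ids {dupes}"
            )
        if vals.columns.has_duplicates:
            dupes = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise TableValidationError(
                f"{self.block_name}: duplicate feature ids {dupes}"
            )
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(vals)
            raise TableValidationError(
                f"{self.block_name}: non-numeric cell at "
                f"sample={bad[0]!r}, feature={bad[1]!r}"
            )
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise TableValidationError(
                f"{self.block_name}: non-finite abundance at "
                f"sample={vals.index[i]!r}, feature={vals.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"{self.block_name}: negative abundance at "
                f"sample={vals.index[i]!r}, feature={vals.columns[j]!r}"
            )

    # -- conveniences -----------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def zero_fraction(self) -> float:
        arr = self.values.to_numpy()
        return float((arr == 0).mean()) if arr.size else 0.0

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        meta = self.feature_meta
        if not meta.empty:
            meta = meta.loc[meta.index.intersection(feature_ids)]
        return FeatureTable(self.block_name, self.values[feature_ids].copy(), meta)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            self.block_name, self.values.loc[list(sample_ids)].copy(), self.feature_meta
        )


def _first_non_numeric(df: pd.DataFrame) -> tuple:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return df.index[bad.to_numpy().nonzero()[0][0]], col
    return df.index[0], df.columns[0]


@dataclass
class CohortMetadata:
    """Per-sample clinical and design variables.

    One row per infant-week plus one row per pooled-QC injection.  Twins
    share their mother's milk, so two infant rows may point at the same
    milk ``sample_id``; feature tables are indexed by the (unique) milk
    sample ids.
    """

    df: pd.DataFrame

    REQUIRED = (
        "sample_id",
        "mother_id",
        "infant_id",
        "twin_set_id",
        "week",
        "is_qc",
        "growth_group",
        "delta_weight_zscore",
        "secretor",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise TableValidationError(f"metadata missing columns {missing}")
        missing_conf = [c for c in CONFOUNDER_NAMES if c not in df.columns]
        if missing_conf:
            raise TableValidationError(f"metadata missing confounders {missing_conf}")
        bio = df[~df["is_qc"].astype(bool)]
        weeks = set(bio["week"].dropna().unique().tolist())
        if not weeks <= {2, 3, 4}:
            raise TableValidationError(f"weeks outside {{2,3,4}}: {sorted(weeks)}")
        qc = df[df["is_qc"].astype(bool)]
        if qc["growth_group"].notna().any():
            raise TableValidationError("QC rows must carry no growth_group")
        groups = set(bio["growth_group"].dropna().unique().tolist())
        if not groups <= set(GROWTH_GROUPS):
            raise TableValidationError(f"unknown growth groups {sorted(groups)}")

    # -- conveniences -----------------------------------------------
    @property
    def biological(self) -> pd.DataFrame:
        return self.df[~self.df["is_qc"].astype(bool)]

    @property
    def qc_sample_ids(self) -> list[str]:
        return list(self.df.loc[self.df["is_qc"].astype(bool), "sample_id"])

    @property
    def milk_sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.biological["sample_id"]))

    @property
    def all_sample_ids(self) -> set[str]:
        return set(self.df["sample_id"])

    def infant_table(self) -> pd.DataFrame:
        """One row per infant (response + confounders for the regressions)."""
        bio = self.biological
        cols = [
            "infant_id",
            "mother_id",
            "twin_set_id",
            "growth_group",
            "delta_weight_zscore",
            "secretor",
            *CONFOUNDER_NAMES,
        ]
        return bio.drop_duplicates("infant_id")[cols].set_index("infant_id")

    def mother_secretor(self) -> pd.Series:
        bio = self.biological
        return bio.drop_duplicates("mother_id").set_index("mother_id")["secretor"]


# ---------------------------------------------------------------- IO


def read_feature_table(path, block_name: str, feature_meta_path=None) -> FeatureTable:
    """Load a delimited feature table and validate it.

    The delimiter (comma or tab) is sniffed.  If the first header column
    is named ``feature_id`` the table stores features in rows and is
    transposed to the canonical samples x features layout.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if (df.index.name or "").strip().lower() == "feature_id":
        df = df.T
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = df.columns.astype(str)
    meta = pd.DataFrame()
    if feature_meta_path is not None:
        meta = pd.read_csv(feature_meta_path, sep=None, engine="python", index_col=0)
        meta.index = meta.index.astype(str)
    table = FeatureTable(block_name, df, meta)
    logger.info(
        "loaded %s: %d samples x %d features, zero fraction %.3f",
        block_name,
        table.n_samples,
        table.n_features,
        table.zero_fraction,
    )
    return table


def write_feature_table(table: FeatureTable, path, sep: str = ",") -> None:
    table.values.to_csv(path, sep=sep)


def write_feature_meta(table: FeatureTable, path, sep: str = ",") -> None:
    meta = table.feature_meta
    if meta.empty:
        meta = pd.DataFrame(index=pd.Index(table.feature_ids, name="feature_id"))
    meta.to_csv(path, sep=sep)


def read_metadata(path) -> CohortMetadata:
    df = pd.read_csv(path, sep=None, engine="python")
    df["is_qc"] = df["is_qc"].astype(bool)
    df["week"] = df["week"].astype("Int64")
    for col in ("growth_group", "infant_id", "mother_id", "twin_set_id", "secretor"):
        if col in df.columns:
            df[col] = df[col].astype("string").replace({"": pd.NA})
    return CohortMetadata(df)


def write_metadata(metadata: CohortMetadata, path, sep: str = ",") -> None:
    metadata.df.to_csv(path, sep=sep, index=False)


def align_blocks(tables, metadata: CohortMetadata | None = None):
    """Restrict all blocks to their common samples, in canonical order.

    Returns the tables (same order as given) re-indexed to the sorted
    intersection of their sample ids (and, when metadata is given, of the
    metadata's sample ids).  Dropped samples are logged.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("align_blocks requires at least one table")
    common = set(tables[0].sample_ids)
    for t in tables[1:]:
        common &= set(t.sample_ids)
    if metadata is not None:
        common &= metadata.all_sample_ids
    if not common:
        raise ValueError("align_blocks: empty sample intersection")
    order = sorted(common)
    aligned = []
    for t in tables:
        dropped = sorted(set(t.sample_ids) - common)
        if dropped:
            logger.info("align_blocks: %s drops %d samples %s",
                        t.block_name, len(dropped), dropped[:5])
        aligned.append(FeatureTable(t.block_name, t.values.loc[order].copy(),
                                    t.feature_meta))
    return aligned


def expand_to_infants(table, metadata: CohortMetadata,
                      weeks=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map milk samples to infant-week observations.

    Twins share their mother's milk sample, so the milk row is duplicated
    for each twin.  ``table`` may be a :class:`FeatureTable` or a plain
    sample x feature DataFrame (e.g. a scaled matrix).  Returns
    ``(X, obs)`` where ``X`` is an observation x feature matrix indexed
    by ``infant_id@W<week>`` and ``obs`` carries the matching metadata
    rows (same index).
    """
    values = table.values if isinstance(table, FeatureTable) else pd.DataFrame(table)
    bio = metadata.biological
    if weeks is not None:
        bio = bio[bio["week"].isin(list(weeks))]
    bio = bio[bio["sample_id"].isin(set(values.index))]
    bio = bio.sort_values(["infant_id", "week"], kind="stable")
    idx = [f"{r.infant_id}@W{r.week}" for r in bio.itertuples()]
    X = values.loc[bio["sample_id"]].copy()
    X.index = pd.Index(idx, name="observation")
    obs = bio.copy()
    obs.index = X.index
    return X, obs
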