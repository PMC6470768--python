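"""End-to-end study pipeline and report tables.

Orchestrates: simulate (optional) -> load -> QC-RSD filter -> scaling ->
AoV-PLS/LDA discriminant models with VIP selection -> univariate
Mann-Whitney + FDR tables -> confounder-adjusted MLR biomarker screen ->
week-3 multi-block fusion (UPCA + MB-PLS + loading-based selection) ->
report tables and a run manifest.

Every stage writes delimited-text artifacts into the study directory so
the subcommands are independently runnable and a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aovpls import AovPlsLda, cv_error_chain
from .fusion import MBPLS, assemble_superblock, select_by_loadings, upca
from .io_tables import (
    BLOCK_NAMES,
    CohortMetadata,
    FeatureTable,
    align_blocks,
    expand_to_infants,
    read_feature_table,
    read_metadata,
    write_feature_table,
)
from .mlr import run_mlr_screen
from .preprocessing import (
    classify_secretor,
    qc_rsd_filter,
    relative_hmo_abundance,
    scale_block,
    secretor_stratified_center,
)
from .synthetic import FL2_FEATURE_ID, SyntheticConfig, simulate_study
from .univariate import run_univariate_screen

logger = logging.getLogger(__name__)

STAGES = ("simulate", "load", "qc_filter", "scale", "discriminate",
          "univariate", "mlr", "fuse", "report")

#: scaling method per block: log-Pareto absorbs the wide dynamic range
#: of the metabolome/lipidome; the remaining blocks are autoscaled.
DEFAULT_SCALING = {
    "metabolome_pos": "log_pareto",
    "metabolome_neg": "log_pareto",
    "lipidome": "log_pareto",
    "glycome": "autoscale",
    "faa": "autoscale",
    "fa": "autoscale",
}


@dataclass
class PipelineConfig:
    """Run configuration (thresholds mirror the study workflow)."""

    study_dir: str = "study"
    blocks: tuple = BLOCK_NAMES
    alpha: float = 0.05
    mw_q_threshold: float = 0.05
    mlr_q_threshold: float = 0.1
    vip_threshold: float = 1.5
    rsd_cutoff: float = 0.30
    n_components: int = 5
    display_components: int = 2
    fusion_week: int = 3
    fusion_components: int = 2
    scaling: dict = field(default_factory=lambda: dict(DEFAULT_SCALING))
    fl2_feature_id: str = FL2_FEATURE_ID
    collapse: str = "mother_mean"
    seed: int = 0
    simulate: dict | None = None  # SyntheticConfig overrides, or None

    def __post_init__(self) -> None:
        for name, v in (("mw_q_threshold", self.mw_q_threshold),
                        ("mlr_q_threshold", self.mlr_q_threshold),
                        ("alpha", self.alpha)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.vip_threshold <= 0:
            raise ValueError("vip_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _fmt(df: pd.DataFrame, decimals: int = 4) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out


class StudyPipeline:
    """Stateful runner; stages populate ``self.manifest['stages']``."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.dir = Path(config.study_dir)
        self.metadata: CohortMetadata | None = None
        self.raw: dict[str, FeatureTable] = {}
        self.filtered: dict[str, FeatureTable] = {}
        self.scaled: dict[str, pd.DataFrame] = {}
        self.scaling_specs: dict = {}
        self.discriminant: dict = {}
        self.vip_selected: dict[str, list] = {}
        self.univariate: dict[str, pd.DataFrame] = {}
        self.mlr: dict = {}
        self.secretor: pd.Series | None = None
        self.fusion: dict = {}
        self.manifest: dict = {
            "package": "milkomics",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "stages": [],
        }

    # ------------------------------------------------------- stages
    def _done(self, stage: str, **info) -> None:
        self.manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s done: %s", stage, info)

    def stage_simulate(self) -> None:
        overrides = dict(self.config.simulate or {})
        overrides.setdefault("seed", self.config.seed)
        cfg = SyntheticConfig(**overrides)
        simulate_study(cfg, self.dir)
        self._done("simulate", n_dyads=cfg.n_dyads, n_mothers=cfg.n_mothers,
                   blocks=sorted(cfg.block_sizes))

    def stage_load(self) -> None:
        self.metadata = read_metadata(self.dir / "samples.csv")
        tables = []
        for name in self.config.blocks:
            path = self.dir / f"{name}.csv"
            meta_path = self.dir / f"features_{name}.csv"
            tables.append(read_feature_table(
                path, name, meta_path if meta_path.exists() else None))
        tables = align_blocks(tables, self.metadata)
        self.raw = {t.block_name: t for t in tables}
        self._done("load", blocks={n: t.n_features for n, t in self.raw.items()},
                   n_samples=tables[0].n_samples)

    def stage_qc_filter(self) -> None:
        counts = {}
        for name, table in self.raw.items():
            filtered = qc_rsd_filter(table, self.metadata, self.config.rsd_cutoff)
            self.filtered[name] = filtered
            counts[name] = f"{filtered.n_features}/{table.n_features}"
            write_feature_table(filtered, self.dir / f"filtered_{name}.csv")
        self._done("qc_filter", kept=counts, rsd_cutoff=self.config.rsd_cutoff)

    def _milk_only(self, table: FeatureTable) -> FeatureTable:
        milk = [s for s in table.sample_ids
                if s in set(self.metadata.milk_sample_ids)]
        return table.subset_samples(milk)

    def stage_scale(self) -> None:
        for name, table in self.filtered.items():
            milk = self._milk_only(table)
            if name == "glycome":
                milk = relative_hmo_abundance(milk)
            method = self.config.scaling.get(name, "autoscale")
            scaled, spec = scale_block(milk.values, method)
            self.scaled[name] = scaled
            self.scaling_specs[name] = spec
            scaled.to_csv(self.dir / f"scaled_{name}.csv")
        self._done("scale", methods={n: self.scaling_specs[n].method
                                     for n in self.scaled})

    def stage_discriminate(self) -> None:
        info = {}
        for name, scaled in self.scaled.items():
            X, obs = expand_to_infants(scaled, self.metadata)
            res = AovPlsLda(
                X.to_numpy(), obs["growth_group"].to_numpy(),
                n_components=self.config.n_components,
                feature_ids=list(X.columns),
                vip_threshold=self.config.vip_threshold,
            ).fit()
            self.discriminant[name] = res
            self.vip_selected[name] = res.selected_features
            pd.DataFrame({
                "feature_id": res.feature_ids,
                "vip": np.round(res.vip_, 4),
            }).sort_values(["vip", "feature_id"], ascending=[False, True],
                           kind="stable").to_csv(
                self.dir / f"vip_{name}.csv", index=False)
            (self.dir / f"aovpls_{name}.txt").write_text(res.summary() + "\n")
            # dyad-level error: majority vote of each infant's week folds
            cv = cv_error_chain(X.to_numpy(), obs["growth_group"].to_numpy(),
                                self.config.n_components,
                                res.n_lda_components)
            votes = pd.DataFrame({
                "infant": obs["infant_id"].to_numpy()[cv.predictions.index],
                "pred": cv.predictions.to_numpy(),
                "true": obs["growth_group"].to_numpy()[cv.predictions.index],
            })
            per_infant = votes.groupby("infant").agg(
                pred=("pred", lambda s: s.mode().iloc[0]),
                true=("true", "first"))
            dyad_error = float((per_infant["pred"] != per_infant["true"]).mean())
            info[name] = {"cv_error_pct": round(100 * res.cv_error, 2),
                          "dyad_cv_error_pct": round(100 * dyad_error, 2),
                          "n_vip": len(res.selected_features)}
        self._done("discriminate", models=info)

    def stage_univariate(self) -> None:
        counts = {}
        for name, table in self.filtered.items():
            milk = self._milk_only(table)
            if name == "glycome":
                milk = relative_hmo_abundance(milk)
            X, obs = expand_to_infants(milk, self.metadata)
            screen = run_univariate_screen(X, obs["growth_group"].to_numpy())
            self.univariate[name] = screen
            counts[name] = int((screen["mw_q"] < self.config.mw_q_threshold).sum())
        self._done("univariate", significant=counts,
                   q_threshold=self.config.mw_q_threshold)

    def stage_mlr(self) -> None:
        info = {}
        for name, scaled in self.scaled.items():
            candidates = self.vip_selected.get(name) or []
            if not candidates:
                empty = pd.DataFrame(
                    columns=["coef", "se", "mlr_p", "mlr_q", "reliable"],
                    index=pd.Index([], name="feature_id"))
                from .mlr import MlrScreenResults
                self.mlr[name] = MlrScreenResults(empty, 0,
                                                  self.config.mlr_q_threshold)
                info[name] = {"n_models": 0, "n_reliable": 0}
                continue
            res = run_mlr_screen(self.scaled[name][candidates], self.metadata,
                                 collapse=self.config.collapse,
                                 reliable_q=self.config.mlr_q_threshold)
            self.mlr[name] = res
            info[name] = {"n_models": res.n_models,
                          "n_reliable": len(res.reliable_features)}
        self._done("mlr", models=info)

    def stage_fuse(self) -> None:
        cfg = self.config
        glycome = self._milk_only(self.filtered["glycome"])
        rel = relative_hmo_abundance(glycome)
        self.secretor = classify_secretor(glycome, self.metadata,
                                          cfg.fl2_feature_id)

        # week-N slice at infant level, identical row order across blocks
        blocks_scaled: dict[str, pd.DataFrame] = {}
        obs_ref = None
        for name in self.scaled:
            if name == "glycome":
                base = rel
            else:
                base = self._milk_only(self.filtered[name])
            # metabolome/lipidome restricted to VIP-selected features
            if name in ("metabolome_pos", "metabolome_neg", "lipidome"):
                keep = self.vip_selected.get(name) or []
                if not keep:
                    logger.info("fusion: block %s has no VIP features; skipped",
                                name)
                    continue
                base = base.subset_features(keep)
            X, obs = expand_to_infants(base, self.metadata,
                                       weeks=(cfg.fusion_week,))
            if obs_ref is None:
                obs_ref = obs
            if name == "glycome":
                statuses = obs["mother_id"].map(self.secretor).to_numpy()
                X = secretor_stratified_center(X, statuses)
            scaled, _ = scale_block(
                X, cfg.scaling.get(name, "autoscale"))
            blocks_scaled[name] = scaled
        if len(blocks_scaled) < 2:
            raise RuntimeError("fusion requires at least two non-empty blocks")

        super_block = assemble_superblock(blocks_scaled)
        labels = obs_ref["growth_group"].to_numpy()
        pca = upca(super_block.matrix.to_numpy(),
                   n_components=min(4, super_block.matrix.shape[0] - 1))
        mb = MBPLS(blocks_scaled, labels,
                   n_components=cfg.fusion_components,
                   positive_class="faster").fit()
        selection = select_by_loadings(
            mb, components=tuple(range(1, cfg.fusion_components + 1)))
        self.fusion = {"superblock": super_block, "upca": pca, "mbpls": mb,
                       "selection": selection, "labels": labels,
                       "blocks_scaled": blocks_scaled,
                       "observations": obs_ref}

        scores = pd.DataFrame(
            mb.super_scores_,
            index=obs_ref.index,
            columns=[f"comp{a + 1}" for a in range(mb.n_components)])
        scores["growth_group"] = labels
        _fmt(scores).to_csv(self.dir / "fusion_scores.csv")
        _fmt(mb.importance_frame()).to_csv(self.dir / "fusion_block_importance.csv")
        _fmt(selection).to_csv(self.dir / "fusion_selection.csv", index=False)
        upca_var = pd.DataFrame({
            "component": np.arange(1, pca.n_components + 1),
            "variance_fraction": np.round(pca.explained_variance_ratio_, 4),
        })
        upca_var.to_csv(self.dir / "fusion_upca_variance.csv", index=False)
        loo_err = fusion_loo_error(blocks_scaled, obs_ref,
                                   n_components=cfg.fusion_components)
        self.fusion["loo_error"] = loo_err
        self._done("fuse", blocks=list(blocks_scaled),
                   n_features=super_block.n_features,
                   loo_error_pct=round(100 * loo_err, 2),
                   upca_var_34=round(float(
                       pca.explained_variance_ratio_[2:4].sum()) * 100, 1)
                   if pca.n_components >= 4 else None)

    def stage_report(self) -> None:
        for name in self.filtered:
            table = make_report_table(
                self.univariate.get(name),
                self.mlr.get(name).table if self.mlr.get(name) else None,
                self.discriminant.get(name),
            )
            table.to_csv(self.dir / f"table_{name}.csv")
        (self.dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True, default=str))
        self._done("report", tables=sorted(self.filtered))

    # ---------------------------------------------------------- run
    def run(self, simulate: bool = True) -> dict:
        stages = [self.stage_simulate] if simulate else []
        stages += [self.stage_load, self.stage_qc_filter, self.stage_scale,
                   self.stage_discriminate, self.stage_univariate,
                   self.stage_mlr, self.stage_fuse, self.stage_report]
        if not simulate:
            self.manifest["stages"].append({"stage": "simulate",
                                            "skipped": True})
        for fn in stages:
            try:
                fn()
            except Exception as exc:  # abort naming the failing stage
                raise RuntimeError(
                    f"pipeline stage {fn.__name__.removeprefix('stage_')!r} "
                    f"failed: {exc}"
                ) from exc
        # rewrite the manifest with the final stage list
        (self.dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True, default=str))
        return self.manifest


def fusion_loo_error(blocks_scaled: dict, obs: pd.DataFrame,
                     n_components: int = 2) -> float:
    """Leave-one-mother-out error of the MB-PLS class assignment.

    Twins share their mother's milk sample, so rows are held out per
    mother — leaving one twin's (identical) row in training would leak
    the fold's profile and force the held-out twin to its co-twin's
    label.  Error is counted per infant row.
    """
    from .pls import loo_cv

    names = list(blocks_scaled)
    widths = [blocks_scaled[n].shape[1] for n in names]
    X = np.hstack([blocks_scaled[n].to_numpy() for n in names])
    labels = obs["growth_group"].to_numpy()
    mothers = obs["mother_id"].to_numpy()

    def fit_predict(X_tr, y_tr, X_te):
        tr, te, c0 = {}, {}, 0
        for nm, p in zip(names, widths):
            tr[nm] = pd.DataFrame(X_tr[:, c0:c0 + p])
            te[nm] = pd.DataFrame(X_te[:, c0:c0 + p])
            c0 += p
        return MBPLS(tr, y_tr, n_components=n_components).fit().predict(te)

    return loo_cv(X, labels, fit_predict, groups=mothers).error_rate


def make_report_table(univariate: pd.DataFrame | None,
                      mlr_table: pd.DataFrame | None,
                      discriminant=None) -> pd.DataFrame:
    """Result table mirroring the study's per-block layout: group
    medians (P25-P75), MW p/q with tier glyphs, VIP flag, MLR p/q with
    the reliable (#) flag."""
    if univariate is None or univariate.empty:
        cols = ["median_slower", "median_faster", "U", "mw_p", "mw_q",
                "tier", "vip", "mlr_p", "mlr_q", "reliable"]
        return pd.DataFrame(columns=cols,
                            index=pd.Index([], name="feature_id"))
    out = univariate.copy()
    if discriminant is not None:
        vip = pd.Series(discriminant.vip_, index=discriminant.feature_ids)
        out["vip"] = vip.reindex(out.index).round(2)
    else:
        out["vip"] = np.nan
    if mlr_table is not None and not mlr_table.empty:
        out["mlr_p"] = mlr_table["mlr_p"].reindex(out.index)
        out["mlr_q"] = mlr_table["mlr_q"].reindex(out.index)
        out["reliable"] = [
            "#" if q < 0.1 else "" for q in out["mlr_q"].fillna(np.inf)
        ]
    else:
        out["mlr_p"] = np.nan
        out["mlr_q"] = np.nan
        out["reliable"] = ""
    return _fmt(out)


def run_pipeline(config: PipelineConfig, simulate: bool = True) -> dict:
    """Run the full analysis; returns the manifest."""
    return StudyPipeline(config).run(simulate=simulate)
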