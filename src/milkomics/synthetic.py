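"""Synthetic cohort and multi-omics block generator.

Emulates the statistical structure of a preterm mother-infant milk
study: two growth groups defined by the tercile split of the change in
weight Z-score between birth and discharge, twin sets sharing a mother's
milk (some discordant for growth), ~20% non-secretor mothers, three
weekly milk samples per mother, pooled-QC technical replicates, and
per-block log-normal feature abundances with planted group-discriminant
features of configurable effect size.

Defaults reproduce the study design: 26 infants (22 mothers, four twin
sets of which two discordant), growth-group ΔZ-score modes at −0.48 and
−1.54 SD, faster:slower ratio 11:15, birth weight negatively correlated
with ΔZ-score, secretor probability 0.8.

All randomness flows from ``SyntheticConfig.seed``; regenerating with
the same config is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (
    CONFOUNDER_NAMES,
    CohortMetadata,
    FeatureTable,
    write_feature_meta,
    write_feature_table,
    write_metadata,
)

#: default features per block (post-QC-filter scale of the study data)
DEFAULT_BLOCK_SIZES = {
    "metabolome_pos": 120,
    "metabolome_neg": 100,
    "lipidome": 100,
    "glycome": 45,
    "faa": 22,
    "fa": 12,
}

DEFAULT_N_PLANTED = {
    "metabolome_pos": 10,
    "metabolome_neg": 10,
    "lipidome": 10,
    "glycome": 6,
    "faa": 4,
    "fa": 3,
}

#: monosaccharide composition codes (Hex Fuc HexNAc NeuAc) used to name
#: glycome features; isomer letters are appended as the block grows.
_HMO_BASE_CODES = (
    "2100", "2010", "2001", "3000", "3010", "3100", "3110", "3120",
    "3210", "3011", "3001", "3002", "3101", "4020", "4010", "4110",
    "4120", "4210", "4230", "4240", "4001", "4011", "4012", "4111",
    "5020", "5130", "5230", "5121", "5011", "5012",
)

FL2_FEATURE_ID = "2100a"  # 2'-fucosyllactose
LNFP1_FEATURE_ID = "3110a"  # lacto-N-fucopentaose I analogue

#: residue masses (Da) used for plausible HMO m/z values
_RESIDUE_MASS = {"hex": 162.0528, "fuc": 146.0579, "hexnac": 203.0794,
                 "neuac": 291.0954}


def hmo_code_catalog(p: int) -> list[str]:
    """``p`` distinct HMO feature ids: composition codes with isomer
    letters (2100a, 2010a, ..., 2100b, ...)."""
    codes = []
    for i in range(p):
        letter = chr(ord("a") + i // len(_HMO_BASE_CODES))
        codes.append(_HMO_BASE_CODES[i % len(_HMO_BASE_CODES)] + letter)
    return codes


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.

    ``n_dyads`` counts infants; twins share a mother, so the number of
    mothers is ``n_dyads - n_twin_sets``.  ``effect_size`` is the
    standardized group mean difference (Cohen's d) planted on the log10
    abundance scale.  ``week_corr`` is the within-mother share of each
    feature's log-scale variance (the study does not report it).
    """

    n_dyads: int = 26
    n_twin_sets: int = 4
    n_discordant_twin_sets: int = 2
    weeks: tuple = (2, 3, 4)
    block_sizes: dict = field(default_factory=lambda: dict(DEFAULT_BLOCK_SIZES))
    n_planted: dict = field(default_factory=lambda: dict(DEFAULT_N_PLANTED))
    effect_size: float = 1.0
    secretor_prob: float = 0.8
    qc_replicates: int = 8
    qc_cv: float = 0.15
    birthweight_corr: float = -0.4
    missing_rate: float = 0.02
    week_corr: float = 0.5
    faster_fraction: float = 11 / 26
    dz_modes: tuple = (-0.479, -1.538)  # faster / slower ΔZ medians (SD)
    dz_spreads: tuple = (0.28, 0.54)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_discordant_twin_sets <= self.n_twin_sets):
            raise ValueError("n_discordant_twin_sets must be <= n_twin_sets")
        if self.n_twin_sets * 2 > self.n_dyads:
            raise ValueError("infeasible twin configuration: "
                             "2 * n_twin_sets exceeds n_dyads")
        if not 0 <= self.secretor_prob <= 1:
            raise ValueError("secretor_prob must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.qc_cv <= 0:
            raise ValueError("qc_cv must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for name, p in self.block_sizes.items():
            if self.n_planted.get(name, 0) > p:
                raise ValueError(f"block {name!r}: n_planted exceeds block size")

    @property
    def n_mothers(self) -> int:
        return self.n_dyads - self.n_twin_sets


@dataclass
class PlantedTruth:
    """Ground truth of the generated study (for recovery tests)."""

    planted: dict  # block -> {feature_id: +1 / -1 (sign of faster-group shift)}
    fut2_feature_ids: list
    fl2_feature_id: str
    secretor_status: dict  # mother_id -> status

    def planted_ids(self, block: str) -> list[str]:
        return list(self.planted.get(block, {}))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


# ------------------------------------------------------------- cohort


def generate_cohort(config: SyntheticConfig) -> CohortMetadata:
    """Draw the cohort design: infants, groups, ΔZ-scores, confounders,
    twin links, maternal secretor status, and the sample grid."""
    rng = np.random.default_rng([config.seed, 0])
    n_inf = config.n_dyads
    n_twins = config.n_twin_sets
    mothers = [f"M{i + 1:03d}" for i in range(config.n_mothers)]

    infant_mother = []
    twin_set = []
    for i in range(n_twins):  # first mothers carry the twin sets
        infant_mother += [mothers[i], mothers[i]]
        twin_set += [f"T{i + 1}", f"T{i + 1}"]
    for i in range(n_twins, config.n_mothers):
        infant_mother.append(mothers[i])
        twin_set.append("")
    infants = [f"I{i + 1:03d}" for i in range(n_inf)]

    # groups: discordant twin sets one of each; remaining twin sets both
    # slower (as observed); singletons fill up to the target faster count
    groups = np.empty(n_inf, dtype=object)
    pos = 0
    for i in range(n_twins):
        if i < config.n_discordant_twin_sets:
            groups[pos], groups[pos + 1] = "faster", "slower"
        else:
            groups[pos] = groups[pos + 1] = "slower"
        pos += 2
    singles = np.arange(pos, n_inf)
    n_faster_target = int(round(config.faster_fraction * n_inf))
    n_faster_single = int(np.clip(
        n_faster_target - config.n_discordant_twin_sets, 0, singles.size))
    chosen = rng.permutation(singles)[:n_faster_single]
    groups[singles] = "slower"
    groups[chosen] = "faster"

    mu = dict(zip(("faster", "slower"), config.dz_modes))
    sd = dict(zip(("faster", "slower"), config.dz_spreads))
    dz = np.array([rng.normal(mu[g], sd[g]) for g in groups])

    # birth weight: target correlation with ΔZ-score
    r = float(np.clip(config.birthweight_corr, -1, 1))
    dz_std = (dz - dz.mean()) / (dz.std() if dz.std() > 0 else 1.0)
    bw = 1.45 + 0.30 * (r * dz_std + np.sqrt(1 - r ** 2) * rng.normal(size=n_inf))
    bw = np.clip(bw, 0.5, None)

    secretor = {
        m: ("secretor" if rng.random() < config.secretor_prob else "non-secretor")
        for m in mothers
    }

    conf = {
        "maternal_bmi": np.round(rng.normal(23.0, 4.0, n_inf), 2),
        "birth_weight": np.round(bw, 3),
        "gestational_age": np.round(np.clip(
            30.0 + 1.5 * rng.normal(size=n_inf) + 1.5 * (bw - 1.45), 27, 34), 1),
        "protein_intake": np.round(rng.normal(3.5, 0.4, n_inf), 2),
        "lipid_intake": np.round(rng.normal(6.0, 0.8, n_inf), 2),
        "energy_intake": np.round(rng.normal(120.0, 12.0, n_inf), 1),
        "parenteral_days": np.round(np.clip(rng.normal(12, 5, n_inf), 0, None), 0),
        "ventilation_days": np.round(np.clip(rng.normal(4, 3, n_inf), 0, None), 0),
        "hospital_stay_days": np.round(np.clip(rng.normal(50, 8, n_inf), 21, None), 0),
    }
    # twins share their mother's BMI
    for i in range(0, 2 * n_twins, 2):
        conf["maternal_bmi"][i + 1] = conf["maternal_bmi"][i]

    rows = []
    for i in range(n_inf):
        for w in config.weeks:
            row = {
                "sample_id": f"{infant_mother[i]}_W{w}",
                "mother_id": infant_mother[i],
                "infant_id": infants[i],
                "twin_set_id": twin_set[i],
                "week": w,
                "is_qc": False,
                "growth_group": groups[i],
                "delta_weight_zscore": round(float(dz[i]), 4),
                "secretor": secretor[infant_mother[i]],
            }
            row.update({k: conf[k][i] for k in CONFOUNDER_NAMES})
            rows.append(row)
    for k in range(config.qc_replicates):
        row = {
            "sample_id": f"QC{k + 1:02d}",
            "mother_id": pd.NA, "infant_id": pd.NA, "twin_set_id": pd.NA,
            "week": pd.NA, "is_qc": True, "growth_group": pd.NA,
            "delta_weight_zscore": np.nan, "secretor": pd.NA,
        }
        row.update({k2: np.nan for k2 in CONFOUNDER_NAMES})
        rows.append(row)
    df = pd.DataFrame(rows)
    df["week"] = df["week"].astype("Int64")
    return CohortMetadata(df)


# -------------------------------------------------------------- blocks


def _feature_meta(block: str, ids: list[str], rng) -> pd.DataFrame:
    meta = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
    if block == "glycome":
        meta["hmo_code"] = ids
        mz = []
        for code in ids:
            h, f, x, s = (int(c) for c in code[:4])
            mz.append(round(h * _RESIDUE_MASS["hex"] + f * _RESIDUE_MASS["fuc"]
                            + x * _RESIDUE_MASS["hexnac"]
                            + s * _RESIDUE_MASS["neuac"] + 20.0268, 4))
        meta["mz"] = mz
        meta["annotation_level"] = 1
    else:
        meta["mz"] = np.round(rng.uniform(60, 1100, len(ids)), 4)
        meta["annotation_level"] = rng.choice(
            np.array([1, 2, 0]), size=len(ids), p=[0.3, 0.4, 0.3])
    meta["rt"] = np.round(rng.uniform(0.5, 18.0, len(ids)), 2)
    return meta


def generate_blocks(metadata: CohortMetadata, config: SyntheticConfig):
    """Generate all omics blocks for a cohort.

    Per feature: log-normal abundance (log10 location U(4,7), scale
    U(0.1,0.5), matching the orders-of-magnitude spread of MS peak
    areas), a within-mother random effect carrying ``week_corr`` of the
    log-scale variance, a smooth multiplicative week drift, planted
    group shifts of ``effect_size`` standard deviations, a
    secretor-dependent collapse of 2'-FL-class features in non-secretor
    milk, pooled-QC technical replicates at CV ``qc_cv``, and
    below-detection zeros at ``missing_rate`` (biological samples only).

    Returns ``(tables, truth)``: block name -> :class:`FeatureTable`
    plus the :class:`PlantedTruth`.
    """
    unknown = set(config.block_sizes) - set(DEFAULT_BLOCK_SIZES)
    if unknown:
        raise ValueError(f"unknown block name(s) {sorted(unknown)}")
    bio = metadata.biological
    mother_rows = bio.drop_duplicates(["mother_id", "week"])
    mothers = list(dict.fromkeys(mother_rows["mother_id"]))
    weeks = sorted(set(int(w) for w in mother_rows["week"].dropna()))
    M, W = len(mothers), len(weeks)

    # per-mother growth score: +1 faster, -1 slower, 0 for discordant twins
    gnum = {"faster": 1.0, "slower": -1.0}
    mother_score = (
        bio.drop_duplicates(["mother_id", "infant_id"])
        .assign(score=lambda d: d["growth_group"].map(gnum))
        .groupby("mother_id")["score"].mean()
        .reindex(mothers)
        .to_numpy()
    )
    secretor = metadata.mother_secretor().reindex(mothers)
    nonsec = (secretor == "non-secretor").to_numpy()

    qc_ids = metadata.qc_sample_ids
    sample_ids = [f"{m}_W{w}" for m in mothers for w in weeks]

    icc = float(config.week_corr)
    tables: dict[str, FeatureTable] = {}
    planted_truth: dict[str, dict] = {}
    prefix = {"metabolome_pos": "MP", "metabolome_neg": "MN", "lipidome": "LP",
              "glycome": "HMO", "faa": "FAA", "fa": "FA"}
    for bi, (block, p) in enumerate(sorted(config.block_sizes.items())):
        rng = np.random.default_rng([config.seed, 1, bi])
        if block == "glycome":
            ids = hmo_code_catalog(p)
        else:
            ids = [f"{prefix[block]}_{j + 1:04d}" for j in range(p)]
        loc = rng.uniform(4.0, 7.0, p)
        sigma = rng.uniform(0.1, 0.5, p)
        slope = rng.normal(0.0, 0.05, p)
        if block == "glycome":
            # 2'-FL dominates secretor milk; LNFP-I is abundant too
            j2fl = ids.index(FL2_FEATURE_ID)
            jlnfp = ids.index(LNFP1_FEATURE_ID)
            loc[j2fl], sigma[j2fl] = 6.9, 0.15
            loc[jlnfp], sigma[jlnfp] = 6.3, 0.2

        n_planted = int(config.n_planted.get(block, 0))
        planted_idx = rng.choice(p, size=n_planted, replace=False) if n_planted else []
        signs = rng.choice([-1.0, 1.0], size=n_planted)

        mother_eff = rng.normal(0.0, 1.0, (M, p)) * (sigma * np.sqrt(icc))
        resid = rng.normal(0.0, 1.0, (M, W, p)) * (sigma * np.sqrt(1 - icc))
        wk = np.array(weeks, dtype=float) - 3.0
        log10v = (loc[None, None, :] + mother_eff[:, None, :] + resid
                  + slope[None, None, :] * wk[None, :, None])
        for j, s in zip(planted_idx, signs):
            log10v[:, :, j] += (s * config.effect_size * sigma[j] / 2.0
                                * mother_score[:, None])
        if block == "glycome":
            fut2_idx = [ids.index(FL2_FEATURE_ID), ids.index(LNFP1_FEATURE_ID)]
            for j in fut2_idx:
                log10v[nonsec, :, j] -= 2.5  # "very low or no detectable" levels

        values = np.power(10.0, log10v).reshape(M * W, p)
        if config.missing_rate > 0:
            mask = rng.random(values.shape) < config.missing_rate
            if block == "glycome":
                mask[:, [ids.index(FL2_FEATURE_ID)]] = False
            values[mask] = 0.0

        pooled = log10v.reshape(M * W, p).mean(axis=0)
        sig_ln = np.sqrt(np.log1p(config.qc_cv ** 2))
        qc_vals = (np.power(10.0, pooled)[None, :]
                   * np.exp(rng.normal(0.0, sig_ln, (len(qc_ids), p))
                            - sig_ln ** 2 / 2.0))

        df = pd.DataFrame(np.vstack([values, qc_vals]),
                          index=pd.Index(sample_ids + qc_ids, name="sample_id"),
                          columns=ids)
        tables[block] = FeatureTable(block, df, _feature_meta(block, ids, rng))
        planted_truth[block] = {ids[j]: int(s) for j, s in zip(planted_idx, signs)}

    truth = PlantedTruth(
        planted=planted_truth,
        fut2_feature_ids=[FL2_FEATURE_ID, LNFP1_FEATURE_ID],
        fl2_feature_id=FL2_FEATURE_ID,
        secretor_status={m: str(secretor[m]) for m in mothers},
    )
    return tables, truth


def simulate_study(config: SyntheticConfig, outdir) -> tuple:
    """Materialize a full synthetic study directory.

    Writes ``samples.csv``, one ``<block>.csv`` + ``features_<block>.csv``
    per block, and ``planted_truth.json``; returns
    ``(metadata, tables, truth)``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata = generate_cohort(config)
    tables, truth = generate_blocks(metadata, config)
    write_metadata(metadata, outdir / "samples.csv")
    for name, table in tables.items():
        write_feature_table(table, outdir / f"{name}.csv")
        write_feature_meta(table, outdir / f"features_{name}.csv")
    truth.to_json(outdir / "planted_truth.json")
    return metadata, tables, truth
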