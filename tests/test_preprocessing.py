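"""Scaling, QC filtering, HMO transforms and secretor classification.

Hand-computed and enumeration oracles back every non-trivial check.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milkomics.preprocessing import (
    HmoComposition,
    autoscale,
    classify_secretor,
    default_pseudocount,
    largest_gap_split,
    log_pareto_scale,
    parse_hmo_code,
    qc_rsd_filter,
    relative_hmo_abundance,
    secretor_stratified_center,
)
from milkomics.io_tables import FeatureTable
from milkomics.synthetic import (
    FL2_FEATURE_ID,
    SyntheticConfig,
    generate_blocks,
    generate_cohort,
)


def _table(arr, block="faa", prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return FeatureTable(block, pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"f{j}" for j in range(arr.shape[1])]))


class TestQcRsdFilter:
    def _metadata_for(self, qc_ids):
        # minimal stand-in: only qc_sample_ids is consulted by the filter
        class _Md:
            qc_sample_ids = list(qc_ids)
        return _Md()

    def test_examples(self):
        # f0: constant (RSD 0, kept); f1: sd/mean = 50/100 = 0.5 (removed)
        qc = np.array([[100.0, 50.0], [100.0, 100.0], [100.0, 150.0]])
        bio = np.full((2, 2), 10.0)
        t = _table(np.vstack([bio, qc]))
        md = self._metadata_for(["s2", "s3", "s4"])
        out = qc_rsd_filter(t, md, cutoff=0.30)
        assert out.feature_ids == ["f0"]

    def test_infinite_cutoff_is_identity(self):
        qc = np.array([[1.0, 9.0], [5.0, 1.0], [9.0, 5.0]])
        t = _table(np.vstack([np.ones((2, 2)), qc]))
        md = self._metadata_for(["s2", "s3", "s4"])
        out = qc_rsd_filter(t, md, cutoff=np.inf)
        assert out.feature_ids == t.feature_ids

    def test_never_removes_below_cutoff(self, rng):
        qc = np.exp(rng.normal(0, 0.05, (10, 30))) * 1e5
        t = _table(np.vstack([np.ones((2, 30)), qc]))
        md = self._metadata_for([f"s{i}" for i in range(2, 12)])
        rsd = qc.std(axis=0, ddof=1) / qc.mean(axis=0)
        out = qc_rsd_filter(t, md, cutoff=0.06)
        expected = [f"f{j}" for j in np.where(rsd <= 0.06)[0]]
        assert out.feature_ids == expected

    def test_too_few_qc_rows_errors(self):
        t = _table(np.ones((4, 2)))
        with pytest.raises(ValueError, match="QC"):
            qc_rsd_filter(t, self._metadata_for(["s0", "s1"]), 0.3)


class TestRelativeHmo:
    def test_proportions(self):
        out = relative_hmo_abundance(_table([[2.0, 3.0, 5.0]], "glycome"))
        assert np.allclose(out.values.to_numpy(), [[20, 30, 50]])

    def test_rows_sum_to_100(self, rng):
        out = relative_hmo_abundance(
            _table(rng.lognormal(5, 1, (12, 9)), "glycome"))
        assert np.allclose(out.values.sum(axis=1), 100, atol=1e-9)

    def test_single_feature_block(self):
        out = relative_hmo_abundance(_table([[3.0], [7.0]], "glycome"))
        assert np.allclose(out.values.to_numpy(), 100.0)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="s1"):
            relative_hmo_abundance(_table([[1.0, 2.0], [0.0, 0.0]], "glycome"))


class TestParseHmoCode:
    @pytest.mark.parametrize("code,expect", [
        ("3210", dict(hex=3, fuc=2, hexnac=1, neuac=0, isomer=None,
                      fucosylation_class="di", sialylated=False)),
        ("4230b", dict(hex=4, fuc=2, hexnac=3, neuac=0, isomer="b",
                       fucosylation_class="di", sialylated=False)),
        ("3000", dict(hex=3, fuc=0, hexnac=0, neuac=0, isomer=None,
                      fucosylation_class="neutral-unfucosylated",
                      sialylated=False)),
        ("3012", dict(hex=3, fuc=0, hexnac=1, neuac=2, isomer=None,
                      fucosylation_class="neutral-unfucosylated",
                      sialylated=True)),
    ])
    def test_examples(self, code, expect):
        c = parse_hmo_code(code)
        for k, v in expect.items():
            assert getattr(c, k) == v

    @pytest.mark.parametrize("bad", ["", "12", "12345", "12a4", "4230B"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_hmo_code(bad)

    @given(st.integers(0, 9), st.integers(0, 9), st.integers(0, 9),
           st.integers(0, 9), st.sampled_from([None, "a", "b", "c"]))
    @settings(max_examples=50, deadline=None)
    def test_format_parse_round_trip(self, h, f, x, s, iso):
        code = HmoComposition(h, f, x, s, iso).format()
        assert parse_hmo_code(code).format() == code


class TestScalers:
    def test_log_pareto_column_means_zero(self, rng):
        out, _ = log_pareto_scale(rng.lognormal(5, 1, (20, 6)))
        assert np.allclose(out.mean(axis=0), 0, atol=1e-10)

    def test_log_pareto_output_variance_equals_sd(self, rng):
        arr = rng.lognormal(5, 1, (30, 5))
        out, spec = log_pareto_scale(arr)
        # dividing by sqrt(sd) leaves variance equal to sd
        assert np.allclose(out.var(axis=0, ddof=1), spec.sd_, rtol=1e-10)

    def test_log_pareto_hand_computed_triplet(self):
        # log10(x+1) of (10,100,1000) = (1.0414, 2.0043, 3.0004)
        x = np.array([[10.0], [100.0], [1000.0]])
        logged = np.log10(x + 1).ravel()
        sd = logged.std(ddof=1)
        expected = (logged - logged.mean()) / np.sqrt(sd)
        out, _ = log_pareto_scale(x, pseudocount=1.0)
        assert np.allclose(out.to_numpy().ravel(), expected)

    def test_log_pareto_requires_pseudocount_with_zeros(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log_pareto_scale(np.array([[0.0, 1.0], [2.0, 3.0]]),
                             pseudocount=0.0)

    def test_default_pseudocount_half_min_nonzero(self):
        arr = pd.DataFrame([[0.0, 8.0], [4.0, 2.0]])
        assert default_pseudocount(arr) == 1.0

    def test_autoscale_unit_variance(self, rng):
        out, _ = autoscale(rng.normal(3, 2, (25, 4)))
        assert np.allclose(out.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(out.var(axis=0, ddof=1), 1, rtol=1e-10)

    def test_autoscale_matches_direct_formula(self, rng):
        arr = rng.normal(0, 5, (15, 3))
        out, _ = autoscale(arr)
        direct = (arr - arr.mean(0)) / arr.std(0, ddof=1)
        assert np.allclose(out.to_numpy(), direct)

    def test_constant_column_guarded(self):
        arr = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            out, spec = autoscale(arr)
        assert np.allclose(out.iloc[:, 0], 0)
        assert spec.scale_[0] == 1.0

    @pytest.mark.parametrize("scaler", [log_pareto_scale, autoscale])
    def test_inverse_round_trip(self, scaler, rng):
        arr = rng.lognormal(4, 0.5, (18, 6))
        out, spec = scaler(arr)
        assert np.allclose(spec.inverse(out.to_numpy()), arr, rtol=1e-8)

    def test_transform_on_new_data_uses_stored_stats(self, rng):
        arr = rng.lognormal(4, 0.5, (18, 6))
        out, spec = log_pareto_scale(arr)
        again = spec.transform(arr)
        assert np.allclose(again, out.to_numpy())


class TestSecretor:
    def test_largest_gap_split_matches_enumeration(self):
        vals = np.array([0.01, 0.02, 11.0, 12.0, 13.0])
        # oracle: best split point by enumerating all, scoring by gap
        v = np.sort(vals)
        gaps = np.diff(v)
        best = int(np.argmax(gaps))
        expected_threshold = (v[best] + v[best + 1]) / 2
        thr, ratio = largest_gap_split(vals)
        assert thr == pytest.approx(expected_threshold)
        assert ratio > 3

    def test_homogeneous_values_not_split(self):
        vals = np.array([10.0, 11.0, 12.5, 13.0, 14.0, 15.5])
        thr, _ = largest_gap_split(vals)
        assert thr is None

    def _study(self, seed, n_mothers=50, secretor_prob=0.8):
        cfg = SyntheticConfig(
            n_dyads=n_mothers, n_twin_sets=0, n_discordant_twin_sets=0,
            secretor_prob=secretor_prob, missing_rate=0.0,
            block_sizes={"glycome": 45}, n_planted={"glycome": 0}, seed=seed)
        md = generate_cohort(cfg)
        tabs, truth = generate_blocks(md, cfg)
        return md, tabs["glycome"], truth

    def test_recovery_on_synthetic_truth(self):
        hits = total = 0
        for seed in (31, 32, 33):
            md, glycome, truth = self._study(seed)
            status = classify_secretor(glycome, md, FL2_FEATURE_ID)
            true = pd.Series(truth.secretor_status)
            hits += (status == true.loc[status.index]).sum()
            total += len(status)
        assert hits / total >= 0.95

    def test_all_secretors_all_called_secretor(self):
        md, glycome, truth = self._study(seed=41, secretor_prob=1.0)
        status = classify_secretor(glycome, md, FL2_FEATURE_ID)
        assert (status == "secretor").all()

    def test_too_few_mothers_errors(self):
        md, glycome, _ = self._study(seed=42, n_mothers=2)
        with pytest.raises(ValueError, match="3 mothers"):
            classify_secretor(glycome, md, FL2_FEATURE_ID)


class TestStratifiedCenter:
    def test_per_stratum_means_zero(self, rng):
        X = rng.normal(5, 2, (20, 4))
        statuses = np.array(["a"] * 12 + ["b"] * 8)
        out = secretor_stratified_center(X, statuses)
        for s in ("a", "b"):
            assert np.allclose(out[statuses == s].mean(axis=0), 0, atol=1e-10)

    def test_single_stratum_equals_plain_centering(self, rng):
        X = rng.normal(0, 1, (10, 3))
        out = secretor_stratified_center(X, np.repeat("a", 10))
        assert np.allclose(out, X - X.mean(axis=0))

    def test_singleton_stratum_warned_and_zeroed(self, rng):
        X = rng.normal(0, 1, (5, 2))
        statuses = np.array(["a", "a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="single sample"):
            out = secretor_stratified_center(X, statuses)
        assert np.allclose(out.iloc[4], 0)

    def test_centering_removes_secretor_clustering(self):
        # after stratified centring the 2'-FL bimodality must vanish
        cfg = SyntheticConfig(
            n_dyads=40, n_twin_sets=0, n_discordant_twin_sets=0,
            missing_rate=0.0, block_sizes={"glycome": 45},
            n_planted={"glycome": 0}, seed=55)
        md = generate_cohort(cfg)
        tabs, truth = generate_blocks(md, cfg)
        rel = relative_hmo_abundance(tabs["glycome"])
        bio = md.biological.drop_duplicates(["mother_id", "sample_id"])
        X = rel.values.loc[bio["sample_id"]]
        statuses = bio["mother_id"].map(
            pd.Series(truth.secretor_status)).to_numpy()
        assert len(set(statuses)) == 2
        j = rel.feature_ids.index(FL2_FEATURE_ID)
        _, ratio_before = largest_gap_split(
            X.groupby(bio["mother_id"].to_numpy()).mean().iloc[:, j].to_numpy())
        centred = secretor_stratified_center(X, statuses)
        per_mother = centred.groupby(bio["mother_id"].to_numpy()).mean()
        thr, _ = largest_gap_split(per_mother.iloc[:, j].to_numpy())
        assert ratio_before >= 3 and thr is None
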