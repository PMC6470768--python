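"""Multi-block fusion: superblock bookkeeping, UPCA reductions, MB-PLS
against the concatenated-PLS oracle, block importances and
loading-based selection."""

import numpy as np
import pandas as pd
import pytest

from milkomics.fusion import (
    MBPLS,
    assemble_superblock,
    select_by_loadings,
    upca,
)
from milkomics.pls import PLS, fit_pca, loo_cv
from milkomics.preprocessing import autoscale

from conftest import two_group_data


def _blocks(rng, n=20, widths=(6, 9), effect=0.0, signal_block=0):
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
    out = {}
    for i, p in enumerate(widths):
        X = rng.standard_normal((n, p))
        if effect and i == signal_block:
            X[labels == "b", : max(1, p // 2)] += effect
        out[f"b{i}"] = pd.DataFrame(
            X, index=[f"s{k}" for k in range(n)],
            columns=[f"x{i}_{j}" for j in range(p)])
    return out, labels


class TestSuperblock:
    def test_widths_and_contiguous_ranges(self, rng):
        widths = (68, 143, 79, 21, 12)
        blocks, _ = _blocks(rng, n=10, widths=widths)
        sb = assemble_superblock(blocks)
        assert sb.n_features == sum(widths)
        start = 0
        for name, p in zip(sb.block_names, widths):
            assert sb.ranges[name] == slice(start, start + p)
            start += p

    def test_inverse_sqrt_weight_equalizes_block_variance(self, rng):
        blocks, _ = _blocks(rng, n=40, widths=(5, 20))
        scaled = {n: autoscale(df)[0] for n, df in blocks.items()}
        sb = assemble_superblock(scaled)  # default 1/sqrt(p_b)
        var = {n: sb.block_view(n).to_numpy().var(ddof=1, axis=0).sum()
               for n in sb.block_names}
        assert var["b0"] == pytest.approx(var["b1"], rel=1e-8)

    def test_single_block_weight_one_identity(self, rng):
        blocks, _ = _blocks(rng, n=8, widths=(4,))
        sb = assemble_superblock({"b0": blocks["b0"]}, weights={"b0": 1.0})
        assert np.allclose(sb.matrix.to_numpy(), blocks["b0"].to_numpy())

    def test_misaligned_samples_rejected(self, rng):
        blocks, _ = _blocks(rng, n=6, widths=(3, 3))
        blocks["b1"].index = [f"z{k}" for k in range(6)]
        with pytest.raises(ValueError, match="misalignment"):
            assemble_superblock(blocks)


class TestUpca:
    def test_two_way_input_equals_pca(self, rng):
        X = rng.standard_normal((12, 7))
        a = upca(X, 3)
        b = fit_pca(X, 3)
        assert np.allclose(a.scores_, b.scores_)
        assert np.allclose(a.explained_variance_ratio_,
                           b.explained_variance_ratio_)

    def test_replicated_weeks_preserve_variance_fractions(self, rng):
        X = rng.standard_normal((15, 6))
        tensor = np.stack([X, X, X], axis=1)  # identical weeks
        t = upca(tensor, 4)
        s = fit_pca(X, 4)
        assert np.allclose(t.explained_variance_ratio_,
                           s.explained_variance_ratio_, atol=1e-10)

    def test_component_pair_variance_report(self, rng):
        res = upca(rng.standard_normal((20, 10)), 4)
        pair = res.explained_variance_ratio_[2:4].sum()
        assert 0 < pair < 1

    def test_tensor_with_nan_rejected(self, rng):
        tensor = rng.standard_normal((5, 3, 4))
        tensor[0, 1, 2] = np.nan
        with pytest.raises(ValueError, match="week coverage"):
            upca(tensor, 2)


class TestMBPLS:
    def test_super_scores_match_concatenated_pls(self, rng):
        """The block-wise NIPALS with super-score deflation must agree
        with ordinary PLS on the weighted concatenated superblock."""
        blocks, labels = _blocks(rng, n=24, widths=(5, 12, 8), effect=1.0)
        res = MBPLS(blocks, labels, n_components=3).fit()
        sb = assemble_superblock(blocks)
        from milkomics.pls import dummy_matrix
        Y, _ = dummy_matrix(labels)
        ref = PLS(sb.matrix.to_numpy(), Y - Y.mean(0), 3).fit()
        for a in range(3):
            r = np.corrcoef(res.super_scores_[:, a], ref.x_scores_[:, a])[0, 1]
            assert abs(r) >= 0.999

    def test_super_score_is_weighted_block_score_sum(self, rng):
        blocks, labels = _blocks(rng, n=16, widths=(4, 6), effect=0.8)
        res = MBPLS(blocks, labels, n_components=2).fit()
        for a in range(2):
            t = np.zeros(16)
            for i, b in enumerate(res.block_names):
                t += res.super_weights_[i, a] * res.block_scores_[b][:, a]
            assert np.allclose(t, res.super_scores_[:, a], atol=1e-8)
            assert np.linalg.norm(res.super_weights_[:, a]) == \
                pytest.approx(1.0)

    def test_importances_sum_to_one(self, rng):
        blocks, labels = _blocks(rng, n=20, widths=(5, 7, 3), effect=1.0)
        res = MBPLS(blocks, labels, n_components=2).fit()
        assert np.allclose(res.block_importance_.sum(axis=0), 1.0, atol=1e-8)

    def test_signal_block_dominates_importance(self, rng):
        blocks, labels = _blocks(rng, n=40, widths=(10, 10), effect=2.0,
                                 signal_block=1)
        res = MBPLS(blocks, labels, n_components=2).fit()
        assert res.block_importance_[1, 0] >= 0.8

    def test_identical_blocks_split_importance_evenly(self, rng):
        X = rng.standard_normal((20, 6))
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        X[labels == "b", :2] += 1.5
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(6)])
        res = MBPLS({"b0": df, "b1": df.copy()}, labels, n_components=1).fit()
        assert res.block_importance_[0, 0] == pytest.approx(0.5, abs=0.05)
        assert res.block_importance_[1, 0] == pytest.approx(0.5, abs=0.05)

    def test_component_oriented_to_positive_class(self, rng):
        blocks, labels = _blocks(rng, n=30, widths=(8, 8), effect=1.5)
        res = MBPLS(blocks, labels, n_components=2, positive_class="b").fit()
        assert res.super_scores_[labels == "b", 0].mean() > \
            res.super_scores_[labels == "a", 0].mean()

    def test_deflation_conserves_block_variance(self, rng):
        blocks, labels = _blocks(rng, n=12, widths=(4, 5), effect=1.0)
        A = 8  # enough components to approach full rank
        res = MBPLS(blocks, labels, n_components=min(A, 11)).fit()
        # explained + residual variance accounts for all of each block
        for i, b in enumerate(res.block_names):
            Xw = (blocks[b].to_numpy() * res.applied_weights[b])
            Xc = Xw - Xw.mean(0)
            recon = sum(np.outer(res.super_scores_[:, a],
                                 res.block_loadings_[b][:, a])
                        for a in range(res.n_components))
            resid_frac = ((Xc - recon) ** 2).sum() / (Xc ** 2).sum()
            assert abs(res.r2x_block_.iloc[i].sum() + resid_frac - 1) <= 1e-8


class TestSelection:
    def test_all_features_returned_ranked(self, rng):
        blocks, labels = _blocks(rng, n=20, widths=(4, 5), effect=1.0)
        res = MBPLS(blocks, labels, n_components=2).fit()
        out = select_by_loadings(res, k=9)
        assert len(out) == 9
        assert (out["loading_norm"].diff().dropna() <= 1e-12).all()

    def test_zero_loading_feature_ranks_last(self, rng):
        blocks, labels = _blocks(rng, n=20, widths=(4, 4), effect=1.5)
        blocks["b0"]["x0_3"] = 0.0  # constant: centred to exactly zero
        res = MBPLS(blocks, labels, n_components=2).fit()
        out = select_by_loadings(res)
        assert out.iloc[-1]["feature_id"] == "x0_3"

    def test_planted_features_fill_top_of_ranking(self):
        r = np.random.default_rng(99)
        blocks, labels = _blocks(r, n=40, widths=(10, 30), effect=2.0,
                                 signal_block=0)
        res = MBPLS(blocks, labels, n_components=2).fit()
        top10 = set(select_by_loadings(res, k=10)["feature_id"])
        planted = {f"x0_{j}" for j in range(5)}  # b0's shifted half
        assert len(top10 & planted) >= 4


class TestFusionRecovery:
    def test_week3_fusion_loo_error_low(self):
        """Planted-signal fusion study: LOO error of the MB-PLS class
        assignment <= 0.15 averaged over 10 seeds."""
        errs = []
        for seed in range(10):
            r = np.random.default_rng(300 + seed)
            blocks, labels = _blocks(r, n=26, widths=(20, 15, 10),
                                     effect=1.6, signal_block=0)
            # add signal to a second block too (multi-omic signal)
            blocks["b2"].iloc[labels == "b", :4] += 1.2
            X = np.hstack([df.to_numpy() for df in blocks.values()])
            widths = [df.shape[1] for df in blocks.values()]

            def fit_predict(X_tr, y_tr, X_te, widths=widths):
                tr, te, c0 = {}, {}, 0
                for i, p in enumerate(widths):
                    tr[f"b{i}"] = pd.DataFrame(X_tr[:, c0:c0 + p])
                    te[f"b{i}"] = pd.DataFrame(X_te[:, c0:c0 + p])
                    c0 += p
                model = MBPLS(tr, y_tr, n_components=2).fit()
                return model.predict(te)

            errs.append(loo_cv(X, labels, fit_predict).error_rate)
        assert np.mean(errs) <= 0.15
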