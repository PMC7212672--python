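"""Module scoring, logistic classification, regression correction,
bootstrap silhouette."""

import warnings

import numpy as np
import pandas as pd
import pytest

import timedrift as td
from timedrift.containers import ConfigError
from timedrift.score import _rank_auc
from tests.conftest import make_norm


def pair_counting_auc(scores, labels):
    """AUC by explicit concordant-pair counting (ties worth one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total


class TestModuleScore:
    def test_degenerate_control_sampling_hand_computed(self):
        # 6 genes, n_bins=1, controls = all 4 non-signature genes:
        # score = mean(sig rows) - mean(other rows), per cell
        rng = np.random.default_rng(0)
        vals = rng.normal(2, 1, size=(6, 5))
        norm = make_norm(vals)
        s = td.module_score(norm, ["g0", "g1"], n_bins=1, n_ctrl=4, seed=0)
        expected = vals[:2].mean(axis=0) - vals[2:].mean(axis=0)
        np.testing.assert_allclose(s.values, expected, atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(40, 20))
        s1 = td.module_score(make_norm(vals), ["g0", "g3"], seed=5)
        s2 = td.module_score(make_norm(vals + 7.0), ["g0", "g3"], seed=5)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-10)

    def test_null_signature_centered_at_zero(self):
        # signature genes exchangeable with controls -> scores center at 0
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(200, 300))
        s = td.module_score(make_norm(vals), [f"g{i}" for i in range(10)],
                            seed=3)
        assert abs(s.mean()) < 0.05

    def test_reproducible_given_seed(self, planted_norm):
        norm, _ = planted_norm
        sig = [f"gene_{i:05d}" for i in range(20, 40)]
        s1 = td.module_score(norm, sig, seed=11)
        s2 = td.module_score(norm, sig, seed=11)
        pd.testing.assert_series_equal(s1, s2)

    def test_absent_genes_warn_all_absent_raise(self, planted_norm):
        norm, _ = planted_norm
        with pytest.warns(UserWarning, match="absent"):
            td.module_score(norm, ["gene_00001", "nope"], seed=0)
        with pytest.raises(ConfigError):
            td.module_score(norm, ["nope"], seed=0)


class TestClassifier:
    def test_auc_by_pair_counting(self):
        # scores [1,2,3,4], labels [0,1,0,1]: 3 of 4 pairs concordant
        model = td.fit_classifier([1, 2, 3, 4], [0, 1, 0, 1])
        assert model.train_auc == pytest.approx(0.75)
        assert pair_counting_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_perfect_separation_capped_not_fatal(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = td.fit_classifier([0, 0.1, 5, 5.1], [0, 0, 1, 1])
        assert model.train_auc == 1.0
        assert np.isfinite(model.slope)
        probs = model.predict_proba([0, 5.1])
        assert probs[0] < 0.5 < probs[1]

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=2000)
        y = rng.random(2000) < 0.5
        model = td.fit_classifier(s, y)
        assert model.train_auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            td.fit_classifier([1, 2], [1, 1])


class TestPredictAuc:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=200)
        y = s + rng.normal(size=200) > 0
        a1, _ = td.predict_auc(None, s, y)
        a2, _ = td.predict_auc(None, np.exp(3 * s), y)
        assert a1 == pytest.approx(a2)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pair_counting_oracle_small_inputs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 11))
        s = np.round(rng.normal(size=n), 1)  # rounding forces some ties
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert _rank_auc(s, y) == pytest.approx(pair_counting_auc(s, y))

    def test_model_transform_preserves_auc(self, planted_norm):
        norm, _ = planted_norm
        sig = td.define_signature(
            td.wilcoxon_dea(norm, norm.cell_meta["affected"].values)
        )
        s = td.module_score(norm, sig.index, seed=1)
        y = norm.cell_meta["affected"].values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = td.fit_classifier(s, y)
        auc_model, roc = td.predict_auc(model, s, y)
        assert auc_model == pytest.approx(model.train_auc)
        assert {"fpr", "tpr", "threshold"} <= set(roc.columns)


class TestRegressOut:
    def test_uncorrelated_gene_becomes_zscore(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(3, 2, size=(1, 50))
        score = np.tile([1.0, -1.0], 25)  # orthogonal to nothing particular
        vals -= (vals @ score)[:, None] * score[None, :] / (score @ score)
        norm = make_norm(vals)
        out = td.regress_out_score(norm, score, np.zeros(50))
        z = (vals[0] - vals[0].mean()) / vals[0].std()
        np.testing.assert_allclose(out[0], z, atol=1e-10)

    def test_perfect_fit_gives_zeros(self):
        score = np.linspace(-1, 1, 30)
        norm = make_norm((2 * score)[None, :])
        out = td.regress_out_score(norm, score, np.zeros(30))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_within_group_orthogonality(self, planted_norm):
        norm, _ = planted_norm
        sig = [f"gene_{i:05d}" for i in range(10)]
        s = td.module_score(norm, sig, seed=2).values
        ct = norm.cell_meta["cell_type"].values
        out = td.regress_out_score(norm, s, ct)
        for g in pd.unique(ct):
            idx = ct == g
            xc = s[idx] - s[idx].mean()
            yc = out[:, idx] - out[:, idx].mean(axis=1, keepdims=True)
            num = np.abs(yc @ xc)
            den = np.sqrt((yc ** 2).sum(axis=1)) * np.linalg.norm(xc)
            r = num / np.where(den == 0, 1.0, den)
            assert r.max() < 1e-8

    def test_small_group_rejected(self):
        norm = make_norm(np.ones((2, 5)))
        with pytest.raises(ConfigError, match="tiny"):
            td.regress_out_score(
                norm, np.arange(5.0), ["a", "a", "a", "tiny", "tiny"]
            )


class TestBootstrapSilhouette:
    @pytest.fixture()
    def scored(self, planted_norm):
        norm, _ = planted_norm
        sig = td.define_signature(
            td.wilcoxon_dea(norm, norm.cell_meta["affected"].values)
        )
        s = td.module_score(norm, sig.index, seed=1)
        return norm, s

    def test_grid_contract_and_direction(self, scored):
        norm, s = scored
        boot = td.bootstrap_silhouette(
            norm, s.values, norm.cell_meta["affected"].values,
            norm.cell_meta["cell_type"].values,
            pct_grid=(20, 50, 80), n_cells=150, reps=4, seed=7,
        )
        assert len(boot) == 3 * 4
        assert set(boot["pct"]) == {20, 50, 80}
        g = boot.groupby("pct").mean()
        assert (g["silhouette_after"] < g["silhouette_before"]).all()

    def test_random_labels_silhouette_near_zero(self, planted_norm):
        norm, _ = planted_norm
        rng = np.random.default_rng(8)
        fake = rng.random(norm.n_cells) < 0.5
        s = rng.normal(size=norm.n_cells)
        boot = td.bootstrap_silhouette(
            norm, s, fake, pct_grid=(50,), n_cells=120, reps=4, seed=9,
        )
        assert abs(boot["silhouette_before"].mean()) < 0.05
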