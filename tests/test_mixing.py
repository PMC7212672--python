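"""kBET mixing statistic, proportionality similarity, variance attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import timedrift as td
from timedrift.containers import ConfigError
from tests.conftest import make_norm


class TestKbet:
    def test_single_label_full_acceptance(self):
        rng = np.random.default_rng(0)
        res = td.kbet(rng.normal(size=(100, 3)), np.zeros(100), k=10)
        assert res.acceptance_rate == 100.0
        assert (res.stats["chi2"] == 0).all()
        assert res.rejection_rate == 0.0

    def test_separated_batches_rejected(self):
        # two far-apart clusters: every neighborhood is pure, chi2 large
        rng = np.random.default_rng(1)
        emb = np.vstack([rng.normal(0, 1, (100, 2)),
                         rng.normal(100, 1, (100, 2))])
        labels = np.repeat([0, 1], 100)
        res = td.kbet(emb, labels, k=15)
        assert res.acceptance_rate == 0.0
        # pure neighborhood oracle: chi2 = sum (obs-exp)^2/exp via scipy
        obs = np.array([15, 0])
        exp = 15 * np.array([0.5, 0.5])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, 1) < 0.05
        np.testing.assert_allclose(res.stats["chi2"], chi2)

    def test_shuffled_labels_acceptance_near_95(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(1500, 8))
        labels = rng.integers(0, 2, size=1500)
        res = td.kbet(emb, labels, n_test=1000, seed=3)
        assert res.acceptance_rate == pytest.approx(95, abs=3)

    def test_acceptance_plus_rejection_100(self):
        rng = np.random.default_rng(4)
        res = td.kbet(rng.normal(size=(200, 4)),
                      rng.integers(0, 3, 200), k=12)
        assert res.acceptance_rate + res.rejection_rate == 100.0

    def test_default_k_heuristic(self):
        assert td.mixing.default_k(np.repeat([0, 1], 100)) == 25
        assert td.mixing.default_k(np.repeat([0, 1], 10)) == 10

    def test_errors_and_warning(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(50, 2))
        with pytest.raises(ConfigError):
            td.kbet(emb, np.zeros(50), k=60)
        with pytest.warns(UserWarning, match="neighborhood"):
            td.kbet(emb, np.arange(50) % 5, k=3)


class TestProportionality:
    def test_self_similarity_one(self):
        rng = np.random.default_rng(0)
        norm = make_norm(rng.normal(size=(30, 4)))
        rho = td.proportionality_matrix(norm)
        np.testing.assert_allclose(np.diag(rho.values), 1.0)

    def test_negated_cell_gives_minus_one(self):
        x = np.array([1.0, -2.0, 1.0])  # zero-mean
        norm = make_norm(np.column_stack([x, -x]))
        rho = td.proportionality_matrix(norm)
        assert rho.values[0, 1] == pytest.approx(-1.0)

    def test_hand_arithmetic_population_convention(self):
        # x=[1,2,3], y=2x: cov=2 var(x), so rho = 2*2v/(v+4v) = 4/5
        # (identical under sample or population convention)
        norm = make_norm(np.column_stack([[1, 2, 3], [2, 4, 6]]))
        rho = td.proportionality_matrix(norm)
        assert rho.values[0, 1] == pytest.approx(0.8)

    def test_symmetric_bounded(self, planted_norm):
        norm, _ = planted_norm
        sub = td.downsample_balanced(
            norm, norm.cell_meta["time_h"].values, n_per_stratum=40, seed=0
        )
        rho = td.proportionality_matrix(sub)
        v = rho.values
        np.testing.assert_allclose(v, v.T, atol=1e-10)
        assert np.nanmin(v) >= -1.0 and np.nanmax(v) <= 1.0
        assert rho.attrs.get("ordering") == "cell_type,time_h"

    def test_constant_cell_reported_missing(self):
        norm = make_norm(np.column_stack([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        rho = td.proportionality_matrix(norm)
        assert np.isnan(rho.values[0, 0]) and np.isnan(rho.values[0, 1])
        assert rho.values[1, 1] == 1.0


class TestDownsample:
    def test_undersized_stratum_kept_whole(self):
        norm = make_norm(np.ones((3, 30)))
        labels = np.repeat(["a"], 30)
        sub = td.downsample_balanced(norm, labels, n_per_stratum=50, seed=1)
        assert sub.n_cells == 30

    def test_exact_output_size(self):
        norm = make_norm(np.ones((3, 800)))
        labels = np.repeat(list("abcd"), 200)
        sub = td.downsample_balanced(norm, labels, n_per_stratum=50, seed=1)
        assert sub.n_cells == 200

    def test_deterministic_given_seed(self, planted_norm):
        norm, _ = planted_norm
        labels = norm.cell_meta["time_h"].values
        s1 = td.downsample_balanced(norm, labels, 30, seed=5)
        s2 = td.downsample_balanced(norm, labels, 30, seed=5)
        assert list(s1.barcodes) == list(s2.barcodes)


class TestVarianceR2:
    def test_covariate_encoding_gives_one(self):
        labels = np.repeat(["a", "b"], 5)
        vals = np.where(labels == "a", 1.0, 5.0)[None, :]
        r2 = td.variance_r2(make_norm(vals), labels)
        assert r2.iloc[0] == pytest.approx(1.0)

    def test_constant_covariate_gives_zero(self):
        rng = np.random.default_rng(0)
        r2 = td.variance_r2(make_norm(rng.normal(size=(5, 8))), np.zeros(8))
        assert (r2 == 0).all()

    def test_anova_identity_by_hand(self):
        # gene [1,2,3,4], groups {1,2} {3,4}: between-SS 4, total-SS 5
        r2 = td.variance_r2(
            make_norm([[1.0, 2.0, 3.0, 4.0]]), np.array([0, 0, 1, 1])
        )
        assert r2.iloc[0] == pytest.approx(0.8)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_eta_squared_oracle(self, trial):
        """r^2 equals one-way-ANOVA eta^2 (pingouin) on small instances."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(2, 4))
        labels = rng.integers(0, k, size=n)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, k, size=n)
        y = rng.normal(size=n)
        r2 = td.variance_r2(make_norm(y[None, :]), labels).iloc[0]
        df = pd.DataFrame({"y": y, "g": labels})
        eta2 = pingouin.anova(data=df, dv="y", between="g",
                              effsize="n2")["n2"].iloc[0]
        assert r2 == pytest.approx(eta2, abs=1e-9)

    def test_constant_gene_zero_by_convention(self):
        r2 = td.variance_r2(make_norm(np.full((1, 6), 3.0)),
                            np.repeat([0, 1], 3))
        assert r2.iloc[0] == 0.0


class TestPcVarianceFraction:
    def test_constant_covariate_zero(self):
        rng = np.random.default_rng(0)
        norm = make_norm(rng.normal(size=(40, 30)))
        assert td.pc_variance_fraction(norm, np.zeros(30), n_pcs=5) == 0.0

    def test_covariate_driving_all_variance(self):
        # one direction carries essentially all variance and is an exact
        # function of the covariate -> fraction near 1
        rng = np.random.default_rng(1)
        labels = np.repeat([0, 1], 25)
        signal = np.where(labels == 0, -10.0, 10.0)
        vals = np.outer(rng.normal(size=30), signal)
        vals += rng.normal(scale=1e-3, size=vals.shape)
        frac = td.pc_variance_fraction(make_norm(vals), labels, n_pcs=5)
        assert frac == pytest.approx(1.0, abs=0.01)

    def test_recovers_planted_share(self, planted_norm):
        """Time should explain a substantial, correction-removable share."""
        norm, _ = planted_norm
        frac = td.pc_variance_fraction(
            norm, norm.cell_meta["time_h"].values, n_pcs=10
        )
        assert 0.1 < frac < 1.0

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(2)
        norm = make_norm(rng.normal(size=(5, 4)))
        with pytest.warns(UserWarning, match="rank"):
            td.pc_variance_fraction(norm, np.array([0, 0, 1, 1]), n_pcs=50)


def test_kbet_improves_after_correction(planted_norm):
    """Acceptance across time labels rises after regressing out the score."""
    norm, _ = planted_norm
    sig = td.define_signature(
        td.wilcoxon_dea(norm, norm.cell_meta["affected"].values)
    )
    s = td.module_score(norm, sig.index, seed=1)
    corr = td.regress_out_score(
        norm, s.values, norm.cell_meta["cell_type"].values
    )
    from timedrift.score import _pca_embed
    t = norm.cell_meta["time_h"].values
    before = td.kbet(_pca_embed(norm.values, 10), t, n_test=300, seed=2)
    after = td.kbet(_pca_embed(corr, 10), t, n_test=300, seed=2)
    assert after.acceptance_rate > before.acceptance_rate
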