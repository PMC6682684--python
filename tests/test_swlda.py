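"""SWLDA classifier tests: decimation, stepwise selection, AUC, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rsvpbci as rb
from rsvpbci.stepwise import stepwise_select

from .conftest import make_epochset


class TestDecimateEpoch:
    def test_409_samples_give_17_blocks(self):
        out = rb.decimate_epoch(np.zeros((32, 409)))
        assert out.shape == (32, 17)

    def test_constant_blocks(self):
        assert np.allclose(rb.decimate_epoch(np.full(48, 2.0)), [2.0, 2.0])

    def test_equals_bruteforce_block_means(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=409)
        out = rb.decimate_epoch(x)
        brute = [x[i * 24:(i + 1) * 24].mean() for i in range(17)]
        assert np.allclose(out, brute)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rb.decimate_epoch(np.zeros(10))


class TestStepwiseSelection:
    def test_planted_features_recovered(self):
        rng = np.random.default_rng(1)
        n = 200
        X = rng.normal(size=(n, 10))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X[:, 3] += 3.0 * y      # effect 3x the unit noise
        X[:, 7] += 3.0 * y
        model = rb.swlda_fit(X, (y > 0).astype(int))
        assert {3, 7} <= set(model.selected_features)
        assert len(model.selected_features) <= 60
        # brute-force check: every excluded feature fails entry at termination
        import statsmodels.api as sm
        sel = list(model.selected_features)
        coded = y
        for j in range(10):
            if j in sel:
                continue
            design = sm.add_constant(X[:, sel + [j]])
            res = sm.OLS(coded, design).fit()
            assert res.pvalues[-1] > model.p_enter

    def test_null_labels_give_empty_model(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 8))
        y = (rng.random(100) < 0.5).astype(int)
        model = rb.swlda_fit(X, y, p_enter=0.001)
        assert model.is_empty
        scores = rb.swlda_score(model, X)
        assert np.ptp(scores) == 0.0

    def test_feature_cap_respected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 40))
        y = (X[:, :20].sum(axis=1) + 0.1 * rng.normal(size=120) > 0).astype(int)
        model = rb.swlda_fit(X, y, max_features=5, p_enter=0.9, p_remove=0.95)
        assert len(model.selected_features) <= 5

    def test_permissive_thresholds_match_ols(self):
        """With no selection pressure the stepwise fit is plain least squares."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(scale=0.1, size=30)
        res = stepwise_select(X, y, p_enter=1.0, p_remove=1.0)
        assert set(res.selected) == {0, 1, 2, 3}
        design = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = {i: c for i, c in zip(res.selected, res.coef)}
        ordered = np.array([fitted[i] for i in range(4)])
        assert np.allclose(ordered, beta[1:], atol=1e-8)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rb.swlda_fit(np.random.default_rng(5).normal(size=(10, 3)),
                         np.ones(10))


class TestSwldaScore:
    def test_single_feature_readout(self):
        model = rb.SwldaModel(selected_features=(1,), weights=np.array([2.0]),
                              intercept=0.0, p_enter=0.1, p_remove=0.15,
                              max_features=60)
        assert rb.swlda_score(model, np.array([[9.0, 3.0]]))[0] == 6.0

    def test_equals_bruteforce_dot_products(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 7))
        model = rb.SwldaModel(selected_features=(0, 4, 6),
                              weights=np.array([1.5, -0.5, 2.0]),
                              intercept=0.3, p_enter=0.1, p_remove=0.15,
                              max_features=60)
        scores = rb.swlda_score(model, X)
        brute = [0.3 + 1.5 * r[0] - 0.5 * r[4] + 2.0 * r[6] for r in X]
        assert np.allclose(scores, brute)

    def test_dimension_mismatch(self):
        model = rb.SwldaModel(selected_features=(5,), weights=np.array([1.0]),
                              intercept=0.0, p_enter=0.1, p_remove=0.15,
                              max_features=60)
        with pytest.raises(ValueError):
            rb.swlda_score(model, np.zeros((3, 2)))


class TestAuc:
    def test_perfect_separation(self):
        assert rb.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_chance(self):
        assert rb.auc([1.0] * 6, [1, 1, 0, 0, 0, 0]) == 0.5

    def test_pair_enumeration_example(self):
        assert rb.auc([2, 1, 4, 3], [1, 0, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 6, size=n).astype(float)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            wins = ties = 0
            for st_, lt in zip(scores, labels):
                if lt != 1:
                    continue
                for sn, ln in zip(scores, labels):
                    if ln != 0:
                        continue
                    wins += st_ > sn
                    ties += st_ == sn
            n_pairs = labels.sum() * (labels == 0).sum()
            assert rb.auc(scores, labels) == pytest.approx(
                (wins + 0.5 * ties) / n_pairs)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    def test_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        base = rb.auc(scores, labels)
        assert rb.auc(scale * scores + shift, labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rb.auc([1.0, 2.0], [1, 1])


class TestCrossvalAuc:
    def _signal_epochs(self, n_target=60, n_nontarget=300, snr=4.0, seed=0):
        rng = np.random.default_rng(seed)
        n = n_target + n_nontarget
        data = rng.normal(size=(n, 4, 96))
        bump = np.exp(-0.5 * ((np.arange(96) - 55) / 6.0) ** 2)
        data[:n_target] += snr * bump[None, None, :]
        labels = ["target"] * n_target + ["nontarget"] * n_nontarget
        order = rng.permutation(n)
        return make_epochset(data[order], np.array(labels, dtype=object)[order])

    def test_strong_signal_high_auc(self):
        mean_auc, folds = rb.crossval_auc(self._signal_epochs(), k=10, seed=1)
        assert mean_auc > 0.95
        assert len(folds) == 10

    def test_null_labels_near_chance(self):
        mean_auc, _ = rb.crossval_auc(self._signal_epochs(snr=0.0), k=10,
                                      seed=2)
        assert 0.35 < mean_auc < 0.65

    def test_deterministic_given_seed(self):
        ep = self._signal_epochs(seed=3)
        a, fa = rb.crossval_auc(ep, k=5, seed=9)
        b, fb = rb.crossval_auc(ep, k=5, seed=9)
        assert a == b and np.array_equal(fa, fb)

    def test_auc_tracks_snr_across_subjects(self):
        """Pipeline AUC rises with the injected SNR (rank correlation > 0)."""
        from scipy.stats import spearmanr
        snrs = np.linspace(0.3, 3.0, 8)
        aucs = [rb.crossval_auc(self._signal_epochs(n_target=30,
                                                    n_nontarget=150,
                                                    snr=s, seed=10 + i),
                                k=5, seed=1)[0]
                for i, s in enumerate(snrs)]
        rho = spearmanr(snrs, aucs).statistic
        assert rho > 0
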