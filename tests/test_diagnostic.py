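"""Feature assembly, ROC correctness and the cross-validated classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hgfmet import FeatureTable, roc_auc, train_classifier_cv
from hgfmet.diagnostic import NeuralNetClassifier
from hgfmet.errors import InputError


def _feature_table(X, y):
    idx = pd.Index([f"s{i}" for i in range(len(y))])
    return FeatureTable(
        X=pd.DataFrame(X, index=idx,
                       columns=[f"f{j}" for j in range(np.shape(X)[1])]),
        y=pd.Series(y, index=idx),
        cancer_type=pd.Series("SYN", index=idx),
    )


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)
        assert res.accuracy == pytest.approx(1.0)

    def test_uninformative_scores(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        res = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_pairwise_comparison_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        y = np.r_[np.ones(2), np.zeros(2), rng.integers(0, 2, n - 4)].astype(int)
        s = np.round(rng.random(n), 1)  # coarse grid forces ties
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(s, y).auc == pytest.approx(wins / (len(pos) * len(neg)))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random(30)
        y = np.r_[np.ones(2), np.zeros(2), rng.integers(0, 2, 26)].astype(int)
        assert roc_auc(np.exp(3 * s) - 0.5, y).auc == pytest.approx(roc_auc(s, y).auc)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.2], [1, 1])


class TestClassifierCV:
    def _separable(self, seed, n=200, gap=6.0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.normal(size=(n, 4))
        X[: n // 2, 0] += gap
        return _feature_table(X, y)

    def test_separable_classes_reach_high_auc(self):
        aucs = [train_classifier_cv(self._separable(s), seed=s).auc for s in range(5)]
        assert min(aucs) >= 0.99

    def test_permuted_labels_give_chance_auc(self):
        aucs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            ft = self._separable(seed, gap=0.0)  # no signal at all
            aucs.append(train_classifier_cv(ft, seed=seed).auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_deterministic_given_seed(self):
        ft = self._separable(3)
        r1 = train_classifier_cv(ft, seed=11)
        r2 = train_classifier_cv(ft, seed=11)
        assert r1.auc == r2.auc
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_small_class_suggests_smaller_k(self):
        ft = self._separable(0, n=20)
        ft.y.iloc[:] = 0
        ft.y.iloc[:3] = 1
        with pytest.raises(InputError, match="smaller k"):
            train_classifier_cv(ft, k_folds=5, seed=0)

    def test_fold_standardization_avoids_leakage(self):
        # a huge outlier in one fold shifts the global mean/SD; a leaked
        # pipeline (standardize once, then split) must diverge from the
        # correct per-fold pipeline on the same data
        rng = np.random.default_rng(4)
        ft = self._separable(4, n=100)
        ft.X.iloc[0, 1] = 1e4
        correct = train_classifier_cv(ft, seed=2)

        from sklearn.model_selection import StratifiedKFold

        X = ft.X.to_numpy().copy()
        y = ft.y.to_numpy()
        Xg = (X - X.mean(axis=0)) / X.std(axis=0)  # leaked: global standardization
        oof = np.empty(len(y))
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=2)
        for fold, (tr, te) in enumerate(skf.split(Xg, y)):
            freq = np.bincount(y[tr], minlength=2)
            sw = (len(tr) / (2.0 * freq))[y[tr]]
            net = NeuralNetClassifier(seed=2 + fold)
            net.fit(Xg[tr], y[tr], sample_weight=sw)
            oof[te] = net.predict_proba(Xg[te])
        assert not np.allclose(oof, correct.predictions["probability"].to_numpy())


class TestAssembly:
    def test_feature_count_and_fallback(self, default_cohort, default_signature, caplog):
        from hgfmet import PathwayDefinition, assemble_features, deconvolve, score_pathway
        from conftest import labels_from_truth

        _, expr, truth = default_cohort
        labels = labels_from_truth(truth)
        log2x = expr.log2_values()
        up = sorted(truth.planted_up_genes)
        down = sorted(truth.planted_down_genes)
        scores = [
            score_pathway(
                log2x,
                PathwayDefinition(f"p{i}", tuple(up[5 * i: 5 * i + 5]),
                                  tuple(down[2 * i: 2 * i + 2])),
                truth.immune_genes, labels.inactivated_samples,
                n_perm=50, seed=i,
            )
            for i in range(3)
        ]
        fr = deconvolve(expr, default_signature)
        with caplog.at_level("WARNING"):
            ft = assemble_features(scores, {s.name: 0.01 for s in scores}, fr, expr,
                                   top_k_pathways=20)
        # 6 cell fractions + 3 pathways + 2 anchor genes
        assert ft.X.shape[1] == 11
        assert any("using all" in r.message for r in caplog.records)
        assert set(ft.y.unique()) == {0, 1}

    def test_sample_mismatch_reported(self, default_cohort, default_signature):
        from hgfmet import assemble_features, deconvolve

        _, expr, _ = default_cohort
        fr = deconvolve(expr, default_signature)
        fr.fractions.drop(index=fr.fractions.index[0], inplace=True)
        with pytest.raises(InputError, match="missing from fractions"):
            assemble_features([], {}, fr, expr)
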