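"""Imbalance score A(P), co-expression weights, permutation null, DS."""

import numpy as np
import pandas as pd
import pytest

from hgfmet import (
    PathwayDefinition,
    coexpression_weights,
    deviation_DS,
    group_compare,
    imbalance_scores,
    permutation_null,
    score_pathway,
)
from hgfmet.pathway import NullSummary, reference_means
from hgfmet.errors import InputError

from conftest import labels_from_truth


def _frame(rows: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T.astype(float)
    if samples is not None:
        df.columns = samples
    return df


class TestWeights:
    def test_two_perfectly_correlated_genes(self):
        expr = _frame({"a": [1, 2, 3], "b": [2, 4, 6]})
        w = coexpression_weights(expr, ["a", "b"])
        np.testing.assert_allclose(w, [1.0, 1.0])

    def test_independent_gene_gets_floor_weight(self):
        expr = _frame({
            "a": [1, -1, 1, -1],
            "b": [2, -2, 2, -2],
            "c": [1, 1, -1, -1],  # sample correlation exactly 0 with a and b
        })
        w = coexpression_weights(expr, ["a", "b", "c"])
        assert w["a"] == pytest.approx(w["b"])
        assert w["c"] < 1e-5
        assert w.mean() == pytest.approx(1.0)

    def test_constant_gene_floored_with_warning(self, caplog):
        expr = _frame({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8], "k": [5, 5, 5, 5]})
        with caplog.at_level("WARNING"):
            w = coexpression_weights(expr, ["a", "b", "k"])
        assert w["k"] < 1e-5
        assert any("constant" in r.message for r in caplog.records)


class TestImbalance:
    def _score(self, up_w, up_dev2, dn_w, dn_dev2):
        genes = [f"u{i}" for i in range(len(up_w))] + [f"d{i}" for i in range(len(dn_w))]
        mu = pd.Series(0.0, index=genes)
        expr = pd.DataFrame(
            {"s": np.sqrt(np.concatenate([up_dev2, dn_dev2]))}, index=genes
        )
        pw = PathwayDefinition(
            "p", tuple(genes[: len(up_w)]), tuple(genes[len(up_w):]),
            weights=pd.Series(np.concatenate([up_w, dn_w]), index=genes),
        )
        return imbalance_scores(expr, pw, mu)["s"]

    def test_equilibrium_is_zero(self):
        assert self._score([1.0], [4.0], [1.0], [4.0]) == pytest.approx(0.0)

    def test_ratio_four_to_one(self):
        # sqrt(weighted up sum) = 4, sqrt(down sum) = 1 -> A = log2(4) = 2
        assert self._score([1.0], [16.0], [1.0], [1.0]) == pytest.approx(2.0)

    def test_weighted_example(self):
        # up: w=(0.5,0.5), dev2=(4,4) -> sqrt(4)=2; down: w=1, dev2=1 -> A=1
        assert self._score([0.5, 0.5], [4.0, 4.0], [1.0], [1.0]) == pytest.approx(1.0)

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(self._score([1.0], [4.0], [1.0], [0.0]))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_and_symmetries(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(1, 6, size=2)
        genes = [f"g{i}" for i in range(m + n)]
        w = pd.Series(rng.uniform(0.1, 2.0, m + n), index=genes)
        mu = pd.Series(rng.normal(size=m + n), index=genes)
        expr = pd.DataFrame(rng.normal(size=(m + n, 4)), index=genes,
                            columns=list("abcd"))
        pw = PathwayDefinition("p", tuple(genes[:m]), tuple(genes[m:]), weights=w)
        A = imbalance_scores(expr, pw, mu)
        for s in expr.columns:  # brute force from raw sums
            num = sum(w[g] * (expr.loc[g, s] - mu[g]) ** 2 for g in genes[:m])
            den = sum(w[g] * (expr.loc[g, s] - mu[g]) ** 2 for g in genes[m:])
            assert A[s] == pytest.approx(np.log2(np.sqrt(num) / np.sqrt(den)), rel=1e-10)
        swapped = PathwayDefinition("q", tuple(genes[m:]), tuple(genes[:m]), weights=w)
        np.testing.assert_allclose(
            imbalance_scores(expr, swapped, mu), -A, rtol=1e-10
        )
        scaled = PathwayDefinition("r", tuple(genes[:m]), tuple(genes[m:]),
                                   weights=w * 7.3)
        np.testing.assert_allclose(
            imbalance_scores(expr, scaled, mu), A, rtol=1e-10
        )


@pytest.fixture(scope="module")
def cohort_log2(default_cohort):
    _, expr, truth = default_cohort
    return expr.log2_values(), truth


class TestPermutationNull:

    def test_deterministic_given_seed(self, cohort_log2):
        log2x, truth = cohort_log2
        ref = truth.activation_label.index[truth.activation_label == "inactivated"]
        a = permutation_null(log2x, (5, 5), truth.immune_genes[:60], ref, 100, seed=9)
        b = permutation_null(log2x, (5, 5), truth.immune_genes[:60], ref, 100, seed=9)
        pd.testing.assert_series_equal(a.mu_prime, b.mu_prime)
        pd.testing.assert_series_equal(a.sd_prime, b.sd_prime)
        assert a.n_perm == 100

    def test_small_pool_rejected(self, cohort_log2):
        log2x, truth = cohort_log2
        ref = truth.activation_label.index[:10]
        with pytest.raises(InputError, match="pool"):
            permutation_null(log2x, (6, 6), truth.immune_genes[:10], ref, 10, seed=0)

    def test_matches_naive_per_draw_recomputation(self, cohort_log2):
        # oracle: replay the documented draw rule and score each draw through
        # the public single-pathway path
        log2x, truth = cohort_log2
        pool = truth.immune_genes[:30]
        ref = truth.activation_label.index[truth.activation_label == "inactivated"]
        m, n, n_perm, seed = 3, 4, 25, 42
        null = permutation_null(log2x, (m, n), pool, ref, n_perm, seed=seed)
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, len(pool))), axis=1, kind="stable")
        mu = reference_means(log2x, ref)
        draws = []
        for d in range(n_perm):
            genes = [pool[i] for i in order[d, : m + n]]
            pw = PathwayDefinition(
                f"null{d}", tuple(genes[:m]), tuple(genes[m:]),
                weights=coexpression_weights(log2x, genes),
            )
            draws.append(imbalance_scores(log2x, pw, mu))
        A = pd.concat(draws, axis=1)
        np.testing.assert_allclose(null.mu_prime, A.mean(axis=1), rtol=1e-9)
        np.testing.assert_allclose(null.sd_prime, A.std(axis=1, ddof=1), rtol=1e-9)

    def test_symmetric_pool_has_null_mean_near_zero(self, cohort_log2):
        log2x, truth = cohort_log2
        pool = truth.immune_genes[100:120]  # null genes, m = n = 10 uses all
        ref = truth.activation_label.index[truth.activation_label == "inactivated"]
        null = permutation_null(log2x, (10, 10), pool, ref, 1000, seed=1)
        assert np.abs(null.mu_prime).mean() < 0.05


class TestDeviationDS:
    def test_identity_centering_and_degenerate(self):
        idx = pd.Index(["a", "b", "c"])
        A = pd.Series([2.0, 1.0, 3.0], index=idx)
        null = NullSummary(
            mu_prime=pd.Series([0.0, 1.0, 0.0], index=idx),
            sd_prime=pd.Series([1.0, 2.0, 0.0], index=idx),
            n_perm=10, seed=0,
        )
        ds = deviation_DS(A, null)
        assert ds["a"] == pytest.approx(2.0)
        assert ds["b"] == pytest.approx(0.0)
        assert np.isnan(ds["c"])

    def test_sample_mismatch_rejected(self):
        A = pd.Series([1.0], index=["a"])
        null = NullSummary(
            mu_prime=pd.Series([0.0], index=["b"]),
            sd_prime=pd.Series([1.0], index=["b"]), n_perm=10, seed=0,
        )
        with pytest.raises(InputError):
            deviation_DS(A, null)


class TestGroupCompare:
    def test_planted_pathway_strongly_up(self, default_cohort):
        _, expr, truth = default_cohort
        labels = labels_from_truth(truth)
        up = sorted(truth.planted_up_genes)[:10]
        down = sorted(truth.planted_down_genes)[:4]
        pw = PathwayDefinition("planted", tuple(up), tuple(down))
        res = score_pathway(
            expr.log2_values(), pw, truth.immune_genes,
            labels.inactivated_samples, n_perm=300, seed=0,
        )
        t, p, direction = group_compare(res.DS, labels)
        assert p < 1e-6
        assert direction == "up"
        assert t > 0

    def test_identical_group_distributions_give_p_one(self, default_cohort):
        _, _, truth = default_cohort
        labels = labels_from_truth(truth)
        ds = pd.Series(0.0, index=labels.labels.index)
        ds.iloc[: len(ds) // 2] = np.tile([0.5, -0.5], len(ds) // 4)
        ds.iloc[len(ds) // 2:] = np.tile([0.5, -0.5], len(ds) // 4)
        t, p, _ = group_compare(ds, labels)
        assert p == pytest.approx(1.0)
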