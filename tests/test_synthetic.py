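"""Generator contracts: shapes, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hgfmet import (
    SyntheticConfig,
    generate_cohort,
    generate_gene_sets,
    generate_signature_matrix,
    generate_survival,
)
from hgfmet.errors import ConfigurationError
from hgfmet.survival import logrank
from hgfmet.synthetic import ACTIVATED, INACTIVATED


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_activated": 0},
            {"n_immune_genes": -3},
            {"coexpr_r": 1.2},
            {"censor_rate": 1.0},
            {"hazard_ratio": 0.0},
            {"n_up_genes": 190, "n_down_genes": 20, "n_immune_genes": 200},
            {"frac_dirichlet_alpha": (1.0, 2.0)},  # wrong length for 6 cell types
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(**kwargs)


class TestCohort:
    def test_counts_forced_by_config(self):
        cfg = SyntheticConfig(n_activated=50, n_inactivated=50, n_normal=20, seed=1)
        expr, truth = generate_cohort(cfg)
        assert expr.n_samples == 120
        assert (truth.activation_label == ACTIVATED).sum() == 50
        assert (truth.activation_label == INACTIVATED).sum() == 50
        assert {"HGF", "MET"} <= set(expr.gene_ids)
        assert (expr.values.to_numpy() >= 0).all()

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=5)
        e1, t1 = generate_cohort(cfg)
        e2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        pd.testing.assert_series_equal(t1.activation_label, t2.activation_label)
        pd.testing.assert_frame_equal(t1.true_fractions, t2.true_fractions)

    def test_planted_coexpression_reaches_target(self):
        cfg = SyntheticConfig(coexpr_r=0.9, n_activated=500, seed=7)
        expr, truth = generate_cohort(cfg)
        act = truth.activation_label.index[truth.activation_label == ACTIVATED]
        r = stats.pearsonr(
            expr.values.loc["HGF", act], expr.values.loc["MET", act]
        )[0]
        assert r >= 0.8

    def test_activated_correlation_exceeds_inactivated(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SyntheticConfig(coexpr_r=0.5, n_activated=200, n_inactivated=200,
                                  n_normal=1, seed=seed)
            expr, truth = generate_cohort(cfg)
            lab = truth.activation_label
            log2x = np.log2(expr.values.loc[["HGF", "MET"]] + 1)
            r_act = stats.pearsonr(*log2x[lab.index[lab == ACTIVATED]].to_numpy())[0]
            r_ina = stats.pearsonr(*log2x[lab.index[lab == INACTIVATED]].to_numpy())[0]
            wins += r_act > r_ina
        assert wins >= 0.95 * n_seeds

    def test_planted_gene_sets_disjoint_and_fraction_rows_simplex(self):
        _, truth = generate_cohort(SyntheticConfig(seed=2))
        assert not (truth.planted_up_genes & truth.planted_down_genes)
        np.testing.assert_allclose(truth.true_fractions.sum(axis=1), 1.0)

    def test_noise_free_mixture_reconstructs_exactly(self):
        cfg = SyntheticConfig(seed=4, noise_sd=0.0, infiltration_boost=2.0)
        expr, truth = generate_cohort(cfg)
        sig = generate_signature_matrix(cfg)
        expected = sig.values.to_numpy() @ truth.true_fractions.to_numpy().T
        boost = np.ones(expr.n_samples)
        boost[: cfg.n_activated] = cfg.infiltration_boost
        observed = expr.values.loc[sig.marker_genes].to_numpy()
        np.testing.assert_allclose(observed, expected * boost[None, :], rtol=1e-12)


class TestSignature:
    def test_shape_and_marker_blocks(self):
        cfg = SyntheticConfig(n_cell_types=6, markers_per_cell_type=10, seed=0)
        sig = generate_signature_matrix(cfg)
        assert sig.values.shape == (60, 6)
        assert (sig.values.to_numpy() >= 0).all()
        for c, ct in enumerate(sig.cell_types):
            block = sig.values.iloc[c * 10:(c + 1) * 10]
            own = block[ct].mean()
            off = block.drop(columns=ct).to_numpy().mean()
            assert own > off

    def test_determinism(self):
        cfg = SyntheticConfig(seed=9)
        pd.testing.assert_frame_equal(
            generate_signature_matrix(cfg).values, generate_signature_matrix(cfg).values
        )


class TestSurvival:
    def test_no_censoring_when_rate_zero(self):
        cfg = SyntheticConfig(seed=1, censor_rate=0.0)
        _, truth = generate_cohort(cfg)
        surv = generate_survival(truth, cfg)
        assert (surv["event"] == 1).all()
        assert (surv["time"] > 0).all()

    def test_censor_rate_approximately_respected(self):
        cfg = SyntheticConfig(seed=2, censor_rate=0.4, n_activated=500, n_inactivated=500)
        _, truth = generate_cohort(cfg)
        surv = generate_survival(truth, cfg)
        assert abs((surv["event"] == 0).mean() - 0.4) < 0.08

    def test_strong_hazard_detected_by_logrank(self):
        cfg = SyntheticConfig(seed=3, hazard_ratio=3.0, n_activated=100, n_inactivated=100)
        _, truth = generate_cohort(cfg)
        surv = generate_survival(truth, cfg)
        _, p = logrank(surv)
        assert p < 0.01

    def test_determinism(self):
        cfg = SyntheticConfig(seed=6)
        _, truth = generate_cohort(cfg)
        pd.testing.assert_frame_equal(
            generate_survival(truth, cfg), generate_survival(truth, cfg)
        )


class TestGeneSets:
    def test_planted_and_decoy_sets(self):
        cfg = SyntheticConfig(seed=1)
        _, truth = generate_cohort(cfg)
        coll = generate_gene_sets(truth, cfg, n_planted_sets=2, n_decoy_sets=5)
        assert len(coll) == 7
        planted = coll["PLANTED_PATHWAY_1"]
        assert len(planted & truth.planted_up_genes) > 0
        decoy = coll["DECOY_SET_1"]
        assert not decoy & (truth.planted_up_genes | truth.planted_down_genes)
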