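"""Shared fixtures: small synthetic cohorts with known planted truth."""

import numpy as np
import pandas as pd
import pytest

from hgfmet import SyntheticConfig, generate_cohort, generate_signature_matrix
from hgfmet.activation import ACTIVATED, INACTIVATED, ActivationLabels


@pytest.fixture(scope="session")
def default_cohort():
    """One default-geometry cohort (100/100 tumors, 50 normals), seed 3."""
    config = SyntheticConfig(seed=3)
    expr, truth = generate_cohort(config)
    return config, expr, truth


@pytest.fixture(scope="session")
def default_signature(default_cohort):
    config, _, _ = default_cohort
    return generate_signature_matrix(config)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for pipeline-level tests."""
    config = SyntheticConfig(
        seed=7, n_activated=40, n_inactivated=40, n_normal=15,
        n_immune_genes=80, n_background_genes=60, n_up_genes=16,
        n_down_genes=8, n_cell_types=4, markers_per_cell_type=6,
    )
    expr, truth = generate_cohort(config)
    return config, expr, truth


def labels_from_truth(truth) -> ActivationLabels:
    """ActivationLabels carrying the planted (noise-free) group assignment."""
    lab = truth.activation_label
    table = pd.DataFrame(
        {
            "scaled_hgf": np.nan,
            "scaled_met": np.nan,
            "ratio": np.nan,
            "label": np.where(lab.to_numpy() == ACTIVATED, ACTIVATED, INACTIVATED),
        },
        index=lab.index,
    )
    return ActivationLabels(table=table, pearson_r=float("nan"), pearson_p=float("nan"))
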