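"""Seed-reproducible synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes in a pooled multi-cancer bulk RNA-seq cohort:

* a ligand/receptor pair (``HGF``, ``MET``) that is tightly co-expressed in a
  pathway-*activated* tumor subpopulation and decoupled over a wide dynamic
  range in the *inactivated* subpopulation;
* immune genes, a subset of which is differentially expressed between the
  two tumor subpopulations (up-shifts larger than down-shifts, mirroring the
  up-dominant differential signal the analysis is designed to detect);
* marker genes whose expression is a linear mixture ``signature x fractions``
  of immune cell types, with a larger infiltration coefficient in activated
  samples;
* exponential survival times with a configurable hazard ratio between
  activation groups and independent exponential censoring.

All values are non-negative on a linear scale (log-normal noise), and every
generator is a pure function of its config + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CANCER_COL,
    PURITY_COL,
    TUMOR_COL,
    ExpressionMatrix,
    GeneSetCollection,
    SignatureMatrix,
)
from .errors import ConfigurationError
from . import io as hio

HGF = "HGF"
MET = "MET"

# ln-scale geometry of the anchor genes: activated samples form a compact
# co-expressed cluster centered above the baseline; inactivated samples draw
# independent offsets over a wide (~e^8-fold) dynamic range so their
# min-max-scaled ratio rarely looks balanced.
_ANCHOR_BASE = 3.0
_ANCHOR_SD = 0.35
_ANCHOR_SHIFT = 1.5
_INACT_HALF_WIDTH = 6.0

_IMMUNE_BASE_MEAN = 1.5
_IMMUNE_BASE_SD = 1.0

_CELL_TYPE_NAMES = [
    "B_cell", "CD4_T", "CD8_T", "Neutrophil", "Macrophage", "DC",
    "NK_cell", "Mast_cell",
]

ACTIVATED = "activated"
INACTIVATED = "inactivated"


@dataclass
class SyntheticConfig:
    """Cohort geometry and effect sizes for the synthetic generators."""

    n_activated: int = 100
    n_inactivated: int = 100
    n_normal: int = 50
    n_immune_genes: int = 200
    n_background_genes: int = 300
    n_up_genes: int = 40
    n_down_genes: int = 20
    n_cell_types: int = 6
    markers_per_cell_type: int = 10
    coexpr_r: float = 0.8
    de_effect: float = 2.0          # log2 up-shift of planted up genes
    down_effect_scale: float = 0.5  # down genes shift by -de_effect * this
    noise_sd: float = 0.5           # sdlog of the log-normal noise
    frac_dirichlet_alpha: tuple | None = None
    infiltration_boost: float = 2.0  # mixture scale multiplier in activated samples
    hazard_ratio: float = 2.0
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_activated": self.n_activated,
            "n_inactivated": self.n_inactivated,
            "n_normal": self.n_normal,
            "n_immune_genes": self.n_immune_genes,
            "n_background_genes": self.n_background_genes,
            "n_cell_types": self.n_cell_types,
            "markers_per_cell_type": self.markers_per_cell_type,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value}")
        if self.n_up_genes < 0 or self.n_down_genes < 0:
            raise ConfigurationError("planted gene counts must be >= 0")
        if self.n_up_genes + self.n_down_genes > self.n_immune_genes:
            raise ConfigurationError("planted up+down genes exceed n_immune_genes")
        if not 0.0 <= self.coexpr_r <= 1.0:
            raise ConfigurationError(f"coexpr_r must be in [0, 1], got {self.coexpr_r}")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        if self.hazard_ratio <= 0:
            raise ConfigurationError(f"hazard_ratio must be > 0, got {self.hazard_ratio}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.infiltration_boost <= 0:
            raise ConfigurationError("infiltration_boost must be > 0")
        self.dirichlet_alpha()  # validates length/positivity eagerly

    def dirichlet_alpha(self, for_normal: bool = False) -> np.ndarray:
        """Concentration vector for mixing fractions.

        Defaults to a decreasing profile for tumors and its reverse for
        normal tissue, so the two compartments have distinct mean mixtures.
        """
        if self.frac_dirichlet_alpha is None:
            alpha = 2.0 / (1.0 + 0.4 * np.arange(self.n_cell_types))
        else:
            alpha = np.asarray(self.frac_dirichlet_alpha, dtype=float)
            if alpha.ndim == 0:
                alpha = np.full(self.n_cell_types, float(alpha))
            if alpha.shape != (self.n_cell_types,):
                raise ConfigurationError(
                    "frac_dirichlet_alpha length must equal n_cell_types"
                )
            if (alpha <= 0).any():
                raise ConfigurationError("frac_dirichlet_alpha entries must be > 0")
        return alpha[::-1].copy() if for_normal else alpha


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    activation_label: pd.Series          # tumor samples -> activated/inactivated
    planted_up_genes: frozenset[str]
    planted_down_genes: frozenset[str]
    immune_genes: list[str] = field(default_factory=list)
    true_fractions: pd.DataFrame | None = None   # all samples x cell types
    true_group: pd.Series | None = None          # tumor samples -> high/low risk

    def __post_init__(self) -> None:
        if self.planted_up_genes & self.planted_down_genes:
            raise ConfigurationError("planted up and down gene sets overlap")
        if self.true_fractions is not None:
            sums = self.true_fractions.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0):
                raise ConfigurationError("true fraction rows must sum to 1")


def _decoupled_offsets(rng: np.random.Generator, n: int) -> np.ndarray:
    """ln-scale offsets for decoupled (inactivated) anchor expression.

    Mostly uniform over a wide dynamic range, with a small saturated /
    silenced subpopulation pinned near the extremes (a common bimodal
    feature of receptor expression). The edge mass keeps the per-gene
    min and max stable across cohorts, which the downstream min-max
    scaling depends on.
    """
    w = _INACT_HALF_WIDTH
    u = rng.uniform(-w, w, n)
    edge = rng.random(n) < 0.1
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    u[edge] = (sign * (w - np.abs(rng.normal(0.0, 0.15, n))))[edge]
    return u


def _cell_type_names(n: int) -> list[str]:
    names = list(_CELL_TYPE_NAMES[:n])
    names += [f"CT{i}" for i in range(len(names) + 1, n + 1)]
    return names


def generate_signature_matrix(config: SyntheticConfig) -> SignatureMatrix:
    """Block-diagonal marker signature: each cell type has its own high block."""
    if config.n_cell_types < 2:
        raise ConfigurationError("signature matrix needs n_cell_types >= 2")
    rng = np.random.default_rng([config.seed, 2])
    cts = _cell_type_names(config.n_cell_types)
    mpc = config.markers_per_cell_type
    genes = [f"MK_{ct}_{k + 1}" for ct in cts for k in range(mpc)]
    high = 10.0, 20.0
    low = 0.1, 1.0
    vals = rng.uniform(*low, size=(len(genes), len(cts)))
    for c in range(len(cts)):
        block = slice(c * mpc, (c + 1) * mpc)
        vals[block, c] = rng.uniform(*high, size=mpc)
    return SignatureMatrix(pd.DataFrame(vals, index=genes, columns=cts))


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the expression matrix, metadata and planted truth."""
    rng = np.random.default_rng([config.seed, 1])
    n_act, n_ina, n_nor = config.n_activated, config.n_inactivated, config.n_normal
    n_tum = n_act + n_ina
    n_all = n_tum + n_nor

    samples = (
        [f"ACT{i + 1:04d}" for i in range(n_act)]
        + [f"INA{i + 1:04d}" for i in range(n_ina)]
        + [f"NOR{i + 1:04d}" for i in range(n_nor)]
    )
    act_sl = slice(0, n_act)
    ina_sl = slice(n_act, n_tum)
    nor_sl = slice(n_tum, n_all)

    # --- anchor genes -----------------------------------------------------
    ln_h = np.empty(n_all)
    ln_m = np.empty(n_all)
    r = config.coexpr_r
    shared = rng.standard_normal(n_act)
    eps_h = rng.standard_normal(n_act)
    eps_m = rng.standard_normal(n_act)
    center = _ANCHOR_BASE + _ANCHOR_SHIFT
    ln_h[act_sl] = center + _ANCHOR_SD * (np.sqrt(r) * shared + np.sqrt(1 - r) * eps_h)
    ln_m[act_sl] = center + _ANCHOR_SD * (np.sqrt(r) * shared + np.sqrt(1 - r) * eps_m)
    ln_h[ina_sl] = _ANCHOR_BASE + _decoupled_offsets(rng, n_ina)
    ln_m[ina_sl] = _ANCHOR_BASE + _decoupled_offsets(rng, n_ina)
    ln_h[nor_sl] = _ANCHOR_BASE + _ANCHOR_SD * rng.standard_normal(n_nor)
    ln_m[nor_sl] = _ANCHOR_BASE + _ANCHOR_SD * rng.standard_normal(n_nor)

    # --- immune genes (planted DE in activated tumors) --------------------
    n_imm = config.n_immune_genes
    immune_genes = [f"IMG{i + 1:04d}" for i in range(n_imm)]
    up_genes = immune_genes[: config.n_up_genes]
    down_genes = immune_genes[config.n_up_genes: config.n_up_genes + config.n_down_genes]
    base_imm = _IMMUNE_BASE_MEAN + _IMMUNE_BASE_SD * rng.standard_normal(n_imm)
    ln_imm = base_imm[:, None] + config.noise_sd * rng.standard_normal((n_imm, n_all))
    ln2 = np.log(2.0)
    ln_imm[: config.n_up_genes, act_sl] += config.de_effect * ln2
    dn_sl = slice(config.n_up_genes, config.n_up_genes + config.n_down_genes)
    ln_imm[dn_sl, act_sl] -= config.de_effect * config.down_effect_scale * ln2

    # --- immune-cell mixture on the marker genes --------------------------
    signature = generate_signature_matrix(config)
    fractions = np.empty((n_all, config.n_cell_types))
    fractions[:n_tum] = rng.dirichlet(config.dirichlet_alpha(), size=n_tum)
    fractions[n_tum:] = rng.dirichlet(config.dirichlet_alpha(for_normal=True), size=n_nor)
    infil_coef = np.ones(n_all)
    infil_coef[act_sl] = config.infiltration_boost
    mix = signature.values.to_numpy() @ fractions.T  # markers x samples
    mix = mix * infil_coef[None, :]
    if config.noise_sd > 0:
        mix = mix * np.exp(config.noise_sd * rng.standard_normal(mix.shape))

    # --- background genes -------------------------------------------------
    n_bg = config.n_background_genes
    base_bg = _IMMUNE_BASE_MEAN + _IMMUNE_BASE_SD * rng.standard_normal(n_bg)
    ln_bg = base_bg[:, None] + config.noise_sd * rng.standard_normal((n_bg, n_all))

    genes = [HGF, MET] + immune_genes + list(signature.marker_genes) + [
        f"BG{i + 1:04d}" for i in range(n_bg)
    ]
    values = np.vstack([
        np.exp(ln_h)[None, :],
        np.exp(ln_m)[None, :],
        np.exp(ln_imm),
        mix,
        np.exp(ln_bg),
    ])
    values_df = pd.DataFrame(values, index=genes, columns=samples)

    purity = np.full(n_all, np.nan)
    purity[:n_tum] = np.clip(
        1.0 - 0.15 * infil_coef[:n_tum] + 0.05 * rng.standard_normal(n_tum), 0.05, 0.99
    )
    meta = pd.DataFrame(
        {
            TUMOR_COL: [True] * n_tum + [False] * n_nor,
            CANCER_COL: "SYN",
            PURITY_COL: purity,
        },
        index=samples,
    )
    expr = ExpressionMatrix(values_df, meta)

    tumor_ids = samples[:n_tum]
    labels = pd.Series(
        [ACTIVATED] * n_act + [INACTIVATED] * n_ina, index=tumor_ids, name="activation"
    )
    truth = SyntheticTruth(
        activation_label=labels,
        planted_up_genes=frozenset(up_genes),
        planted_down_genes=frozenset(down_genes),
        immune_genes=immune_genes,
        true_fractions=pd.DataFrame(
            fractions, index=samples, columns=signature.cell_types
        ),
        true_group=pd.Series(
            np.where(labels.to_numpy() == ACTIVATED, "high", "low"),
            index=tumor_ids,
            name="risk_group",
        ),
    )
    return expr, truth


def generate_survival(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Exponential event times with ``hazard_ratio`` between risk groups.

    Censoring is an independent exponential clock calibrated so the expected
    censored fraction is ``censor_rate``.
    """
    if truth.true_group is None:
        raise ConfigurationError("truth has no risk groups for survival generation")
    rng = np.random.default_rng([config.seed, 3])
    groups = truth.true_group
    base_rate = 0.1
    rates = np.where(groups.to_numpy() == "high", base_rate * config.hazard_ratio, base_rate)
    event_t = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        censor_lambda = config.censor_rate / (1 - config.censor_rate) * rates.mean()
        censor_t = rng.exponential(1.0 / censor_lambda, size=len(groups))
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        time, event = event_t, np.ones(len(groups), dtype=int)
    return pd.DataFrame(
        {"time": time, "event": event, "group": groups.to_numpy()}, index=groups.index
    )


def generate_gene_sets(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    n_planted_sets: int = 3,
    n_decoy_sets: int = 12,
    genes_per_set: int = 18,
) -> GeneSetCollection:
    """A GMT-style collection: planted pathways (enriched in the planted DE
    genes, up-dominant) plus decoy sets of null immune genes."""
    rng = np.random.default_rng([config.seed, 4])
    up = sorted(truth.planted_up_genes)
    down = sorted(truth.planted_down_genes)
    null = [g for g in truth.immune_genes
            if g not in truth.planted_up_genes and g not in truth.planted_down_genes]
    n_up_pick = min(10, len(up))
    n_dn_pick = min(4, len(down))
    n_null_pick = max(genes_per_set - n_up_pick - n_dn_pick, 0)
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for k in range(n_planted_sets):
        members = (
            list(rng.choice(up, n_up_pick, replace=False))
            + list(rng.choice(down, n_dn_pick, replace=False))
            + list(rng.choice(null, min(n_null_pick, len(null)), replace=False))
        )
        name = f"PLANTED_PATHWAY_{k + 1}"
        sets[name] = frozenset(members)
        desc[name] = "planted immune pathway (contains planted DE genes)"
    for k in range(n_decoy_sets):
        members = rng.choice(null, min(genes_per_set, len(null)), replace=False)
        name = f"DECOY_SET_{k + 1}"
        sets[name] = frozenset(members)
        desc[name] = "decoy set of null immune genes"
    return GeneSetCollection(sets, desc)


def write_cohort(
    outdir: str | Path,
    config: SyntheticConfig,
    expr: ExpressionMatrix,
    truth: SyntheticTruth,
    signature: SignatureMatrix,
    survival: pd.DataFrame,
    gene_sets: GeneSetCollection,
) -> dict[str, Path]:
    """Write every generated artifact as plain text; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "signature": outdir / "signature.tsv",
        "survival": outdir / "survival.tsv",
        "immune_genes": outdir / "immune_genes.txt",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    hio.write_expression_tsv(expr, paths["expression"])
    hio.write_metadata_tsv(expr.sample_meta, paths["metadata"])
    hio.write_signature_tsv(signature, paths["signature"])
    hio.write_survival_tsv(survival, paths["survival"])
    hio.write_gene_list(truth.immune_genes, paths["immune_genes"])
    hio.write_gmt(gene_sets, paths["gene_sets"])
    truth_payload = {
        "activation_label": truth.activation_label.to_dict(),
        "planted_up_genes": sorted(truth.planted_up_genes),
        "planted_down_genes": sorted(truth.planted_down_genes),
        "immune_genes": truth.immune_genes,
        "true_group": truth.true_group.to_dict() if truth.true_group is not None else None,
        "true_fractions": truth.true_fractions.round(10).to_dict(orient="index")
        if truth.true_fractions is not None else None,
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    paths["config"].write_text(json.dumps(asdict(config), indent=1, sort_keys=True))
    return paths
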