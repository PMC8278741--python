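# hgfmet

Analysis pipeline for studying how activation of the HGF/c-MET signalling
axis reshapes the tumor immune microenvironment in bulk expression cohorts
— and for turning that signal into a tumor/normal diagnostic. It is aimed
at computational biologists working with pooled multi-cancer RNA-seq
matrices (genes × samples, non-negative normalized values) who want a
tested, seed-reproducible implementation of the following chain:

1. **Activation labelling.** HGF (the ligand) and MET (its receptor
   tyrosine kinase) are each min–max scaled to [0, 1] over the tumor
   samples; a sample is called *pathway-activated* when the scaled ratio
   HGF/MET lies in the inclusive window [0.5, 1.5] (co-expressed ligand and
   receptor), otherwise *inactivated*.
2. **Immune-gene screen.** Welch two-sample tests on log2(x+1) values
   between the activation groups, at raw p < 0.05 (fold change is reported
   but never used as a filter; BH adjustment is an opt-in flag).
3. **Over-representation analysis.** Hypergeometric upper-tail test of the
   screened genes against a GMT collection within the immune-gene universe,
   BH-adjusted.
4. **Pathway imbalance and degree scores.** For a pathway *P* with *m*
   up-regulated and *n* down-regulated members, per sample

   &nbsp;&nbsp;&nbsp;&nbsp;A(P) = log₂ ( √(Σᵢ ωᵢ (Xᵢ − μᵢ)²) / √(Σⱼ ωⱼ (Xⱼ − μⱼ)²) )

   where *X* is the sample's log2 expression, μ the gene's mean over a
   reference group (inactivated tumors by default) and ω a co-expression
   network weight. A(P) = 0 means the up- and down-deviations balance.
   A(P) is standardized into a degree score DS(P) = (A − μ′)/sd′, with μ′
   and sd′ the per-sample mean and SD of A over 1000 random same-shape gene
   sets drawn from the immune pool (weights and reference means recomputed
   per draw).
5. **Immune deconvolution.** Non-negative least squares of each sample's
   marker-gene expression against a cell-type signature matrix, normalized
   onto the simplex; the raw coefficient sum is kept as an
   absolute-infiltration proxy. Fractions are correlated with HGF/MET
   (Pearson, optionally purity-adjusted partial correlation).
6. **Diagnostic model.** Cell fractions + top-pathway degree scores +
   log2 HGF/MET feed a single-hidden-layer neural network (16 logistic
   units, weighted cross-entropy) under stratified k-fold cross-validation;
   out-of-fold probabilities are pooled into one ROC.
7. **Survival.** Median-dichotomized features compared by the two-group
   log-rank test, with Kaplan–Meier coordinates for plotting.

A first-class synthetic-cohort generator (`hgfmet.synthetic`) plants every
effect the pipeline is meant to detect — a co-expressed HGF/MET
subpopulation, differential immune genes, signature-driven cell mixtures
with boosted infiltration in activated samples, and survival hazards — so
each stage can be tested against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (100 activated / 100 inactivated tumors, 50 normals; 40 planted
up- and 20 planted down-regulated immune genes; six cell types):

```bash
python analysis/01_simulate.py
python analysis/02_activation.py
python analysis/03_differential_expression.py
python analysis/04_pathway_scores.py
python analysis/05_infiltration.py
python analysis/06_diagnostic.py
python analysis/07_survival.py
```

Selected output (all tables land under `results/`):

```
100 activated / 100 inactivated tumor samples
agreement with planted labels: 93.0%
HGF-MET Pearson r in the activated group: 0.917 (p = 6.58e-41)

48 up / 23 down differential immune genes of 200 screened
planted recovery: 40/40 up, 20/20 down

pathway             n_up  n_down     t        p_value  direction
PLANTED_PATHWAY_2     11       4  6.61   7.31e-10      up
PLANTED_PATHWAY_3     10       4  5.68   7.01e-08      up
PLANTED_PATHWAY_1     10       4  4.73   4.82e-06      up
DECOY_SET_6            2       1 -1.76   8.04e-02      down

fraction MAE vs planted truth: 0.0239
infiltration abundance activated 2.28 vs inactivated 1.13 (Welch p = 1.78e-88)

pooled cross-validated AUC = 0.945, accuracy at 0.5 = 0.932
planted risk groups: log-rank chi2 = 29.47, p = 5.67e-08
```

Reading it: the ratio window recovers 93% of the planted activation
labels; the Welch screen finds every planted differential gene (48 up
calls = 40 planted + 8 expected false positives at p < 0.05 over 140 null
genes); the three planted pathways dominate the degree-score contrast
while decoys stay null; deconvolution recovers mixing fractions to ~0.02
absolute error and the planted two-fold infiltration boost; and the
integrated classifier separates tumors from normals with AUC ≈ 0.95.

The same stages are exposed as a CLI (`hgfmet simulate`, `hgfmet run
--config pipeline.yaml`, and per-stage subcommands `activation`, `degs`,
`enrich`, `score`, `deconvolve`, `diagnose`, `survival`) and as plain
library functions (`hgfmet.analyze` for the in-memory end-to-end run).

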