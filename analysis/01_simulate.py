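#!/usr/bin/env python
"""Generate the study cohort: expression, truth, signature, survival, gene sets.

Writes everything under results/data/ as plain text; later scripts only read
those files, so the whole analysis is reproducible from this seed.
"""

from pathlib import Path

import hgfmet as h
from hgfmet.synthetic import write_cohort

SEED = 20260101 % (2**31)
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config = h.SyntheticConfig(seed=SEED)
    expr, truth = h.generate_cohort(config)
    signature = h.generate_signature_matrix(config)
    survival = h.generate_survival(truth, config)
    gene_sets = h.generate_gene_sets(truth, config)
    paths = write_cohort(OUT, config, expr, truth, signature, survival, gene_sets)
    print(f"cohort: {expr.n_genes} genes x {expr.n_samples} samples "
          f"({config.n_activated} activated / {config.n_inactivated} inactivated "
          f"tumors, {config.n_normal} normals)")
    print(f"planted: {len(truth.planted_up_genes)} up / "
          f"{len(truth.planted_down_genes)} down immune genes, "
          f"{config.n_cell_types} cell types, hazard ratio {config.hazard_ratio}")
    for name, p in sorted(paths.items()):
        print(f"  wrote {name}: {p.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
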