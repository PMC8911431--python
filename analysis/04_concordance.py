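#!/usr/bin/env python
"""The analytical core on the curated pairs: correlation battery,
bootstrap 2-D PCA, and the per-seed-gene sign-concordance binomial table
with Bonferroni correction across all 42 seed genes.

Writes results/correlation_battery.json, results/pca.json and
results/sign_concordance.tsv.  Run 03_pair_homologs.py first.
"""

import dataclasses
import json
from pathlib import Path

from degmeta import (
    correlation_battery,
    datasets,
    pca_2d_bootstrap,
    sign_concordance_table,
)
from degmeta import io as dio

OUT = Path(__file__).resolve().parent.parent / "results"
pairs = dio.read_pairs(OUT / "homolog_pairs.tsv")
seed = datasets.load_seed_degs()

battery = correlation_battery(pairs)
(OUT / "correlation_battery.json").write_text(
    json.dumps(dataclasses.asdict(battery), indent=2)
)
print(f"correlations over {battery.n} pairs: r={battery.r:.3f} "
      f"(p={battery.r_p:.2g}), R={battery.spearman:.3f}, "
      f"tau={battery.tau:.3f}, gamma={battery.gamma:.3f}")

pca = pca_2d_bootstrap(pairs, n_boot=999, seed=20260928)
(OUT / "pca.json").write_text(json.dumps(dataclasses.asdict(pca), indent=2))
print(f"PCA: r={pca.r:.3f}, eigenvalues=({pca.eigenvalues[0]:.3f}, "
      f"{pca.eigenvalues[1]:.3f}); PC1 loadings {pca.loadings[0]} "
      f"(difference axis), PC2 {pca.loadings[1]} (sum axis)")

rows = sign_concordance_table(seed, pairs)
dio.write_sign_concordance(rows, OUT / "sign_concordance.tsv")
sig = [r for r in rows if r.p_adj is not None and r.p_adj < 0.05]
print(f"sign concordance: {len(rows)} seed genes, "
      f"{sum(1 for r in rows if r.p is None)} without partners (ND)")
for r in sig:
    print(f"  significant after Bonferroni: {r.gene} "
          f"(opposite {r.n_pc1}, matching {r.n_pc2}, p={r.p:.3g}, "
          f"p_adj={r.p_adj:.3g})")
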