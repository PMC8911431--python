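#!/usr/bin/env python
"""Generate every synthetic input the pipeline consumes and sanity-check
its statistical structure.

Writes paired log2 fold changes, multi-study DEG tables with a homolog
map, a 3-vs-3 negative-binomial count matrix with planted DEGs, and
8-vs-8 qPCR triplicates under results/simulated/.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from degmeta import (
    SimConfig,
    simulate_counts,
    simulate_deg_tables,
    simulate_paired_log2,
    simulate_qpcr,
)
from degmeta import io as dio

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=20260928)

pairs = simulate_paired_log2(cfg)
dio.write_pairs(pairs, OUT / "paired_log2.tsv")
r = np.corrcoef([p.seed_log2 for p in pairs], [p.partner_log2 for p in pairs])[0, 1]
print(f"paired log2: {len(pairs)} pairs, target rho {cfg.rho}, sample r {r:.3f}")

seed_degs, partner_degs, hmap = simulate_deg_tables(cfg)
dio.write_deg_table(seed_degs, OUT / "seed_degs.tsv")
dio.write_deg_table(partner_degs, OUT / "partner_degs.tsv")
pd.DataFrame([dataclasses.asdict(e) for e in hmap]).to_csv(
    OUT / "homolog_map.tsv", sep="\t", index=False
)
print(
    f"DEG tables: {len(seed_degs)} seed genes, {len(partner_degs)} partner "
    f"records, {round(cfg.frac_discordant * cfg.n_seed_genes)} planted discordant"
)

matrix, planted = simulate_counts(cfg)
dio.write_expression_matrix(matrix, OUT / "counts.tsv", OUT / "groups.tsv")
(OUT / "planted_degs.txt").write_text("\n".join(planted) + "\n")
print(f"counts: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples, "
      f"{len(planted)} planted DEGs at |log2| = {cfg.effect_log2}")

qpcr = simulate_qpcr(cfg)
dio.write_qpcr_table(qpcr, OUT / "qpcr.tsv")
print(f"qPCR: {len(qpcr)} animals x {cfg.n_qpcr_replicates} replicates, "
      f"group effect x{cfg.qpcr_effect}")
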