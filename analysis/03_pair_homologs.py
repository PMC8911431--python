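#!/usr/bin/env python
"""Pair the 42 hippocampal stress-reactivity DEGs with their curated
hemoglobin/beta-protocadherin homologs from hypertensive-vs-normotensive
studies, writing the paired fold changes to results/homolog_pairs.tsv.
"""

from collections import Counter
from pathlib import Path

from degmeta import datasets, pair_homologs
from degmeta import io as dio

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

seed = datasets.load_seed_degs()
partners = datasets.load_hypertension_family_degs()
hmap = datasets.load_homolog_map()

pairs = pair_homologs(seed, partners, hmap)
dio.write_pairs(pairs, OUT / "homolog_pairs.tsv")

by_seed = Counter(p.seed_gene for p in pairs)
print(f"{len(pairs)} homolog pairs from {len(seed)} seed DEGs, "
      f"{len(partners)} partner records, {len(hmap)} map entries")
for gene, n in sorted(by_seed.items()):
    print(f"  {gene}: {n} partner study records")
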