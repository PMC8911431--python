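"""Pipeline orchestration: pair -> correlate -> PCA -> sign test ->
contrasts, with per-stage artifacts and a single summary JSON.

Stages run in the fixed verification order.  Every stage logs its input
and output row counts; all randomness flows from the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import datasets, io as dio
from .concordance import (
    correlation_battery,
    pca_2d_bootstrap,
    sign_concordance_table,
)
from .contingency import (
    build_2x2,
    binomial_direction_test,
    chi2_2x2,
    directional_acceptance_probability,
    equivalence_test,
    fisher_exact,
    polarize_divergence,
)
from .homology import pair_homologs
from .records import DegmetaError, DegRecord, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and thresholds for one pipeline run.

    Paths left as ``None`` fall back to the packaged curated tables.
    """

    seed_deg_path: Optional[str] = None
    partner_deg_path: Optional[str] = None
    homolog_map_path: Optional[str] = None
    divergence_deg_path: Optional[str] = None
    annotation_path: Optional[str] = None
    out_dir: str = "degmeta_out"
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None
    n_boot: int = 999
    seed: int = 0
    run_pairing: bool = True
    run_concordance: bool = True
    run_contrasts: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError("alpha must lie in (0, 1]")


def _battery_dict(b) -> dict:
    return dataclasses.asdict(b)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write artifacts under out_dir.

    Returns the summary dictionary (also written as summary.json).
    A stage failure raises, naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}

    seed_degs = (
        dio.read_deg_table(config.seed_deg_path)
        if config.seed_deg_path
        else datasets.load_seed_degs()
    )
    partner_degs = (
        dio.read_deg_table(config.partner_deg_path)
        if config.partner_deg_path
        else datasets.load_hypertension_family_degs()
    )
    homolog_map = (
        dio.read_homolog_map(config.homolog_map_path)
        if config.homolog_map_path
        else datasets.load_homolog_map()
    )

    pairs = []
    if config.run_pairing:
        try:
            pairs = pair_homologs(seed_degs, partner_degs, homolog_map)
        except DegmetaError as exc:
            raise DegmetaError(f"stage 'pair' failed: {exc}") from exc
        dio.write_pairs(pairs, out / "pairs.tsv")
        log.info("pair: %d seed + %d partner records -> %d pairs",
                 len(seed_degs), len(partner_degs), len(pairs))
        summary["stages"].append("pair")
        summary["n_pairs"] = len(pairs)

    if config.run_concordance:
        if not pairs:
            raise DegmetaError("stage 'concord' failed: no pairs available")
        try:
            battery = correlation_battery(pairs)
            pca = pca_2d_bootstrap(pairs, n_boot=config.n_boot, seed=config.seed)
            rows = sign_concordance_table(seed_degs, pairs, m=config.bonferroni_m)
        except DegmetaError as exc:
            raise DegmetaError(f"stage 'concord' failed: {exc}") from exc
        (out / "correlation_battery.json").write_text(
            json.dumps(_battery_dict(battery), indent=2)
        )
        (out / "pca.json").write_text(json.dumps(dataclasses.asdict(pca), indent=2))
        dio.write_sign_concordance(rows, out / "sign_concordance.tsv")
        log.info("concord: %d pairs -> battery(n=%d), %d sign rows",
                 len(pairs), battery.n, len(rows))
        summary["stages"].append("concord")
        summary["correlation"] = _battery_dict(battery)
        summary["pca_eigenvalues"] = list(pca.eigenvalues)
        summary["significant_seed_genes"] = [
            r.gene for r in rows if r.p_adj is not None and r.p_adj < config.alpha
        ]

    if config.run_contrasts:
        divergence = (
            dio.read_deg_table(config.divergence_deg_path)
            if config.divergence_deg_path
            else datasets.load_divergence_degs()
        )
        annotation = (
            dio.read_annotation(config.annotation_path)
            if config.annotation_path
            else datasets.load_direction_annotation()
        )
        try:
            polarities = [polarize_divergence(rec) for rec in divergence]
            table = build_2x2(polarities, annotation)
            one_sided, two_sided = fisher_exact(table)
            chi2, chi2_p = chi2_2x2(table)
            wild_tail = binomial_direction_test(
                table.a, table.a + table.b, "ge"
            ) if table.a + table.b else None
            domestic_tail = binomial_direction_test(
                table.d, table.c + table.d, "ge"
            ) if table.c + table.d else None
        except DegmetaError as exc:
            raise DegmetaError(f"stage 'contrast' failed: {exc}") from exc
        report = {
            "table": {"wild_hypertensive": table.a, "wild_normotensive": table.b,
                      "domestic_hypertensive": table.c, "domestic_normotensive": table.d},
            "fisher_one_sided": one_sided,
            "fisher_two_sided": two_sided,
            "chi2": chi2,
            "chi2_p": chi2_p,
            "binomial_ge_tail_wild_row": wild_tail,
            "binomial_ge_tail_domestic_row": domestic_tail,
        }
        (out / "contrast.json").write_text(json.dumps(report, indent=2))
        log.info("contrast: %d divergence records -> 2x2 %s",
                 len(divergence), report["table"])
        summary["stages"].append("contrast")
        summary["contrast"] = report

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def snp_pattern_report(counts=None) -> dict:
    """Direction tests on the SNP-marker counts (packaged by default)."""
    if counts is None:
        counts = datasets.load_snp_direction_counts()
    report = {}
    for name, dc in counts.items():
        entry = {
            "n_res": dc.n_res,
            "n_gt": dc.n_gt,
            "n_lt": dc.n_lt,
            "p_accept_neutral_drift": directional_acceptance_probability(dc),
        }
        eq = equivalence_test(dc)
        if eq is not None:
            entry["p_equivalence_one_sided"] = eq
        report[name] = entry
    return report
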