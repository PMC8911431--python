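"""Loaders for the packaged curated tables.

The package ships the published summary tables the meta-analysis runs on:
the 42 seed DEGs of the tame-vs-aggressive rat hippocampus contrast, the
37 hemoglobin/beta-protocadherin DEG records from hypertensive-vs-
normotensive studies, the curated family-level homolog map, the
published sign-concordance counts, the domestic-vs-wild divergence
records with their human-direction annotation, the per-animal qPCR
summaries, and the SNP direction counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as dio
from .records import (
    DegRecord,
    DirectionalCounts,
    HomologMapEntry,
    QpcrMeasurement,
)

_PKG = "degmeta.data"


def _path(name: str):
    return resources.files(_PKG).joinpath(name)


def load_seed_degs() -> list[DegRecord]:
    """The 42 hippocampal stress-reactivity DEGs (tame vs aggressive rats)."""
    return dio.read_deg_table(_path("rat_hippocampus_degs.tsv"))


def load_hypertension_family_degs() -> list[DegRecord]:
    """The 37 hemoglobin-subunit and beta-protocadherin DEG records from
    hypertensive-vs-normotensive studies (27 hemoglobin + 10 protocadherin)."""
    return dio.read_deg_table(_path("hypertension_family_degs.tsv"))


def load_homolog_map() -> list[HomologMapEntry]:
    """Curated family-level homolog map (hemoglobin and beta-protocadherin)."""
    return dio.read_homolog_map(_path("homolog_family_map.tsv"))


def load_published_sign_counts() -> pd.DataFrame:
    """Published per-seed-gene sign-concordance counts with the printed
    p-values (columns gene, n_pc1, n_pc2, p_printed, p_adj_printed)."""
    return pd.read_csv(_path("sign_concordance_counts.tsv"), sep="\t", dtype=str)


def load_divergence_degs() -> list[DegRecord]:
    """Hemoglobin/protocadherin DEG records from domestic-vs-wild contrasts."""
    return dio.read_deg_table(_path("divergence_degs.tsv"))


def load_direction_annotation() -> dict[str, str]:
    """gene -> human hypertension direction of downregulation."""
    return dio.read_annotation(_path("human_direction_annotation.tsv"))


def load_qpcr_measurements() -> list[QpcrMeasurement]:
    """Per-animal qPCR relative-expression summaries for *Ascl3* and
    *Defb17* (8 tame vs 8 aggressive rats).

    Raw technical replicates are not published; each animal's printed
    replicate mean (M0) is loaded as a single-replicate measurement, which
    is exactly what the group-level summaries consume.  The ND cell
    (aggressive animal 6, *Defb17*) is treated as missing.
    """
    df = pd.read_csv(_path("qpcr_relative_expression.tsv"), sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        if str(row["m0"]).strip().upper() == "ND":
            continue
        out.append(
            QpcrMeasurement(
                rat_id=row["rat_id"],
                group=row["group"],
                gene=row["gene"],
                replicate_values=(float(row["m0"]),),
            )
        )
    return out


def load_snp_direction_counts() -> dict[str, DirectionalCounts]:
    """Genome-wide and candidate-marker SNP direction counts at TBP sites."""
    return dio.read_directional_counts(_path("snp_direction_counts.json"))
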