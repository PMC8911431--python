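"""TSV exchange formats for DEG tables, homolog maps, pairs, qPCR data
and annotations.

All tables are tab-delimited UTF-8 with a header row.  Published p-value
bounds such as "<1e-4" parse to the bound with a flag; write/read of any
record list is the identity.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .records import (
    DegRecord,
    DirectionalCounts,
    HomologMapEntry,
    HomologPair,
    QpcrMeasurement,
    SignConcordanceRow,
    ValidationError,
)

PathLike = Union[str, Path]

_DEG_COLUMNS = ["study_id", "species", "tissue", "contrast", "gene", "log2", "p", "p_adj"]


def parse_p_value(text: str) -> tuple[float, bool]:
    """Parse a p-value cell; "<X" forms return (X, True)."""
    s = str(text).strip()
    is_bound = s.startswith("<")
    if is_bound:
        s = s[1:].strip()
    # tolerate the typographic form "10^-4"
    if s.startswith("10^"):
        s = "1e" + s[3:].strip("^")
    try:
        value = float(s)
    except ValueError:
        raise ValidationError(f"unparseable p-value {text!r}") from None
    return value, is_bound


def format_p_value(value: Optional[float], is_bound: bool = False) -> str:
    if value is None:
        return "ND"
    return f"<{value:g}" if is_bound else f"{value:.6g}"


def read_deg_table(path: PathLike) -> list[DegRecord]:
    """Read a per-study DEG table; malformed rows raise with line numbers."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            log2 = float(row["log2"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}:{line}: unparseable log2 {row['log2']!r}"
            ) from None
        p, p_bound = parse_p_value(row["p"])
        p_adj, p_adj_bound = parse_p_value(row["p_adj"])
        try:
            records.append(
                DegRecord(
                    study_id=row["study_id"],
                    species=row["species"],
                    tissue=row["tissue"],
                    contrast=row["contrast"],
                    gene=row["gene"],
                    log2=log2,
                    p=p,
                    p_adj=p_adj,
                    p_is_bound=p_bound,
                    p_adj_is_bound=p_adj_bound,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from None
    return records


def write_deg_table(records: Sequence[DegRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["p"] = format_p_value(r.p, r.p_is_bound)
        d["p_adj"] = format_p_value(r.p_adj, r.p_adj_is_bound)
        del d["p_is_bound"], d["p_adj_is_bound"]
        rows.append(d)
    pd.DataFrame(rows, columns=_DEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_homolog_map(path: PathLike) -> list[HomologMapEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["seed_gene", "partner_gene", "partner_species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return [
        HomologMapEntry(
            seed_gene=row["seed_gene"],
            partner_gene=row["partner_gene"],
            partner_species=row["partner_species"],
            family=row.get("family", ""),
        )
        for _, row in df.iterrows()
    ]


def write_pairs(pairs: Sequence[HomologPair], path: PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
        path, sep="\t", index=False
    )


def read_pairs(path: PathLike) -> list[HomologPair]:
    df = pd.read_csv(path, sep="\t", dtype={"seed_gene": str, "partner_gene": str})
    return [
        HomologPair(
            seed_gene=row.seed_gene,
            seed_log2=float(row.seed_log2),
            partner_gene=row.partner_gene,
            partner_log2=float(row.partner_log2),
            study_id=str(row.study_id),
            species=str(row.species),
            tissue=str(row.tissue),
        )
        for row in df.itertuples(index=False)
    ]


def write_sign_concordance(
    rows: Sequence[SignConcordanceRow], path: PathLike
) -> None:
    """Sign-concordance table with a full-precision and a printed-style
    p column (two decimals, or an order-of-magnitude for small values)."""

    def printed(p: Optional[float]) -> str:
        if p is None:
            return "ND"
        if p < 0.005:
            return f"1e{int(round(math.log10(p)))}"
        return f"{p:.2f}"

    records = []
    for r in rows:
        records.append(
            {
                "gene": r.gene,
                "n_pc1": r.n_pc1,
                "n_pc2": r.n_pc2,
                "p": "ND" if r.p is None else f"{r.p:.6g}",
                "p_adj": "ND" if r.p_adj is None else f"{r.p_adj:.6g}",
                "p_printed": printed(r.p),
                "p_adj_printed": printed(r.p_adj),
                "n_excluded_zero": r.n_excluded_zero,
                "significant": bool(r.p_adj is not None and r.p_adj < 0.05),
            }
        )
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def read_qpcr_table(path: PathLike) -> list[QpcrMeasurement]:
    """Read per-replicate qPCR values: rat_id, group, gene,
    replicate_index, value; rows with value "ND" are skipped (missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rat_id", "group", "gene", "replicate_index", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    grouped: dict[tuple[str, str, str], list[tuple[int, float]]] = {}
    for _, row in df.iterrows():
        if str(row["value"]).strip().upper() == "ND":
            continue
        key = (row["rat_id"], row["group"], row["gene"])
        grouped.setdefault(key, []).append(
            (int(row["replicate_index"]), float(row["value"]))
        )
    out = []
    for (rat, group, gene), reps in sorted(grouped.items()):
        reps.sort()
        out.append(
            QpcrMeasurement(
                rat_id=rat,
                group=group,
                gene=gene,
                replicate_values=tuple(v for _, v in reps),
            )
        )
    return out


def write_qpcr_table(
    measurements: Sequence[QpcrMeasurement], path: PathLike
) -> None:
    rows = []
    for m in measurements:
        for i, v in enumerate(m.replicate_values):
            rows.append(
                {
                    "rat_id": m.rat_id,
                    "group": m.group,
                    "gene": m.gene,
                    "replicate_index": i,
                    "value": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path: PathLike) -> dict[str, str]:
    """gene -> effect of downregulation ("normotensive"/"hypertensive")."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "downregulation_direction" not in df.columns:
        raise ValidationError(f"{path}: need gene and downregulation_direction")
    return dict(zip(df["gene"], df["downregulation_direction"]))


def read_expression_matrix(values_path: PathLike, groups_path: PathLike):
    """Gene x sample TSV (first column gene symbols) + sample->group TSV."""
    from .deg_calling import ExpressionMatrix

    df = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    if groups.shape[1] < 2:
        raise ValidationError(f"{groups_path}: need sample and group columns")
    mapping = dict(zip(groups.iloc[:, 0], groups.iloc[:, 1]))
    labels = []
    for s in df.columns:
        if s not in mapping:
            raise ValidationError(f"sample {s!r} has no group assignment")
        labels.append(mapping[s])
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        group_labels=labels,
        values=df.values,
    )


def write_expression_matrix(matrix, values_path: PathLike, groups_path: PathLike) -> None:
    matrix.to_frame().to_csv(values_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": matrix.sample_ids, "group": matrix.group_labels}
    ).to_csv(groups_path, sep="\t", index=False)


def read_directional_counts(path: PathLike) -> dict[str, DirectionalCounts]:
    """JSON of named DirectionalCounts objects."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: DirectionalCounts(**fields) for name, fields in raw.items()}
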