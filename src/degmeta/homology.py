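"""Pairing seed DEGs with their homologous DEGs from other studies.

Family-level homology (e.g. rat *Hbb-b1* with human *HBA1*) cannot be
inferred from gene symbols, so the curated homolog map is a first-class
input.  Exact symbol matches after normalization are added as a fallback
so that one-to-one orthologs need no map entry.  A partner gene that is
differentially expressed in k study-tissue records yields k pairs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .records import DegRecord, HomologMapEntry, HomologPair, ValidationError

log = logging.getLogger(__name__)


def normalize_symbol(symbol: str) -> str:
    """Canonical form used for matching: stripped and upper-cased.

    Hyphens and digits are preserved; family-level matching is the map's
    job, not string surgery.
    """
    s = symbol.strip()
    if not s:
        raise ValidationError("empty gene symbol")
    return s.upper()


def pair_homologs(
    seed: Sequence[DegRecord],
    others: Sequence[DegRecord],
    homolog_map: Sequence[HomologMapEntry] = (),
    fallback_exact_match: bool = True,
) -> list[HomologPair]:
    """Emit one :class:`HomologPair` per (map entry, matching partner study
    record), plus exact normalized-symbol matches when the fallback is on.

    Output is deterministic: sorted by (seed_gene, study_id, partner_gene)
    and free of duplicate (seed, partner, study) triples.
    """
    seed_by_symbol: dict[str, DegRecord] = {}
    for rec in seed:
        key = normalize_symbol(rec.gene)
        if key in seed_by_symbol:
            raise ValidationError(f"duplicate seed gene symbol {rec.gene!r}")
        seed_by_symbol[key] = rec

    # (normalized partner symbol, species) -> partner study records
    partners: dict[str, list[DegRecord]] = {}
    for rec in others:
        partners.setdefault(normalize_symbol(rec.gene), []).append(rec)

    emitted: set[tuple[str, str, str, str]] = set()
    pairs: list[HomologPair] = []

    def emit(seed_rec: DegRecord, partner_rec: DegRecord) -> None:
        key = (
            seed_rec.gene,
            partner_rec.gene,
            partner_rec.study_id,
            partner_rec.tissue,
        )
        if key in emitted:
            return
        emitted.add(key)
        pairs.append(
            HomologPair(
                seed_gene=seed_rec.gene,
                seed_log2=seed_rec.log2,
                partner_gene=partner_rec.gene,
                partner_log2=partner_rec.log2,
                study_id=partner_rec.study_id,
                species=partner_rec.species,
                tissue=partner_rec.tissue,
            )
        )

    for entry in homolog_map:
        seed_rec = seed_by_symbol.get(normalize_symbol(entry.seed_gene))
        if seed_rec is None:
            log.warning(
                "homolog map references seed gene %r absent from seed DEGs",
                entry.seed_gene,
            )
            continue
        for partner_rec in partners.get(normalize_symbol(entry.partner_gene), []):
            if (
                entry.partner_species
                and partner_rec.species
                and normalize_symbol(entry.partner_species)
                != normalize_symbol(partner_rec.species)
            ):
                continue
            emit(seed_rec, partner_rec)

    if fallback_exact_match:
        for key, seed_rec in seed_by_symbol.items():
            for partner_rec in partners.get(key, []):
                emit(seed_rec, partner_rec)

    pairs.sort(key=lambda p: (p.seed_gene, p.study_id, p.partner_gene, p.tissue))
    return pairs
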