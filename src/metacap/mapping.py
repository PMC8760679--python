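"""ASV -> GSMM matching and the reaction expectation matrix.

An ASV is matched to models by taxon-name equality at the lowest available
rank: species is tried first, then genus, then family; the first rank with
at least one matching model wins and all models at that rank are kept.
ASVs resolved only above family, or matching no model at any rank, are
unmappable and excluded from the reaction-level analysis.

For a mapped ASV j the expectation matrix entry E(i, j) is the frequency of
occurrence of reaction i among the models matched to j:

    E(i, j) = |{models of j containing i}| / |{models of j}|

so each column of E is a probability profile over reactions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MODEL_RANKS, AsvCountTable, ModelCatalog, TaxonomyTable
from .errors import ContractError

#: Match outcome rank for ASVs mapped to no model.
NO_MATCH = "none"


@dataclass(frozen=True)
class ModelMatch:
    """Match result for one ASV: the rank it matched at and the model ids."""

    asv_id: str
    matched_rank: str  # species | genus | family | none
    model_ids: tuple

    def __post_init__(self) -> None:
        if (self.matched_rank == NO_MATCH) != (len(self.model_ids) == 0):
            raise ContractError(
                f"{self.asv_id}: matched_rank={self.matched_rank!r} inconsistent "
                f"with {len(self.model_ids)} matched models"
            )


def match_asv_to_models(asv_id, taxonomy: TaxonomyTable, catalog: ModelCatalog) -> ModelMatch:
    """Match one ASV against the catalog at the lowest available rank.

    A species-level name that matches nothing falls back to genus, then
    family ("lowest rank with at least one match"). No match anywhere, or a
    taxonomy resolved only above family, yields ``matched_rank='none'`` —
    a value, not an error.
    """
    row = taxonomy.assignments.loc[asv_id]
    for rank in MODEL_RANKS:  # species, genus, family
        name = row[rank]
        if name is None:
            continue
        models = catalog.models_at(rank, name)
        if models:
            return ModelMatch(asv_id, rank, tuple(m.model_id for m in models))
    return ModelMatch(asv_id, NO_MATCH, ())


def match_all(taxonomy: TaxonomyTable, catalog: ModelCatalog) -> list[ModelMatch]:
    """Match every ASV in the taxonomy table, preserving order."""
    return [match_asv_to_models(a, taxonomy, catalog) for a in taxonomy.asv_ids]


def build_expectation_matrix(matches: list[ModelMatch], catalog: ModelCatalog) -> pd.DataFrame:
    """Build E (reactions x mapped ASVs) from per-ASV model matches.

    Rows are the union of reactions over all matched models; unmapped ASVs
    are excluded. Models are deduplicated by id within each ASV's matched
    set; several catalog entries sharing one taxon name all count toward
    the denominator.
    """
    mapped = [m for m in matches if m.matched_rank != NO_MATCH]
    if not mapped:
        raise ContractError("no ASV could be mapped to any model at family rank or lower")
    by_id = {m.model_id: m for m in catalog.models}
    reactions = sorted({r for mm in mapped for mid in set(mm.model_ids) for r in by_id[mid].reactions})
    rxn_index = {r: i for i, r in enumerate(reactions)}
    E = np.zeros((len(reactions), len(mapped)))
    for j, mm in enumerate(mapped):
        ids = sorted(set(mm.model_ids))
        for mid in ids:
            for r in by_id[mid].reactions:
                E[rxn_index[r], j] += 1.0
        E[:, j] /= len(ids)
    return pd.DataFrame(E, index=reactions, columns=[m.asv_id for m in mapped])


def mapping_summary(
    matches: list[ModelMatch],
    e_matrix: pd.DataFrame | None = None,
    abundances: pd.DataFrame | None = None,
) -> dict:
    """Summarize the mapping: ASVs and mean models per ASV per rank, total
    reactions, and — when a reaction abundance matrix is supplied — the
    fraction of reactions present (a_r > 0) in every sample and the minimum
    per-sample fraction of reactions present.
    """
    per_rank_n: dict = {r: 0 for r in MODEL_RANKS}
    per_rank_models: dict = {r: [] for r in MODEL_RANKS}
    unmapped = 0
    for m in matches:
        if m.matched_rank == NO_MATCH:
            unmapped += 1
        else:
            per_rank_n[m.matched_rank] += 1
            per_rank_models[m.matched_rank].append(len(set(m.model_ids)))
    summary = {
        "n_asvs": len(matches),
        "n_mapped": sum(per_rank_n.values()),
        "n_unmapped": unmapped,
        "mapped_per_rank": dict(per_rank_n),
        "mean_models_per_asv_per_rank": {
            r: (float(np.mean(v)) if v else 0.0) for r, v in per_rank_models.items()
        },
        "n_reactions": 0 if e_matrix is None else int(e_matrix.shape[0]),
        "empty_matrix": e_matrix is None or e_matrix.shape[1] == 0,
    }
    if abundances is not None:
        present = abundances.to_numpy() > 0
        summary["fraction_reactions_in_all_samples"] = float(present.all(axis=0).mean())
        summary["min_fraction_reactions_per_sample"] = float(present.mean(axis=1).min())
    return summary


def restrict_to_table(e_matrix: pd.DataFrame, table: AsvCountTable) -> pd.DataFrame:
    """Drop E columns for ASVs absent from a count table (convenience)."""
    keep = [a for a in e_matrix.columns if a in set(table.asv_ids)]
    if not keep:
        raise ContractError("no mapped ASV appears in the count table")
    return e_matrix[keep]
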