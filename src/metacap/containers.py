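"""In-memory containers for amplicon community data and GSMM catalogs.

The containers wrap pandas objects (and a scikit-bio tree) and enforce the
structural invariants the downstream analyses rely on: unique identifiers,
non-negative integer counts, hierarchically truncated taxonomy, non-empty
model reaction sets, and full subsystem coverage.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ContractError, FormatError

#: Taxonomic ranks from broadest to most specific.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Ranks at which a genome-scale metabolic model may be labelled, tried in
#: order from most to least specific when matching ASVs.
MODEL_RANKS = ("species", "genus", "family")

#: Subsystem label for reactions without a pathway annotation.
UNASSIGNED_SUBSYSTEM = "Unassigned"

_WS = re.compile(r"\s+")


def normalize_taxon_name(name: str) -> str:
    """Normalize a taxon name for matching.

    Trims whitespace, collapses underscores and internal runs of whitespace
    to single spaces, and compares case-insensitively. This absorbs the
    spelling drift between reference taxonomies and model catalogs
    (``Lachnospiraceae_UCG-001`` vs ``lachnospiraceae ucg-001``).
    """
    return _WS.sub(" ", name.strip().replace("_", " ")).casefold()


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AsvCountTable:
    """Samples x ASVs matrix of non-negative integer read counts.

    ``counts`` is indexed by sample id with one column per ASV id. Counts
    stay integral; every downstream quantity is computed from relative
    abundances, which the normalized reaction abundance formula makes
    scale-invariant, so no normalized copy is stored.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise FormatError("count table needs at least one sample and one ASV")
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "ASV")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("count table contains non-numeric cells")
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at sample {self.counts.index[r]!r}, "
                f"ASV {self.counts.columns[c]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("count table contains non-integer cells")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples stay all-zero."""
        totals = self.counts.sum(axis=1).to_numpy(dtype=float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts.div(safe, axis=0)


@dataclass
class TaxonomyTable:
    """Per-ASV rank assignments (domain..species), hierarchically truncated.

    ``assignments`` is indexed by ASV id with the seven columns of
    :data:`RANKS`; missing ranks are ``None``. A missing rank forces all
    lower ranks missing — entries violating this are truncated on
    construction with a warning rather than rejected, since reference
    taxonomies occasionally emit such gaps.
    """

    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.assignments.copy()
        missing_cols = [r for r in RANKS if r not in df.columns]
        if missing_cols:
            raise FormatError(f"taxonomy table missing rank columns: {missing_cols}")
        df = df[list(RANKS)]
        df = df.where(df.notna(), None)
        df = df.map(lambda v: None if v is None or str(v).strip() in ("", "NA") else str(v).strip())
        _check_unique(df.index, "ASV")
        # enforce hierarchical truncation
        arr = df.to_numpy(dtype=object)
        fixed = 0
        for i in range(arr.shape[0]):
            gap = False
            for j in range(len(RANKS)):
                if arr[i, j] is None:
                    gap = True
                elif gap:
                    arr[i, j] = None
                    fixed += 1
        if fixed:
            warnings.warn(
                f"taxonomy: {fixed} rank assignments below a missing rank were "
                "forced to missing (hierarchical truncation)",
                stacklevel=2,
            )
        self.assignments = pd.DataFrame(arr, index=df.index, columns=list(RANKS))

    @property
    def asv_ids(self) -> list:
        return list(self.assignments.index)

    def lowest_rank(self, asv_id) -> tuple[str | None, str | None]:
        """Return ``(rank, name)`` of the deepest assigned rank, or ``(None, None)``."""
        row = self.assignments.loc[asv_id]
        for rank in reversed(RANKS):
            if row[rank] is not None:
                return rank, row[rank]
        return None, None

    def require_cover(self, table: AsvCountTable) -> None:
        missing = set(table.asv_ids) - set(self.asv_ids)
        if missing:
            raise ContractError(
                f"taxonomy table missing {len(missing)} ASVs from the count table, "
                f"e.g. {sorted(missing)[:3]}"
            )


@dataclass
class SampleMetadata:
    """Sample -> dietary group and sample type (digesta / feed / water)."""

    table: pd.DataFrame  # index sample_id, columns: group, sample_type

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise FormatError("metadata needs a 'group' column")
        if "sample_type" not in self.table.columns:
            self.table = self.table.assign(sample_type="digesta")
        _check_unique(self.table.index, "sample")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def group_of(self, sample_id) -> str:
        return self.table.loc[sample_id, "group"]

    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: dict = {}
        for g in self.table["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list:
        return list(self.table.index[self.table["group"] == group])

    def require_cover(self, table: AsvCountTable, min_groups: int = 1) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ContractError(f"metadata missing samples: {sorted(missing)[:3]}")
        if len(self.groups()) < min_groups:
            raise ContractError(f"need at least {min_groups} groups, found {len(self.groups())}")


@dataclass(frozen=True)
class Model:
    """A genome-scale metabolic model reduced to its reaction content."""

    model_id: str
    rank: str
    name: str
    reactions: frozenset

    def __post_init__(self) -> None:
        if self.rank not in MODEL_RANKS:
            raise FormatError(
                f"model {self.model_id!r}: rank {self.rank!r} not in {MODEL_RANKS} "
                "(only family or lower ranks are mappable)"
            )
        if not self.reactions:
            raise FormatError(f"model {self.model_id!r} has an empty reaction set")


@dataclass
class ModelCatalog:
    """A GSMM collection: (taxon label, reaction set) pairs plus a
    reaction -> subsystem (pathway) map.

    Reactions absent from the subsystem map are filed under
    :data:`UNASSIGNED_SUBSYSTEM`. A reaction may belong to several
    subsystems.
    """

    models: list[Model]
    subsystems: dict = field(default_factory=dict)  # reaction -> tuple of subsystem names

    def __post_init__(self) -> None:
        _check_unique([m.model_id for m in self.models], "model")
        subs = {}
        all_reactions = set()
        for m in self.models:
            all_reactions |= m.reactions
        for rxn, names in self.subsystems.items():
            if isinstance(names, str):
                names = (names,)
            subs[rxn] = tuple(names)
        for rxn in all_reactions:
            if rxn not in subs or not subs[rxn]:
                subs[rxn] = (UNASSIGNED_SUBSYSTEM,)
        self.subsystems = subs
        # match index: (rank, normalized name) -> models
        self._by_rank_name: dict = {}
        for m in self.models:
            self._by_rank_name.setdefault((m.rank, normalize_taxon_name(m.name)), []).append(m)

    @property
    def reaction_ids(self) -> list:
        out = set()
        for m in self.models:
            out |= m.reactions
        return sorted(out)

    @property
    def subsystem_names(self) -> list:
        names = set()
        for v in self.subsystems.values():
            names.update(v)
        return sorted(names)

    def models_at(self, rank: str, name: str) -> list[Model]:
        """All models labelled with ``name`` at ``rank`` (normalized match)."""
        return list(self._by_rank_name.get((rank, normalize_taxon_name(name)), []))

    def subsystems_of(self, reaction) -> tuple:
        return self.subsystems.get(reaction, (UNASSIGNED_SUBSYSTEM,))


@dataclass
class PhyloTree:
    """A rooted tree over ASVs with non-negative branch lengths."""

    tree: TreeNode

    def __post_init__(self) -> None:
        leaves = [t.name for t in self.tree.tips()]
        _check_unique(leaves, "leaf")
        patched = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                patched += 1
            elif node.length < 0:
                raise FormatError(f"negative branch length at node {node.name!r}")
        if self.tree.length is None:
            self.tree.length = 0.0
        if patched:
            warnings.warn(f"tree: {patched} missing branch lengths set to 0", stacklevel=2)

    @property
    def leaf_names(self) -> list:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.tree.traverse(include_self=True)))
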