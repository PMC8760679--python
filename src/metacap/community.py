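"""Taxonomic community summaries: aggregation, core microbiota, shared
ASVs, rarefaction, and alpha diversity.

These are the composition-level descriptors reported alongside the
reaction-level analysis: relative abundances aggregated to a rank (or to
each ASV's lowest assigned rank), core ASVs at a prevalence threshold,
ASV overlap between sample types under a minimum-relative-abundance
presence rule, rarefaction to a common depth, and per-sample alpha
diversity (observed ASVs, Shannon, Pielou, Faith's PD).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import RANKS, AsvCountTable, PhyloTree, TaxonomyTable
from .errors import ContractError


def _faith_pd_presence(tree: PhyloTree, present: set) -> float:
    """Faith's PD: branch length of the minimal subtree spanning the root
    and all present leaves — a branch counts iff its subtree holds at
    least one present leaf. Handles multifurcations (star trees)."""
    total = 0.0
    has_present: dict = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            has_present[id(node)] = node.name in present
        else:
            has_present[id(node)] = any(has_present[id(c)] for c in node.children)
        if node.parent is not None and has_present[id(node)]:
            total += node.length or 0.0
    return total


def aggregate_relative_abundance(
    table: AsvCountTable, taxonomy: TaxonomyTable, rank_mode: str = "lowest"
) -> pd.DataFrame:
    """Aggregate counts to taxon labels, then convert to relative abundance.

    ``rank_mode`` is a fixed rank name (``"phylum"``, ``"genus"``, ...) or
    ``"lowest"``, which labels each ASV by its deepest assigned rank — the
    'genus or lowest taxonomy level' convention. ASVs with no usable label
    are pooled under ``"Unclassified"``. Empty samples stay all-zero with a
    warning.
    """
    if rank_mode != "lowest" and rank_mode not in RANKS:
        raise ContractError(f"rank_mode must be 'lowest' or one of {RANKS}, got {rank_mode!r}")
    taxonomy.require_cover(table)
    labels = {}
    for asv in table.asv_ids:
        if rank_mode == "lowest":
            _, name = taxonomy.lowest_rank(asv)
        else:
            name = taxonomy.assignments.loc[asv, rank_mode]
        labels[asv] = name if name is not None else "Unclassified"
    grouped = table.counts.T.groupby(pd.Series(labels)).sum().T  # samples x taxa
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} empty samples yield all-zero rows", stacklevel=2
        )
    safe = totals.replace(0, 1)
    return grouped.div(safe, axis=0)


def top_taxa(aggregated: pd.DataFrame, n: int) -> tuple[list, float]:
    """Top-``n`` taxa by mean relative abundance and their summed coverage.

    Ties break lexicographically by label for determinism. Asking for more
    taxa than exist returns them all.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    means = aggregated.mean(axis=0)
    order = sorted(means.index, key=lambda t: (-means[t], str(t)))
    chosen = order[: min(n, len(order))]
    return chosen, float(means[chosen].sum())


@dataclass
class CoreSet:
    """Core ASVs of a sample group at a prevalence threshold (percent)."""

    group: str
    threshold: float
    members: frozenset
    prevalence: pd.Series  # percent of samples in which each ASV is present


def core_asvs(
    table: AsvCountTable,
    samples_subset=None,
    prevalence_threshold: float = 80.0,
    min_rel_abundance: float = 0.0,
    group: str = "all",
) -> CoreSet:
    """Core ASVs: prevalence (percent of samples present) >= threshold.

    Presence defaults to raw count > 0; a positive ``min_rel_abundance``
    switches to a relative-abundance floor. The >= comparison means an ASV
    seen in exactly 80% of samples is core at threshold 80.
    """
    if not (0 < prevalence_threshold <= 100):
        raise ContractError("prevalence threshold must lie in (0, 100]")
    if min_rel_abundance < 0:
        raise ContractError("min_rel_abundance must be >= 0")
    samples = list(samples_subset) if samples_subset is not None else table.sample_ids
    if not samples:
        raise ContractError("empty sample subset")
    missing = set(samples) - set(table.sample_ids)
    if missing:
        raise ContractError(f"samples not in table: {sorted(missing)[:3]}")
    if min_rel_abundance > 0:
        present = table.relative_abundance().loc[samples] >= min_rel_abundance
    else:
        present = table.counts.loc[samples] > 0
    prevalence = 100.0 * present.mean(axis=0)
    members = frozenset(prevalence.index[prevalence >= prevalence_threshold])
    return CoreSet(group=group, threshold=prevalence_threshold, members=members, prevalence=prevalence)


def set_intersections(sets: dict) -> dict:
    """Venn-style region counts for 2-4 named sets.

    Returns ``{frozenset of names: count}`` for every non-empty membership
    pattern; region counts sum to the union size. More than 4 sets raise
    (report pairwise overlaps instead).
    """
    if not (2 <= len(sets) <= 4):
        raise ContractError("set_intersections supports 2-4 sets")
    names = list(sets)
    regions: dict = {}
    universe = set().union(*sets.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(*(set(sets[n]) for n in names if n not in combo)) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = len(inside - outside)
    assert sum(regions.values()) == len(universe)
    return regions


@dataclass
class OverlapResult:
    """Shared ASVs between two disjoint sample groups."""

    label_a: str
    label_b: str
    shared: frozenset
    n_shared: int
    abundance_fraction_a: float  # fraction of group A reads carried by shared ASVs
    abundance_fraction_b: float
    per_sample_fraction: pd.Series  # per sample, relative abundance of shared ASVs


def shared_asvs(
    table: AsvCountTable,
    group_a_samples,
    group_b_samples,
    min_rel_abundance: float = 0.0005,
    labels: tuple = ("A", "B"),
) -> OverlapResult:
    """ASVs present in both sample groups under an abundance presence rule.

    An ASV is present in a group if its relative abundance reaches
    ``min_rel_abundance`` (default 0.05%) in at least one of the group's
    samples. Also reports the fraction of each group's reads carried by
    the shared ASVs.
    """
    a = list(group_a_samples)
    b = list(group_b_samples)
    if set(a) & set(b):
        raise ContractError("sample groups must be disjoint")
    rel = table.relative_abundance()
    present_a = (rel.loc[a] >= min_rel_abundance).any(axis=0)
    present_b = (rel.loc[b] >= min_rel_abundance).any(axis=0)
    shared = frozenset(present_a.index[present_a & present_b])
    shared_cols = list(shared)

    def frac(samples):
        tot = table.counts.loc[samples].to_numpy().sum()
        if tot == 0:
            return 0.0
        return float(table.counts.loc[samples, shared_cols].to_numpy().sum() / tot)

    per_sample = rel.loc[a + b, shared_cols].sum(axis=1)
    return OverlapResult(
        label_a=labels[0],
        label_b=labels[1],
        shared=shared,
        n_shared=len(shared),
        abundance_fraction_a=frac(a),
        abundance_fraction_b=frac(b),
        per_sample_fraction=per_sample,
    )


def rarefy(table: AsvCountTable, depth: int, seed: int | None = None) -> AsvCountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Multivariate hypergeometric draw per sample, deterministic for a fixed
    seed. Samples with fewer than ``depth`` reads are dropped with a
    warning; a sample totalling exactly ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ContractError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(f"rarefy: dropped {len(dropped)} samples below depth {depth}", stacklevel=2)
    if len(keep) == 0:
        raise ContractError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for s in keep:
        counts = table.counts.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    return AsvCountTable(pd.DataFrame(rows, index=list(keep), columns=table.asv_ids))


def alpha_diversity(
    table: AsvCountTable, tree: PhyloTree | None = None, shannon_base: float = np.e
) -> pd.DataFrame:
    """Per-sample alpha diversity.

    observed = ASVs with count > 0; Shannon H = -sum p log p over present
    ASVs (natural log by default); Pielou = H / log(observed), defined 0
    for single-ASV samples; Faith's PD (needs the tree) = branch length of
    the minimal subtree spanning the root and all present leaves.
    """
    rel = table.relative_abundance().to_numpy()
    counts = table.counts.to_numpy()
    observed = (counts > 0).sum(axis=1)
    H = np.zeros(len(table.sample_ids))
    for i in range(rel.shape[0]):
        p = rel[i][rel[i] > 0]
        H[i] = float(-(p * (np.log(p) / np.log(shannon_base))).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(observed > 1, H / (np.log(observed) / np.log(shannon_base)), 0.0)
    out = pd.DataFrame(
        {"observed_asvs": observed, "shannon": H, "pielou": pielou},
        index=table.sample_ids,
    )
    if tree is not None:
        tree_leaves = set(tree.leaf_names)
        missing = set(table.asv_ids) - tree_leaves
        if missing:
            raise ContractError(f"tree lacks leaves for ASVs: {sorted(missing)[:5]}")
        asv_ids = np.array(table.asv_ids, dtype=object)
        out["faith_pd"] = [
            _faith_pd_presence(tree, set(asv_ids[counts[i] > 0]))
            for i in range(counts.shape[0])
        ]
    return out
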