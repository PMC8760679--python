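"""Pairwise differential reaction testing and pathway enrichment.

For each pair of dietary groups, every reaction's abundances are compared
with a two-sample t-test (Student's pooled-variance by default, Welch by
flag), p-values are Benjamini-Hochberg adjusted over the testable
reactions, and reactions with adjusted p <= 0.05 are called significant.
Subsystems (pathways) are then tested for over-representation of
significant reactions with a one-sided Fisher's exact test, BH-adjusted
across subsystems; each enriched subsystem is assigned a direction from the
sign of the mean t-statistic of its significant reactions.
"""
from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ModelCatalog, SampleMetadata
from .errors import ContractError

logger = logging.getLogger(__name__)

ALPHA = 0.05


def two_sample_t(values_a, values_b, welch: bool = False) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test; returns ``(t, p, testable)``.

    The t sign follows ``mean(a) - mean(b)``. When both groups have zero
    variance the hypothesis is untestable (no within-group spread to
    estimate error from); ``(nan, nan, False)`` is returned and the
    reaction is excluded from the multiple-testing universe.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (float("nan"), float("nan"), False)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return (float(res.statistic), float(res.pvalue), True)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjustment (monotone, capped at 1, original order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_reactions(
    abundance: pd.DataFrame,
    metadata: SampleMetadata,
    diet_pair: tuple,
    alpha: float = ALPHA,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-reaction differential table for one pair of diets.

    Columns: mean1, mean2, mean_diff (diet1 - diet2), t, p, p_adj,
    significant, tested. BH runs over the testable reactions only;
    untestable reactions carry NaN p-values and ``tested=False``.
    """
    d1, d2 = diet_pair
    groups = set(metadata.groups())
    for d in (d1, d2):
        if d not in groups:
            raise ContractError(f"unknown diet label {d!r}")
    s1 = [s for s in metadata.samples_in(d1) if s in abundance.index]
    s2 = [s for s in metadata.samples_in(d2) if s in abundance.index]
    if len(s1) < 2 or len(s2) < 2:
        raise ContractError(f"both diets need >=2 samples ({d1}: {len(s1)}, {d2}: {len(s2)})")
    A = abundance.loc[s1].to_numpy(dtype=float)
    B = abundance.loc[s2].to_numpy(dtype=float)
    mean1, mean2 = A.mean(axis=0), B.mean(axis=0)
    testable = ~((A.var(axis=0, ddof=1) == 0) & (B.var(axis=0, ddof=1) == 0))
    t = np.full(abundance.shape[1], np.nan)
    p = np.full(abundance.shape[1], np.nan)
    if testable.any():
        with warnings.catch_warnings():
            # near-constant reactions trigger scipy's precision-loss warning;
            # exactly-constant ones are already excluded as untestable
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(A[:, testable], B[:, testable], axis=0, equal_var=not welch)
        t[testable] = res.statistic
        p[testable] = res.pvalue
    p_adj = np.full(abundance.shape[1], np.nan)
    p_adj[testable] = benjamini_hochberg(p[testable])
    significant = np.zeros(abundance.shape[1], dtype=bool)
    significant[testable] = p_adj[testable] <= alpha
    return pd.DataFrame(
        {
            "diet1": d1,
            "diet2": d2,
            "mean1": mean1,
            "mean2": mean2,
            "mean_diff": mean1 - mean2,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
            "tested": testable,
        },
        index=abundance.columns,
    )


def _direction(t_values: np.ndarray, diet1, diet2) -> str:
    """Direction label for an enriched subsystem from its significant
    reactions' t-statistics: diet1 if the mean t is positive, diet2 if
    negative, 'mixed' when signs disagree and the mean is within its own
    95% CI half-width of zero."""
    mean_t = float(np.mean(t_values))
    signs_disagree = (t_values > 0).any() and (t_values < 0).any()
    n = t_values.size
    if signs_disagree and n > 1:
        half = sps.t.ppf(0.975, n - 1) * t_values.std(ddof=1) / np.sqrt(n)
        if abs(mean_t) < half:
            return "mixed"
    return str(diet1) if mean_t > 0 else str(diet2)


def pathway_enrichment(
    diff_table: pd.DataFrame,
    catalog: ModelCatalog,
    alpha: float = ALPHA,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher's exact subsystem enrichment over one pair's tested reactions.

    For each subsystem the 2x2 table counts significant/non-significant
    reactions inside/outside the subsystem (reactions in several subsystems
    count once per subsystem). One-sided over-representation by default;
    BH across subsystems with at least one tested reaction; enriched at
    adjusted p <= ``alpha``. Subsystems with zero tested reactions are
    skipped and logged. With no significant reactions the table is empty.
    """
    tested = diff_table[diff_table["tested"]]
    sig = set(tested.index[tested["significant"]])
    if not sig:
        return pd.DataFrame(
            columns=[
                "diet1", "diet2", "sig_in", "sig_out", "nonsig_in", "nonsig_out",
                "p", "p_adj", "enriched", "direction", "mean_t_sig", "ci_low", "ci_high",
            ]
        )
    d1 = diff_table["diet1"].iloc[0]
    d2 = diff_table["diet2"].iloc[0]
    n_tested = len(tested)
    by_sub: dict = {}
    for rxn in tested.index:
        for sub in catalog.subsystems_of(rxn):
            by_sub.setdefault(sub, []).append(rxn)
    skipped = [s for s in catalog.subsystem_names if s not in by_sub]
    if skipped:
        logger.info("enrichment: %d subsystems with no tested reactions skipped", len(skipped))
    rows = []
    for sub in sorted(by_sub):
        members = by_sub[sub]
        a = sum(1 for r in members if r in sig)
        b = len(sig) - a
        c = len(members) - a
        d = n_tested - a - b - c
        p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1]
        t_sig = tested.loc[[r for r in members if r in sig], "t"].to_numpy()
        if t_sig.size:
            mean_t = float(t_sig.mean())
            if t_sig.size > 1:
                half = sps.t.ppf(0.975, t_sig.size - 1) * t_sig.std(ddof=1) / np.sqrt(t_sig.size)
            else:
                half = np.nan
            direction = _direction(t_sig, d1, d2)
            ci_low, ci_high = mean_t - half, mean_t + half
        else:
            mean_t, ci_low, ci_high, direction = np.nan, np.nan, np.nan, "none"
        rows.append((d1, d2, a, b, c, d, p, np.nan, False, direction, mean_t, ci_low, ci_high))
    out = pd.DataFrame(
        rows,
        index=sorted(by_sub),
        columns=[
            "diet1", "diet2", "sig_in", "sig_out", "nonsig_in", "nonsig_out",
            "p", "p_adj", "enriched", "direction", "mean_t_sig", "ci_low", "ci_high",
        ],
    )
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["enriched"] = out["p_adj"] <= alpha
    return out


def pairwise_all(
    abundance: pd.DataFrame,
    metadata: SampleMetadata,
    catalog: ModelCatalog | None = None,
    alpha: float = ALPHA,
    welch: bool = False,
) -> dict:
    """Differential (and, given a catalog, enrichment) tables for every
    unordered pair of diets, keyed ``(diet1, diet2)`` with diet1 preceding
    diet2 in metadata order — 6 diets yield 15 pairs."""
    groups = metadata.groups()
    if len(groups) < 2:
        raise ContractError("pairwise analysis needs at least 2 diets")
    out = {}
    for d1, d2 in itertools.combinations(groups, 2):
        diff = differential_reactions(abundance, metadata, (d1, d2), alpha=alpha, welch=welch)
        enr = pathway_enrichment(diff, catalog, alpha=alpha) if catalog is not None else None
        out[(d1, d2)] = (diff, enr)
    return out


def direction_matrix(results: dict) -> pd.DataFrame:
    """Machine twin of the enrichment heat map: enriched subsystems x diet
    pairs with +1 (diet1), -1 (diet2), 0 (mixed/absent) direction codes."""
    cols = {}
    for (d1, d2), (_, enr) in results.items():
        label = f"{d1} vs {d2}"
        col = {}
        if enr is not None:
            for sub, row in enr[enr["enriched"]].iterrows():
                col[sub] = 1 if row["direction"] == d1 else (-1 if row["direction"] == d2 else 0)
        cols[label] = col
    mat = pd.DataFrame(cols).fillna(0).astype(int)
    return mat.sort_index()
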