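"""Normalized reaction abundances, z-score standardization, and PCA.

The central quantity is the per-sample normalized abundance of reaction i,

    a_r(i) = sum_j a_ASV(j) E(i, j) / sum_j a_ASV(j)

where a_ASV(j) is the read count (or any positively scaled abundance) of
mapped ASV j in the sample and E(i, j) is the expectation matrix column of
that ASV. Only mapped ASVs enter numerator and denominator, which makes
a_r a weighted mean of the E(i, .) row: scale-invariant per sample and
bounded by [min_j E(i,j), max_j E(i,j)].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AsvCountTable, SampleMetadata
from .errors import ContractError


def compute_reaction_abundances(table: AsvCountTable, e_matrix: pd.DataFrame) -> pd.DataFrame:
    """Compute a_r for every sample (rows) and reaction (columns).

    ASVs absent from E (unmapped) are excluded from both numerator and
    denominator. A sample with zero total count over mapped ASVs has no
    defined reaction profile and raises :class:`ContractError`.
    """
    missing = [a for a in e_matrix.columns if a not in set(table.asv_ids)]
    if missing:
        raise ContractError(
            f"expectation matrix references ASVs absent from the count table: {missing[:3]}"
        )
    A = table.counts[list(e_matrix.columns)].to_numpy(dtype=float)  # samples x mapped ASVs
    denom = A.sum(axis=1)
    if np.any(denom <= 0):
        bad = [table.sample_ids[i] for i in np.flatnonzero(denom <= 0)]
        raise ContractError(f"samples with zero total mapped abundance: {bad[:5]}")
    vals = (A @ e_matrix.to_numpy().T) / denom[:, None]
    return pd.DataFrame(vals, index=table.sample_ids, columns=list(e_matrix.index))


@dataclass
class StandardizedMatrix:
    """Per-column z-scores; zero-variance columns are zeroed and flagged."""

    values: pd.DataFrame
    zero_variance: list = field(default_factory=list)


def zscore_standardize(matrix: pd.DataFrame) -> StandardizedMatrix:
    """Standardize each column to mean 0, sd 1 (ddof=1) across samples.

    Columns with zero variance cannot be standardized; they are set to 0
    and listed in ``zero_variance``. Requires at least two samples.
    """
    if matrix.shape[0] < 2:
        raise ContractError("standardization needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = sd == 0
    safe = np.where(flat, 1.0, sd)
    z = (x - mean) / safe
    z[:, flat] = 0.0
    return StandardizedMatrix(
        values=pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        zero_variance=list(matrix.columns[flat]),
    )


@dataclass
class PcaResult:
    """PCA scores, loadings, percent variance explained, and optional
    per-group mean scores with 95% confidence intervals."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_pct: np.ndarray  # per returned component, of total variance
    explained_pct_all: np.ndarray  # over the full rank (sums to 100)
    mean: np.ndarray  # column means removed before the SVD
    group_scores: pd.DataFrame | None = None  # (group, component) -> mean, ci_low, ci_high


def pca(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    metadata: SampleMetadata | None = None,
    standardize: bool = False,
) -> PcaResult:
    """PCA via SVD of the column-centered matrix.

    Variance-explained percentages are fractions of the total variance, so
    they are non-increasing and sum to 100% over all ``min(n-1, p)``
    components. The sign of each component is fixed by forcing its
    largest-magnitude loading positive. With ``standardize=True`` columns
    are z-scored first (the "standardized ASVs" path). When metadata is
    given, per-group mean scores carry 95% t-based confidence intervals
    (group n-1 degrees of freedom — group sizes here are small).
    """
    if matrix.shape[0] < 2:
        raise ContractError("PCA needs at least 2 samples")
    if standardize:
        matrix = zscore_standardize(matrix).values
    x = matrix.to_numpy(dtype=float)
    n, p = x.shape
    rank = min(n - 1, p)
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ContractError(f"n_components={n_components} exceeds min(samples-1, features)={rank}")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # reproducible orientation: largest-|loading| entry of each PC positive
    for k in range(rank):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s**2
    explained_all = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros(rank)
    scores = u[:, :n_components] * s[:n_components]
    comps = [f"PC{k + 1}" for k in range(n_components)]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=comps)
    loadings_df = pd.DataFrame(vt[:n_components].T, index=matrix.columns, columns=comps)
    group_scores = None
    if metadata is not None:
        rows = []
        for g in metadata.groups():
            samp = [s_ for s_ in metadata.samples_in(g) if s_ in scores_df.index]
            sub = scores_df.loc[samp]
            m = sub.mean(axis=0)
            ng = len(samp)
            if ng > 1:
                half = stats.t.ppf(0.975, ng - 1) * sub.std(axis=0, ddof=1) / np.sqrt(ng)
            else:
                half = pd.Series(np.nan, index=comps)
            for c in comps:
                rows.append((g, c, m[c], m[c] - half[c], m[c] + half[c], ng))
        group_scores = pd.DataFrame(
            rows, columns=["group", "component", "mean", "ci_low", "ci_high", "n"]
        )
    return PcaResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_pct=explained_all[:n_components],
        explained_pct_all=explained_all,
        mean=mean,
        group_scores=group_scores,
    )
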