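"""Ordination and environmental model selection.

The sample matrix of oligotype relative abundances (samples x oligotypes,
genus-normalised, 'other' bucket excluded) is decomposed by centered,
unscaled PCA. Oligotypes are projected onto the first two components in the
biplot convention (loadings scaled by singular values), groups of oligotypes
are compared by the Euclidean distance between their centroids in the
PC1/PC2 plane, and each component's sample scores are regressed on all
2^4 subsets of the four environmental covariates — temperature, salinity,
dissolved oxygen and trailing weekly precipitation — keeping the subset
that minimises the BIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: canonical covariate column names, in report order
COVARIATES = ("temp_c", "salinity_psu", "dissolved_oxygen", "weekly_precip")

#: RSS floor (per observation) that keeps the BIC finite on perfect fits
_RSS_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# covariate preparation
# ---------------------------------------------------------------------------

def weekly_precip(daily: pd.Series, sample_date) -> float:
    """Trailing 7-day precipitation sum, sampling day included.

    ``daily`` must be indexed by date. If any of the 7 days is absent from
    the series the result is missing (NaN), never an implicit 0.
    """
    sample_date = pd.Timestamp(sample_date)
    window = pd.date_range(end=sample_date, periods=7)
    values = daily.reindex(window)
    if values.isna().any():
        return float("nan")
    return float(values.sum())


def add_weekly_precip(env: pd.DataFrame, daily: pd.Series) -> pd.DataFrame:
    """Attach a ``weekly_precip`` column computed from a daily series."""
    out = env.copy()
    out["weekly_precip"] = [
        weekly_precip(daily, d) for d in pd.to_datetime(out["date"])
    ]
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Centered-covariance PCA of a samples x oligotypes matrix."""

    scores: pd.DataFrame          # samples x PCs
    loadings: pd.DataFrame        # oligotypes x PCs
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: pd.Series               # per-oligotype centering vector

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame, drop_missing: bool = True) -> PCAResult:
    """Principal components of a samples x oligotypes relative-abundance matrix.

    The matrix is column-centered but not variance-scaled (all entries share
    units). Missing samples (any NaN in the row) are dropped when
    ``drop_missing``; at least 2 samples and 2 oligotypes must remain. The
    sign of each component is fixed deterministically: the largest-magnitude
    loading entry is made positive.
    """
    X = matrix.copy()
    if drop_missing:
        X = X.dropna(axis=0, how="any")
    if X.isna().any().any():
        raise ValueError("matrix contains missing values; enable drop_missing")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(
            f"PCA needs >=2 usable samples and >=2 oligotypes, got {X.shape}"
        )
    mean = X.mean(axis=0)
    C = (X - mean).to_numpy(dtype=float)
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for j in range(S.size):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    pcs = [f"PC{j + 1}" for j in range(S.size)]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=X.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=pcs),
        singular_values=S,
        explained_variance_ratio=ratio,
        mean=mean,
    )


def project_oligotypes(r: PCAResult) -> pd.DataFrame:
    """Oligotype coordinates on (PC1, PC2) in the biplot convention.

    Each oligotype's coordinate is its loading scaled by the corresponding
    singular value; a zero-variance oligotype lands at the origin.
    """
    if r.n_components < 2:
        raise ValueError("projection requires at least 2 principal components")
    coords = r.loadings.iloc[:, :2] * r.singular_values[:2]
    coords.columns = ["PC1", "PC2"]
    return coords


def group_centroid_distance(
    coords: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Pairwise Euclidean distances between group centroids in the PC1/PC2 plane.

    ``groups`` maps oligotype id -> group label; oligotypes without a label
    are ignored. At least two non-empty groups are required.
    """
    labelled = {o: g for o, g in groups.items() if o in coords.index}
    names = sorted(set(labelled.values()))
    if len(names) < 2:
        raise ValueError("centroid distances require at least 2 non-empty groups")
    centroids = {
        g: coords.loc[[o for o, lab in labelled.items() if lab == g]].mean(axis=0)
        for g in names
    }
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        d = float(np.linalg.norm(centroids[a] - centroids[b]))
        out.loc[a, b] = out.loc[b, a] = d
    return out


# ---------------------------------------------------------------------------
# best-subset BIC regression
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    """Exhaustive best-subset OLS table for one response.

    ``table`` has one row per covariate subset (including the intercept-only
    model); ``selected`` is the BIC-minimising subset among full-rank fits.
    """

    table: pd.DataFrame
    selected: tuple[str, ...]
    n_samples: int

    @property
    def selected_row(self) -> pd.Series:
        mask = self.table["subset"].apply(lambda s: s == self.selected)
        return self.table[mask].iloc[0]


def _bic(rss: float, n: int, k: int) -> float:
    """Gaussian BIC with the error variance profiled out: n ln(RSS/n) + k ln(n)."""
    rss = max(rss, n * _RSS_FLOOR)
    return n * np.log(rss / n) + k * np.log(n)


def best_subset_bic(
    pc_scores: pd.Series,
    env: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
) -> ModelSelectionResult:
    """Fit all covariate subsets by OLS and rank them by BIC.

    The intercept is always included (the empty subset is the intercept-only
    model). Samples missing the response or any covariate are removed
    listwise; at least 6 complete samples are required. A rank-deficient
    design is flagged and excluded from the argmin.
    """
    covariates = tuple(covariates)
    df = env.loc[:, list(covariates)].copy()
    df["_y"] = pc_scores
    df = df.dropna(axis=0, how="any")
    n = df.shape[0]
    if n < 6:
        raise ValueError(f"best-subset regression needs >=6 complete samples, got {n}")
    y = df["_y"].to_numpy(dtype=float)

    rows = []
    for size in range(len(covariates) + 1):
        for subset in combinations(covariates, size):
            X = sm.add_constant(df.loc[:, list(subset)].to_numpy(dtype=float), has_constant="add")
            k = X.shape[1]
            full_rank = int(np.linalg.matrix_rank(X)) == k
            if full_rank:
                fit = sm.OLS(y, X).fit()
                rss = float(fit.ssr)
                coefs = dict(zip(("intercept",) + subset, fit.params))
                bic = _bic(rss, n, k)
            else:
                rss, coefs, bic = np.nan, {}, np.nan
            rows.append(
                {
                    "subset": subset,
                    "k": k,
                    "rss": rss,
                    "bic": bic,
                    "full_rank": full_rank,
                    "coefficients": coefs,
                }
            )
    table = pd.DataFrame(rows)
    usable = table[table["full_rank"]]
    if usable.empty:
        raise ValueError("all candidate designs are rank-deficient")
    selected = tuple(usable.loc[usable["bic"].idxmin(), "subset"])
    return ModelSelectionResult(table=table, selected=selected, n_samples=n)


def best_subsets_for_pcs(
    r: PCAResult, env: pd.DataFrame, n_pcs: int = 2,
    covariates: Sequence[str] = COVARIATES,
) -> dict[str, ModelSelectionResult]:
    """Best-subset BIC selection for the first ``n_pcs`` components."""
    out = {}
    for pc in r.scores.columns[:n_pcs]:
        out[pc] = best_subset_bic(r.scores[pc], env, covariates)
    return out
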