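"""Descriptive multivariate views of the quantified proteome.

Plot-ready tables rather than rendered figures: PCA biplot coordinates
(sample scores overlaid with the strongest protein loadings), a Z-scored
heatmap of the top differentially expressed proteins with hierarchical
row/column ordering, per-protein five-number summaries for group box
plots, and set-overlap/coverage counts against a curated annotation (for
example, a solute-carrier family list).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

from .containers import ConfigurationError, DataError, ProteinQuantMatrix


@dataclass
class PCAResult:
    """Sample scores, orthonormal protein loadings and explained-variance
    ratios from an SVD of the centered (optionally scaled) matrix."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray
    top_loadings: list[str] = field(default_factory=list)
    dropped_proteins: list[str] = field(default_factory=list)


def pca_biplot(
    matrix: ProteinQuantMatrix,
    protein_subset: list[str] | None = None,
    k_loadings: int = 10,
    scale: bool = True,
) -> PCAResult:
    """PCA of samples over a protein subset, with biplot annotations.

    Proteins with any missing value are dropped (complete-case; reported
    in ``dropped_proteins``).  Each protein is centered and, by default,
    unit-scaled before the SVD, so molecule classes on different variance
    scales contribute comparably.  ``top_loadings`` are the ``k_loadings``
    proteins with the largest Euclidean loading norm over the first two
    components.
    """
    data = matrix.data
    if protein_subset is not None:
        missing = set(protein_subset) - set(data.index)
        if missing:
            raise DataError(f"subset proteins not in matrix: {sorted(missing)}")
        data = data.loc[protein_subset]
    complete = data.dropna(axis=0)
    dropped = sorted(set(data.index) - set(complete.index))
    if len(complete) < 3:
        raise DataError(
            f"only {len(complete)} complete-case proteins; need >= 3 for PCA"
        )

    X = complete.to_numpy(dtype=float).T  # samples x proteins
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_comp = min(X.shape)
    comps = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(U * S, index=complete.columns, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=complete.index, columns=comps)
    total = float((S**2).sum())
    evr = S**2 / total if total > 0 else np.zeros_like(S)

    norms = np.sqrt((loadings.iloc[:, : min(2, n_comp)] ** 2).sum(axis=1))
    top = list(norms.sort_values(ascending=False).index[:k_loadings])
    return PCAResult(scores, loadings, evr, top, dropped)


@dataclass
class HeatmapSpec:
    """Z-scored top-protein matrix plus clustered display orders."""

    matrix: pd.DataFrame  # proteins x samples, row Z-scores
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def select_top_de(de: pd.DataFrame, k: int = 50) -> list[str]:
    """Top-k differentially expressed proteins: smallest adjusted p, ties
    broken by larger |log_fc| then accession."""
    ranked = de.assign(_abs_fc=de["log_fc"].abs()).sort_values(
        ["p_adjusted", "_abs_fc", "protein"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return list(ranked["protein"].head(k))


def zscore_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Per-row Z-score over present values (sample SD, n-1 denominator)."""
    vals = data.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    return pd.DataFrame((vals - mean) / sd, index=data.index, columns=data.columns)


def _nan_aware_linkage(X: np.ndarray, method: str) -> np.ndarray:
    dist = nan_euclidean_distances(X)
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method=method)


def zscore_heatmap(
    de: pd.DataFrame,
    matrix: ProteinQuantMatrix,
    k: int = 50,
    method: str = "average",
) -> HeatmapSpec:
    """Z-score heatmap of the top-k DE proteins with clustered ordering.

    Rows (proteins) and columns (samples) are ordered by agglomerative
    hierarchical clustering with Euclidean distance and, by default,
    average linkage; missing cells are handled pairwise-complete.
    """
    top = select_top_de(de, k)
    top = [p for p in top if p in matrix.data.index]
    if len(top) < 2:
        raise DataError("need >= 2 proteins for heatmap clustering")
    Z = zscore_rows(matrix.data.loc[top])
    X = Z.to_numpy(dtype=float)
    row_link = _nan_aware_linkage(X, method)
    col_link = _nan_aware_linkage(X.T, method)
    return HeatmapSpec(
        matrix=Z,
        row_order=[int(i) for i in leaves_list(row_link)],
        col_order=[int(i) for i in leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
    )


def group_boxplot_stats(
    matrix: ProteinQuantMatrix,
    design: pd.DataFrame,
    proteins: list[str],
) -> pd.DataFrame:
    """Five-number summaries (min, Q1, median, Q3, max) per protein and
    cohort over present values, with linear-interpolation quartiles.

    A group with no present values yields NaN summaries.
    """
    missing = set(proteins) - set(matrix.data.index)
    if missing:
        raise DataError(f"proteins not in matrix: {sorted(missing)}")
    rows = []
    for protein in proteins:
        for group, members in design.groupby("group")["sample_id"]:
            cols = [s for s in members if s in matrix.data.columns]
            vals = matrix.data.loc[protein, cols].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                summary = dict.fromkeys(
                    ("min", "q1", "median", "q3", "max"), np.nan
                )
            else:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                summary = {
                    "min": float(vals.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(vals.max()),
                }
            rows.append(
                {"protein": protein, "group": group, "n": int(vals.size), **summary}
            )
    return pd.DataFrame(rows)


def annotation_overlap(
    identified: set[str], annotation: pd.DataFrame
) -> tuple[int, pd.DataFrame, float]:
    """Coverage of a curated annotation by the identified proteins.

    ``annotation`` has columns ``protein`` and ``family``.  Returns the
    overall overlap count |identified ∩ annotated|, a per-family table
    (n_annotated, n_identified, fraction), and the mean fraction across
    families.
    """
    if not {"protein", "family"} <= set(annotation.columns):
        raise ConfigurationError(
            "annotation table needs 'protein' and 'family' columns"
        )
    annotated = set(annotation["protein"])
    overlap = len(identified & annotated)
    rows = []
    for family, members in annotation.groupby("family")["protein"]:
        fam = set(members)
        hit = len(fam & identified)
        rows.append(
            {
                "family": family,
                "n_annotated": len(fam),
                "n_identified": hit,
                "fraction": hit / len(fam) if fam else np.nan,
            }
        )
    per_family = pd.DataFrame(rows)
    mean_fraction = float(per_family["fraction"].mean()) if rows else np.nan
    return overlap, per_family, mean_fraction
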