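"""Normalization and cross-cohort harmonization of expression matrices.

The pipeline's conventions, applied in this order where relevant:

1. quantile normalization across samples within a cohort (ties within a
   column receive the mean of the reference values of their tied ranks);
2. mean-combination of technical replicate columns into one specimen column;
3. for linear-scale summarized arrays, rescaling every sample to a common
   trimmed-mean target intensity (default 600);
4. per-gene z-scoring within a cohort (population SD), the meaning of
   "normalized" for all pathway-level scores;
5. cross-cohort harmonization: duplicate specimens kept only in the first
   cohort that carries them, panels optionally restricted to the common gene
   intersection.

Genes with any missing value in a cohort are dropped from that cohort before
quantile normalization (count logged); missingness is never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.stats import trim_mean

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean distribution.

    After the transform every column's sorted values equal the across-column
    mean of sorted values; gene order is preserved.  Tied values within a
    column receive the mean of the reference values of their tied ranks.
    A single-column matrix is returned unchanged with a warning.
    """
    if X.n_samples < 2:
        logger.warning("quantile_normalize: single sample, returned unchanged")
        return X
    df = _drop_missing_genes(X.data)
    vals = df.to_numpy(dtype=float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values over exact-tie groups
        tied = pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    return X.with_data(pd.DataFrame(out, index=df.index, columns=df.columns))


def _drop_missing_genes(df: pd.DataFrame) -> pd.DataFrame:
    missing = df.isna().any(axis=1)
    if missing.any():
        logger.warning("dropping %d genes with missing values", int(missing.sum()))
        df = df.loc[~missing]
    return df


def combine_replicates(X: ExpressionMatrix,
                       replicate_map: Mapping[str, str]) -> ExpressionMatrix:
    """Mean-combine technical replicate columns into one column per specimen.

    ``replicate_map`` maps sample (column) ids to biological specimen ids;
    columns absent from the map pass through under their own id.  Output
    column order follows first occurrence in the input.
    """
    for sample in replicate_map:
        if sample not in X.data.columns:
            raise KeyError(f"replicate map names unknown sample {sample!r}")
    specimen_of = {s: replicate_map.get(s, s) for s in X.sample_ids}
    order: list[str] = []
    groups: dict[str, list[str]] = {}
    for s in X.sample_ids:
        spec = specimen_of[s]
        if spec not in groups:
            groups[spec] = []
            order.append(spec)
        groups[spec].append(s)
    for spec, cols in groups.items():
        if len(cols) == 0:
            raise ValueError(f"replicate group {spec!r} is empty")
    combined = {spec: X.data[cols].mean(axis=1) for spec, cols in groups.items()}
    out = pd.DataFrame({spec: combined[spec] for spec in order}, index=X.data.index)
    return X.with_data(out)


def scale_to_target_intensity(X: ExpressionMatrix, target: float = 600.0,
                              trim: float = 0.02) -> ExpressionMatrix:
    """Rescale each sample so its 2%-trimmed mean equals ``target``.

    The convention of summarized linear-intensity arrays scaled to a common
    target intensity; requires linear-scale non-negative input.
    """
    if X.scale != "linear":
        raise ValueError("target-intensity scaling applies to linear-scale matrices")
    vals = X.data.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("target-intensity scaling requires non-negative values")
    tm = np.array([trim_mean(vals[:, j], trim) for j in range(vals.shape[1])])
    if np.any(tm == 0):
        bad = [X.sample_ids[j] for j in np.flatnonzero(tm == 0)]
        raise ValueError(f"all-zero (trimmed-mean 0) columns: {bad}")
    out = vals * (target / tm)[None, :]
    return X.with_data(pd.DataFrame(out, index=X.data.index, columns=X.data.columns))


def zscore_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples (population SD).

    Constant genes become all-zero rows (warning); this is the "normalized"
    of every pathway-level expression score.
    """
    if X.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    vals = X.data.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning("zscore_genes: %d constant genes set to zero", int(constant.sum()))
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (vals - mean) / safe_sd
    out[constant, :] = 0.0
    return X.with_data(pd.DataFrame(out, index=X.data.index, columns=X.data.columns))


def harmonize_cohorts(cohorts: Sequence[ExpressionMatrix],
                      drop_duplicates: bool = True,
                      intersect_genes: bool = True) -> list[ExpressionMatrix]:
    """Cross-study harmonization before a pooled analysis.

    Duplicate sample ids across cohorts are kept in the first cohort (input
    order) and removed from later ones.  When ``intersect_genes`` is set,
    every cohort is restricted and row-ordered to the cross-cohort gene
    intersection (ordered as in the first cohort).  Idempotent.
    """
    if len(cohorts) == 0:
        raise ValueError("need at least one cohort")
    out = [c.with_data(c.data.copy()) for c in cohorts]

    if drop_duplicates:
        seen: set[str] = set()
        for i, c in enumerate(out):
            dup = [s for s in c.sample_ids if s in seen]
            if dup:
                logger.warning("cohort %s: dropping %d duplicate samples",
                               c.cohort_id, len(dup))
                out[i] = c.with_data(c.data.drop(columns=dup))
            seen.update(out[i].sample_ids)

    if intersect_genes and len(out) > 1:
        common = set(out[0].gene_ids)
        for c in out[1:]:
            common &= set(c.gene_ids)
        if not common:
            names = [c.cohort_id for c in cohorts]
            raise ValueError(f"empty gene intersection across cohorts {names}")
        order = [g for g in out[0].gene_ids if g in common]
        out = [c.with_data(c.data.loc[order]) for c in out]
    return out


@dataclass
class ClusterResult:
    """Agglomerative merge tree over one axis of an expression matrix."""

    ids: list[str]  # item ids in the (lexicographically sorted) linkage order
    linkage_matrix: np.ndarray
    order: list[str]  # dendrogram leaf ordering

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering into ``k`` clusters (id -> cluster label)."""
        flat = fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.ids, (int(x) for x in flat)))

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        root = to_tree(self.linkage_matrix)

        def fmt(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = node.get_left(), node.get_right()
            lb = max(node.dist - left.dist, 0.0)
            rb = max(node.dist - right.dist, 0.0)
            return f"({fmt(left)}:{lb:.6g},{fmt(right)}:{rb:.6g})"

        return fmt(root) + ";"


def hierarchical_cluster(X: ExpressionMatrix, axis: str = "samples",
                         metric: str = "euclidean",
                         method: str = "complete") -> ClusterResult:
    """Agglomerative clustering of genes or samples.

    Items are pre-sorted lexicographically by id before linkage so that ties
    are broken deterministically regardless of input column/row order.
    Missing values are an error: impute or drop genes first.
    """
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    obs = X.data.T if axis == "samples" else X.data
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if obs.isna().any().any():
        raise ValueError("missing values present; impute or drop before clustering")
    obs = obs.sort_index()  # deterministic tie-break by lexicographic id
    Z = linkage(obs.to_numpy(dtype=float), method=method, metric=metric)
    ids = list(obs.index)
    order = [ids[i] for i in leaves_list(Z)]
    return ClusterResult(ids=ids, linkage_matrix=Z, order=order)
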