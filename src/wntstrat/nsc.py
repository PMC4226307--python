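"""Nearest shrunken centroid (NSC) classification of Wnt/beta-catenin state.

The classifier standardizes each class centroid's offset from the overall
centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n),

with s_i the pooled within-class SD of gene i and fudge s0 = median_i s_i,
soft-thresholds the offsets by Delta,

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0),

and reconstructs shrunken centroids xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik.
A sample is assigned to the class minimizing the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2  -  2 log pi_k

over the genes shared between model and sample; posteriors are the softmax
of -delta_k / 2.  Delta is selected by stratified cross-validation as the
largest value tying the minimum CV error (preferring sparser models).

For transfer to an external tumor cohort the cohort is gene-z-scored within
itself, the model is retrained on z-scored training data restricted to the
shared genes (same Delta), and classification proceeds on the z-scores.
Per-gene z-scoring makes the calls invariant to per-gene affine distortions
of the cohort, which is the package's declared cross-platform convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix
from .preprocess import zscore_genes

logger = logging.getLogger(__name__)


def soft_threshold(d: float | np.ndarray, delta: float) -> float | np.ndarray:
    """sign(d) * max(|d| - delta, 0); delta must be non-negative."""
    if delta < 0:
        raise ValueError("shrinkage delta must be >= 0")
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


@dataclass
class WntCall:
    """Classifier output for one sample: Wnt-class posterior and binary call."""

    sample_id: str
    posterior: float  # posterior of the Wnt class
    call: str  # "Wnt+" | "Wnt-"


@dataclass
class ShrunkenCentroidModel:
    """Fitted NSC model storing the full shrinkage path.

    ``dik`` holds the unshrunken standardized offsets, so the shrunken model
    for any Delta on (or off) the grid is available via
    :meth:`shrunken_offsets` without refitting.
    """

    genes: list[str]
    classes: list[str]
    centroids: pd.DataFrame  # classes x genes
    overall_centroid: pd.Series  # gene -> mean
    s: pd.Series  # gene -> pooled within-class SD
    s0: float
    m_k: pd.Series  # class -> sqrt(1/n_k - 1/n)
    priors: pd.Series  # class -> prior
    dik: pd.DataFrame  # classes x genes, unshrunken offsets
    delta: float = 0.0
    delta_grid: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    training_data: pd.DataFrame | None = None  # genes x samples, for transfer
    training_classes: pd.Series | None = None

    def shrunken_offsets(self, delta: float | None = None) -> pd.DataFrame:
        d = self.delta if delta is None else delta
        return self.dik.apply(lambda row: soft_threshold(row.to_numpy(), d),
                              axis=1, result_type="broadcast")

    def shrunken_centroids(self, delta: float | None = None) -> pd.DataFrame:
        dp = self.shrunken_offsets(delta)
        scale = self.m_k.to_numpy()[:, None] * (self.s + self.s0).to_numpy()[None, :]
        return self.overall_centroid.to_numpy()[None, :] + scale * dp

    def nonzero_gene_count(self, delta: float | None = None) -> int:
        """Genes with a nonzero shrunken offset in any class."""
        dp = self.shrunken_offsets(delta)
        return int((dp != 0).any(axis=0).sum())


def train_nsc(X: ExpressionMatrix, classes, delta_grid=None,
              priors: str = "uniform") -> ShrunkenCentroidModel:
    """Fit the NSC model on a genes-by-samples training matrix.

    ``classes`` labels each sample; every class needs >= 2 samples.  The
    default Delta grid spans [0, max |d_ik|] in 30 steps.  ``priors`` is
    "uniform" or "empirical".
    """
    labels = pd.Series(classes)
    if len(labels) != X.n_samples:
        raise ValueError("class labels must match sample count")
    labels.index = X.sample_ids
    class_names = list(pd.unique(labels))
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"classes with < 2 samples: {list(small.index)}")

    values = X.data.to_numpy(dtype=float)
    n = X.n_samples
    overall = values.mean(axis=1)

    cents, mks, ss_within = {}, {}, np.zeros(X.n_genes)
    for cls in class_names:
        cols = (labels == cls).to_numpy()
        n_k = int(cols.sum())
        sub = values[:, cols]
        cents[cls] = sub.mean(axis=1)
        mks[cls] = np.sqrt(1.0 / n_k - 1.0 / n)
        ss_within += ((sub - cents[cls][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss_within / (n - len(class_names)))
    s0 = float(np.median(s))

    centroids = pd.DataFrame(cents, index=X.gene_ids).T.loc[class_names]
    m_k = pd.Series(mks).loc[class_names]
    dik = (centroids - overall[None, :]) / (
        m_k.to_numpy()[:, None] * (s + s0)[None, :])

    if priors == "uniform":
        pri = pd.Series(1.0 / len(class_names), index=class_names)
    elif priors == "empirical":
        pri = counts.loc[class_names] / n
    else:
        raise ValueError("priors must be 'uniform' or 'empirical'")

    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(np.abs(dik.to_numpy()).max()), 30)
    return ShrunkenCentroidModel(
        genes=X.gene_ids, classes=class_names, centroids=centroids,
        overall_centroid=pd.Series(overall, index=X.gene_ids),
        s=pd.Series(s, index=X.gene_ids), s0=s0, m_k=m_k, priors=pri,
        dik=dik, delta=0.0, delta_grid=np.asarray(delta_grid, dtype=float),
        training_data=X.data.copy(), training_classes=labels.copy(),
    )


def classify(model: ShrunkenCentroidModel, X: ExpressionMatrix,
             delta: float | None = None) -> pd.DataFrame:
    """Posterior per class and argmin-discriminant call for every sample.

    Genes are matched by symbol; the cohort may carry a subset of the model
    genes (missing model genes are dropped from the discriminant sum), but
    zero shared genes is an error.  Returns a DataFrame indexed by sample
    with one posterior column per class plus a ``call`` column.
    """
    shared = [g for g in model.genes if g in set(X.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between model and cohort")
    cent = model.shrunken_centroids(delta)[shared]
    denom = (model.s + model.s0).loc[shared].to_numpy()
    x = X.data.loc[shared].to_numpy(dtype=float)  # genes x samples

    # discriminant: standardized squared distance minus prior credit
    disc = np.empty((len(model.classes), X.n_samples))
    for i, cls in enumerate(model.classes):
        resid = (x - cent.loc[cls].to_numpy()[:, None]) / denom[:, None]
        disc[i] = (resid ** 2).sum(axis=0) - 2.0 * np.log(model.priors[cls])
    log_post = -disc / 2.0
    log_post -= log_post.max(axis=0, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=0, keepdims=True)

    out = pd.DataFrame(post.T, index=X.sample_ids, columns=model.classes)
    out["call"] = [model.classes[i] for i in disc.argmin(axis=0)]
    return out


def to_wnt_calls(assignments: pd.DataFrame, wnt_class: str) -> list[WntCall]:
    """Binary Wnt+/Wnt- view of a classification table."""
    if wnt_class not in assignments.columns:
        raise ValueError(f"class {wnt_class!r} not among {list(assignments.columns)}")
    calls = []
    for sid, row in assignments.iterrows():
        is_wnt = row["call"] == wnt_class
        calls.append(WntCall(sample_id=str(sid), posterior=float(row[wnt_class]),
                             call="Wnt+" if is_wnt else "Wnt-"))
    return calls


def cross_validate(X: ExpressionMatrix, classes, delta_grid=None,
                   folds: int = 5, seed: int = 0,
                   priors: str = "uniform") -> tuple[float, pd.DataFrame]:
    """Stratified K-fold misclassification error along the Delta grid.

    Returns the chosen Delta (largest value tying the minimum mean error,
    i.e. the sparsest model among the best) and the per-Delta error curve.
    Folds are stratified by class; if a class is smaller than ``folds`` the
    fold count is reduced with a warning (error if < 2 remain possible).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = pd.Series(classes)
    labels.index = X.sample_ids
    min_class = int(labels.value_counts().min())
    if min_class < 2:
        raise ValueError("every class needs >= 2 samples for stratified CV")
    if folds > min_class:
        logger.warning("reducing folds from %d to %d (smallest class)", folds, min_class)
        folds = min_class

    full = train_nsc(X, labels, delta_grid=delta_grid, priors=priors)
    grid = full.delta_grid

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros((folds, len(grid)))
    idx = np.arange(X.n_samples)
    for f, (train_idx, test_idx) in enumerate(skf.split(idx, labels.to_numpy())):
        X_tr = ExpressionMatrix(X.data.iloc[:, train_idx], cohort_id=X.cohort_id,
                                scale=X.scale)
        X_te = ExpressionMatrix(X.data.iloc[:, test_idx], cohort_id=X.cohort_id,
                                scale=X.scale)
        y_tr = labels.iloc[train_idx]
        y_te = labels.iloc[test_idx].to_numpy()
        model = train_nsc(X_tr, y_tr, delta_grid=grid, priors=priors)
        for j, d in enumerate(grid):
            pred = classify(model, X_te, delta=d)["call"].to_numpy()
            errors[f, j] = float((pred != y_te).mean())

    curve = pd.DataFrame({"delta": grid, "cv_error": errors.mean(axis=0)})
    best = curve["cv_error"].min()
    chosen = float(curve.loc[np.isclose(curve["cv_error"], best), "delta"].max())
    return chosen, curve


def transfer_classify(model: ShrunkenCentroidModel, cohort: ExpressionMatrix,
                      delta: float | None = None,
                      min_shared: float = 0.2) -> pd.DataFrame:
    """Apply the model to an external cohort under the z-scoring convention.

    The cohort is gene-z-scored within itself; the model is retrained on
    z-scored training data restricted to the shared genes with the same
    Delta and priors; classification then proceeds as usual.  Refuses when
    fewer than ``min_shared`` of the model genes are on the cohort panel.
    """
    if model.training_data is None:
        raise ValueError("model carries no training data; cannot transfer")
    shared = [g for g in model.genes if g in set(cohort.gene_ids)]
    frac = len(shared) / len(model.genes)
    if frac < min_shared:
        raise ValueError(
            f"cohort {cohort.cohort_id!r} shares only {frac:.1%} of model genes "
            f"(< {min_shared:.0%}); refusing to transfer")

    train = ExpressionMatrix(model.training_data.loc[shared],
                             cohort_id="training", scale="log2")
    train_z = zscore_genes(train)
    prior_kind = "uniform" if model.priors.nunique() == 1 else "empirical"
    refit = train_nsc(train_z, model.training_classes,
                      delta_grid=model.delta_grid, priors=prior_kind)
    refit.delta = model.delta if delta is None else delta

    cohort_z = zscore_genes(
        ExpressionMatrix(cohort.data.loc[shared], cohort_id=cohort.cohort_id,
                         scale=cohort.scale))
    result = classify(refit, cohort_z, delta=refit.delta)
    counts = result["call"].value_counts().to_dict()
    logger.info("cohort %s: call counts %s", cohort.cohort_id, counts)
    return result
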