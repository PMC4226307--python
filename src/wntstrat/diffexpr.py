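"""Permutation-based two-group differential expression with FDR and fold change.

The per-gene statistic is the moderated d familiar from significance analysis
of microarrays:

    d_i = (mean_A - mean_B) / (s_i * c + s0),   c = sqrt(1/n_A + 1/n_B)

where s_i is the pooled within-group SD and the fudge factor s0 is the median
over genes of s_i * c, guarding against near-zero-variance genes.  The false
discovery rate at a cut |d| >= t is estimated by label permutation:

    FDR(t) = mean_b #{ |d*_b| >= t } / #{ |d| >= t }

and a gene's q-value is the minimum FDR over all cuts t <= |d_i| (clipped to
[0, 1]), which makes q monotone non-increasing in |d| by construction.  The
mean of the permuted exceedance counts (the estimator of the original
significance-analysis formulation) is used rather than the median: with a
couple of hundred genes the median count at the most extreme cuts is
frequently exactly zero, which would hand the top-ranked genes q = 0 under a
pure null and destroy type-I-error control; the mean keeps the estimate
strictly positive once any permutation exceeds the cut.  No pi0 correction
is applied (conservative).  When
the number of distinct label assignments does not exceed the requested B, all
distinct assignments are enumerated instead of sampled.

Calls require both gates: q <= fdr threshold and linear fold change
2^|log2FC| >= fc threshold.  Expression is assumed to be on the log2 scale,
so log2FC = mean_A - mean_B.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class DiffExprResult:
    """Per-gene statistic, log2 fold change, q-value and up/down/none call."""

    table: pd.DataFrame  # index gene; columns d, log2fc, q, called
    group_a: str
    group_b: str
    s0: float

    @property
    def up(self) -> list[str]:
        return list(self.table.index[self.table["called"] == "up"])

    @property
    def down(self) -> list[str]:
        return list(self.table.index[self.table["called"] == "down"])


def _resolve_groups(X: ExpressionMatrix, groups, group_a) -> tuple[np.ndarray, str, str]:
    labels = pd.Series(groups)
    if len(labels) != X.n_samples:
        raise ValueError("group labels must match sample count")
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    a = uniq[0] if group_a is None else group_a
    if a not in uniq:
        raise ValueError(f"group_a {a!r} not among labels {uniq}")
    b = uniq[1] if uniq[0] == a else uniq[0]
    mask_a = (labels == a).to_numpy()
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    return mask_a, str(a), str(b)


def _dstat(values: np.ndarray, mask_a: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated d and log2FC for one label assignment (genes x samples input)."""
    A, B = values[:, mask_a], values[:, ~mask_a]
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    s0 = float(np.median(se))
    d = (ma - mb) / (se + s0)
    return d, ma - mb, s0


def gene_statistic(X: ExpressionMatrix, groups,
                   group_a=None) -> tuple[pd.DataFrame, float]:
    """Moderated d and log2 fold change (group A minus group B) per gene.

    Returns the per-gene table and the fudge factor s0.
    """
    mask_a, a, b = _resolve_groups(X, groups, group_a)
    d, lfc, s0 = _dstat(X.data.to_numpy(dtype=float), mask_a)
    return pd.DataFrame({"d": d, "log2fc": lfc}, index=X.data.index), s0


def _permutation_masks(mask_a: np.ndarray, B: int,
                       rng: np.random.Generator) -> np.ndarray:
    """B x n boolean matrix of permuted group-A memberships.

    Enumerates all distinct assignments when there are no more than B of
    them; otherwise samples B uniform label permutations.
    """
    n, na = len(mask_a), int(mask_a.sum())
    n_distinct = comb(n, na)
    if n_distinct < 10:
        raise ValueError(f"only {n_distinct} distinct label assignments; need >= 10")
    if n_distinct <= B:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), na)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((B, n), dtype=bool)
    for i in range(B):
        masks[i, rng.permutation(n)[:na]] = True
    return masks


def permutation_fdr(X: ExpressionMatrix, groups, B: int = 1000, seed: int = 0,
                    group_a=None) -> pd.Series:
    """Permutation q-values for the moderated d statistic.

    See the module docstring for the estimator.  ``B`` must be >= 100; the
    seed controls the sampled permutations (ignored under full enumeration).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    mask_a, _, _ = _resolve_groups(X, groups, group_a)
    values = X.data.to_numpy(dtype=float)
    d_obs, _, _ = _dstat(values, mask_a)

    rng = np.random.default_rng(seed)
    masks = _permutation_masks(mask_a, B, rng)
    n_genes = values.shape[0]
    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs, kind="mergesort")
    thresholds = abs_obs[order]
    # observed counts #{|d| >= t_j}
    obs_ge = n_genes - np.searchsorted(thresholds, thresholds, side="left")

    perm_counts = np.empty((masks.shape[0], n_genes))
    for i in range(masks.shape[0]):
        d_perm, _, _ = _dstat(values, masks[i])
        sorted_perm = np.sort(np.abs(d_perm))
        perm_counts[i] = len(sorted_perm) - np.searchsorted(
            sorted_perm, thresholds, side="left")
    mean_perm = perm_counts.mean(axis=0)

    fdr_at_t = mean_perm / obs_ge
    q_sorted = np.minimum.accumulate(np.clip(fdr_at_t, 0.0, 1.0))
    q = np.empty(n_genes)
    q[order] = q_sorted
    return pd.Series(q, index=X.data.index, name="q")


def call_differential(table: pd.DataFrame, fdr: float = 0.01,
                      fc: float = 1.5) -> tuple[list[str], list[str]]:
    """Split genes into up/down lists by the joint q-value and fold-change gate.

    ``fc`` is on the linear scale (e.g. 1.5 means 2^|log2FC| >= 1.5).
    """
    if not 0 < fdr <= 1:
        raise ValueError("fdr threshold must be in (0, 1]")
    if fc < 1:
        raise ValueError("fold-change threshold must be >= 1")
    if len(table) == 0:
        return [], []
    lfc_gate = np.log2(fc)
    passing = table["q"] <= fdr
    up = list(table.index[passing & (table["log2fc"] >= lfc_gate)])
    down = list(table.index[passing & (table["log2fc"] <= -lfc_gate)])
    return up, down


def differential_expression(X: ExpressionMatrix, groups, B: int = 1000,
                            seed: int = 0, fdr: float = 0.01, fc: float = 1.5,
                            group_a=None) -> DiffExprResult:
    """Full two-group analysis: statistic, permutation q-values, calls."""
    mask_a, a, b = _resolve_groups(X, groups, group_a)
    table, s0 = gene_statistic(X, groups, group_a=a)
    table["q"] = permutation_fdr(X, groups, B=B, seed=seed, group_a=a)
    up, down = call_differential(table, fdr=fdr, fc=fc)
    called = pd.Series("none", index=table.index)
    called[up] = "up"
    called[down] = "down"
    table["called"] = called
    return DiffExprResult(table=table, group_a=a, group_b=b, s0=s0)
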