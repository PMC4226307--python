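"""Pathway-level expression scores and enrichment/regulation tests.

Two scores, both computed on gene-z-scored expression ("normalized" means a
per-gene z across samples within one cohort, never pooled across cohorts):

* canonical score: mean z over the pathway genes present on the panel;
* oncogenic signed score: (sum of induced-gene z - sum of inhibited-gene z)
  divided by the number of signature genes on the panel, so induced genes
  weigh positively and inhibited genes negatively.

Overrepresentation of a gene set among differentially expressed genes is the
one-sided Fisher exact (hypergeometric upper-tail) test against the platform
panel as the universe, Bonferroni-corrected across tested pathways.
Differential pathway regulation between subtypes uses a Welch t-test with
Bonferroni correction plus a label-permutation p-value with the +1 correction
(so permutation p can never be exactly zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class PathwayScoreTable:
    """Pathway x sample score matrix plus per-pathway panel coverage."""

    scores: pd.DataFrame  # pathways x samples
    coverage: pd.Series  # pathway -> number of member genes on the panel
    provenance: str  # "canonical" | "oncogenic-signed"


@dataclass
class OverrepResult:
    """One-sided Fisher overrepresentation of a gene set among DE genes."""

    pathway: str
    k: int  # DE genes inside the set
    K: int  # set genes on the panel
    n: int  # DE genes on the panel
    N: int  # panel size (universe)
    p_raw: float
    p_bonferroni: float


def canonical_pathway_scores(Xz: ExpressionMatrix,
                             sets: list[GeneSet]) -> PathwayScoreTable:
    """Mean z-score over each pathway's genes present on the panel.

    A set with no genes on the panel scores NA for every sample (warning).
    """
    panel = set(Xz.gene_ids)
    rows, cov = {}, {}
    for gs in sets:
        present = [g for g in gs.members if g in panel]
        cov[gs.name] = len(present)
        if not present:
            logger.warning("pathway %s has no genes on the panel; score NA", gs.name)
            rows[gs.name] = np.full(Xz.n_samples, np.nan)
        else:
            rows[gs.name] = Xz.data.loc[present].mean(axis=0).to_numpy()
    scores = pd.DataFrame(rows, index=Xz.sample_ids).T
    return PathwayScoreTable(scores=scores, coverage=pd.Series(cov),
                             provenance="canonical")


def oncogenic_signature_score(Xz: ExpressionMatrix, signed_set: GeneSet) -> pd.Series:
    """Direction-weighted mean z for one signed signature.

    score = (sum_induced z - sum_inhibited z) / (members on panel).
    Every member present on the panel must carry a direction sign.
    """
    if signed_set.direction is None:
        raise ValueError(f"gene set {signed_set.name!r} has no direction signs")
    panel = set(Xz.gene_ids)
    present = [g for g in signed_set.members if g in panel]
    if not present:
        logger.warning("signature %s has no genes on the panel", signed_set.name)
        return pd.Series(np.nan, index=Xz.sample_ids, name=signed_set.name)
    unsigned = [g for g in present if g not in signed_set.direction]
    if unsigned:
        raise ValueError(
            f"members without direction on panel in {signed_set.name!r}: {unsigned}")
    signs = np.array([signed_set.direction[g] for g in present], dtype=float)
    z = Xz.data.loc[present].to_numpy(dtype=float)
    score = (signs[:, None] * z).sum(axis=0) / len(present)
    return pd.Series(score, index=Xz.sample_ids, name=signed_set.name)


def oncogenic_signature_scores(Xz: ExpressionMatrix,
                               signed_sets: list[GeneSet]) -> PathwayScoreTable:
    panel = set(Xz.gene_ids)
    rows = {gs.name: oncogenic_signature_score(Xz, gs).to_numpy() for gs in signed_sets}
    cov = {gs.name: len([g for g in gs.members if g in panel]) for gs in signed_sets}
    scores = pd.DataFrame(rows, index=Xz.sample_ids).T
    return PathwayScoreTable(scores=scores, coverage=pd.Series(cov),
                             provenance="oncogenic-signed")


def overrepresentation_test(de_genes, gene_set: GeneSet, universe,
                            n_tests: int = 1) -> OverrepResult:
    """Hypergeometric upper-tail P(X >= k) of set membership among DE genes.

    ``universe`` is the platform panel; ``de_genes`` must be a subset of it.
    ``n_tests`` applies a Bonferroni factor (use
    :func:`overrepresentation_tests` to test a collection).
    """
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError(f"DE genes outside universe: {sorted(de - universe)[:5]}")
    on_panel = set(gene_set.members) & universe
    if not on_panel:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the universe")
    k = len(de & on_panel)
    K, n, N = len(on_panel), len(de), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return OverrepResult(pathway=gene_set.name, k=k, K=K, n=n, N=N,
                         p_raw=p, p_bonferroni=min(1.0, p * n_tests))


def overrepresentation_tests(de_genes, sets: list[GeneSet],
                             universe) -> list[OverrepResult]:
    """Test every set, Bonferroni-corrected across the collection."""
    return [overrepresentation_test(de_genes, gs, universe, n_tests=len(sets))
            for gs in sets]


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Welch t with the zero-variance degenerate case mapped to t = 0."""
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 0.0
    se = np.sqrt(vx / len(x) + vy / len(y))
    return float((x.mean() - y.mean()) / se)


def differential_pathway_test(scores: PathwayScoreTable, subtypes,
                              reference: str = "TN", B: int = 1000,
                              seed: int = 0) -> pd.DataFrame:
    """Welch t of the reference subtype vs each other subtype, per pathway.

    Returns one row per (pathway, contrast) with the t statistic, its
    asymptotic p, a Bonferroni p over all pathway-contrast pairs, and a
    label-permutation p with the +1 correction.  Both groups need >= 2
    samples; a pathway with zero variance in both groups gets t = 0, p = 1
    (warning).
    """
    labels = pd.Series(subtypes)
    labels = labels.reindex(scores.scores.columns)
    if reference not in set(labels.dropna()):
        raise ValueError(f"reference subtype {reference!r} absent")
    others = [s for s in pd.unique(labels.dropna()) if s != reference]
    rng = np.random.default_rng(seed)

    rows = []
    contrasts = others if others else [reference]
    n_hyp = len(scores.scores.index) * len(contrasts)
    for contrast in contrasts:
        ref_cols = labels.index[labels == reference]
        con_cols = ref_cols if contrast == reference else labels.index[labels == contrast]
        if len(ref_cols) < 2 or len(con_cols) < 2:
            raise ValueError(f"contrast {reference} vs {contrast}: group with < 2 samples")
        for pathway in scores.scores.index:
            x = scores.scores.loc[pathway, ref_cols].to_numpy(dtype=float)
            y = scores.scores.loc[pathway, con_cols].to_numpy(dtype=float)
            t_obs = _welch_t(x, y)
            if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
                logger.warning("pathway %s: zero variance in both groups", pathway)
                p_t = 1.0
            else:
                df_w = _welch_df(x, y)
                p_t = float(2 * stats.t.sf(abs(t_obs), df_w)) if df_w > 0 else 1.0
            pooled = np.concatenate([x, y])
            t_perm = _permuted_welch(pooled, len(x), B, rng)
            exceed = int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
            p_perm = (1 + exceed) / (B + 1)
            rows.append({
                "pathway": pathway, "contrast": f"{reference} vs {contrast}",
                "t": t_obs, "p_t": min(p_t, 1.0),
                "p_bonferroni": min(1.0, p_t * n_hyp), "p_perm": p_perm,
            })
    return pd.DataFrame(rows)


def _permuted_welch(pooled: np.ndarray, n_ref: int, B: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Welch t for B random splits of ``pooled`` into groups of n_ref / rest."""
    n = len(pooled)
    idx = np.argsort(rng.random((B, n)), axis=1)
    values = pooled[idx]  # B x n, randomly ordered
    a, b = values[:, :n_ref], values[:, n_ref:]
    va = a.var(axis=1, ddof=1) / n_ref
    vb = b.var(axis=1, ddof=1) / (n - n_ref)
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / se
    return np.where(se == 0, 0.0, t)


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    if vx + vy == 0:
        return 0.0
    return (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
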