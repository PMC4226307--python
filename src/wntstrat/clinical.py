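"""Exact-test association of Wnt calls with clinical variables.

Contingency tables cross the binary Wnt call with pathological subtype,
intrinsic subtype, histological grade, or lymph-node status.  2x2 tables use
Fisher's exact test (two-sided p = sum of hypergeometric point masses no
larger than the observed table's).  2xK tables use the Freeman-Halton
generalization: exact enumeration of all tables with the observed margins
when the total count is small enough, otherwise a fixed-margin Monte-Carlo
estimate with the +1 correction.

The subtype association is reported both as the full 2xK table and as a
collapsed TN-vs-other 2x2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import inf

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import ClinicalTable
from .nsc import WntCall

logger = logging.getLogger(__name__)

ASSOCIATION_VARIABLES = ("pathological_subtype", "intrinsic_subtype",
                         "grade", "node_status")

# exact Freeman-Halton enumeration limits: spec'd N threshold plus a table cap
EXACT_N_MAX = 200
_EXACT_TABLE_CAP = 500_000


@dataclass
class ContingencyTable:
    """Wnt+/Wnt- by clinical-category count table."""

    counts: pd.DataFrame  # rows Wnt+, Wnt-; columns categories
    variable: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_table(calls, clinical: ClinicalTable, variable: str) -> ContingencyTable:
    """Cross-tabulate Wnt calls against one clinical variable.

    ``calls`` is a list of :class:`WntCall` or a sample-indexed Series of
    Wnt+/Wnt- labels.  Samples missing either the call or the variable are
    excluded (count logged).
    """
    if variable not in ASSOCIATION_VARIABLES:
        raise ValueError(f"variable must be one of {ASSOCIATION_VARIABLES}")
    if isinstance(calls, list) and calls and isinstance(calls[0], WntCall):
        call_series = pd.Series({c.sample_id: c.call for c in calls})
    else:
        call_series = pd.Series(calls)

    merged = pd.DataFrame({
        "wnt": call_series,
        "var": clinical.data[variable].reindex(call_series.index),
    })
    usable = merged.dropna()
    n_excluded = len(merged) - len(usable)
    if n_excluded:
        logger.info("build_table(%s): excluded %d samples with NA", variable, n_excluded)
    if usable.empty:
        raise ValueError(f"no usable samples for variable {variable!r}")

    counts = pd.crosstab(usable["wnt"], usable["var"])
    counts = counts.reindex(index=["Wnt+", "Wnt-"], fill_value=0)
    counts = counts.sort_index(axis=1)
    counts.index.name, counts.columns.name = "wnt_call", variable
    return ContingencyTable(counts=counts, variable=variable, n_excluded=n_excluded)


def collapse_binary(table: ContingencyTable, positive: str) -> ContingencyTable:
    """Collapse a 2xK table to 2x2: ``positive`` category vs pooled rest."""
    if positive not in table.counts.columns:
        raise ValueError(f"category {positive!r} not in table")
    rest = [c for c in table.counts.columns if c != positive]
    counts = pd.DataFrame({
        positive: table.counts[positive],
        "other": table.counts[rest].sum(axis=1),
    })
    counts.index.name = "wnt_call"
    return ContingencyTable(counts=counts, variable=f"{table.variable}:{positive}",
                            n_excluded=table.n_excluded)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact p for a 2x2 table (two-sided or 'greater').

    A table with a zero row or column margin carries no information and
    returns p = 1.
    """
    counts = _as_array(table, expect_cols=2)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return 1.0
    _, p = stats.fisher_exact(counts, alternative=alternative)
    return float(min(p, 1.0))


def _as_array(table, expect_cols: int | None = None) -> np.ndarray:
    counts = table.counts.to_numpy() if isinstance(table, ContingencyTable) \
        else np.asarray(table)
    if counts.shape[0] != 2 or (expect_cols and counts.shape[1] != expect_cols):
        raise ValueError(f"expected a 2x{expect_cols or 'K'} table, got {counts.shape}")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(int)
    return counts


def _log_table_prob(row1: np.ndarray, col_sums: np.ndarray, r1: int, N: int) -> float:
    """log P(table | margins) = sum_j log C(c_j, a_j) - log C(N, r1)."""
    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(logC(col_sums, row1)) - logC(N, r1))


def _enumerate_first_rows(col_sums: np.ndarray, r1: int, cap: int):
    """Yield all first-row vectors with the given margins; None if cap exceeded."""
    K = len(col_sums)
    out: list[np.ndarray] = []

    def rec(j: int, remaining: int, prefix: list[int]) -> bool:
        if j == K - 1:
            if 0 <= remaining <= col_sums[j]:
                out.append(np.array(prefix + [remaining]))
                if len(out) > cap:
                    return False
            return True
        tail_capacity = int(col_sums[j + 1:].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(col_sums[j], remaining)
        for a in range(lo, hi + 1):
            if not rec(j + 1, remaining - a, prefix + [a]):
                return False
        return True

    return out if rec(0, r1, []) else None


def fisher_exact_2xK(table, mc_reps: int = 100_000, seed: int = 0) -> float:
    """Freeman-Halton exact (or Monte-Carlo) p for a 2xK table.

    A 2x2 input reduces exactly to the two-sided 2x2 test.  Tables with
    total N <= 200 are enumerated exactly (unless the enumeration would
    exceed an internal table cap); larger tables are estimated by sampling
    ``mc_reps`` tables with the observed margins, with the +1 correction.
    """
    counts = _as_array(table)
    if counts.shape[1] == 2:
        return fisher_exact_2x2(counts, alternative="two-sided")
    col_sums = counts.sum(axis=0)
    r1 = int(counts[0].sum())
    N = int(counts.sum())
    if N == 0 or r1 == 0 or r1 == N or (col_sums == 0).all():
        return 1.0
    keep = col_sums > 0  # empty categories carry no probability mass
    counts, col_sums = counts[:, keep], col_sums[keep]

    log_p_obs = _log_table_prob(counts[0], col_sums, r1, N)
    tol = 1e-9 * abs(log_p_obs) + 1e-12

    if N <= EXACT_N_MAX:
        rows = _enumerate_first_rows(col_sums, r1, _EXACT_TABLE_CAP)
        if rows is not None:
            logs = np.array([_log_table_prob(r, col_sums, r1, N) for r in rows])
            p = float(np.exp(logs[logs <= log_p_obs + tol]).sum())
            return min(p, 1.0)
        logger.warning("2xK enumeration exceeds table cap; falling back to Monte-Carlo")

    rng = np.random.default_rng(seed)
    samples = rng.multivariate_hypergeometric(col_sums, r1, size=mc_reps)
    logs = gammaln(col_sums + 1)[None, :] - gammaln(samples + 1) \
        - gammaln(col_sums[None, :] - samples + 1)
    log_probs = logs.sum(axis=1) - (
        gammaln(N + 1) - gammaln(r1 + 1) - gammaln(N - r1 + 1))
    hits = int((log_probs <= log_p_obs + tol).sum())
    return (1 + hits) / (mc_reps + 1)


@dataclass
class AssociationResult:
    """One association analysis: table(s) and Fisher p-values."""

    variable: str
    table: ContingencyTable
    p: float
    collapsed: ContingencyTable | None = None
    p_collapsed: float | None = None


def associate(calls, clinical: ClinicalTable, variable: str,
              collapse: str | None = None, mc_reps: int = 100_000,
              seed: int = 0) -> AssociationResult:
    """Build the table for one variable and test it.

    2-category variables use the 2x2 test directly; wider tables use
    Freeman-Halton.  ``collapse`` names a category (e.g. "TN") to also test
    as a category-vs-rest 2x2.
    """
    table = build_table(calls, clinical, variable)
    p = fisher_exact_2xK(table, mc_reps=mc_reps, seed=seed)
    collapsed = p_collapsed = None
    if collapse is not None and table.counts.shape[1] > 2:
        collapsed = collapse_binary(table, collapse)
        p_collapsed = fisher_exact_2x2(collapsed)
    return AssociationResult(variable=variable, table=table, p=p,
                             collapsed=collapsed, p_collapsed=p_collapsed)
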