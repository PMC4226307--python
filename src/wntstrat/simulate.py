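"""Synthetic perturbation and tumor-cohort generators with planted Wnt structure.

Two generators share one configuration:

* :func:`simulate_perturbation_training` emulates an oncogene-transfection
  experiment in mammary epithelial cells: replicate profiles for a control
  class and five oncogenic classes (beta-catenin, E2F3, Myc, Ras, Src), each
  oncogene with a disjoint signed signature of uniquely induced (+) and
  inhibited (-) genes shifted by ``pathway_effect`` standard deviations.

* :func:`simulate_tumor_cohorts` emulates a multi-study breast-tumor
  meta-analysis: several cohorts on partially overlapping gene panels with
  per-cohort affine distortion, technical replicate columns, optional
  duplicated specimens shared between consecutive cohorts, subtype labels
  (HR+/HER2+/TN), a latent Wnt-activation state enriched in triple-negative
  samples that shifts the beta-catenin signature genes, grade and node
  annotation correlated with Wnt state, and censored exponential survival
  whose lung- and brain-metastasis hazards (but not bone, by default) depend
  on Wnt state.

Baseline expression is i.i.d. N(0, 1) on the log2 scale.  All randomness
flows through ``numpy.random.default_rng`` seeded from the config, so a fixed
seed gives byte-identical output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    SurvivalRecord,
)

ONCOGENE_CLASSES = ("beta-catenin", "E2F3", "Myc", "Ras", "Src")
CONTROL_CLASS = "control"

_DEFAULT_HAZARD_RATIOS = {
    "OS": 1.5,
    "RFS": 1.5,
    "MFS:lung": 2.5,
    "MFS:brain": 2.5,
    "MFS:bone": 1.0,
    "MFS:other": 1.0,
}
# baseline hazards per month for a Wnt- patient; MFS is split across sites
_DEFAULT_BASELINE_HAZARDS = {"OS": 0.008, "RFS": 0.012, "MFS": 0.02}
_DEFAULT_SITE_WEIGHTS = {"lung": 0.35, "brain": 0.35, "bone": 0.20, "other": 0.10}

GRADE_LEVELS = (1, 2, 3)
_GRADE_PROBS_WNT_POS = (0.05, 0.25, 0.70)
_GRADE_PROBS_WNT_NEG = (0.25, 0.45, 0.30)
_P_NODE_POS = {True: 0.55, False: 0.45}
# pathological -> intrinsic subtype emission probabilities
_INTRINSIC_GIVEN_PATH = {
    "HR+": (("luminal", 0.85), ("normal-like", 0.10), ("HER2e", 0.05)),
    "HER2+": (("HER2e", 0.80), ("luminal", 0.15), ("basal", 0.05)),
    "TN": (("basal", 0.80), ("normal-like", 0.10), ("HER2e", 0.10)),
}


@dataclass
class SimulationConfig:
    """Knobs of both generators; defaults are the emulated study conditions."""

    n_genes: int = 1000
    n_cohorts: int = 5
    samples_per_cohort: int = 60
    subtype_proportions: tuple[float, float, float] = (0.55, 0.15, 0.30)  # HR+, HER2+, TN
    p_wnt_given_tn: float = 0.6
    p_wnt_given_other: float = 0.02
    pathway_effect: float = 1.5  # mean shift in SD units on signature genes
    signature_size: int = 30  # induced genes per oncogene; as many inhibited
    replicate_fraction: float = 0.1
    panel_overlap_fraction: float = 0.7
    shared_duplicates: int = 0  # specimens copied from cohort c into cohort c+1
    distortion: bool = True  # per-cohort per-gene affine transform
    replicate_noise_sd: float = 0.2
    perturbation_replicates: int = 10
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HAZARD_RATIOS))
    baseline_hazards: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE_HAZARDS))
    site_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SITE_WEIGHTS))
    censor_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.subtype_proportions), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"subtype proportions must sum to 1, got {self.subtype_proportions}")
        for p in (self.p_wnt_given_tn, self.p_wnt_given_other,
                  self.replicate_fraction, self.panel_overlap_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        if any(hr <= 0 for hr in self.hazard_ratios.values()):
            raise ValueError("hazard ratios must be positive")
        if self.n_cohorts < 1:
            raise ValueError("need at least one cohort")
        if self.perturbation_replicates < 3:
            raise ValueError("need >=3 replicates per perturbation class")
        needed = 2 * self.signature_size * len(ONCOGENE_CLASSES)
        if needed > self.n_genes:
            raise ValueError(
                f"{self.n_genes} genes cannot host {needed} signature genes")


@dataclass
class GroundTruth:
    """Planted truth for scoring downstream callers."""

    wnt_status: pd.Series  # specimen id -> bool
    signatures: dict[str, GeneSet]  # oncogene class -> signed signature
    panels: dict[str, list[str]]  # cohort id -> gene panel
    replicate_map: dict[str, str]  # sample column -> specimen id
    subtype: pd.Series  # specimen id -> pathological subtype

    @property
    def wnt_signature(self) -> GeneSet:
        return self.signatures["beta-catenin"]


def _gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def _signatures(cfg: SimulationConfig) -> dict[str, GeneSet]:
    """Disjoint signed signatures carved from the start of the gene universe."""
    genes = _gene_universe(cfg.n_genes)
    s = cfg.signature_size
    out: dict[str, GeneSet] = {}
    for j, cls in enumerate(ONCOGENE_CLASSES):
        induced = genes[2 * j * s: (2 * j + 1) * s]
        inhibited = genes[(2 * j + 1) * s: (2 * j + 2) * s]
        direction = {g: 1 for g in induced} | {g: -1 for g in inhibited}
        out[cls] = GeneSet(name=f"{cls}-signature", members=tuple(induced + inhibited),
                           description=f"uniquely induced/inhibited by {cls}",
                           direction=direction)
    return out


def simulate_perturbation_training(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series, dict[str, GeneSet]]:
    """Control + oncogene-transfected replicate profiles with signed signatures.

    Returns the log2 expression matrix, a per-sample class label Series, and
    the per-oncogene signed gene sets.  ``pathway_effect == 0`` is allowed and
    produces pure-null data.
    """
    rng = np.random.default_rng([cfg.seed, 0xA11CE])
    genes = _gene_universe(cfg.n_genes)
    sigs = _signatures(cfg)
    classes = [CONTROL_CLASS, *ONCOGENE_CLASSES]
    n_rep = cfg.perturbation_replicates

    sample_ids, labels = [], []
    for cls in classes:
        for r in range(1, n_rep + 1):
            sample_ids.append(f"{cls}_r{r}")
            labels.append(cls)
    X = rng.standard_normal((cfg.n_genes, len(sample_ids)))

    gene_pos = {g: i for i, g in enumerate(genes)}
    for cls in ONCOGENE_CLASSES:
        cols = [i for i, lab in enumerate(labels) if lab == cls]
        sig = sigs[cls]
        X[np.ix_([gene_pos[g] for g in sig.induced], cols)] += cfg.pathway_effect
        X[np.ix_([gene_pos[g] for g in sig.inhibited], cols)] -= cfg.pathway_effect

    mat = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=sample_ids),
                           cohort_id="HMEC-perturbation", scale="log2")
    return mat, pd.Series(labels, index=sample_ids, name="class"), sigs


def _uniform_censor_bound(rate_scale: float, censor_rate: float) -> float:
    """Upper bound b of U(0, b) censoring giving roughly the target censor rate.

    For an Exp(lambda) event time and U(0, b) censoring,
    P(censored) = (1 - exp(-lambda*b)) / (lambda*b); solve for b.
    """
    if censor_rate <= 0:
        return math.inf
    f = lambda x: (1.0 - math.exp(-x)) / x - censor_rate
    x = brentq(f, 1e-9, 1e9)
    return x / rate_scale


def _simulate_endpoint(rng: np.random.Generator, cfg: SimulationConfig,
                       specimen_ids: Sequence[str], wnt: np.ndarray,
                       endpoint: str) -> list[SurvivalRecord]:
    hrs = cfg.hazard_ratios
    records = []
    if endpoint in ("OS", "RFS"):
        lam0 = cfg.baseline_hazards[endpoint]
        lam = lam0 * np.where(wnt, hrs.get(endpoint, 1.0), 1.0)
        event_t = rng.exponential(1.0 / lam)
        site_of = [None] * len(specimen_ids)
    else:  # MFS: competing site-specific latent times, first one wins
        lam_mfs = cfg.baseline_hazards["MFS"]
        sites = list(cfg.site_weights)
        w = np.array([cfg.site_weights[s] for s in sites])
        w = w / w.sum()
        site_lam = np.empty((len(specimen_ids), len(sites)))
        for j, s in enumerate(sites):
            hr = hrs.get(f"MFS:{s}", 1.0)
            site_lam[:, j] = lam_mfs * w[j] * np.where(wnt, hr, 1.0)
        latent = rng.exponential(1.0 / site_lam)
        first = latent.argmin(axis=1)
        event_t = latent.min(axis=1)
        site_of = [sites[j] for j in first]

    base_rate = cfg.baseline_hazards[endpoint]
    bound = _uniform_censor_bound(base_rate, cfg.censor_rate)
    censor_t = rng.uniform(0.0, bound, len(specimen_ids)) if math.isfinite(bound) \
        else np.full(len(specimen_ids), math.inf)
    for i, sid in enumerate(specimen_ids):
        if event_t[i] <= censor_t[i]:
            site = site_of[i] if endpoint == "MFS" else None
            records.append(SurvivalRecord(sid, float(event_t[i]), 1, endpoint, site))
        else:
            records.append(SurvivalRecord(sid, float(censor_t[i]), 0, endpoint, None))
    return records


def simulate_tumor_cohorts(
    cfg: SimulationConfig,
) -> tuple[list[ExpressionMatrix], ClinicalTable, list[SurvivalRecord], GroundTruth]:
    """Multi-cohort tumor collection with planted Wnt structure.

    Each cohort gets its own gene panel (a core shared by all cohorts, sized by
    ``panel_overlap_fraction`` and always containing the signature genes, plus
    a random half of the remaining genes), its own per-gene affine distortion
    when ``distortion`` is on, technical replicate columns tagged ``_r<k>`` in
    the sample ids, and optional duplicated specimens shared with the next
    cohort.  Wnt+ specimens have the beta-catenin signature shifted by
    ``pathway_effect`` (induced up, inhibited down).  Survival is exponential
    per endpoint with the configured hazard ratios for Wnt+ and independent
    uniform censoring.
    """
    rng = np.random.default_rng([cfg.seed, 0x7B1D])
    genes = np.array(_gene_universe(cfg.n_genes))
    sigs = _signatures(cfg)
    wnt_sig = sigs["beta-catenin"]

    # --- panels: shared core (includes signatures) + cohort-private half of the rest
    core_size = max(round(cfg.panel_overlap_fraction * cfg.n_genes),
                    len(wnt_sig.members))
    sig_genes = list(wnt_sig.members)
    non_sig = [g for g in genes if g not in set(sig_genes)]
    extra_core = rng.choice(non_sig, size=max(core_size - len(sig_genes), 0),
                            replace=False)
    core = set(sig_genes) | set(extra_core.tolist())
    rest = [g for g in genes if g not in core]

    cohort_ids = [f"cohort{c + 1}" for c in range(cfg.n_cohorts)]
    panels: dict[str, list[str]] = {}
    for cid in cohort_ids:
        if rest and cfg.panel_overlap_fraction < 1.0:
            private = rng.choice(rest, size=len(rest) // 2, replace=False)
            panel_set = core | set(private.tolist())
        else:
            panel_set = core | set(rest)
        panels[cid] = [g for g in genes if g in panel_set]  # universe order

    gene_pos = {g: i for i, g in enumerate(genes)}
    sig_idx_up = np.array([gene_pos[g] for g in wnt_sig.induced])
    sig_idx_dn = np.array([gene_pos[g] for g in wnt_sig.inhibited])

    matrices: list[ExpressionMatrix] = []
    clin_rows: list[dict] = []
    all_records: list[SurvivalRecord] = []
    wnt_by_specimen: dict[str, bool] = {}
    subtype_by_specimen: dict[str, str] = {}
    replicate_map: dict[str, str] = {}
    carry: list[tuple[str, np.ndarray]] = []  # duplicated (specimen, latent profile)

    subtype_names = ("HR+", "HER2+", "TN")
    props = np.asarray(cfg.subtype_proportions)

    for c, cid in enumerate(cohort_ids):
        n = cfg.samples_per_cohort
        specimen_ids = [f"{cid}_s{i + 1:03d}" for i in range(n)]
        subtypes = rng.choice(subtype_names, size=n, p=props)
        p_wnt = np.where(subtypes == "TN", cfg.p_wnt_given_tn, cfg.p_wnt_given_other)
        wnt = rng.random(n) < p_wnt

        latent = rng.standard_normal((cfg.n_genes, n))
        latent[np.ix_(sig_idx_up, np.flatnonzero(wnt))] += cfg.pathway_effect
        latent[np.ix_(sig_idx_dn, np.flatnonzero(wnt))] -= cfg.pathway_effect

        # inject duplicated specimens carried over from the previous cohort
        dup_from_prev = carry
        carry = []
        if dup_from_prev:
            dup_ids = [sid for sid, _ in dup_from_prev]
            latent = np.concatenate(
                [latent, np.column_stack([prof for _, prof in dup_from_prev])], axis=1)
            specimen_ids = specimen_ids + dup_ids
        if cfg.shared_duplicates and c + 1 < cfg.n_cohorts:
            k = min(cfg.shared_duplicates, n)
            carry = [(specimen_ids[i], latent[:, i].copy()) for i in range(k)]

        panel_idx = np.array([gene_pos[g] for g in panels[cid]])
        panel_vals = latent[panel_idx, :]
        if cfg.distortion:
            slope = rng.uniform(0.8, 1.2, size=len(panel_idx))[:, None]
            offset = rng.uniform(-0.5, 0.5, size=len(panel_idx))[:, None]
            panel_vals = slope * panel_vals + offset

        # technical replicates: re-measure the first fraction of specimens
        n_rep = int(cfg.replicate_fraction * n)
        cols, col_ids = [], []
        for i, sid in enumerate(specimen_ids):
            if i < n_rep:
                for r in (1, 2):
                    noisy = panel_vals[:, i] + rng.normal(
                        0.0, cfg.replicate_noise_sd, len(panel_idx))
                    cols.append(noisy)
                    col_ids.append(f"{sid}_r{r}")
                    replicate_map[f"{sid}_r{r}"] = sid
            else:
                cols.append(panel_vals[:, i])
                col_ids.append(sid)
                replicate_map[sid] = sid
        df = pd.DataFrame(np.column_stack(cols), index=panels[cid], columns=col_ids)
        matrices.append(ExpressionMatrix(df, cohort_id=cid, scale="log2"))

        for i, sid in enumerate(specimen_ids):
            if sid in wnt_by_specimen:  # duplicated specimen: annotate once
                continue
            is_wnt = bool(wnt[i]) if i < n else wnt_by_specimen[sid]
            wnt_by_specimen[sid] = is_wnt
            subtype_by_specimen[sid] = str(subtypes[i]) if i < n else subtype_by_specimen[sid]
            grade_p = _GRADE_PROBS_WNT_POS if is_wnt else _GRADE_PROBS_WNT_NEG
            intr_choices, intr_p = zip(*_INTRINSIC_GIVEN_PATH[subtype_by_specimen[sid]])
            clin_rows.append({
                "sample_id": sid,
                "pathological_subtype": subtype_by_specimen[sid],
                "intrinsic_subtype": rng.choice(intr_choices, p=intr_p),
                "grade": int(rng.choice(GRADE_LEVELS, p=grade_p)),
                "node_status": "positive"
                if rng.random() < _P_NODE_POS[is_wnt] else "negative",
                "wnt_call": pd.NA,
            })

        new_specimens = [sid for sid in specimen_ids if sid not in
                         {r.sample_id for r in all_records}]
        wnt_vec = np.array([wnt_by_specimen[sid] for sid in new_specimens])
        for endpoint in ("OS", "RFS", "MFS"):
            all_records.extend(
                _simulate_endpoint(rng, cfg, new_specimens, wnt_vec, endpoint))

    clinical = ClinicalTable(pd.DataFrame(clin_rows).set_index("sample_id"))
    truth = GroundTruth(
        wnt_status=pd.Series(wnt_by_specimen, name="wnt_status"),
        signatures=sigs,
        panels=panels,
        replicate_map=replicate_map,
        subtype=pd.Series(subtype_by_specimen, name="pathological_subtype"),
    )
    return matrices, clinical, all_records, truth
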