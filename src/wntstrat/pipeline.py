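"""Config-driven orchestration of the full stratification analysis.

Stages: simulate (or ingest) -> preprocess -> differential expression ->
pathway scores -> classifier transfer -> clinical association -> survival.
Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so editing one stage's parameters never changes
another stage's randomness, and a rerun with the same config is
byte-identical.  A manifest records the config hash, stage seeds, package
version and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import associate
from .diffexpr import differential_expression
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    write_clinical_survival,
    write_expression,
    write_gmt,
)
from .nsc import cross_validate, to_wnt_calls, train_nsc, transfer_classify
from .pathways import canonical_pathway_scores, differential_pathway_test
from .preprocess import combine_replicates, harmonize_cohorts, quantile_normalize, \
    scale_to_target_intensity, zscore_genes
from .simulate import SimulationConfig, simulate_perturbation_training, \
    simulate_tumor_cohorts
from .survival import endpoint_records, km_estimate, logrank_test, \
    site_specific_records

logger = logging.getLogger(__name__)

WNT_TRAINING_CLASS = "Wnt"
SURVIVAL_ANALYSES = ("OS", "RFS", "MFS", "MFS:lung", "MFS:brain", "MFS:bone")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters plus the mandatory master seed."""

    seed: int
    output_dir: str = "wntstrat-out"
    simulation: dict = field(default_factory=dict)
    diffexpr_B: int = 500
    fdr: float = 0.01
    fc: float = 1.5
    pathway_B: int = 500
    cv_folds: int = 5
    priors: str = "uniform"
    target_intensity: float = 600.0
    mc_reps: int = 100_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValueError("pipeline config must set a master 'seed'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        """Canonical YAML of the analysis parameters (output_dir excluded,
        so the hash identifies the analysis, not where it was written)."""
        raw = dataclasses.asdict(self)
        raw.pop("output_dir", None)
        return yaml.safe_dump(raw, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _binary_training_labels(labels: pd.Series) -> pd.Series:
    """Wnt (beta-catenin) vs pooled other (controls + remaining oncogenes)."""
    return labels.map(lambda c: WNT_TRAINING_CLASS if c == "beta-catenin" else "other")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis on simulated cohorts and write all outputs.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "seeds": {},
        "counts": {},
    }

    # --- simulate -----------------------------------------------------------
    sim_seed = stage_seed(cfg.seed, "simulate")
    manifest["seeds"]["simulate"] = sim_seed
    sim_cfg = SimulationConfig(**{**cfg.simulation, "seed": sim_seed})
    train_X, train_labels, signatures = simulate_perturbation_training(sim_cfg)
    cohorts, clinical, records, truth = simulate_tumor_cohorts(sim_cfg)
    manifest["counts"]["cohorts"] = len(cohorts)
    manifest["counts"]["specimens"] = len(truth.wnt_status)
    write_gmt(signatures.values(), out / "signatures.gmt")

    # --- preprocess ---------------------------------------------------------
    processed = []
    for X in cohorts:
        if X.scale == "linear":
            X = scale_to_target_intensity(X, cfg.target_intensity)
        X = quantile_normalize(X)
        rep_map = {s: truth.replicate_map[s] for s in X.sample_ids
                   if truth.replicate_map.get(s, s) != s}
        X = combine_replicates(X, rep_map)
        processed.append(X)
    processed = harmonize_cohorts(processed, drop_duplicates=True,
                                  intersect_genes=False)
    manifest["counts"]["samples_after_harmonize"] = sum(
        c.n_samples for c in processed)

    # --- differential expression (TN vs other, first cohort) ----------------
    de_seed = stage_seed(cfg.seed, "diffexpr")
    manifest["seeds"]["diffexpr"] = de_seed
    first = processed[0]
    subtype = truth.subtype.reindex(first.sample_ids)
    de_groups = subtype.map(lambda s: "TN" if s == "TN" else "other")
    de = differential_expression(first, de_groups, B=cfg.diffexpr_B,
                                 seed=de_seed, fdr=cfg.fdr, fc=cfg.fc,
                                 group_a="TN")
    de.table.to_csv(out / "diffexpr.tsv", sep="\t", index_label="gene")
    manifest["counts"]["de_up"] = len(de.up)
    manifest["counts"]["de_down"] = len(de.down)

    # --- pathway scores + differential regulation ---------------------------
    path_seed = stage_seed(cfg.seed, "pathways")
    manifest["seeds"]["pathways"] = path_seed
    score_frames = []
    for X in processed:
        Xz = zscore_genes(X)
        tab = canonical_pathway_scores(Xz, list(signatures.values()))
        long = tab.scores.stack().rename("score").reset_index()
        long.columns = ["pathway", "sample_id", "score"]
        long.insert(0, "cohort", X.cohort_id)
        score_frames.append(long)
    pd.concat(score_frames, ignore_index=True).to_csv(
        out / "pathway_scores.tsv", sep="\t", index=False)

    first_z = zscore_genes(processed[0])
    first_scores = canonical_pathway_scores(first_z, list(signatures.values()))
    ptest = differential_pathway_test(
        first_scores, subtype.reindex(first_z.sample_ids), reference="TN",
        B=cfg.pathway_B, seed=path_seed)
    ptest.to_csv(out / "pathway_tests.tsv", sep="\t", index=False)

    # --- classifier: train on perturbation data, transfer to cohorts --------
    clf_seed = stage_seed(cfg.seed, "classifier")
    manifest["seeds"]["classifier"] = clf_seed
    binary = _binary_training_labels(train_labels)
    model = train_nsc(train_X, binary, priors=cfg.priors)
    chosen, curve = cross_validate(train_X, binary, delta_grid=model.delta_grid,
                                   folds=cfg.cv_folds, seed=clf_seed,
                                   priors=cfg.priors)
    model.delta = chosen
    curve.to_csv(out / "cv_curve.tsv", sep="\t", index=False)
    manifest["classifier_delta"] = chosen

    all_calls = []
    call_counts = {}
    for X in processed:
        result = transfer_classify(model, X)
        calls = to_wnt_calls(result, WNT_TRAINING_CLASS)
        all_calls.extend(calls)
        call_counts[X.cohort_id] = sum(c.call == "Wnt+" for c in calls)
    manifest["counts"]["wnt_positive_per_cohort"] = call_counts
    call_series = pd.Series({c.sample_id: c.call for c in all_calls})
    call_series.rename("wnt_call").to_csv(out / "wnt_calls.tsv", sep="\t",
                                          index_label="sample_id")

    # --- clinical association -----------------------------------------------
    assoc_seed = stage_seed(cfg.seed, "association")
    manifest["seeds"]["association"] = assoc_seed
    clinical.data["wnt_call"] = call_series.reindex(clinical.data.index)
    assoc_rows = []
    for variable, collapse in (("pathological_subtype", "TN"),
                               ("intrinsic_subtype", "basal"),
                               ("grade", None), ("node_status", None)):
        res = associate(call_series, clinical, variable, collapse=collapse,
                        mc_reps=cfg.mc_reps, seed=assoc_seed)
        assoc_rows.append({"variable": variable, "p": res.p,
                           "table": res.table.counts.to_json()})
        if res.p_collapsed is not None:
            assoc_rows.append({"variable": res.collapsed.variable,
                               "p": res.p_collapsed,
                               "table": res.collapsed.counts.to_json()})
    pd.DataFrame(assoc_rows).to_csv(out / "associations.tsv", sep="\t", index=False)

    # --- survival ------------------------------------------------------------
    surv_rows = []
    km_dir = out / "km_curves"
    km_dir.mkdir(exist_ok=True)
    for analysis in SURVIVAL_ANALYSES:
        if ":" in analysis:
            endpoint, site = analysis.split(":")
            recs = site_specific_records(endpoint_records(records, endpoint), site)
        else:
            recs = endpoint_records(records, analysis)
        lr = logrank_test(recs, call_series)
        surv_rows.append({"analysis": analysis, "statistic": lr.statistic,
                          "p": lr.p_value,
                          "observed_wnt_pos": lr.observed.get("Wnt+", 0.0),
                          "expected_wnt_pos": lr.expected.get("Wnt+", 0.0)})
        for label in ("Wnt+", "Wnt-"):
            sub = [r for r in recs if call_series.get(r.sample_id) == label]
            if not sub:
                logger.warning("%s: no %s records; skipping curve", analysis, label)
                continue
            curve = km_estimate(sub)
            name = analysis.replace(":", "_") + ("_pos" if label == "Wnt+" else "_neg")
            curve.to_frame().to_csv(km_dir / f"{name}.tsv", sep="\t", index=False)
    pd.DataFrame(surv_rows).to_csv(out / "survival_tests.tsv", sep="\t", index=False)

    write_clinical_survival(clinical, records, out / "clinical_survival.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
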