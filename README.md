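# wntstrat

Wnt/β-catenin activation stratification of breast-tumor expression cohorts.

Triple-negative breast cancer (TNBC) lacks targeted therapies, and
transcriptional Wnt/β-catenin activation has been proposed as a hallmark of a
TNBC subset with elevated risk of lung and brain — but not bone — metastasis.
`wntstrat` is a tested, reusable implementation of the full analysis that
supports that kind of claim: pathway-level Wnt scoring in expression cohorts,
a β-catenin-trained nearest-shrunken-centroid (NSC) classifier transferred
across heterogeneous microarray cohorts to call tumors Wnt+/Wnt−, and
association of the calls with clinical subtype, grade, node status and
site-specific survival. A first-class synthetic-data module generates
perturbation training sets and multi-cohort tumor collections with planted
Wnt structure, so every stage can be validated against known ground truth.

It is intended for computational biologists who want to run, audit, or
stress-test this class of cross-cohort signature-transfer analysis.

## Methods at a glance

- **Pathway score** for sample *j* and gene set *S* on gene-z-scored
  expression: `score(S, j) = mean_{i in S} z_ij`; the signed (oncogenic)
  variant weights induced genes `+1` and inhibited genes `−1`.
- **Differential expression**: moderated statistic
  `d_i = (x̄_A − x̄_B) / (s_i·c + s_0)` with permutation-estimated FDR
  `FDR(t) = mean_b #{|d*_b| ≥ t} / #{|d| ≥ t}` and the joint call gate
  q ≤ 0.01 and linear fold change ≥ 1.5.
- **NSC classifier**: class offsets
  `d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s_0))` soft-thresholded by Δ,
  discriminant `δ_k(x) = Σ_i (x_i − x̄'_ik)² / (s_i + s_0)² − 2 log π_k`,
  Δ chosen by stratified cross-validation; cohorts are gene-z-scored before
  transfer, which makes calls invariant to per-gene affine platform effects.
- **Association**: Fisher's exact test (2×2) and Freeman–Halton (2×K, exact
  enumeration or fixed-margin Monte-Carlo).
- **Survival**: Kaplan–Meier product-limit curves with Greenwood variance and
  the two-group log-rank test; site-specific metastasis-free survival treats
  other-site metastases as censoring.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Run the whole pipeline on a simulated 3-cohort collection (180 tumors):

```python
from wntstrat.pipeline import PipelineConfig, run_pipeline
import pandas as pd

cfg = PipelineConfig(seed=7, output_dir="readme-out",
                     simulation={"n_cohorts": 3, "samples_per_cohort": 60})
manifest = run_pipeline(cfg)
print(manifest["counts"]["wnt_positive_per_cohort"])
print(pd.read_csv("readme-out/survival_tests.tsv", sep="\t")
        [["analysis", "statistic", "p"]].round(4).to_string(index=False))
```

prints

```
{'cohort1': 11, 'cohort2': 10, 'cohort3': 13}
 analysis  statistic      p
       OS     2.4420 0.1181
      RFS     0.1100 0.7402
      MFS    19.4943 0.0000
 MFS:lung     6.9243 0.0085
MFS:brain    19.6639 0.0000
 MFS:bone     0.0806 0.7765
```

The classifier, trained only on simulated β-catenin-vs-other perturbation
profiles, calls 34 of 180 tumors Wnt+; the log-rank tests recover the planted
hazard structure — Wnt+ tumors carry excess lung and brain metastasis risk
(p = 0.0085 and p < 1e−4) while bone metastasis is indistinguishable between
groups (p = 0.78). The association table written alongside
(`associations.tsv`) shows the Wnt+ calls concentrated in triple-negative
tumors (Fisher p ≈ 4e−19 for subtype in this run) and in grade-3 disease.

The same stages are exposed as a CLI:

```sh
wnt-strat simulate --out sim/ --seed 3
wnt-strat run --config cfg.yaml --out out/
wnt-strat diffexpr --matrix X.tsv --labels labels.tsv -B 1000 --seed 7 --out de.tsv
wnt-strat assoc --calls out/wnt_calls.tsv --clinical out/clinical_survival.tsv \
    --variable grade --out grade.tsv
wnt-strat survive --records out/clinical_survival.tsv --calls out/wnt_calls.tsv \
    --endpoint MFS --site lung --out-prefix km_lung
```

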