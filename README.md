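# sftdx

Cross-platform gene-expression integration anchored on stable housekeeping
genes, and immunohistochemical diagnostic-accuracy analysis, for a concrete
neuropathology question: distinguishing meningeal **solitary fibrous
tumours (SFT)** and **haemangiopericytomas (HPC)** from meningiomas and
synovial sarcomas using **ALDH1A1/ALDH1** and **CD34**.

The package is for computational pathology / transcriptomics analysts who
need to (a) compare one gene's expression across expression matrices
produced by different laboratories and array platforms, and (b) turn
percent-stained-cell IHC scores into sensitivity/specificity tables with
confidence intervals and combined-marker rules.

## What it computes

**Expression arm.**  Given several log2 matrices (genes/probes × samples):

1. within-set quantile normalization;
2. probe → EntrezGene collapsing (Affymetrix extension class `_at` ≻ `s_at`
   ≻ other first, then highest variance);
3. selection of cross-study-stable housekeeping genes by the smallest
   *inter-set variance of intra-set variances* (default retained fraction
   354/451);
4. sequential batch merging with **Distance Weighted Discrimination**:
   minimize Σᵢ 1/rᵢ + C·Σᵢ ξᵢ with rᵢ = yᵢ(wᵀxᵢ + b) + ξᵢ, ξᵢ ≥ 0,
   ‖w‖₂ ≤ 1, then translate both batches along w so their mean projections
   meet at the pooled midpoint;
5. PCA + silhouette check that batch structure is gone;
6. Welch t / Mann–Whitney comparisons and fold changes
   FC = 2^(Δ mean log2) for the target gene, overall and per site stratum.

**IHC arm.**  Markers are called positive at ≥5% stained cells (bands
5–10 / 11–50 / >50%); 2×2 tables against a meningioma reference yield
SE/SP/PPV/NPV with Wilson (or Clopper–Pearson) 95% CIs, AND/OR combined
rules, and exact McNemar comparison of paired marker sensitivities.

A synthetic-data module generates multi-platform expression sets with known
batch offsets and effect sizes, and IHC cohorts either stochastically or
from exact count quotas, so the whole pipeline is testable without any
external download.

## Worked example

```python
from sftdx import quota_ihc_cohort, build_contingency, diagnostic_metrics
from sftdx.accuracy import MENINGEAL_SFT, MENINGIOMAS, CombinedRule

cohort = quota_ihc_cohort()          # the published joint ALDH1xCD34 counts
for rule in ("ALDH1", "CD34", CombinedRule("and")):
    t = build_contingency(cohort, rule, MENINGEAL_SFT, MENINGIOMAS)
    m = diagnostic_metrics(t)
    print(f"{t.marker:>13}: SE={100*m.se:.1f}% SP={100*m.sp:.1f}% "
          f"PPV={100*m.ppv:.1f}% NPV={100*m.npv:.1f}%")
```

prints

```
        ALDH1: SE=84.0% SP=98.8% PPV=91.3% NPV=97.6%
         CD34: SE=92.0% SP=95.1% PPV=74.2% NPV=98.7%
 ALDH1 & CD34: SE=80.0% SP=100.0% PPV=100.0% NPV=97.0%
```

i.e. for meningeal SFT versus meningioma, ALDH1 staining alone is highly
specific (98.8%), and requiring double ALDH1+CD34 positivity drives
specificity and positive predictive value to 100% at the cost of
sensitivity (80%).

The expression arm end to end, on synthetic data:

```python
from sftdx.synthetic import integration_benchmark, simulate_multiplatform_cohort
from sftdx.pipeline import PipelineConfig, run_expression_arm

truth, layouts = integration_benchmark(fold_change=9.5, seed=1)
sets, annots = simulate_multiplatform_cohort(truth, layouts)
bundle = run_expression_arm(PipelineConfig(out_dir="results", seed=1),
                            sets=sets, probe_annotations=annots,
                            candidates=truth.housekeeping_ids)
fc = {(c["group_a"], c["group_b"]): c["fold_change"]
      for c in bundle["comparisons"]}
print(round(fc[("SFT/HPC", "synovial_sarcoma")], 2),
      round(bundle["batch_silhouette"], 3))
```

prints `9.79 -0.072`: four sets on four platforms with batch offsets up to
4 log2 units merge into one matrix on which the configured 9.5× target
effect is recovered (9.79) and the batch silhouette drops below zero
(batches indistinguishable in PC space; before adjustment it is ≈0.89).

A `sftdx` console script wraps the same pipeline
(`simulate`, `integrate`, `stats`, `ihc-accuracy`, `run-all`); see
`sftdx --help`.

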