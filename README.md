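# ascmaturity

Scoring the maturity of antibody-secreting cells (ASCs) from flow and mass
cytometry data.

## The problem

Plasmablasts and plasma cells — collectively ASCs — mature over weeks to
months after vaccination or infection, and mature, long-lived plasma cells
are what sustains durable antibody titers. No single surface marker defines
maturity, but eight markers change with characteristic kinetics during an
immune response: CD19, CD20, CD28, CD45, CD56, CD138, HLA-DR and Ki67. This
package implements a maturity index built on that observation:

1. **Gate** blood ASCs as live, single CD3⁻CD27⁺CD38⁺ events from FCS files
   (with spillover compensation and channel harmonization).
2. **Normalize** each marker's ASC median intensity between a negative and a
   positive internal control population from the same tube,
   `(MedFI_ASC − MedFI_neg) / (MedFI_pos − MedFI_neg)`, giving unitless,
   batch-invariant expression values comparable across instruments and
   studies.
3. **Assemble** a multi-dataset cohort, apply inclusion rules (ASC count
   ≥ 50, age ≥ 10 y), trim values to [−2, 5] and **impute** panel gaps by
   chained equations with a random-forest donor-draw model (m = 20 completed
   tables).
4. **Train** a random forest (ntree = 100, mtry = 6) to predict the day
   post-immune-intervention (DPI) from the eight markers. The predicted DPI
   of any sample — tissue, disease cohorts, unknown immune state — is read
   as a surrogate for its average ASC maturity.

The forest is stored as explicit node lists, so variable-importance
diagnostics (minimal tree depth, root fraction, node usage, out-of-bag
permutation MSE increase) are exact tree traversals, and models serialize to
portable JSON. A synthetic-data module generates both cohort-level marker
kinetics (with ground-truth maturity) and event-level FCS samples (with
ground-truth population labels), standing in for the public repository
corpus the method targets.

## Worked example

Simulate a small multi-dataset vaccination study and run the full protocol —
filters, dataset-level 75/25 split, trim, imputation, training, held-out
evaluation:

```python
from ascmaturity.simulate import SimConfig, simulate_cohort
from ascmaturity.workflow import run_study

cfg = SimConfig(n_datasets=8, subjects_per_dataset=6, seed=7)
cohort, truth = simulate_cohort(cfg)
res = run_study(cohort, seed=7, m=5)

print(f"kinetic samples: {len(res.train)} training / {len(res.validation)} validation")
print(f"training   r = {res.train_r:.3f} ({res.train_eval['label']})")
print(f"validation r = {res.validation_r:.3f} ({res.validation_eval['label']})")
print(res.validation_eval["per_stage"].to_string(index=False))
```

```
kinetic samples: 138 training / 86 validation
training   r = 0.985 (very strong)
validation r = 0.733 (moderate)
       stage  n  median_predicted_dpi     ci_low    ci_high
       early 18             17.782333  14.269368  21.295297
intermediate 18             74.847271  53.290144  96.404398
        late 18            113.663681  99.127967 128.199396
  very_early 16             11.349634   9.848983  12.850285
   very_late 16            126.016716 114.927273 137.106160
```

The Pearson r correlates actual with predicted DPI: near-perfect in-sample,
moderate on datasets the model never saw — the gap reflects between-study
batch variation. The stage table shows median predicted DPI rising
monotonically across immune-response stages, i.e., the score recovers the
maturation time course. Which markers drive the model:

```python
from ascmaturity.maturity_model import minimal_depth_report
rep = minimal_depth_report(res.model).table
print(rep.sort_values("root_fraction", ascending=False).head(3).to_string(index=False))
```

```
marker  root_fraction  mean_minimal_depth  node_usage_fraction  trees_containing
  CD56           0.60                0.48             0.161153               100
  Ki67           0.26                1.70             0.122817               100
HLA-DR           0.14                1.02             0.153912               100
```

CD56 and Ki67 dominate the tree roots — the two markers with the strongest
(and opposite) kinetics in this simulation.

The same workflow is scriptable from the shell (`asc-maturity --help`):
`simulate`, `gate`, `normalize`, `assemble`, `split`, `impute`, `train`,
`predict`, `evaluate`, `importance`, chained through CSV/JSON artifacts.
`predict` also accepts a plain normalized-expression CSV for pre-gated data.

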