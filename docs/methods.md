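# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Problem setting

Antibody-secreting cells (ASCs — plasmablasts and plasma cells) mature over
weeks to months after an immune event. There is no single surface marker for
maturity, but eight markers (CD19, CD20, CD28, CD45, CD56, CD138, HLA-DR,
Ki67) change with characteristic kinetics after a timed vaccination or
infection. The package's core idea: train a random forest to predict the day
post-immune-intervention (DPI) of a blood sample from those eight markers,
then read the predicted DPI of any sample — including samples of unknown
immune state, from tissue or disease cohorts — as a surrogate for its average
ASC maturity.

## Event processing and gating

FCS 3.0/3.1 files are read without any intensity transformation; spillover
compensation is applied as `x_comp = x_raw @ inv(S)` with rows of `S` as
source detectors (the flowCore convention), using the spillover matrix stored
in the file. ASCs are gated as live, single CD3− CD27+ CD38+ events. Flow
samples are cleaned by an FSC-A/SSC-A rectangle and an FSC-A/FSC-H singlet
ratio band (0.75–1.25); mass cytometry samples, which carry no scatter
channels, use a DNA1/DNA2 intercalator rectangle instead. Samples lacking a
viability channel skip the live gate with a logged warning. Gate positions
are acquisition-dependent in real data; the defaults are placed at the valley
points of the simulator's bimodal log-normal mixtures (negative component
median e⁴ ≈ 55, positive e⁷ ≈ 1100, log-SD 0.4, so the default cut at
e^5.5 ≈ 245 sits > 3.7 log-SD from both modes) and every bound is
overridable per dataset.

## Normalization

Raw median intensities (MedFI) are not comparable across instruments and
panels. Each marker's ASC MedFI is therefore anchored between two internal
control populations measured in the same tube:

    normalized = (MedFI_ASC − MedFI_neg) / (MedFI_pos − MedFI_neg)

This min–max anchor form is used because it (i) consumes exactly one negative
and one positive control, (ii) yields the unitless scale whose tails motivate
the later trim to [−2, 5], and (iii) is invariant under any positive affine
transform of the intensity axis — precisely the per-sample batch effects the
anchoring removes (tested to < 1e−9 under randomized transforms). Defaults:
T cells are the negative control for all eight markers; B cells are the
positive control for the B-cell-expressed markers (CD19, CD20, CD45, HLA-DR);
markers without a natural positive lymphocyte population (CD28, CD56, CD138,
Ki67) use the top decile of all live cells on that marker as reference
positive. All assignments are overridable, since the appropriate control
depends on the panel at hand. Median convention: mean of the two middle order
statistics for even counts. Empty populations yield *missing*, never 0.

## Cohort rules

Inclusion: absolute ASC count ≥ 50 (configurable to 10 or 100 for the
sensitivity analysis) and subject age ≥ 10 years, with age required to be
present. Kinetic samples are those with DPI in [5, 180]. Immune-response
stages: baseline (DPI ≤ 1), very early [5, 10), early [10, 19], intermediate
[20, 50], late [51, 99], very late [100, 180]; the conventional very-early
and early ranges overlap at day 10, resolved here half-open so the labels
partition; DPI in (1, 5) or above 180 is unassigned. Normalized values
outside [−2, 5] are set to missing at the value level (the sample survives
and the cell is re-filled by imputation) rather than dropping whole samples,
which maximizes n and matches the impute-before-train ordering.

Training/validation splits are made at the dataset level — samples from one
study never cross arms, the correct design for clustered multi-study data.
The search is greedy swapping with 200 seeded random restarts (23 datasets
have 2²³ partitions, too many to enumerate), minimizing
`|achieved sample fraction − 0.75|` plus the standardized absolute arm
difference in mean DPI (weight 1, the primary balance parameter) and in mean
age and sex proportion (weight 0.25 each).

## Imputation

Panels differ between datasets, so whole dataset × marker blocks are missing.
Missing cells are filled by chained equations with a random-forest
conditional model and donor draws: initialize from observed marginals; per
iteration and per marker, fit a 10-tree forest of that marker on the other
seven (current completed values, originally-observed rows only); for each
missing cell pick one tree uniformly and draw a donor uniformly from the
observed training values in the terminal node the cell reaches. Five chain
iterations; the whole chain runs m = 20 times with sub-seeds, yielding a
bundle of 20 completed tables that agree bit-for-bit on observed cells.
Donor draws guarantee every imputed value lies in the marker's observed
support. DPI, age and sex are deliberately excluded from the imputation
predictors: the markers later predict DPI, and conditioning the fill-in on
the outcome would leak it into the predictors.

## The maturity forest

A regression forest of DPI on the eight markers, trained on the stacked
bundle (m × n rows). Per tree: bootstrap rows with replacement, CART
variance-reduction splits over mtry = 6 candidate predictors per node,
minimum terminal-node size 5 (the convention of R's randomForest `nodesize`
for regression), leaf value = mean target. Defaults ntree = 100, mtry = 6.
Trees are fit with scikit-learn's CART and immediately extracted into flat
node lists (split marker, threshold, children, leaf value, node count), so
prediction is an exact tree walk and the structural diagnostics are
library-independent. Each tree's bootstrap is regenerated from a stored
per-tree seed, making out-of-bag (OOB) membership reproducible from the
serialized model (portable JSON) alone.

Prediction for samples with missing markers imputes them m times jointly
with a context cohort (typically the training cohort) and averages the
per-copy predictions. Predictions are means of leaf means and therefore
bounded by the training DPI range [5, 180].

Importance diagnostics:

* **Minimal depth**: per marker and tree, the depth of its shallowest split
  (root = 0); reported as root fraction, mean minimal depth over the trees
  containing the marker (trees without it are excluded and their count
  disclosed — conventions differ here, this one is stated), and the marker's
  share of all internal nodes.
* **Permutation importance**: per tree, MSE on its own OOB rows before and
  after permuting one marker's OOB column; reported as the raw mean MSE
  increase in days² (not SD-normalized; both conventions exist, raw is
  simpler to interpret as lost squared error).

Evaluation is the Pearson correlation of predicted vs actual DPI, with the
qualitative labels poor (|r| < 0.3), fair (0.3–0.6; the conventional
terminology leaves 0.5–0.6 unnamed and it is folded into fair), moderate
(0.6–0.8), very strong (≥ 0.8). Stage-wise summaries use median with a
notch-style 95% CI (1.57·IQR/√n). Two-group comparisons use Mann-Whitney U
(exact for both n ≤ 8 without ties, tie-corrected normal approximation
otherwise); multi-group comparisons use one-way ANOVA with Tukey HSD or
Kruskal-Wallis with Bonferroni-corrected pairwise follow-ups.

## Synthetic data

The simulator stands in for the public multi-dataset corpus the method is
designed for; its defaults are the package's reference study conditions.

**Cohort level.** 23 datasets × 10 subjects × 6 sampling days
(0, 7, 14, 28, 90, 180). Marker means follow a gamma-pulse family
`b + A·(t/τ)·exp(1 − t/τ)` — a single interpretable peak at t = τ of height
b + A — chosen because the observed kinetics are stage-wise medians, not
functional forms; parameters are calibrated so stage-wise medians reproduce
the observed directionality: transient increases for CD19 (τ = 18), CD45
(14), HLA-DR (12), CD138 (8); a fast pulse then decay for Ki67 (τ = 6,
amplitude 1.4); an early dip with late recovery above baseline for CD56
(`b − A·pulse + 0.4·t/180`); flat CD20 and CD28. Noise: dataset batch shift
SD 0.10 (small by design — the control-population anchoring is what removes
batch effects), subject effect SD 0.15, residual SD 0.25, all in normalized
units. Panel missingness removes whole dataset × marker blocks; 53 of the
184 slots are absent (28.8% overall, the corpus-level missingness the
pipeline must tolerate), with the marker choice seeded-random but never
eliminating a marker corpus-wide. ASC counts are a shifted negative binomial
(shift 10, mean 250, shape 1.5) that deliberately produces sub-50 values so
the inclusion filter is exercised. Ages are uniform 18–75 (the age filter is
tested on constructed tables instead). Latent maturity is by construction
the time since the immune event.

What the simulator does **not** emulate: pre-existing immunity and the
early-response dip in average maturity seen in longitudinal subjects,
non-Gaussian batch effects, age–marker couplings (available as optional
linear terms, off by default), antigen-specific ASC subsets, and real
panel/instrument idiosyncrasies. Passing recovery tests therefore shows the
pipeline machinery is correct under the stated noise model, not that the
real-data performance numbers transfer.

**Event level.** Samples are mixtures of log-normal populations (T cells,
B cells, ASCs, dead cells, debris, doublets) with ≥ 5 log-SD separation
between negative and positive components of every gating marker; doublets
have FSC-A ≈ 2 × FSC-H (flow) or high DNA intercalator signal (mass).
Ground-truth event labels are retained for precision/recall checks.

## Problem sizes and numerical choices

The default synthetic study (1,380 samples before filters, ~1,050 kinetic
samples, ~780/~270 per arm, m = 20, ntree = 100) runs the full pipeline in
about a minute on one CPU; tests use smaller scales chosen to keep each
check in seconds while still exercising the contract under test. Tolerances:
normalization anchors and affine invariance at 1e−9; oracle equivalences
(tree walks, Pearson) exact or 1e−12; stochastic recovery criteria (train
r ≥ 0.8, held-out r ≥ 0.5, gating precision/recall ≥ 0.95, imputation-bias
< 0.1 units) at the default study conditions with fixed seeds. Degenerate
inputs: empty populations yield missing MedFI; coincident controls raise and
the marker is recorded missing; zero-variance targets produce constant
forests; all-identical groups give F = 0, p = 1.

## Known limitations

* The FCS layer covers list-mode FCS 3.0/3.1 with float/double/uniform
  integer data — the dialects the pipeline writes and the common public
  repository formats — not FCS 2.0/3.2, bit-packed integers, or multi-data-
  segment files.
* The min–max anchor normalization and the per-marker control table are one
  consistent reconstruction of the harmonization scheme; real deployments
  should override `ControlSpec` per panel.
* Greedy split search is heuristic; for few datasets it is exhaustive in
  effect (restarts cover the space), for many it only approximates the
  balance optimum.
* Prediction-time imputation against a context cohort makes scores depend
  (weakly) on that context; complete samples are context-free.
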