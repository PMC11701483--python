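# Methods

This note documents the models, generative assumptions, numerical
choices, and limitations behind `biotypegcn`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from external data.

## The clustering model

**Features.** A subject's functional network connectivity (FNC) is the
Pearson correlation matrix between C component time courses; the feature
vector is its upper triangle in row-major order (i ascending, then j), a
convention fixed package-wide because templates, overlaps, and network
contributions all depend on one canonical edge order. Raw Pearson r is
the default feature scale; a Fisher-z transform is available as an
opt-in (`biotypegcn.fnc.fisher_z`) but is not applied by default.

**Population graph.** Nodes are subjects; the phenotypic affinity is the
indicator sum s(u,v) = 1[same gender] + 1[|age difference| ≤ w], default
w = 24 months, gated by a Gaussian kernel exp(−(1−ρ)²/2σ²) on the
correlation distance 1−ρ between the two subjects' FNC vectors, with σ
set to the mean pairwise distance. The kernel is computed on
*column-centered* FNC so that ρ reflects each subject's deviation
pattern rather than the population-mean connectivity every subject
shares. Each node keeps its top-10 edges and the matrix is symmetrized
by maximum. All three choices (window, kernel, top-k) are exposed in the
graph configuration; the affinity form follows the established
population-graph construction for phenotype-aware GCNs, since no
canonical weighting is prescribed for this setting.

**Architecture.** The propagation matrix is the renormalized
Â = D^(−1/2)(A+I)D^(−1/2); self-loops are added only here so the raw
adjacency stays interpretable. The encoder is two graph-convolution
layers (d → 256 → 64 by default; widths configurable) with ReLU on the
hidden layer and a linear embedding layer; the decoder mirrors it; the
decoder reconstructs node *features*, not the adjacency. A one-logit
affine head on the embedding provides the patient-vs-control
cross-entropy. Node features are column-standardized inside the trainer:
the shared mean FNC pattern and per-edge scale carry no subject
information, and leaving them in both dominates the reconstruction
objective and conditions the optimization badly. The embedding passes
through a full-batch normalization layer (per-column standardization, no
learned affine). This is load-bearing: without it, full-batch Adam keeps
enlarging the embedding scale along the classifier direction long after
the diagnostic task is solved — transductive overfitting — and K-means
on patient embeddings then splits patients by classifier confidence
rather than by connectivity pattern. Fixing the variance budget makes
the cross-entropy term allocate *direction*, not scale, and the
reconstruction term retains the within-patient structure. (The
embedding-layer bias is redundant under this normalization; its gradient
is identically zero.)

**Objective.** L = γ₁·L_rec + γ₂·L_CE + γ₃·L_cluster with
γ = (0.01, 0.01, 0.1) and Adam at learning rate 10⁻³ (both defaults are
the published operating point of this model family). L_rec is the mean
squared reconstruction error, L_CE the mean binary cross-entropy over
supervised nodes (mask-aware for cross-validation), and L_cluster the
deep K-means loss on patient embeddings

    L_cluster = (1/p) Σᵢ Σₖ softmaxₖ(−α‖zᵢ−μₖ‖²) · ‖zᵢ−μₖ‖² ,

a soft-min whose inverse temperature α anneals geometrically (default
1 → 1000) so the loss converges to the classical K-means objective; the
test suite verifies the hard limit against best-of-50 classical K-means.
Only patient nodes enter the clustering term (the patient subgraph, with
its connections unchanged, feeds the clustering layer); controls
contribute through reconstruction and the diagnostic head.

**Training protocol.** Two phases: (1) pretrain encoder/decoder/head
without the clustering term (default 100 epochs); (2) initialize
centroids by greedy farthest-point seeding refined by one classical
K-means run on the pretrained patient embeddings, then jointly minimize
the full objective (default 200 epochs), updating centroids by gradient
together with the network weights. An emptied cluster is re-seeded at
the farthest patient embedding; three recurrences raise an error.
Gradients are analytic (finite-difference-verified in the tests);
optimization is full-batch Adam implemented in numpy; everything runs on
one CPU. All randomness — initialization and K-means seeding — flows
from a single integer seed, and identical seed + config reproduces
biotype assignments bitwise. More pretraining is not better: beyond a
few hundred full-batch epochs the diagnostic term starts consuming
embedding variance that the subtype structure lives in, so the epoch
defaults are deliberate operating points, not a convergence criterion.

**Assignment convention.** Patients go to the nearest centroid; biotype
labels are renumbered by descending cluster size (ties by centroid
norm), so biotype 1 is always the largest cluster; templates are
per-biotype means of *raw* FNC vectors, never of embeddings; ties in
template projection resolve to biotype 1.

## Model selection

The number of clusters is chosen by the elbow of the cluster sum of
squares (CSS). The CSS-vs-K curve is computed by classical K-means
(best of restarts, with the previous K's solution plus the farthest
point among the candidate initializations, which makes the curve
provably non-increasing) on the patient embeddings of the model trained
with the clustering term inactive. Training the joint model separately
per candidate K would compress each K's embeddings toward its own
centroids — at K = 1 it collapses them entirely — making CSS values
incomparable across K, which is why selection runs on
clustering-neutral embeddings. The elbow is the K maximizing the
perpendicular distance to the chord joining the curve's endpoints after
min-max normalizing both axes; ties and exactly linear curves resolve to
the smallest interior K with a warning.

## Validation toolbox

- **Internal indices.** Davies–Bouldin and Calinski–Harabasz are
  implemented from their definitions and cross-checked against
  brute-force oracles and scikit-learn on random instances to 10⁻⁸.
  Each method's indices are evaluated in the space it clusters in (raw
  FNC for the conventional baselines, embeddings for the deep ones).
- **Baselines.** (1) Ward agglomerative and (2) K-means on raw patient
  FNC; (3) the same architecture on an edgeless graph (propagation =
  identity), i.e. a plain deep autoencoder with deep K-means; (4) the
  graph autoencoder without diagnostic and clustering terms followed by
  classical K-means. Baselines 3–4 reuse this codebase so comparisons
  are architecture-controlled; all methods run at the same K.
- **Fold stability.** K-fold retraining keeps the transductive graph and
  masks the held-out tenth out of the diagnostic loss and the clustering
  set; fold templates are aligned to the full-data templates by optimal
  assignment on the template correlation matrix, and per-biotype Pearson
  r is reported.
- **Random-feature ablation.** Node features are replaced by
  moment-matched Gaussian noise with the topology fixed, isolating the
  contribution of FNC from the graph; on planted cohorts the ARI to
  ground truth is ~0.
- **Cross-cohort transfer.** Templates from one cohort label another by
  nearest Euclidean distance; discriminative edges are the top-k by |t|
  of covariate-adjusted two-sample tests (biotype vs healthy controls by
  default; a biotype-vs-biotype mode exists because the comparison group
  is a legitimate analysis choice); edges are grouped into the 7 networks
  and consistency is the Pearson correlation between the vectorized
  28-cell contribution matrices, and between whole-FNC mean-difference
  vectors.
- **Group statistics.** Covariate-adjusted t-tests are OLS on a group
  indicator plus covariates (exactly the pooled t-test when covariates
  are empty); Cohen's d uses the df-weighted pooled SD; FDR is
  Benjamini–Hochberg, with cognitive measures adjusted as one family and
  per-edge tests within their edge family.

## Longitudinal treatment models

Reduction rate at week t is (baseline − score_t)/baseline per subject ×
scale; week 0 is always 0 and the rate is invariant to rescaling scores.
"Baseline regressed out" is implemented by default as cross-sectional
residualization of the rate on the baseline score at each week
(including baseline as an LME covariate is the provided alternative).
Two models, estimated by statsmodels MixedLM (REML) with subject random
intercept and slope: reduction ~ week × biotype, and
response ~ week × biotype + med × biotype + week × med. The second model
uses the adjusted reduction as the response: the medication-benefit
contrast (med × biotype) is a between-subject level comparison, and on
raw scores it is swamped by between-subject baseline variance that the
reduction rate removes by construction. Week enters numerically
(categorical week is available as a sensitivity mode). Per-term F
statistics are Wald chi-square of the term's coefficient block divided
by its df, referred to F(df_num, N_obs − N_subjects − rank + 1)
(containment-style denominator); the choice is validated by a 200-run
null simulation holding the empirical size near the nominal 5%. Singular
random-slope fits fall back to a random intercept, flagged in the
output.

## The synthetic cohort generator

The generator emulates the statistical structure the model assumes, not
raw fMRI. Defaults define the study conditions used throughout the tests
and the acceptance script: 600 subjects (200 controls, 400 patients in
two equal subtypes), C = 53 components in the 7-network layout
(5, 2, 9, 9, 17, 7, 4).

- **Base pattern:** within-network edges mean 0.45, between-network 0.15,
  plus a fixed per-edge jitter (SD 0.05) shared by all subjects —
  within > between connectivity is the canonical resting-state pattern.
- **Subtype effects:** each subtype shifts the edges of its
  network-block pairs (defaults: subtype 1 → CC–DM and SM–VI; subtype 2
  → DM–DM and CC–CB) by `effect_size × noise_sd` (a standardized mean
  shift; default effect 0.8 on noise SD 0.1). Placing effects on blocks
  rather than single edges is what makes the 7-network contribution
  analysis meaningful on synthetic data.
- **Covariates:** age, gender, site, and mean framewise displacement
  leave diffuse linear traces with per-edge loadings drawn once
  (SDs 5·10⁻⁴/month, 5·10⁻³, 5·10⁻³, 5·10⁻²/mm); chosen an order of
  magnitude below the planted subtype separation, as nuisance effects
  typically are relative to the structure of interest.
- **Noise:** i.i.d. Gaussian per edge with post-hoc clipping to (−1, 1);
  a Fisher-z pathway is available via the transform, and exact
  correlation-matrix sampling is available through
  `generate_timecourses`, which nearest-PSD-repairs the target
  (eigenvalue floor 10⁻⁶, unit-diagonal rescaling) and samples
  row-standardized Gaussian time courses.
- **Longitudinal arm:** treated patients follow
  score(t) = baseline − effect(biotype, arm)·g(t) + b₀ + b₁·g(t) + ε with
  the monotone saturating response fraction g(t) = 1 − exp(−t/1.5 weeks).
  The onset-then-plateau shape mirrors how ADHD medication effects set in
  within days and level off — and it is what makes a per-(biotype, arm)
  effect visible to the med × biotype term of the additive model: a pure
  linear-slope interaction is a three-way (week × med × biotype) effect
  that the published model structure does not contain. Default plateau
  reductions: biotype 1 on MPH 24 points, all other cells 10, on a
  baseline of 40 ± 5; noise SD 2, random intercept SD 2, random response
  SD 3.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: scanner physics, head motion, temporal
autocorrelation of component time courses, non-Gaussian FNC marginals,
site-by-edge interactions beyond additive offsets, comorbidity,
diagnosis noise, and dropout or missed visits in the longitudinal arm.
Recovery of planted structure at a given effect size says nothing about
whether real disorder cohorts contain such structure.

## Problem sizes and numerical choices

The test suite runs the full method at C = 20 components (190 edges) and
600 subjects — with the default network-block effect placement, fewer
components leave too few affected edges for the planted-recovery regime
to be meaningful — and uses a 64 → 32 architecture with 60/120 epochs;
the acceptance script runs model selection at the full C = 53 (1378
edges) with the 256 → 64 architecture. Degenerate inputs are handled
explicitly: all-zero adjacency warns at construction and errors at
training; coincident centroids make DBI undefined (error); zero
within-cluster scatter returns a +∞ CHI sentinel; constant columns in
correlation tables are flagged per pair rather than failing the table;
zero baselines make reduction rates undefined (error). Delimited-text
outputs are comma-separated UTF-8 with LF endings; every writer emits a
SHA-256 sidecar that readers verify, and one global seed fans out to
per-stage seeds through a fixed spawn-key scheme so stages are
independently reproducible.

## Known limitations

- The exact affinity weighting, architecture depth/width, training
  schedule, and elbow procedure of the original model family are
  unpublished; the defaults here are this package's own documented
  choices, exposed in configuration.
- Transductive only: new cohorts are labeled by template projection, not
  by running the encoder out-of-graph.
- The mixed-model F test uses a Wald/containment approximation rather
  than Satterthwaite or Kenward–Roger degrees of freedom; its
  calibration is demonstrated by simulation at the shipped study size,
  not proven in general.
- Full-batch training with a fixed epoch budget has no early-stopping
  criterion; on cohorts much easier or harder than the defaults the
  epoch defaults may be off their best operating point.
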