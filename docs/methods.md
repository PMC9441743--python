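# Methods

This note documents the models, defaults and numerical choices behind
`causalbag`, and what the synthetic experiments do and do not show.

## Variables and the synthetic study population

The model operates on eight variables per subject: chronological age
[years], sex (0 = male, 1 = female), BMI [kg/m²], systolic blood
pressure (BP) [mmHg], waist-to-hip ratio (WHR), smoking (0 non-smoker,
1 past, 2 current), drinking (0 non-drinker, 1 ≤ 1 glass/week,
2 > 1 glass/week) and the brain age gap (BAG) [years].

Real cohorts of this kind are restricted-access, so
`synthetic_data.default_study_scm()` defines a fully specified
structural causal model with the plausible ground-truth graph

```
sex → {bmi, bp, smoking, drinking}      whr → {bmi, bp}
{bmi, whr, smoking, drinking} → bag     age: exogenous, isolated
```

Age is isolated by construction because the BAG is age-bias-corrected
and WHR is discretized with sex-specific thresholds; nothing points into
age or sex and nothing leaves the BAG, matching the domain constraints
used in structure learning.

Mechanisms are linear-Gaussian for continuous nodes and CPT-based for
categorical ones (a categorical node with continuous parents would
discretize them with the clinical scheme first; the default graph does
not need this).  Cohorts are drawn by ancestral sampling in topological
order from a single `numpy` generator, so a (spec, n, seed) triple is
byte-reproducible.

Default ("realistic") parameters are loosely matched to a general adult
population: age uniform on [21, 82] (range as reported for such cohorts;
a uniform density is a deliberate simplification — its SD ≈ 17.6 y is
larger than the ≈ 14 y of a real cohort), P(female) = 1050/2025, WHR
~ N(0.88, 0.08), BMI ≈ 27 ± 4 with males ≈ 1.1 higher, BP ≈ 127 ± 15
with males ≈ 13 higher, and sex-conditional smoking/drinking tables
back-computed from published marginal counts with male percentages.
The BAG mechanism is centered so its cohort mean is ≈ 0 with SD ≈ 3.5,
which at the ±3 y cut-offs yields roughly 20/60/20% class shares.
Default cohort size is 2,025 and the default simulation seed 20220822.

### The strong-coefficient variant

`default_study_scm(strong=True)` is used for structure-recovery
experiments.  Every edge is set to a standardized effect of ~0.4–0.55 SD
of the child.  This is a deliberate choice, not timidity: the NOTEARS
score on *standardized* data is the sum of per-node residual variances,
and for a near-deterministic fork (child R² → 1) a reversed chain can
attain a strictly lower penalized score than the generating graph — we
verified this directly by scoring both structures.  For a two-parent
collider with equal standardized coefficients b, the true structure
beats the competing chain iff b² < 0.5, with the largest margin near
b = 0.5.  Effects of ~0.5 SD therefore put the generating graph at the
score optimum while still satisfying "strong" faithfulness (all adjacent
pairs correlate with |r| > 0.1; age correlates with nothing).

## Brain-age stage

* **Folds.** 10-fold cross-validation, age-stratified: subjects are
  sorted by age and fold labels assigned by shuffled round-robin over
  consecutive age blocks, so every fold spans the age range (fold mean
  ages agree to < 1 y at n = 2,000).  Within each iteration, 15% of the
  training portion is held out (again age-stratified: one subject per
  contiguous age chunk) as the validation set.
* **Regressor.** A feed-forward MLP (scikit-learn `MLPRegressor`
  underneath) trained by minibatch Adam with a manual epoch loop so that
  early stopping monitors the *external* validation set — the same split
  later used to fit the bias correction, which must never see test
  data.  Candidate architectures: (256), (256, 128), (256, 128, 64),
  (256, 128, 64, 32); selection by lowest cross-validated MAE, exact
  ties broken toward fewer parameters.  Defaults: 500 max epochs,
  patience 20, learning rate 1e-3, batch 128.  Inputs are z-scored with
  training-fold statistics only; ages are mean-centered during training
  (an untrained network outputs ≈ 0, and Adam would otherwise spend
  hundreds of epochs climbing ~50 years of output bias).
* **Order invariance.** All seeded steps operate on an internal
  age-sorted canonical order, so permuting input rows leaves pooled
  errors bit-identical (ties in age are broken by input position; with
  continuous ages these have measure zero).
* **Bias correction.** α, β are the OLS coefficients of predicted on
  chronological age, fitted per CV iteration on the validation subjects
  and applied to the test fold.  Algebraic consequences used as tests:
  an exact affine distortion is inverted exactly, and a within-sample
  fit drives the OLS slope of (corrected − chronological) on
  chronological to zero at machine precision.
* **Sign convention.** BAG = corrected predicted age − chronological
  age; positive = accelerated aging.
* **Pipeline signal.** In the end-to-end pipeline the 223 synthetic
  morphometric features are affine in *biological* brain age
  (chronological age + SCM BAG) plus Gaussian noise, so the estimated
  BAG recovers the simulated one.  A config switch drives features by
  age alone, in which case the estimated BAG is pure prediction error —
  useful for testing the regression stage in isolation.

## Discretization

Fixed clinical cut-offs only (no data-driven binning): BMI 25/30, BP
120/140, age 35/65, BAG −3/+3, WHR 0.95/1.0 (male) and 0.80/0.85
(female).  The outer bins are open intervals, so a value exactly on an
edge belongs to the closed middle ("normal") category; this convention
is a documented package choice (edge-exact values are rare in continuous
data) and is applied uniformly.  Codes are ordered 0 = low, 1 = normal,
2 = high for every variable so that edge-sign classification is well
defined.

## Structure learning

NOTEARS: minimize `0.5/n‖X − XW‖² + λ‖W‖₁` subject to
`h(W) = tr(exp(W∘W)) − d = 0` via an augmented Lagrangian (ρ starts at
1, ×10 whenever h fails to shrink 4-fold, h_tol = 1e-8, at most 100 dual
iterations, ρ capped at 1e16); the inner solver is L-BFGS-B on the split
positive/negative parametrization with zero initialization, so runs are
deterministic.  Failure to reach h_tol raises an error carrying the
final h rather than returning a silently cyclic matrix.

Forbidden edges (into age or sex; out of BAG; BMI/WHR/BP into
smoking/drinking) are enforced as (0, 0) box constraints, so they are
exact zeros at every iterate, not post-hoc masked.

Data preprocessing: continuous variables z-scored; sex and the ordinal
smoking/drinking codes keep their spacing but are **mean-centered** —
the least-squares model has no intercept and uncentered regressors
demonstrably distort every weight.  Structure learning runs on the
continuous/ordinal encoding by default (discretizing first is also
possible since any discrete table is numeric).

Pruning keeps |w| > threshold and verifies acyclicity.  The threshold is
chosen from the grid {0.05, 0.1, 0.15, 0.2, 0.3} (configurable) by
refitting the Bayesian network per candidate and maximizing the
unweighted mean of (average node AUC, BAG-node AUC); the bi-objective
"maximize both" is scalarized as this mean, and exact ties prefer the
larger threshold (sparser graph).  Recovery experiments use λ = 0.1 and
a fixed prune threshold 0.25; at n = 2,000 the strong-coefficient SCM is
recovered to SHD ≤ 2 (the residual 1–2 usually being one reversed fork
edge, the orientation of which is only weakly identified on standardized
data).

## Bayesian network

CPDs are Dirichlet posterior means,
`P(x|pa) = (count + c) / (total + c·card)` with pseudo-count c = 1 per
cell by default (c = 0 gives maximum likelihood and errors on unseen
parent configurations); an unobserved configuration yields the uniform
row.  Inference is exact variable elimination with a min-degree
ordering; correctness is ordering-independent and tested against
full-joint enumeration on random 8-node ternary networks (≤ 3⁸ terms).
Zero-probability evidence raises an explicit error.

Validation predicts each node from all other variables.  Under full
evidence only the node's Markov blanket factors matter, which allows a
vectorized scorer (verified row-by-row against variable elimination).
AUC is one-vs-rest macro-averaged over states — the averaging convention
is configurable in principle, macro being the default for robustness to
class imbalance; classes absent from a test fold are skipped with a
logged warning, and a node that is single-class everywhere reports NaN
and is excluded from averages.  The CV protocol is 10-fold repeated 10
times; reports carry per-node means and SDs across repetitions.

## Causal queries

Interventions use graph mutilation — sever all edges into the do-node
and clamp its CPD to a point mass — followed by exact inference.  For
point interventions on a fully specified discrete model this equals the
truncated-factorization / backdoor-adjustment formulas, and the tests
verify both equalities by enumeration (and that parentless nodes give
observation = intervention to 1e-12).  Symbolic do-calculus rewriting is
deliberately not implemented: mutilation is equivalent here and directly
testable.

Edge signs: for edge (p → c), m(s) = E[c-code | p = s] marginalizing
other parents; strictly increasing m is "positive", strictly decreasing
"negative", anything else "non-linear" (a flat profile additionally
carries a zero-effect flag).  The numeric rule is a documented stand-in
for a qualitative convention; it is exposed with the supporting m(s)
values so users can apply their own cut.

## Problem sizes in tests and the acceptance script

Unit and acceptance tests run on cohorts of 400–5,000 subjects (50,000
for CPT-recovery checks), five seeds for structure recovery, 50 random
networks for the inference and do-calculus oracles, and a 500–1,000
subject end-to-end pipeline with a one-hidden-layer MLP and reduced
epoch budgets — sizes chosen to exercise every claim while keeping a
full run in minutes on one core.  The pipeline is verified
byte-reproducible by running it twice into separate directories and
comparing artifacts.

## Limitations

* Synthetic morphometric features are independent noisy affine functions
  of (brain) age; they do not mimic the covariance structure, units or
  nonlinearities of real segmentation outputs, so the brain-age MAE
  achieved here says nothing about attainable MAE on real MRI features.
* The SCM is linear-Gaussian/CPT; non-linear mechanisms (beyond what
  discretization induces) are not simulated, so "non-linear" edge labels
  arise in tests only from constructed CPDs.
* Uniform ages overweight the extremes relative to a real cohort;
  stratification and bias-correction results should transfer, but
  absolute error numbers will differ.
* Structure learning inherits the standardization ambiguity of
  score-based discovery: single fork-edge orientations with similar
  residual variances are weakly identified, which is why recovery is
  asserted as SHD ≤ 2 rather than exact equality.
* No counterfactual (twin-network) queries and no identification theory
  for partially observed graphs: the fitted model is fully specified by
  construction.
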