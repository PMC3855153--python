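# Methods

## The problem

Constraint-based Bayesian network structure learning infers a partially
directed acyclic graph (PDAG) from conditional-independence (CI) statements
estimated from data.  Molecular expression data carry node-specific noise
whose variance can differ by orders of magnitude across molecules
(abundance, assay sensitivity, binding affinities, spectral overlap).  This
package studies — analytically and by simulation — how such discrepancies
distort (i) pairwise Pearson correlations, (ii) first-order partial
correlations, and (iii) the output of Markov-blanket-based learners
(Grow-Shrink and IAMB), on the three canonical three-gene motifs, and
provides the bootstrap machinery to measure the effect on real or synthetic
single-cell expression data.

## Motif models

Each motif is a linear structural equation model over (x, y, z) with a
single shared coupling α and per-node noise scales (σx, σy, σz) multiplying
i.i.d. zero-mean, unit-variance disturbances:

* common-effect:  z = αx + αy + σz·εz (x, y exogenous);
* three-chain:    y = αx + σy·εy,  z = αy + σz·εz;
* coherent type-I FFL:  y = αx + σy·εy,  z = αx + αy + σz·εz.

With coefficient matrix B (strictly lower triangular in the topological
order) and D = diag(σ²), the implied covariance is
Σ = (I−B)⁻¹ D (I−B)⁻ᵀ.  Correlations come from normalizing Σ; partial
correlations from the precision matrix Ω = Σ⁻¹ via
ρ_ij·rest = −Ω_ij/√(Ω_ii Ω_jj), which for three variables is the
first-order partial correlation.  Σ depends only on second moments, so it is
identical for Gaussian and centered-lognormal disturbances at fixed scales.

Asymptotic limits (noise scale of one node → ∞) are computed symbolically
(sympy) from the same closed forms and cross-checked numerically at scale
10⁶.  Entries whose limit remains a function of α or the finite scales are
evaluated at the supplied parameters and flagged `parameter_dependent`.

## Default parameters, and why

* **Coupling α = 2.0** for simulation experiments.  The coupling is a free
  design constant held fixed across all experiments; it must avoid α ∈
  {0, 1}, because the FFL precision entry Ω_xy = −α/σy² + α²/σz² vanishes at
  α = 1 with σy = σz, making the distribution unfaithful to the FFL graph
  (x ⊥ y | z exactly, so no algorithm can recover the x−y edge).  Analytic
  results are exposed for arbitrary α; defaults are configurable everywhere.
* **Large-noise variance σ² = 10⁴** (vs baseline 1).  The asymptotic regime
  means correlations of order 1/σ fall below the detection power of the CI
  test at the experiment's sample size.  At n = 2000 and significance 0.01
  the detection boundary is |ρ| ≈ 0.06; σ² = 10⁴ puts the vanishing
  correlations near 0.01–0.03 (clearly undetectable), while σ² = 100 would
  leave them near 0.1–0.2, i.e. still comfortably detectable and therefore
  not asymptotic at this n.
* **Sample size n = 2000, replicates R = 200** for the motif experiments;
  the expression pipeline resamples m = 800 cells from n = 853 with R = 200.
  These are the study conditions of the emulated experiments.  `--fast`
  modes (R = 50 with n = 500 / m = 200) preserve all qualitative outcomes.
* **Significance levels**: 0.001 for tallying dependency significance,
  0.01 for structure learning.
* **Confidence cutoffs 0.8 / 0.2** for "present" / "unreliable" edges
  (rule-of-thumb thresholds; configurable and reported in outputs).

## Structure learning

GS grows a candidate Markov blanket by sweeping variables in fixed column
order (adding any variable dependent on the target given the current
blanket), then shrinks it by removing members independent given the rest.
IAMB replaces the growing sweep with forward stepwise selection by largest
|t| of the CI test, with ties broken by column order; shrinking is
identical.  Markov blankets are symmetric by definition; estimated ones may
not be.  `symmetry_correct` offers the AND rule (drop unilateral entries;
conservative default) and the OR rule (add the missing reciprocal entries),
both idempotent.  Blankets are reduced to a skeleton by searching separating
sets within the union of the two endpoint blankets, by increasing size then
lexicographic order, recording the first separating set found (including for
non-adjacent pairs, so v-structure identification has them available).
Unshielded triples a−c−b are oriented a→c←b iff c is outside the recorded
separating set of (a, b); conflicting orientation demands leave the edge
undirected and are logged.  Orientations are propagated with Meek rules
R1–R3 to a fixpoint; the fourth classical rule is only reachable when
orientations are injected as background knowledge, which this learner does
not support, so R1–R3 are complete here.  A directed cycle can never be
produced (checked; an input forcing one raises).

The CI test is the exact t-test for the (partial) Pearson correlation:
t = r·√(df/(1−r²)), df = n − 2 − |S|, two-sided p-value.  Partial
correlations of any order are computed by inverting the relevant submatrix
of the sample correlation matrix, which is computed once per dataset.  A
d-separation oracle (networkx) can replace the sample test to verify the
algorithms' soundness independently of sampling noise.

## Bootstrap edge confidence

The confidence of an edge is the fraction of structure-learning replicates
containing it: parametric mode resimulates the known model, nonparametric
mode resamples rows with replacement (with per-replicate column centering).
Bookkeeping: a directed arc counts 1 for its direction; an undirected edge
counts 0.5 per direction plus 1 to the pair's undirected tally; a pair-level
adjacency confidence (presence in any orientation) is also reported.
Whether reported percentages should split undirected edges across directions
is a convention; both views are serialized.  Replicate-level failures
(degenerate resamples) are recorded by index, never silently dropped.

## Expression pipeline

For a three-variable dataset wired like the coherent FFL (default roles:
first variable regulates the second, both regulate the third; the wiring is
a JSON-configurable `StructureSpec`), each bootstrap replicate learns three
networks: G1 from the resample itself; G2 from data simulated out of a
per-equation OLS fit to the resample (fitted residual variances); G3 the
same with residual variances constrained to a common value — arithmetic mean
of the fitted variances by default (geometric mean and dof-pooled variants
are available).  Raw-mode resimulation uses centered-lognormal residuals
(fixed shape rescaled to the target variance, for determinism); log-mode
uses Gaussian residuals.  Comparing G2 with G3 isolates the effect of the
noise-variance discrepancy on the inferred topology.

The lognormal shape default is 0.5 (skewness ≈ 1.75, in the range of the
single-cell intensity data the pipeline emulates).  Much larger shapes are
counterproductive: at shape 1 the excess kurtosis (~110) inflates the
variance of the partial-correlation estimator so badly that the t-test
rejects a true zero partial over half the time, drowning the
variance-equalization contrast in test miscalibration.  The shape is a
parameter of both `simulate_from_fit` and `run_comparison`.

## Synthetic stand-in data

`synthesize_sachs_like` emulates a three-molecule single-cell sample
(default n = 853): a coherent-FFL-wired linear Gaussian model on the log
scale is exponentiated.  This yields strictly positive, positively skewed
marginals, variance increasing with the mean across the molecules, and
raw-scale fitted residual variances differing roughly two- to three-fold,
while the log scale is homoscedastic — so log-transforming removes both the
skew and the variance discrepancy.  What it does **not** emulate: measurement
floor/saturation, cell-population substructure, zero inflation, or any
deviation of the true wiring from the assumed FFL.  Passing tests on this
generator demonstrate the machinery and the variance-equalization
phenomenon, not properties of any real dataset; the real flow-cytometry
sample is neither bundled nor required.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1]; |r| = 1 maps to an infinite t and
  p = 0.  Constant columns raise immediately with the column name.
* Singular conditioning submatrices and singular OLS designs raise
  `ValueError`; inside bootstrap loops such failures are caught, logged with
  the replicate index, and tallied in the output.
* RNG: one root `SeedSequence` per experiment, child streams spawned per
  replicate, so replicate r is reproducible in isolation and all outputs are
  bit-identical under a fixed root seed.
* Sample-vs-analytic assertions use standard-error bands (4–5 SE) rather
  than absolute tolerances.

## Known limitations

* Three-node motifs only; no cycles or feedback, no latent confounders.
* The CI test assumes (approximate) joint normality; heavy-tailed data
  degrade its calibration (quantified above), which is itself one of the
  study's observations in disguise — another reason the log transform
  matters for raw expression data.
* Separating-set search is restricted to the blanket union, which is exact
  for faithful distributions but inherits any blanket-estimation error.
* The asymptotic-limit table entries that stay parameter-dependent are
  reported numerically at the supplied parameters, not as symbolic formulas.
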