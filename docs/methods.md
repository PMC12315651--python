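# Methods

This note documents the statistical procedures implemented in `scnmorph`,
the choices made where the methodology is genuinely open, and what the
synthetic cohort generator does and does not emulate.

## Cohort morphometry

Each ROI's mean cortical thickness is compared between groups by OLS-ANCOVA:
thickness on intercept + group indicator (case = 1) + covariates. The group
coefficient is the covariate-adjusted case-minus-control difference in mm,
tested two-sided with n − p degrees of freedom. Covariates are age (years),
education (years, treated continuous), smoking and drinking (0/1), and eTIV
(mm³); the coding follows common practice since covariate coding details are
rarely published. Multiple comparisons are handled by Bonferroni with the
divisor equal to the number of ROIs tested (68 by default, configurable).
Results are ordered by (adjusted p, raw p) so the two orderings always agree,
including among the ties at p_adj = 1 that Bonferroni produces.

Degenerate case: a saturated fit (zero residual variance) makes the t
statistic 0/0. The implementation detects residual variance at numerical
noise level and reports t = 0 when the coefficient is itself numerically
zero, ±∞ otherwise.

Demographic tables use a Shapiro–Wilk gate (α = 0.05 in both groups) to
choose between the independent-samples t test and the Mann–Whitney U test
for continuous variables, and the chi-square test (no continuity correction
by default, flag available) for categorical ones.

## Network construction

Structural covariance networks are group-level: within each group
separately, thickness columns are residualized on the covariates by OLS, and
the network is the Pearson correlation matrix of the residual columns —
equal to the partial correlation given those covariates. Residualizing
within groups (covariate slopes estimated per group) mirrors the fact that
each group's matrix is built from its own subjects; a pooled-residualization
mode is available via the library by residualizing before splitting.

Weights are mapped to positive values before thresholding. The default is
the absolute value, the standard choice in covariance-network work; a
shift-to-nonnegative transform (subtract the minimum off-diagonal weight) is
provided because published descriptions of "transforming to positive values"
are ambiguous. The transform is recorded in the network's provenance field.

Thresholding retains the K = round(d·N(N−1)/2) strongest edges at each
density d on the grid 0.05–0.40 in steps of 0.01 (36 levels, both endpoints
included). Ties at the cutoff are broken by lexicographic (row, column)
order, which makes graphs bit-reproducible and edge sets nested across the
grid.

## Graph metrics

All graphs are binary and undirected. Cp is the Watts–Strogatz mean
clustering coefficient (degree < 2 nodes contribute 0); Lp is the mean
shortest-path length over ordered pairs in the largest connected component;
global efficiency is the mean inverse distance over all pairs with
disconnected pairs contributing 0; local efficiency averages the global
efficiency of each node's neighbor-induced subgraph. These disconnection
conventions matter because 68-node graphs at density 0.05 are often
disconnected; they are the standard connectomics conventions and are stated
here rather than silently applied.

Small-world indices normalize against random references: γ = Cp/⟨Cp_rand⟩,
λ = Lp/⟨Lp_rand⟩, σ = γ/λ. The null model is degree-preserving double-edge
swap rewiring with at least 10·|E| successful swaps per reference and 100
references per graph by default (both configurable; published analyses
usually leave the construction unstated). Graphs too sparse to rewire fall
back to Erdős–Rényi references with matched node and edge counts. Nodal
profiles report degree, nodal efficiency and normalized betweenness, a
conventional set chosen because "nodal topological characteristics" are not
standardized.

Metric-versus-density curves are summarized by the trapezoidal AUC over the
grid, a threshold-independent summary.

## Permutation inference

Group-level metrics yield a single value per group, so subject-level tests
do not apply. Between-group AUC differences are tested by shuffling subjects
between groups with group sizes preserved, recomputing the entire pipeline —
including within-group residualization on the permuted labels — for every
shuffle, and comparing |observed AUC difference| to the permutation null.
The p-value uses the add-one estimator (1 + #{|null| ≥ |obs|})/(n_perm + 1),
which is never exactly zero and is exact under exchangeability. The default
is 1000 permutations; calibration tests use 199 to keep desk-scale runtimes.
Per-density differences and pointwise p-values are emitted uncorrected as
descriptive output; the AUC test is the primary inference. When a metric is
undefined at some density for any rebuilt network, that density is dropped
from the AUC consistently for observed and null pipelines and a warning is
raised.

Bonferroni across the seven global metrics is left to the caller (the
association and morphometry stages correct within their own families); the
pipeline reports raw permutation p-values per metric.

## Behavioral analyses

BIS-11 scoring uses the standard published 30-item partition (AI 8 items,
MI 11, NPI 11), supplied as a configurable table. Reverse scoring of the
standard reverse-keyed items is available but off by default, matching
descriptions of plain 1–5 scoring. Severity categories follow the
symptom-count scheme 0–1 none / 2–3 mild / 4–5 moderate / ≥6 severe. VAS
craving must lie in [0, 10].

Partial correlations residualize both variables on intercept + covariates
and test r with t = r·√(df/(1−r²)), df = n − 2 − k. Association tables are
computed within the case group with age, education, smoking, drinking,
abstinence duration and eTIV as covariates, and report raw p at the
conventional 0.05 level alongside Bonferroni-adjusted p over the
(region × variable) family, since correction practice varies.

## Mediation

Simple (X→M→Y) and serial (X→M1→M2→Y) models are estimated by OLS path
regressions with the identical covariate set in every regression, which
makes the decomposition c = c′ + Σ indirect exact (asserted to 1e-10 in the
tests). Confidence intervals are percentile bootstrap over subject
resampling, 5000 draws by default; the bias-corrected flavor is deliberately
not the default because the percentile interval is simpler to reason about
and adequate for regression coefficients. Coefficients are carried on raw
scales (mm, BIS points, VAS units, symptom counts) without standardization —
an optional concern for the caller — so indirect effects can be large in
magnitude when X is measured in mm. The proportion mediated is reported
signed and unbounded: suppression legitimately yields values below 0 or
above 100%.

The exactly-deterministic textbook chains (e.g. M = 2X, Y = 3M with no
noise) are rank deficient — the mediator is collinear with X in the outcome
model — so the tests verify the vanishing-noise limit with hierarchical
noise scales instead.

## Synthetic cohort generator

The generator emulates the data structure the analyses assume, with defaults
fixed at the study conditions: 52 controls vs 103 cases, 68
Desikan–Killiany ROIs, male-cohort-like covariate marginals (age ~ N(33, 7²)
years, education ~ N(9, 3²) years, smoking Bernoulli 0.3/0.9 and drinking
0.3/0.7 by group, eTIV ~ N(1.5×10⁶, (1.5×10⁵)²) mm³), each with a small
linear effect on all ROI thicknesses so covariate confounding is real.

Thickness is multivariate normal around a 2.5 mm baseline with residual sd
0.12 mm and a group-specific correlation matrix built from a Watts–Strogatz
graph: C = I + s·A followed by nearest-positive-definite projection
(eigenvalue clipping at 1e-6, rescale to unit diagonal). Defaults plant a
small-world contrast — controls k = 12, rewiring p = 0.1; cases p = 0.8 —
so the case network is more randomized, and 0.15 mm thinning in the left
fusiform and right pars opercularis of cases. When the two groups' topology
parameters are equal the same realized adjacency is shared, making
equal-parameter specs exact nulls for permutation calibration.

Behavior follows a planted linear chain rooted at the right pars
opercularis: MI = 20 + a1·(thickness − 2.5) − 0.05·(age − 33) + ε,
VAS = 5 + d21·(MI − 20) + ε clipped to [0, 10], and severity latent
= 6 + b2·(VAS − 5) + b1·(MI − 20) + c′·(thickness − 2.5) + ε rounded and
clipped to an integer symptom count in 0–11. Chain noise scales (MI sd 2.5,
VAS sd 1.0, severity sd 1.0) were chosen so boundary clipping is rare
(≲0.3%) and does not bias path recovery; because the latent severity is
generated from the *clipped* VAS, the planted b2 is exactly the regression
coefficient of severity on VAS. Intercepts are shared across groups so the
planted chain is the only thickness→behavior pathway — a deliberate departure
from realism (controls get nonzero craving and symptom scores) that keeps
pooled-cohort mediation unconfounded by group. Use duration (cases only) is
planted against left fusiform thickness at −60 months/mm with sd 25, giving
a recoverable negative partial correlation of realistic size; abstinence is
~N(9, 6²) months.

What the generator does **not** emulate: vertex-level surfaces or images
(generation starts at ROI summaries), site/scanner effects, missing data,
non-Gaussian thickness distributions, ordinal BIS item responses (subscale
scores are generated directly; item-level scoring is exercised by its own
unit tests), or realistic effect sizes for the behavioral chain — the
planted couplings are stronger than typical empirical ones so that
desk-scale cohorts have power. Passing tests therefore demonstrate
correctness and calibration of the machinery, not expected effect sizes on
real data.

A single seed fans out into independent substreams (topology, covariates,
thickness noise, behavior) via seed-sequence spawning, so cohorts are
bit-reproducible and stage-level draws do not interact.

## Problem sizes in the test suite

The acceptance-style checks run at sizes chosen for single-CPU desk scale:
permutation calibration uses 200 null cohorts at n_perm = 199 with the
clustering-coefficient AUC (the normalized indices would require a random
ensemble per permutation); planted-contrast power uses 20 cohorts of
150/150 with 8-graph reference ensembles; mediation recovery uses 50 cohorts
of 600/600 at 500 bootstrap draws; small-world sanity uses 20-graph
ensembles. Library defaults remain at the full sizes (1000 permutations,
5000 bootstrap draws, 100 reference graphs).

## Known limitations

* Networks are group-level only; no individual-subject covariance networks.
* Graphs are binary after thresholding; no weighted metric variants.
* Severity is treated as a continuous count in mediation; no ordinal-logit
  variant.
* The ANCOVA is the classical homoskedastic OLS version; no robust/sandwich
  errors.
* Nodal permutation inference is not implemented (nodal curves are
  descriptive only).
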