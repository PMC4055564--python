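# Methods

## Model and scores

A conditional Gaussian Bayesian network (CGBN) over variables V factorizes
the joint density as a product of local models: discrete nodes carry CPTs
indexed by the joint configuration of their discrete parents; continuous
nodes are Gaussian, mean linear in continuous parents, with
(intercept, coefficients, variance) switched by the discrete-parent
configuration. Continuous→discrete edges are structurally excluded, which is
the condition under which exact inference stays closed-form on the
continuous side.

**Discrete families (BDeu).** For a child with r states and q discrete-parent
configurations, the marginal likelihood uses symmetric Dirichlet
hyperparameters α/(rq) per cell:

    ln m = Σ_j [ lnΓ(α/q) − lnΓ(α/q + N_j) + Σ_k ( lnΓ(α/(rq) + N_jk) − lnΓ(α/(rq)) ) ]

α (the equivalent sample size, default 1) is the single smoothing knob. The
implementation is validated to 1e-10 against a sequential
posterior-predictive (chain-rule) oracle, and `exp(ln m)` is verified to sum
to one over all datasets of fixed small size.

**Continuous families (normal–inverse-gamma regression).** Within each
discrete-parent configuration j, the child y regresses on (1, continuous
parents) with the conjugate prior

    β | σ² ~ N(0, σ²/ν · I),    σ² ~ InvGamma(ν/2, ν·σ0²/2),

giving the closed-form marginal likelihood of a Student-t predictive.
Configurations with no rows contribute 0 (the marginal likelihood of no data
is 1). Defaults ν = 1, σ0² = 1: a unit pseudo-observation of prior precision
and a unit prior variance scale, appropriate for roughly standardized
measurements. The closed form is validated to relative 1e-4 against numerical
integration (Gauss–Hermite over the coefficient prior, adaptive quadrature
over ln σ²).

Network score = Σ over nodes of the family score (decomposability is tested).
The Bayes-factor screen for a candidate v is
`score(v | phenotype) − score(v | ∅)`, i.e. the log marginal-likelihood ratio
of dependence versus independence.

## Parameter fitting

Posterior means: discrete CPT rows `(N_jk + α/(rq)) / (N_j + α/q)`;
continuous nodes use the NIG posterior mean β_n and the posterior-mean
variance b_n/(a_n − 1). Since a_n = (ν + n_j)/2 can be ≤ 1 at the default
ν = 1 for strata with n_j ≤ 1, the variance falls back to b_n/a_n (the
inverse of the posterior-mean precision) in that case; empty strata fall back
to the prior (uniform CPT row; β = 0, σ² = σ0²). With α > 0 no CPT cell is
ever exactly zero, so fitted networks cannot produce impossible evidence.

## Exact inference

`predict` computes P(target | evidence) exactly. The query first prunes to
the ancestral closure of {evidence ∪ target} (barren unobserved nodes
marginalize to 1 exactly); remaining hidden discrete nodes are enumerated;
for each full discrete configuration the continuous subnetwork is jointly
Gaussian, so observed continuous evidence enters through a multivariate
normal density and hidden continuous nodes marginalize by dropping rows of
the joint. A guard refuses queries whose hidden discrete space exceeds 2^20
configurations. When the target's entire Markov blanket is observed — the
normal case when scoring a dataset — the posterior instead factorizes over
the target's CPT and its children's local densities, which is algebraically
identical and O(blanket) per row. Both routes are tested to 1e-10 against a
dense oracle that enumerates every discrete configuration and assembles the
joint Gaussian by (I − B)⁻¹ matrix algebra, and against forward-sampling
conditional frequencies (10⁶ samples, 3 SE).

Records presenting a discrete state absent from the training state list are
rejected with an error rather than silently smoothed.

## Structure search

All four searches maximize the decomposable score under three constraints:
acyclicity (depth-first-search check per candidate), the CG edge rule, and a
per-node parent limit (default 3). Equal-gain ties break lexicographically on
(parent, child) so results are reproducible.

* **K2** orders nodes — phenotype first (so it can only gain children, the
  topology that predicts best), then ascending log Bayes factor of dependence
  on the phenotype (most plausibly independent earliest) — and greedily adds
  best preceding-node parents per child, continuous children first, then
  discrete. At the parent limit an addition may trigger the removal of an
  existing parent when the swap strictly improves the family score.
* **Greedy exhaustive** hill-climbs from the empty graph by the single best
  legal edge addition (optionally removal, with backtracking) until no move
  strictly improves the score.
* **Pheno-centric** first grows phenotype→child edges, then co-parents of the
  accepted children; every edge touches the phenotype's Markov blanket and
  the phenotype never receives parents.
* **Simulated annealing** proposes uniform random single-edge moves for a
  budget of n³ proposals (n = number of variables), accepting worsening moves
  with probability exp(Δ/T). T₀ is the median |Δscore| over 100 probe
  proposals; the geometric schedule spans the budget, cooling to 10⁻⁶·T₀ by
  the final proposal (floored at 10⁻⁸), so short runs still end effectively
  greedy — a fixed per-step cooling rate independent of the budget left small
  runs hot and unconverged. The best structure visited is returned.

Instrumented counters record the distinct candidate edges each search
examines; tests check them against the intended complexity envelopes
(K2 ≤ (k/2)n², greedy ≤ n² + kn² per sweep, pheno-centric ≤ n + kn²).

## Validation machinery

AUC is the midrank Mann-Whitney statistic (ties count ½). Its standard error,
the 95% CI and the paired two-sided test for two AUCs on the same records use
DeLong's structural components; identical score vectors give p = 1 by
convention, and the paired test is checked against a 10,000-draw permutation
reference. The convex-hull AUC integrates the upper concave envelope of the
ROC points. Cross-validation uses seeded stratified folds; structure and
parameters are learned inside each training fold only (verified by
recomputing fold scores from an externally trained model), and hyperparameter
tuning grid-searches (α, ν) by pooled CV AUC with ties going to the smaller
(more regularizing) values. Both pooled and per-fold AUCs are reported:
pooled is the headline (stabler at small n). Bootstrap edge frequencies come
from re-learning on resamples of the rows (resamples that lose a phenotype
class are redrawn and logged); consensus networks add edges in descending
frequency, skipping — not stopping at — any edge that would create a cycle or
violate the CG rule, and record pooled CV AUC (parameters refit per fold on
the fixed structure) after each addition. Opposite edge directions are
counted as distinct edges; reconciling A→B with B→A into an undirected vote
is a reasonable alternative not taken here.

## Synthetic-data engine

`random_cgbn` draws a node permutation headed by a binary phenotype (balanced
by default — the case-control design the package targets), keeps each legal
forward edge with probability `edge_prob` (down-sampling to the parent
limit), draws CPT rows from a symmetric Dirichlet(1), residual variances from
U(0.5, 1.5), coefficient magnitudes from `effect_range` with random sign, and
gives continuous nodes with q > 1 discrete-parent configurations evenly
spaced intercepts with spacing drawn from `effect_range` — the mechanism that
creates class signal. Forward sampling is vectorized in topological order.

What the generator emulates: mixed case-control data whose phenotype has a
multi-node Markov blanket of continuous and discrete markers with roughly
standardized scales. What it does not emulate: heavy-tailed or skewed
measurement distributions, batch effects, missingness, correlated noise, or
label error — so passing the simulation experiments demonstrates correctness
of the machinery and the qualitative cost of discretization, not performance
on any particular real assay.

`discretize_equal_width` bins each continuous column into `bins` (default 10)
equal-width bins over the fitting data's [min, max]; the maximum maps to the
last bin. The fitted edges and observed-bin state lists are reused for test
data: out-of-range values clip to the extreme bins, and a bin unobserved in
the fitting data maps to the nearest observed bin (ties to the lower bin) so
test records never present unseen states. Fitting edges on the training set
only avoids test-set leakage. Constant columns become single-state with a
warning.

## Reproduction experiments

`cgbn.experiments` (driven by `scripts/acceptance.py` and the acceptance
tests) runs two designs, both using greedy exhaustive search with default
priors and parent limit 3, training size n = 25, test size 200 (test size is
a package choice; large enough that test-set noise is secondary):

* **Mixed 20-node networks** — 10 networks of 5 discrete + 15 continuous
  variables, `edge_prob` 0.5, `effect_range` (0.8, 1.8): many moderately
  informative blanket members, so the ensemble predicts near ceiling from raw
  data while each 10-bin discretized child is individually starved at
  n = 25. Reported: mean test AUC before and after discretization.
* **25-node random-kind networks** — node kinds drawn uniformly (phenotype
  always binary discrete), `edge_prob` 0.4, same effect range, ≥10
  replicates. Reported: mean AUC degradation caused by discretization at
  N = 25 (the N ≈ number-of-variables regime); replicates where the two
  pipelines tie exactly carry no information about the cost and are excluded
  from the average. The degradation shrinks as N grows to 200 (checked in the
  acceptance tests).

Generator settings were fixed once to place the experiments in the intended
regime (true-network AUC at ceiling; discretization costly at small n) and
are exposed as ordinary configuration for sensitivity analysis.

## Numerical and degenerate-input choices

Scores and densities are handled in natural-log space throughout; posterior
normalization uses log-sum-exp. Empty datasets are rejected; single-class
label vectors are a domain error for ROC analysis; infeasible stratification
(fewer members of a class than folds) is a domain error for CV. Zero-variance
DeLong comparisons report p = 1 for a zero difference and p = 0 otherwise.
Rows with missing cells are dropped at load time with a logged count
(complete-case contract); imputation is out of scope.

## Known limitations

Inference cost is exponential in the number of *relevant hidden* discrete
nodes (guarded at 2^20 configurations); fully observed prediction is linear
in the blanket. Continuous phenotypes, dynamic networks, latent variables and
missing-data modeling are not supported. Parity with other CGBN
implementations' numeric scores is not claimed: prior parameterizations
differ across packages, and this package's scores are validated against
independent mathematical oracles instead.
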