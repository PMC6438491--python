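# Methods

## Model

Binary latent class model with one latent node and two manifest items.
Per subject i (i.i.d.): D_i ~ Bernoulli(δ); given D_i = j,
F_i ~ Bernoulli(φ_j) and L_i ~ Bernoulli(λ_j), independently. The joint
factorizes as P(D,F,L) = P(D)·P(F|D)·P(L|D), i.e. the common-cause Bayesian
network D → F, D → L under the (causal) Markov condition. Observable cells:

θ_jk = δ·φ₁^j(1−φ₁)^{1−j}·λ₁^k(1−λ₁)^{1−k} + (1−δ)·φ₀^j(1−φ₀)^{1−j}·λ₀^k(1−λ₀)^{1−k}.

A stochastic intervention on D is modelled by graph surgery: edges into D are
removed, its marginal is set to δ′, and every other conditional table is kept
(modularity). The post-regime cells θ′_jk are therefore the same expression
with δ replaced by δ′.

Key structural facts the package computes rather than assumes:

- **Observational non-identifiability.** Three independent cell frequencies
  against five parameters: at any generic interior point the 3×5 Jacobian of
  the forward map has rank 3, leaving a 2-dimensional solution family with
  identical likelihoods.
- **Identification by intervention.** Stacking both regimes gives a 6×6
  Jacobian of generic rank 6 (zero-dimensional solution set) whenever
  δ′ ≠ δ. Solutions of the combined moment equations come in label-swap
  mirror pairs (δ,φ₀,φ₁,λ₀,λ₁,δ′) ↔ (1−δ,φ₁,φ₀,λ₁,λ₀,1−δ′); the assumed
  direction of the intervention (treatment reduces prevalence, δ′ < δ)
  selects the canonical branch.
- **Null intervention.** When δ′ = δ the two constraint blocks differ only
  in which column carries the prevalence derivative ([c C 0] vs [0 C c]),
  so the stacked rank drops to 4, not 3: δ′ is pinned to δ by the linearity
  of θ in the prevalence, and the solution family keeps the observational
  dimension 2. `dof_analysis` reports this rank deficiency explicitly.

## Moment-system solver

`solve_moment_system` minimizes the six residuals θ_jk(x) − r_jk,
θ′_jk(x) − r′_jk (cells 01, 10, 11 per regime; cell 00 is determined by
normalization) over the box [0,1]⁶ with bound-constrained trust-region least
squares from 32 deterministic quasi-random (Sobol) interior starts, stopping
early once a start reaches max-abs residual 1e−11. Found solutions are merged
within an L∞ radius of 1e−5, the mirror branch is constructed analytically by
the label swap (the closed form makes its residual identical), and the result
is classified:

- `identified_pair`: interior solution with a well-conditioned Jacobian;
- `degenerate_infinite`: |δ − δ′| < 1e−3 at the best branch, or smallest
  singular value of the 6×6 moment Jacobian below 1e−8 at an interior point
  (equal conditionals, null intervention);
- `boundary`: rank deficiency at a solution on the box boundary (the
  extremal-frequency case, e.g. a cell frequency of exactly 1);
- `infeasible`: no tuple attains the frequencies within tolerance. Before
  this verdict, an 11-point-per-axis grid search over the box supplies a
  candidate that is polished once more, so solver non-convergence is not
  mistaken for overdetermination.

Exact (distribution-level) inputs must be met to 1e−9. Finite-sample
frequencies are solved in the least-squares sense with tolerance
3/√t (six binomial standard errors of a worst-case cell at the smaller
regime size); the max-abs residual is always reported rather than tested for
goodness of fit. Rank decisions use a relative singular-value cutoff of
1e−10; coordinates within 1e−6 of {0, 1} count as boundary.

`solution_manifold` walks the observational 2-D family by predictor–corrector
continuation: a random step of length 0.08 in the null space of the 3×5
Jacobian, corrected back by bounded least squares, accepting points with
residual ≤ 1e−8 and pairwise L∞ separation > 1e−4; rejection sampling from
random interior starts is the fallback when a step stalls.

`check_feasibility` classifies a single regime or a pair as feasible /
infeasible / boundary-extremal. Boundary-extremal means feasible with an
extremal input cell (relative frequency 0 or 1 up to 1e−9), which is attained
only on the boundary of the parameter box where infinitely many tuples fit.
A useful fact for constructing infeasible pairs: both regimes share
sign(cov(F,L)) = sign((φ₁−φ₀)(λ₁−λ₀)), so a positively correlated pre table
with a negatively correlated post table cannot be fit (the shipped example
has a least-squares residual floor ≈ 0.21). The brute-force grid oracle
`grid_min_residual` is exposed for cross-checks; the max-abs cell deviation
is 3-Lipschitz in the sup norm, which bounds how far the grid minimum can sit
above zero for feasible inputs (3 · half grid step).

## Bayesian machinery

Posteriors are computed on a deterministic tensor grid: each Beta prior
component is discretized at the midpoints of `grid_size` (default 21)
equal-width bins, weighted by its density and renormalized; point-mass
components contribute a single node. The multinomial cell likelihood is
evaluated per regime and the posterior is normalized over the grid. The
production integrator factorizes the sums over the prevalence axes; its
algebraic identity with full-tensor direct summation is verified in the test
suite to 1e−10. The advertised grid error of an expectation is half a bin
width (0.5 / grid_size); grid choice trades determinism for resolution, and
the default was chosen so a full 6-parameter posterior stays around a second.

With intervention data the posterior is computed over six parameters; the
`direction` option truncates the prior to δ′ < δ (or >). This encodes the
qualitative assumption that the treatment lowers the latent prevalence and is
what breaks the label-swap mirror: without it, a swap-symmetric prior leaves
the posterior bimodal and expectations average the two branches. The
prior-sensitivity demonstrations therefore pass `direction="reduced"`
whenever post counts are present.

`estimate_hyperprior` realizes the parameter bookkeeping of the ρ-indexed
prior family literally: ρ adds one dimension, and the deterministic coupling
δ′ = f(δ) (or a fixed δ′) removes one, so the evidence per family member is
well defined and the posterior over ρ is proportional to prior weight times
evidence. Only deterministic couplings are implemented; a stochastic
dependence between δ and δ′ is arguably more realistic but has no canonical
form, so it is left out deliberately.

## Synthetic data

`simulate_intervention_study` draws the two regimes as independent i.i.d.
samples sharing the conditional chances, with per-regime substreams derived
deterministically from one master seed (so the pre sample is unchanged when
only the post size changes). The generator's default study conditions are the
worked example δ = 0.6, φ₀ = 0.2, φ₁ = 0.7, λ₀ = 0.1, λ₁ = 0.8, δ′ = 0.3 —
a majority latent class with strong, well-separated item loadings and a
treatment that halves the prevalence — at 10⁴ subjects per regime (10⁵ in
law-of-large-numbers checks, where the binomial standard error ≈ 0.0016
makes a 0.01 tolerance a 6σ margin).

What the generator does *not* emulate: within-subject correlation when the
same individuals are observed in both regimes (the likelihood treatment the
solver matches uses independent products, so paired designs are out of
scope), missing data, misclassification of the manifest items, covariates,
more than two classes or items. Passing tests show the machinery is correct
under the model's own assumptions; they say nothing about robustness to
violations of conditional independence or of intervention modularity in real
studies.

## Numerical choices and edge cases

- Cells are computed in linear space (they cannot underflow at this model
  size); log-likelihoods take logs of cells with explicit −∞ when a positive
  count meets a zero cell; zero-total counts are a domain error for the
  likelihood but legal for the posterior (which is then the prior).
- Boundary parameter values (0 or 1) are legal inputs everywhere; dimension
  analysis switches to one-sided differences there and flags the report.
- Jacobians are central differences with step 1e−6.
- Tie-break for the mirror pair under `direction="unconstrained"`: branches
  are returned in ascending δ with a warning that the order carries no
  meaning.
- Numbers are serialized as shortest round-tripping decimal text, so
  write-then-read is exact.

## Known limitations

The degeneracy thresholds (|δ−δ′| < 1e−3, singular value < 1e−8) separate
the exact pathologies from solver noise but are not a proof of the exact
non-degeneracy boundary; inputs engineered between those scales will be
classified by whichever side of the threshold they fall on. Structure
discrimination compares exact marginals with threshold 1e−9; with estimated
marginals the caller must supply a sampling-noise threshold, and a chain
whose intervention effect is smaller than it will be reported as
indistinguishable.
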