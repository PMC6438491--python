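# latentid

Identifiability of binary latent class models from observational and
intervention data.

## The problem

A latent class model explains the association between two observed binary
variables — fear *F* and loathing *L* in the running example — through a
hidden binary variable *D* (depression) that renders them conditionally
independent:

    P(D=1) = δ,    P(F=1 | D=j) = φⱼ,    P(L=1 | D=j) = λⱼ,   j = 0, 1

so the observable cell probabilities are a two-component mixture of products
of Bernoullis,

    θ_jk = P(F=j, L=k) = δ · φ₁ʲ(1−φ₁)^(1−j) · λ₁ᵏ(1−λ₁)^(1−k)
                       + (1−δ) · φ₀ʲ(1−φ₀)^(1−j) · λ₀ᵏ(1−λ₀)^(1−k).

The four cells carry only three independent frequencies, against five
parameters: the moment equations θ_jk = r_jk leave a **2-dimensional family**
of parameter tuples with identical likelihoods. The model is statistically
unidentifiable — no amount of observational data, and no Bayesian analysis,
pins the parameters down; posterior expectations stay prior-dependent forever.

A **stochastic intervention** on the latent node (say, a treatment that
changes the probability of depression to a new value δ′ while leaving the
conditionals φⱼ, λⱼ untouched) adds three more frequencies. Six equations,
six unknowns: the combined system determines all parameters **uniquely up to
the label swap** (δ,φ₀,φ₁,λ₀,λ₁,δ′) ↔ (1−δ,φ₁,φ₀,λ₁,λ₀,1−δ′), and the
qualitative knowledge that the treatment *reduces* the prevalence (δ′ < δ)
selects a single branch.

The package is aimed at methodologists who want to study this mechanism
concretely: it implements the forward model, seeded two-regime simulation,
the moment-system solver with degeneracy/feasibility diagnosis, grid-based
Bayesian machinery that exhibits the prior-(in)sensitivity contrast, and a
minimal causal Bayesian-network layer (graph surgery, structure
discrimination among common-cause and chain candidates).

## Worked example

`latentid demo` runs the depression/fear/loathing example end to end with
δ = 0.6, φ₀ = 0.2, φ₁ = 0.7, λ₀ = 0.1, λ₁ = 0.8 and an intervention lowering
the prevalence to δ′ = 0.3 (10 000 subjects per regime, seed 2018):

```
generating parameters: {'delta': 0.6, 'phi0': 0.2, 'phi1': 0.7, 'lambda0': 0.1, 'lambda1': 0.8}
intervention: delta' = 0.3 (reduced)
observational accounting: 5 parameters, 3 constraints, solution dimension 2
with intervention: 6 parameters, 6 constraints, solution dimension 0
pre frequencies:  [0.3287, 0.1715, 0.1573, 0.3425]
post frequencies: [0.5183, 0.1285, 0.1649, 0.1883]
moment solve: identified_pair, residual 6.61e-15
recovered (canonical branch): delta=0.5972 phi0=0.1926 phi1=0.7070 lambda0=0.1008 lambda1=0.7927 delta'=0.3122
structure discrimination: supported = common cause
```

Reading the output: from the observational regime alone, two degrees of
freedom remain (the 2-D solution family); adding the intervention regime
reduces the solution set to dimension 0. The solver then recovers the
generating parameters from the sampled frequencies to within sampling noise
(exactly two mirror branches exist; the canonical one, with δ′ < δ, is
shown), and the intervention's effect on *both* manifest marginals singles
out the common-cause structure against the two chain alternatives.

The same steps are available as library calls (`cell_probabilities`,
`simulate_intervention_study`, `solve_moment_system`, `dof_analysis`,
`posterior_over_parameters`, `discriminate_structure`, ...) and as the CLI
subcommands `simulate`, `identify`, `dof`, `bayes`, `intervene`,
`discriminate`.

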