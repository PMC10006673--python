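# Methods

## Model

entroflux infers a steady-state fluxome `v` conditioned on a transcriptome
`g` by maximum entropy. Every reaction flux is proportional to the copy
number of its catalyzing enzyme, `v_i = (k_i η_i) q_i`, where the turnover
`k_i` and the condition-specific attenuation `η_i ∈ [0,1]` are unobserved.
Taking expression `g_i` as a proxy for `q_i`, the flux per enzyme copy
`v_i/g_i` is given probability weight `P_g(v_i) = (v_i/g_i)/V` with
multiplicity `g_i`; under the assumption that every copy of an enzyme
carries the same flux, `V = Σ_i v_i`. The Shannon entropy of this
distribution,

    H_g(v) = − Σ_i (v_i/V) log( v_i / (g_i V) )    [nats],

is maximized over the split-flux polytope `{S v = 0, LB ≤ v ≤ UB}`
intersected with `{Σ v_i = V}`. At fixed `V` the identity

    H_g(v) = −(1/V) Σ_i v_i log(v_i/g_i) + log V

makes the program equivalent to minimizing the forward Kullback–Leibler
divergence between the normalized fluxome `P = v/V` and the normalized
per-reaction transcriptome `Q = g/G`. Both formulations are implemented as
separate numerical routes and are required (and tested) to return the same
fluxome. `−Σ p log p` terms make the objective strictly concave on the
positive orthant, so the optimum is unique; multistart agreement is part of
the test suite.

Assumptions worth keeping in mind: mRNA stands in for enzyme abundance
(post-transcriptional regulation is exactly the noise the entropy prior is
meant to absorb, not to model); all copies of an enzyme carry equal flux;
the network is at steady state; and the solution is *not* guaranteed free
of thermodynamically infeasible cycles (TICs) — the toy fixture exists
precisely to exercise that regime.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `V_total` | 1000 | fixed total split flux, mmol/gDW/h; large enough that no reaction is pushed against its bound, and it restricts the polytope to a compact slice that speeds the solve. |
| `epsilon` | 1e-8 | smoothing added to `v_i` and `g_i` inside the logarithm so zero fluxes/abundances stay finite; mapped expression is additionally floored at `epsilon`. |
| split bounds | [0, 1000] | substituted for non-finite bounds after splitting reversible reactions; finite model bounds always win. |
| `or_mode` | `sum` | GPR OR-node convention (isozymes add capacity); `max` is available since the convention is not universal. AND nodes always take the minimum (complexes limited by the scarcest subunit). |
| median imputation | — | reactions whose GPR is absent or evaluates to missing receive the median of the GPR-derived values; the median is computed over GPR-assigned reactions only, which avoids a self-referential definition. Forward and reverse split copies share one abundance (one enzyme, two directions). |

## Numerical choices

* All nonlinear programs are solved with scipy's `trust-constr`
  interior-point method with analytic gradients and exact (diagonal)
  Hessians; iteration cap 3000, gradient tolerance 1e-9. Feasibility is
  checked first with an LP (`linprog`/HiGHS): an empty polytope yields
  `status="infeasible"` on the result object, never an exception, so batch
  cohort runs continue.
* The entropy route minimizes `−H_g` with `V` held at the constraint
  value; the KL route minimizes `Σ v_i log((v_i+ε)/(g_i+ε))`. On the
  constraint surface the two differ by an affine transform, which is what
  makes the equivalence a meaningful cross-check of both codes.
* Warm start at the expression-proportional point `V·g/Σg` clipped to
  bounds (the unconstrained KL optimum); a failed solve retries once from
  an LP-interior point. Uniqueness makes the start irrelevant to the
  answer.
* A solution is reported `optimal` only if `‖S v‖∞ ≤ 1e-6·V` and
  `|Σ v − V| ≤ 1e-6·V`; otherwise the status degrades to
  `numerical_failure`.
* SPOT is solved as `max g·v` under `S v = 0`, bounds rescaled by the
  largest finite bound, and the quadratic constraint `‖v‖₂ ≤ 1`
  (inequality form — it binds at any nonzero optimum with nonnegative
  `g`); the returned vector is rescaled to `Σ v = V` for readability, which
  is immaterial to the Pearson-based comparisons.
* FBA + min ℓ² pins biomass at exactly its LP optimum (no relaxation); the
  pinned variable is eliminated from the stage-2 QP so the equality
  Jacobian keeps full rank. Because interior-point iterates stall a small
  distance from active bounds, the QP solution is polished by snapping
  near-bound coordinates and re-solving the free block as a minimum-norm
  least-squares system; the polish is accepted only when feasible and not
  worse, which by strong convexity can only move the point closer to the
  unique optimum.
* Mann–Whitney: for combined n ≤ 20 the two-sided p is exact by
  exhaustive enumeration of all group assignments with mid-ranks,
  `p = P(|U − n_a n_b/2| ≥ |U_obs − n_a n_b/2|)`; larger samples use the
  tie- and continuity-corrected normal approximation. Benjamini–Hochberg
  adjusted values accompany raw p when many pathways are tested.
* Degenerate inputs: zero-expression genes are floored at `epsilon`; a
  constant flux vector makes a Pearson score undefined and returns NaN; a
  zero glucose flux makes the lactate yield NaN rather than raising.

## Synthetic data

The benchmark emulates the situation where ground-truth fluxomes exist:
reference fluxomes are drawn uniformly from the polytope with cobrapy's
artificially-centered hit-and-run sampler (thinning 100, seeded,
deterministic), and each reference gets a transcriptome in which a random
fraction λ of reactions has expression equal to its absolute net flux while
the remainder draws from an exponential distribution — matching the
long-tailed shape of real expression data — whose mean equals the mean
absolute flux, so informative and uninformative genes share a scale. Values
reach gene level through one-gene-per-reaction pseudo-GPRs; one reference
sample set is shared across all λ levels, making the λ comparison paired
and the expression-blind FBA baseline exactly λ-invariant.

The stand-in network (`random_flow_network`) is a seeded unit-stoichiometry
flow network: a chain backbone from uptake to secretion (labelled with
glycolysis/TCA subsystems to define the carbon-core scoring subset) plus
random internal edges, some reversible, which create parallel routes and
TICs. Default size ~43 reactions with a single uptake capped at 10 —
a deliberate miniature chosen to keep the default sweep (11 λ × 50
samples) around a minute or two of CPU.

What this synthetic setting does *not* show: real GPRs are many-to-many,
real stoichiometry is not unit-valued, and the carbon-core advantage that
biomass-maximizing FBA displays on curated genome-scale models does not
transfer to the flow network (its biomass proxy is just maximal
throughput), so core-scale FBA scores here are low where published
genome-scale experiments find them high. Genome-scale conclusions — the
entropy method's accuracy rising with λ and dominating FBA + min ℓ² at
every λ — are the ones the synthetic benchmark is designed to probe.
`scripts/genome_scale_benchmark.py` runs the identical protocol on a real
reconstruction (e.g. iJO1366) when a model file is supplied locally.

The synthetic Warburg cohort in `scripts/acceptance.py` uses a seven-
reaction glucose→pyruvate→{lactate | TCA} network with log-normal baseline
expression and a six-fold glycolytic (tumor-like) or oxidative (normal-
like) shift; it demonstrates that the fitted fluxomes separate the groups
on the `v_lac/v_glc` yield, not that tumors behave this way — that claim
needs real cohorts.

## Design choices that were genuinely open

* ε placement: smoothing is applied inside the logarithm to both flux and
  abundance, and mapped abundances are floored at ε, making every test
  deterministic; adding ε only to `v` is the main alternative and is why
  the placement is configurable.
* The total-flux constraint sums *split* fluxes, so a balanced TIC
  contributes both directions to `V`; enrichment and yield statistics use
  *net* fluxes, so a balanced TIC contributes nothing there.
* Pathway enrichment is implemented literally as (mean |net flux| over the
  pathway) / (sum of |net flux| over the network); the mean/sum asymmetry
  is kept as-is because the index is only ever compared between groups.
* Exchange reactions are detected structurally (all stoichiometric
  coefficients on one side), the standard convention.

## Limitations

* No TIC elimination: the entropy program dampens but does not prevent
  spurious cycles; a thermodynamically consistent variant would double the
  variable count and is out of scope.
* Protein-abundance input is not supported; expression is the only
  conditioning channel.
* The interior-point solver is dense-linear-algebra bound above a few
  thousand split reactions; genome-scale human models will be slow (tens
  of minutes) though not infeasible.
* Exact Mann-Whitney enumeration is limited to combined n ≤ 20 by
  combinatorics; beyond that the normal approximation is standard but
  approximate.
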