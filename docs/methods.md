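# Methods

## The model and its duals

A constraint-based metabolic model is the LP data `(S, b, c, v_LB, v_UB)`:
`S` is the m×n stoichiometric matrix, `b` the per-metabolite net
accumulation/depletion rate (zero at steady state), `c` the objective
weights, and the bounds encode reversibility and medium composition
(COBRA sign convention: negative exchange flux is uptake). The primal is

    max  c·v   s.t.  S v = b,  v_LB ≤ v ≤ v_UB

and the dual, over multipliers λ (free, per metabolite), μ_LB ≥ 0 and
μ_UB ≥ 0 (per reaction),

    min  b·λ − v_LB·μ_LB + v_UB·μ_UB   s.t.  Sᵀλ − μ_LB + μ_UB = c.

Shadow prices follow the sensitivity convention λ_i = ∂Z*/∂b_i for the
*maximization* primal. scipy's HiGHS backend reports equality marginals
for the minimized form, so the adapter flips their sign for FBA; for the
inconsistency-score LP (a minimization) the marginal is ∂IS*/∂b_i
directly and is used unflipped. Reduced costs are reconstructed from dual
stationarity (`r = c − Sᵀλ`, split by sign into μ_UB/μ_LB, with
multipliers of infinite bounds fixed at zero) rather than read from
solver bound-marginals; this is backend-independent and satisfies
complementary slackness by construction at the solver's optimum. Strong
duality is exercised two ways in the tests: against the dual objective
assembled from the solver's λ, and against an independent solve of the
explicitly constructed dual program.

Infeasible and unbounded solves are reported as statuses, never raised
silently; infeasibility in a model containing zeroed-out (knocked-out)
reactions is additionally flagged as potentially lethal, since a lethal
deletion under a demanded flux is the common cause.

## Validity ranges

Z(b_i) is a concave piecewise-linear function of a single right-hand-side
entry, and the solver's λ_i is a supergradient at the current point. The
validity range [G−, G+] is the linear piece on which λ_i is the true
slope. Rather than bisection re-solves or solver-native basis ranging
(which is basis-dependent at degenerate optima), each endpoint is found
with one auxiliary LP over (v, δ):

    max/min δ   s.t.  S v − δ e_i = b,  bounds,  c·v ≥ Z(0) + λ_i δ − tol

Concavity makes the last constraint hold with equality exactly on the
linear piece, so the extremal δ is the endpoint. δ is capped at 1e9 and
endpoints at the cap are reported as ±∞. The tolerance (1e-6 throughout
the package) leaks into the endpoint by ~tol/|λ|, which is below the
reporting precision of any downstream use. Records whose range width is
below `eps_range` (default 1e-6) are marked invalid and excluded from
downstream comparisons.

## Degeneracy checking

At a degenerate optimum the dual is not unique and Z(b_i) has a kink at
the current point, so the solver's λ_i is ambiguous. The brute-force
check re-solves the primal with b_i displaced by δ and compares the
finite-difference slopes λ⁺ = (Z(+δ) − Z)/δ and λ⁻ = (Z(−δ) − Z)/(−δ)
with the solver's value; a deviation beyond tolerance (default 1e-5,
ten times the solver feasibility tolerance) flags the metabolite.
Displacements use δ = p·G± with p = 0.2 by default (p ∈ {0.5, 0.9} give
identical results on fixtures whose ranges are respected, and the
perturbed problems are fresh solves, never warm-started, so no basis
carry-over can mask a degenerate dual).

One subtlety: at a kink, strict validity ranging always returns a
one-sided range — the direction with zero width is precisely the one
that reveals the second supergradient. Skipping it would make the check
blind to the very degeneracy it exists to detect. The checker therefore
probes a zero-width direction with a small trial displacement
(p × the problem scale, geometrically shrunk while the perturbed LP is
infeasible) and stores λ⁺/λ⁻ as absent only when no feasible
perturbation exists in that direction. A range side narrower than
1e-4 × problem scale is treated as zero-width: perturbing inside it
would divide solver noise of order 1e-6 by a comparably small δ. The
standalone `incremental_shadow_price`/`decremental_shadow_price`
operations keep the strict precondition (they refuse when G⁺ ≤ 0 or
G⁻ ≥ 0) since their contract is evaluation inside the validity range.

Classification under growth maximization: λ < −eps → growth-limiting
(extra outflow raises growth), |λ| ≤ eps → non-limiting. Positive shadow
prices of intracellular metabolites are reported unclassified — they
fall outside the limiting/non-limiting dichotomy that growth
maximization defines.

## Expression integration (GIMME/TEAM style)

Gene thresholds are gene-specific: x_g is the θ-quantile (linear
interpolation between order statistics, so thresholds move continuously
with θ) of gene g's own expression distribution pooled across all
samples; the default θ = 0.88. Penalties are p_g = max(0, x_g − EXP_g);
genes present in the model but absent from the data get penalty 0 (no
evidence, no penalty). Reaction penalties come from the GPR tree: OR
takes the minimum over branches (any sufficiently expressed isozyme
carries the flux), AND the maximum (a complex is limited by its
least-expressed member); an empty rule gives 0. The inconsistency score

    min  Σ_j c_j |v_j|   s.t.  S v = b,  bounds,  v_RMF ≥ v_RMF,min

penalizes flux *magnitude*, so a reversible penalized reaction cannot
earn negative penalty by running backward. The absolute values are
linearized with auxiliary variables t_j ≥ |v_j| carrying the penalties —
equivalent to splitting each reaction into two nonnegative
half-reactions with a shared penalty, but keeping v intact so fluxes
need no recombination and the equality-constraint duals are unchanged.
The RMF bound is a fraction (default 0.3) of the FBA maximum of the RMF
flux; a zero maximum is an error ("RMF unreachable") because the
constraint exists to exclude the trivial all-zero solution. Direction
prediction: λ_i > tol → abundance predicted to decrease (letting the
metabolite deplete lowers the inconsistency), λ_i < −tol → increase.

`theta_scan` re-runs thresholds → penalties → solve per θ with a
caller-supplied scoring callback; since quantiles are monotone in θ,
penalties and hence the optimal IS are non-decreasing in θ on a fixed
model and sample (a property the tests verify).

## Dynamics statistics

Temporal variation is the coefficient of variation σ/μ of a metabolite's
time course restricted to points within a window (default 30 minutes
after the perturbation), with the sample (n−1) standard deviation —
the conventional estimator for the short series this is applied to.
A labeled baseline at time 0 is included by default (configurable).
Series with zero mean get an undefined CV and are excluded downstream.

The quadrant permutation test computes centers m_S (of the shadow
prices) and m_T (of the CVs) — mean by default, median available — and
counts p_original, the metabolites in the "incorrect" quadrant
(λ < m_S and CV > m_T). The pairing between the λ and CV vectors is then
permuted (default 10^5 draws, single seed) and the p-value is the
fraction of permutations with p_i ≤ p_original. The inclusive count is
deliberate: under label permutation the quadrant count is discrete
(hypergeometric), and the exclusive variant `p_i < p_original` is
anti-conservative — an exact calculation on the synthetic null puts its
type-I error at 8% for a nominal 5% level, versus 2.7% (valid,
conservative) for the inclusive count. The exclusive variant is kept
behind a flag for comparison with analyses that used it. When center =
median, the p-value is invariant to any common monotone rescaling of the
CVs.

MCC is computed from the 2×2 confusion matrix (it equals the Pearson
correlation of the two binary label vectors); its p-value comes from a
two-sided label-permutation null (|MCC_perm| ≥ |MCC_obs|, default 10^5
draws, seeded), since no closed-form null is appropriate at these sample
sizes. Spearman (midrank ties) and Pearson correlations with two-sided
p-values are delegated to scipy.

## Synthetic data: what it emulates and what it does not

The toy fixtures embody the canonical geometries: `figure1` (a single
growth-limiting pool), `degenerate` (a kink in Z(b) from two unequal
sinks), `branched` (a two-metabolite chain), `two_pathway_team` (isozyme
pathways with contrasting expression), `nitrogen_assimilation` (two
redundant assimilation pathways with distinct GPRs and a growth demand,
so the double knockout is lethal while single knockouts reroute
invisibly in the duals). Every ground truth is derived by hand at
generation time and verified against the live solver in the tests, so
generator and solver check each other. Random LP instances are feasible
by construction (b = S·v0 for an interior v0) and bounded (finite
bounds); continuous random coefficients make accidental degeneracy a
measure-zero event.

The expression generator separates a designated condition sample from a
background band per gene (active genes 3 spreads above, inactive 3
spreads below), so active-gene penalties are exactly zero at any θ < 1
when noise is zero. The time-course generator produces positive
lognormal-shaped series whose log-scale spread targets a chosen CV:
in signal mode, negative-λ metabolites draw target CVs from (0.02, 0.15)
and zero-λ metabolites from (0.4, 1.0) — a deliberately clear separation
representing tightly controlled versus freely varying pools — while null
mode draws CVs independently of λ for calibration. None of these emulate
the measurement-error structure, compartment ambiguity or temporal
autocorrelation of real chemostat or metabolomics data; passing tests
demonstrate the correctness and calibration of the machinery, not the
biological effect sizes recoverable from any particular dataset.

Problem sizes used by the acceptance script — 100 random models for the
duality oracle, 10 for the linearity oracle, 200 null and 50 signal
datasets of 60 metabolites at 10^4 permutations for the statistics — are
chosen so the whole script completes in seconds while keeping Monte-Carlo
standard errors well inside the margins being tested.

## Numerical choices and limitations

- Single tolerance 1e-6 for feasibility/optimality comparisons;
  degeneracy mismatch tolerance 1e-5; range cap 1e9 (≈ ∞).
- Knockouts zero reaction bounds instead of deleting columns so that
  metabolite and reaction indices align across strains in differential
  shadow-price tables.
- Exchange reactions are recognized structurally (stoichiometry touching
  exactly one metabolite); media apply only to them, and exchanges absent
  from a medium are closed for uptake (lower bound 0) with secretion left
  open.
- No flux-variability analysis, loopless FBA, MILP variants or
  parsimonious FBA; no enumeration of alternate primal optima (the
  degeneracy check detects their dual signature instead).
- Shadow prices are sensitivities of an optimum, not kinetic quantities:
  they say nothing about response speeds or the new steady-state
  concentrations a perturbed cell will reach, and results on lumped
  multi-condition datasets compare raw (unnormalized) shadow prices
  across conditions.
- Genome-scale reproductions depend on the exact model version and on a
  medium-to-exchange-bounds mapping that published media recipes do not
  determine uniquely; the reproduction script therefore requires the
  medium as explicit input and reports it alongside its output.
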