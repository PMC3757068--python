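# fluximba — flux imbalance analysis for constraint-based metabolic models

Flux balance analysis (FBA) predicts steady-state reaction fluxes in a
metabolic network by linear programming: maximize an objective `c·v`
(usually biomass production) subject to mass balance `S·v = b` (with
`b = 0` at steady state) and flux bounds `v_LB ≤ v ≤ v_UB`. The *dual*
variables of the mass-balance constraints — the **shadow prices**
`λ_i = ∂Z*/∂b_i` — measure how the optimum responds when metabolite *i* is
allowed to accumulate (`b_i > 0`) or deplete (`b_i < 0`). Under growth
maximization a *negative* shadow price marks a **growth-limiting
metabolite**: permitting extra outflow from it raises the achievable
growth rate. `fluximba` is a toolkit for extracting, validating and
interpreting these sensitivities:

- **model_core** — a lightweight model container (stoichiometry, bounds,
  objective, Boolean gene–protein–reaction rules) with SBML (via cobrapy),
  JSON and TSV readers/writers, medium application and in-silico gene
  knockouts (reactions are disabled by zeroing bounds so metabolite
  indices stay aligned across strains);
- **duality** — the FBA primal, its explicitly constructed dual
  (strong duality is checked, not assumed), and per-metabolite shadow
  prices with their validity ranges `[G−, G+]`;
- **degeneracy** — brute-force incremental/decremental shadow prices
  `λ⁺ = (Z(+δ) − Z)/δ`, `λ⁻ = (Z(−δ) − Z)/(−δ)` recomputed from fresh LP
  solves, flagging metabolites whose recomputed sensitivity disagrees with
  the solver's dual value (alternate/degenerate optima), plus
  growth-limitation classification and wild-type-vs-knockout Δλ tables;
- **team** — GIMME/TEAM-style expression integration: gene-specific
  penalty thresholds `x_g` (the θ-quantile of each gene's own expression
  distribution), penalties `p_g = max(0, x_g − EXP_g)` propagated through
  GPR rules (OR → min, AND → max), and minimization of the inconsistency
  score `IS = Σ_j c_j·|v_j|` under a required-metabolic-functionality
  (RMF) constraint; the TEAM shadow price `∂IS*/∂b_i` predicts whether a
  metabolite's abundance should rise (λ < 0) or fall (λ > 0);
- **stats** — temporal variation of metabolite time courses (coefficient
  of variation over a post-perturbation window), a quadrant permutation
  test linking shadow prices to temporal variation, the Matthews
  correlation coefficient with a permutation p-value, and Spearman/Pearson
  correlation reports;
- **fixtures** — deterministic toy networks with hand-derived ground
  truths and seeded generators for random LP instances, synthetic
  expression matrices and synthetic time courses.

## Worked example

Write the one-metabolite toy model (one source capped at 10, one
objective sink capped at 1000) and analyze it:

```bash
$ fluximba synth figure1 --out fig1.tsv
$ fluximba fba --model fig1.tsv
objective       10
R1      10
R2      10
$ fluximba shadow-prices --model fig1.tsv
metabolite_id   compartment     lambda  range_low       range_high      valid
M[c]    c       -1.0    -990.000001     10.0    True
```

The optimum saturates the source (`Z = 10`). The shadow price of M is
−1: every unit of extra outflow permitted from M (`b_M < 0`) adds one
unit of objective, so M is growth-limiting. That sensitivity is valid for
`b_M ∈ [−990, 10]` — relaxation is eventually capped by the sink bound
(1000), tightening by the source bound (10).

A degenerate optimum is caught by the brute-force check. In the
`degenerate` fixture, M is drained by two sinks of unequal objective
weight, so the optimum sits at a kink of `Z(b_M)`:

```bash
$ fluximba synth degenerate --out degen.json
$ fluximba check-degeneracy --model degen.json
metabolite_id   lambda_solver   lambda_plus     lambda_minus    p       degenerate
M[c]    -1.0    -1.0    -0.5    0.2     True
# 1 degenerate shadow price(s)
```

Tightening the balance removes weight-1 flux (`λ⁺ = −1`) while relaxing
it routes the surplus through the weight-0.5 sink (`λ⁻ = −0.5`); the
solver's single dual value cannot represent both, and the metabolite is
flagged.

The same machinery is available as a library:

```python
from fluximba import make_fixture, solve_fba, shadow_price_table

model, truth = make_fixture("figure1")
primal, dual = solve_fba(model)
print(primal.objective_value)      # 10.0
print(dual.shadow_prices)          # [-1.]
```

Other subcommands: `fluximba team` (expression integration; reports `IS`
and per-metabolite predicted directions), `fluximba dynamics`
(CV/shadow-price join and the quadrant permutation test),
`fluximba report` (the full pipeline into a TSV/JSON bundle).

## Documentation

The modeling assumptions, parameter defaults, numerical choices and known
limitations are described in `docs/methods.md`.
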