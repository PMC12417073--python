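# Methods

## Model and assumptions

`retap` operates entirely within steady-state constraint-based modeling:
fluxes v satisfy S·v = 0 with box bounds lb ≤ v ≤ ub, and every question is
answered by linear programming over that polytope. The method inherits the
usual GSM assumptions — no kinetic, regulatory or thermodynamic
information, growth as a single biomass drain, exchange fluxes signed with
uptake negative — and adds one of its own: that a reaction whose *feasible
flux interval* must move between a low-production and a high-production
regime is a plausible genetic target, regardless of which particular flux
distribution the cell realises. Working with FVA intervals rather than
single FBA optima makes the ranking independent of solver degeneracy:
only LP optima are ever stored, so repeated runs are bit-identical.

## Procedure

1. **Yield ceiling.** Maximum growth µ_max is the biomass optimum under the
   given medium. The maximum theoretical yield (MTY) of the product is then
   the product-flux optimum *with the biomass lower bound already raised to
   b·µ_max*. Computing the MTY under the floor (rather than in the
   unconstrained model) guarantees that the 100 % enforcement step of the
   scan is feasible by construction instead of failing late.
2. **Fraction scan.** Production is enforced as a floor only — the product
   reaction's lower bound is raised to f·MTY with its upper bound untouched
   — at fractions f = 0.1, 0.2, …, 1.0 by default. A floor, not a fixed
   value, matches how enforced-objective scanning is done in this family of
   methods and keeps each successive feasible set nested inside the last,
   which is also the property the span-nestedness tests check. The grid is
   configurable (any strictly increasing grid in (0,1] with ≥ 4 points; two
   points are needed per state). Fraction 0 is not included: at f = 0.1 the
   original lower bound is barely perturbed, so the near-zero state is
   already represented, and a 0 % step would duplicate it.
3. **State summaries.** For each reaction the two smallest fractions form
   the low state and the two largest the high state. The summary is
   deliberately crude: µ is the arithmetic mean of the four interval
   endpoints (equivalently of the two midpoints), σ the overall spread
   (largest max − smallest min across both spans). The "average of the
   range" phrase admits a second reading — the mean of the two widths — but
   a width cannot serve as a location parameter, so the endpoint mean is
   used. Signed net fluxes are kept throughout; reversible reactions are
   not split, so a reaction that flips direction shows up as a large |Δµ|
   exactly as it should.
4. **Overlap and score.** The overlap index η = ∫ min(φ_low, φ_high) dx is
   evaluated analytically: equal σ gives a single density crossing and the
   closed form 2Φ(−|Δµ|/(2σ)); unequal σ gives exactly two crossings from a
   quadratic in x, and η is a sum of normal CDF differences over the three
   pieces (the wider density is the minimum between the crossings, the
   narrower one outside). A quadrature fallback over the joint µ±8σ
   envelope handles numerically degenerate discriminants. The score is
   1/η, capped (default 10⁶) so disjoint states produce a finite, sortable
   value rather than infinity.
5. **Intervention.** |Δµ| below `flux_diff_cutoff` is noise → no action.
   Δµ > 0 → overexpress; Δµ < 0 → downregulate, upgraded to **knockout**
   when the reaction's feasible interval at the *highest* fraction is
   pinned at zero (|v_min|, |v_max| ≤ `knockout_eps`). The terminal span —
   not the high-state mean — is the right witness for "must shut off":
   the high-state µ averages the last two fractions, so it sits above zero
   (≈ a quarter of the penultimate span width) even for a reaction that is
   strictly forced to zero at full production, and a mean-based rule with a
   tight ε would never fire. When no terminal span is available (direct
   calls with bare summaries) the |µ_high| ≤ ε fallback applies.
6. **Filtering and ranking.** The product, biomass and carbon reactions are
   always excluded (they are enforced or trivially correlated, not
   targets); exchanges (id prefixes `EX_`/`DM_`/`SK_`) are excluded by
   default; then the score and |Δµ| cutoffs apply. Ordering is descending
   score, ties by descending |Δµ|, then ascending reaction id — fully
   deterministic. Gene mapping reports the verbatim GPR string plus the
   flattened, deduplicated, sorted gene list; no boolean reasoning over
   isozymes vs complexes is attempted, because the right manipulation for
   an AND vs OR rule is a wet-lab decision the flat list should not
   prejudge.

## Parameters

| name | default | units | why |
|---|---|---|---|
| `biomass_min_fraction` | 0.1 | – | keeps states physiological; 10 % of µ_max is feasible for toy and genome-scale models alike |
| `n_fractions` | 10 | – | the conventional 10 %…100 % grid; ≥ 4 required |
| `flux_diff_cutoff` | 1e-4 | mmol/gDW/h | below LP noise, a mean shift is not evidence |
| `score_cutoff` | 1.0 | – | keep anything with less-than-total overlap |
| `knockout_eps` | 1e-6 | mmol/gDW/h | numerically zero flux |
| `sigma_floor` | 1e-6 | mmol/gDW/h | a fixed flux still needs a proper density |
| `score_cap` | 1e6 | – | finite, sortable stand-in for 1/0 |
| `uptake_rate` | 10 | mmol/gDW/h | a standard glucose-scale uptake bound |

LP tolerances: optimality 1e-6 relative, feasibility 1e-9; solves go
through cobrapy/optlang (GLPK). Solver choice is hidden behind the
`optimize_flux` / `flux_variability` contracts.

## What the synthetic fixtures emulate — and what they do not

`build_branched_toy` plants the canonical target topology: a carbon source
feeding a linear trunk to a hub that splits between a product branch and a
competing biomass branch (1:1 trunk stoichiometry, so every expectation is
a hand LP), optionally a cofactor drain coupled to the product branch, and
a decoy pathway on an independent substrate whose span never responds to
enforcement. Seeded jitter perturbs only decoy bounds — never
stoichiometry — so the analytic ground truth holds for every seed; jittered
bounds are rounded to 6 decimals so every serialisation round-trips
bit-faithfully. With uptake U, floor fraction b and product stoichiometry
y, the planted truths are µ_max = U, MTY = y·(1−b)·U, product branch pinned
at (1−b)·U and competing branch at b·U at full enforcement.

These fixtures establish correctness of the machinery, not predictive
power on real organisms: they have no cofactor balancing across branches,
no alternative routes to the product, no redundant isoenzymes, and flux
ranges that shrink monotonically by construction. Passing the recovery
suite shows the algorithm finds what its own model of "target" defines; it
says nothing about how often GSM-derived targets work in vivo.

## Numerical and design choices

- Degenerate FVA intervals (min marginally above max from solver round-off)
  are collapsed to their midpoint; span nestedness across fractions is
  asserted to 1e-6.
- The overlap integral is exact up to CDF evaluation; the dense-trapezoid
  oracle in the tests is an independent path, not the implementation.
- Problem sizes in the test and acceptance runs — ≤ 10-reaction fixtures,
  20 seeded models for the vertex-enumeration comparison, 1000 gaussian
  pairs, 22 recovery instances — keep the brute-force oracles exact and the
  whole suite in the seconds range; the pipeline itself is the same code
  path a genome-scale model would take, at minutes per scan.
- Reading both SBML L3-FBC and BiGG JSON covers the two dialects
  genome-scale models are actually distributed in; earlier SBML levels are
  rejected with an explicit message rather than half-parsed.

## Known limitations

- Plain FVA: thermodynamically infeasible loops can inflate spans; loopless
  variants are not implemented.
- Gaussian summaries are a deliberate two-moment caricature of interval
  data; reactions with strongly asymmetric span evolution may be under- or
  over-scored.
- No minimization-of-adjustment reference state (MOMA/ROOM-style): the
  ranking compares feasible sets, not predicted mutant behaviour.
- Capture statistics on published genome-scale reconstructions require the
  model downloads plus the heterologous pathway definitions of the original
  studies and are outside the test surface of this repository.
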