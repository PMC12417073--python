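# retap

Reaction-target prioritization for metabolic engineering: given a
constraint-based genome-scale model (GSM) and a desired product, `retap`
ranks every reaction by how strongly its feasible flux range must shift
between low-production and high-production states, and translates the
ranked reactions into overexpression, downregulation or knockout gene
targets.

## Who this is for

Strain engineers and modelers running design–build–test–learn cycles who
need a short, prioritized list of genetic targets to raise the flux to a
product — without the cost of bilevel strain-design programs. The method
only needs an SBML L3-FBC or BiGG-JSON model, the ids of the product,
biomass and carbon-source reactions, and an uptake rate.

## The method

All computations are standard flux balance / flux variability analysis
(FBA/FVA) over the flux polytope {v : S·v = 0, lb ≤ v ≤ ub}.

1. **Maximum theoretical yield (MTY).** Maximize biomass to get µ_max, fix
   the biomass lower bound to a floor `b·µ_max` (default b = 0.1), then
   maximize the product flux: this optimum is the MTY.
2. **Enforced-production scan.** For each fraction f in {0.1, …, 1.0} set
   the product reaction's lower bound to f·MTY (upper bound untouched) and
   run FVA for every reaction, recording its feasible flux span
   [v_min(f), v_max(f)].
3. **State gaussians.** For each reaction, fit a normal distribution to the
   two lowest fractions (the *low-production state*) and to the two highest
   (the *high-production state*): µ is the mean of the four span endpoints,
   σ the overall max minus overall min across the two spans (floored so the
   density is proper).
4. **Overlap score.** Compute the overlap index
   η = ∫ min(φ_low(x), φ_high(x)) dx of the two densities — 1 for identical
   states, 0 for disjoint ones — analytically through the crossing points of
   the two densities. The reported score is **1/η** (capped): a reaction
   that *must* change flux to allow high production has nearly disjoint
   states and a high score.
5. **Intervention and genes.** The sign of Δµ = µ_high − µ_low picks the
   action: rising → overexpress, falling → downregulate, falling and pinned
   at zero at full enforcement → knockout. Surviving targets are ranked by
   score and annotated with their gene–protein–reaction (GPR) rules and the
   flattened gene lists.

Selectivity knobs (biomass floor, score cutoff, flux-difference cutoff,
exchange exclusion) control how many targets are returned; tightening any
of them never returns more targets.

## Worked example

The package ships a generator for a small branched model with planted
ground truth: carbon uptake 10 mmol/gDW/h feeds a trunk `R1` to a hub
metabolite, which splits into a product branch `R2 → EX_P` and a competing
biomass branch `R3 → BIOMASS`, plus a decoy pathway that is uncorrelated
with production.

```bash
retap make-fixture --out toy.json
retap run --model toy.json --product EX_P --biomass BIOMASS --carbon EX_A \
          --uptake 10 --out toy_targets.tsv
```

With the default 10 % biomass floor the log reports `mty=9 max_growth=10`
(one flux unit is reserved for biomass, nine remain for product), and
`toy_targets.tsv` contains:

```
rank  reaction_id  reaction_name             score    overlap   intervention  mu_low  sigma_low  mu_high  sigma_high  delta_mu  genes    gpr
1     R1           trunk step 1              4.93297  0.202718  overexpress   6.175   8.1        9.775    0.9         3.6       gT1      gT1
2     R2           product branch            4.93297  0.202718  overexpress   5.175   8.1        8.775    0.9         3.6       gP1;gP2  gP1 and gP2
3     R3           competing biomass branch  4.93297  0.202718  downregulate  4.825   8.1        1.225    0.9         -3.6      gB1;gB2  gB1 or gB2
```

Reading the rows: forcing production up pulls the trunk and product branch
means from ~5–6 up to ~9 (overexpress their genes), and squeezes the
competing branch from ~4.8 down to ~1.2 — its floor — so it should be
downregulated; with `--biomass-min 0` it is forced to exactly zero and is
reported as a knockout. The decoy reaction has identical low and high
states (overlap 1, lowest possible score) and is filtered out. Each run
also writes a `*.manifest.json` with every parameter plus the computed MTY
and maximum growth, sufficient to replay the run exactly.

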