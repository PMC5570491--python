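# exoflux

Condition-specific metabolic models from quantitative extracellular
metabolomic profiles.

Targeted exometabolomics measures how fast cultured cells take up and
secrete a panel of metabolites (fluxes in U = fmol/cell/hr; negative =
uptake, positive = secretion). Those measurements constrain only a small
subset of the exchange reactions of a genome-scale metabolic model, and
cells grown in serum-containing medium exchange many unmeasured compounds —
closing every unmeasured exchange typically leaves no feasible steady
state. `exoflux` turns one sample's measured profile into a reduced,
sample-specific model and provides the downstream phenotyping toolbox, for
anyone doing constraint-based analysis of cultured-cell metabolomics
(cancer cell panels being the archetypal use case).

## The method

Starting from a model with stoichiometric matrix `S`, bounds `lb ≤ v ≤ ub`
and a biomass reaction:

1. **Medium setup** — all exchanges open to ±2,000 U, then class bounds
   (ions −100, vitamins −1, essential amino acids −10, water/protons
   −100 U), oxygen to (−1,000, 0) U, reactive-oxygen uptakes closed, and a
   minimal-growth bound `v_biomass ≥ 0.008` U.
2. **Qualitative screening** — each profiled metabolite is tested in both
   directions by forcing a tiny exchange flux (±10⁻⁴ U) and checking
   feasibility; directions the network cannot realize are discarded.
3. **Quantitative integration** — each measured flux *x* becomes a bound
   pair with a 20% allowance (the min/max of 0.8·*x* and 1.2·*x*), applied
   one exchange at a time with an FBA growth check; an infeasible pair is
   rolled back and logged.
4. **Exchange-cardinality completion** — every unmeasured exchange is
   split into nonnegative uptake/secretion components `v_e` and

   ```
   min 1ᵀ·v_e   s.t.  [S S_e]·[v; v_e] = 0,  lb ≤ v ≤ ub,  0 ≤ v_e
   ```

   is solved: the one-norm relaxation of the minimum number of missing
   exchanges needed for a feasible steady state. An FVA-style loop then
   verifies that each active exchange is necessary (closing it breaks
   feasibility), re-running the LP when it is not, and an exact
   subset-enumeration oracle is provided for small instances. Unused
   exchanges and blocked internal reactions (|v| < 10⁻⁴ U everywhere) are
   pruned away.
5. **Phenotyping** — parsimonious FBA (linear optimum fixed, then the
   squared Euclidean norm of internal fluxes minimized for uniqueness)
   feeds metabolite-centric flux splits `P*_ij = S_ij·v_j / Φ_i` for ATP,
   NADH, NADPH and FADH2, the ATP yield `Φ_ATP / |v_glc|`, and
   energy-phenotype calls; phenotypic phase planes, oxygen-uptake
   "oxotype" classification, GPR-aware gene/reaction essentiality
   (terminated < 5%, reduced 5–95% of wild-type growth), and
   reductive-carboxylation detection (FVA range of isocitrate
   dehydrogenase/aconitase entirely negative = obligate reverse flux)
   complete the suite.

Everything is exercised on generated toy networks with analytically known
answers (see `exoflux.fixtures`), including the textbook energy fixtures:
anaerobic glycolysis yields 2 ATP per glucose, full aerobic oxidation 32
at P/O ratios 2.5 (NADH) and 1.5 (FADH2).

## Worked example

```python
from exoflux import fixtures, mincard

# A toy network whose biomass needs two precursors importable only through
# unmeasured exchanges, among five candidates (seed shuffles which).
model, profile, truth = fixtures.make_exchange_completion_fixture(
    n_candidates=5, n_required=2, seed=3)
measured = [f"EX_{met}_e" for met in profile.entries]

cm = mincard.build_condition_model(model, measured, sample_id="demo")
print("added:", sorted(a.exchange_id for a in cm.added_exchanges))
print("ground truth:", truth)
print("removed exchanges:", len(cm.removed_exchanges),
      "blocked reactions:", len(cm.removed_blocked))
```

prints

```
added: ['EX_m00_e', 'EX_m03_e']
ground truth: ['EX_m00_e', 'EX_m03_e']
removed exchanges: 3 blocked reactions: 3
```

— the completion recovers exactly the withheld exchange pair and prunes
the three decoy exchanges together with their now-dead transporters. The
same pipeline runs from the shell:

```
exoflux fixtures --template exchange_completion --n-candidates 5 \
    --n-required 2 --seed 3 --out comp
exoflux build --model comp.json --measured EX_a_e,EX_w_e --sample demo \
    --out cond
```

## Layout

- `exoflux.model_core` — model/profile I/O (SBML L3-FBC, COBRA JSON, TSV
  tables), reversible-reaction splitting, unit conversions
- `exoflux.constraints` — medium config, screening, allowance integration
- `exoflux.mincard` — cardinality LP, minimality verification, oracle,
  pruning
- `exoflux.flux_engine` — FBA, parsimonious FBA, FVA, growth checks,
  hit-and-run sampling
- `exoflux.phenotyping` / `exoflux.perturbation` — flux splits, yields,
  phase planes, oxotypes, essentiality, reductive carboxylation
- `exoflux.fixtures` — deterministic toy networks and synthetic profiles

See `docs/methods.md` for the modeling assumptions and numerical choices.
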