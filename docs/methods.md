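# Methods

## Model representation and units

Models are COBRApy `Model` objects read from SBML (Level 3 + FBC v2) or
COBRA-style JSON. Exchange reactions are identified structurally as
boundary pseudo-reactions touching exactly one metabolite, with negative
flux meaning uptake. All fluxes are carried in U = fmol/cell/hr; under a
unitary cell weight of 10⁻¹² g this is numerically identical to
mmol/gDW/hr, so models parameterized in the conventional unit need no
rescaling. The doubling-time conversion is the exponential-growth closed
form μ = ln 2 / T (88 h ↔ 0.008 h⁻¹, 18.2 h ↔ 0.038 h⁻¹), and dry weight
is scaled between cell types proportionally to volume.

## Medium model

`MediumConfig` encodes the growth environment of cells in
serum-supplemented medium of unknown composition: a generous default
exchange window (±2,000 U), uptake caps per nutrient class (ions −100 U,
vitamins −1 U, essential amino acids −10 U, bulk compounds such as water
and protons −100 U), oxygen limited to (−1,000, 0) U, and reactive-oxygen
uptakes (superoxide, hydrogen peroxide) closed so the network cannot
substitute ROS import for genuine oxygen consumption. A minimal-growth
lower bound (default 0.008 U, a ~88-hour doubling time) stays on the
biomass reaction throughout, ensuring every downstream model supports a
nonzero growth phenotype.

## Profile integration

Screening forces ±10⁻⁴ U through each mapped exchange, per direction, and
keeps only directions for which the model remains feasible; a metabolite
with no catabolic (or anabolic) route is thereby dropped for uptake
(resp. secretion) without discarding the other direction.

Quantitative bounds use a fractional allowance *a* (default 0.2) around
each measured flux *x*. The naive pair (1−a)x, (1+a)x inverts its order
for uptakes (negative x), so the implementation takes the min/max — this
reproduces the documented extreme bounds, e.g. −860 × 1.2 = −1,032 U as a
*lower* bound. Pairs are applied in profile row order; since rollback
outcomes depend on order, the order is deterministic and the full
applied/restored/discarded partition is returned as a ledger. The growth
check after each pair is a plain feasibility test at the standing
minimal-growth bound (no biomass maximization), matching the constraint
that actually persists in the models.

## Exchange-cardinality completion (the core LP)

Candidates are all exchanges absent from the measured set. Each is closed
and replaced by two nonnegative unidirectional components (uptake and
secretion), capped at 2,000 U so the LP is bounded, and the sum of
component fluxes is minimized subject to steady state and the measured
bounds. The one-norm is a relaxation of the support cardinality; it
recovers the true minimum with high probability when the number of
independent constraints is much larger than that minimum, which holds for
genome-scale instances and is *verified* rather than assumed here:

- A component counts as active when its net flux (uptake minus secretion,
  so paired components are never both reported) exceeds 10⁻⁶ U.
- The minimality loop closes all non-active candidates, then closes each
  active exchange in turn and tests feasibility. A removable exchange is
  excluded from the candidate pool and the LP re-run; the loop is capped
  at 10 iterations (each strictly shrinks the pool, and no shipped
  instance needs more than 2).
- `brute_force_min_card` enumerates candidate subsets in increasing size
  (refusing more than 15 candidates) and is used in the test suite as the
  independent oracle; the L1-plus-verification pipeline matches it on
  every shipped instance, including a constructed case where the raw L1
  optimum has cardinality 2 against a true minimum of 1 (a cheap but
  capacity-limited precursor route plus a top-up).
- Determinism: candidates enter the LP in lexicographic id order and the
  GLPK simplex is deterministic, so repeated runs return identical active
  sets.

Pruning removes non-active candidate exchanges outright, then removes
internal reactions that cannot carry |v| ≥ 10⁻⁴ U anywhere in the
feasible space (COBRApy's blocked-reaction FVA). Pruning must preserve
feasibility and the objective optimum to a relative 10⁻⁶, else it aborts —
an overlarge ε is the usual cause.

## Optimization kernel

FBA and FVA run through COBRApy/optlang on GLPK with feasibility and
optimality tolerances of 10⁻⁹. Parsimonious FBA fixes the stage-1 linear
optimum within a relative tolerance of 10⁻⁶ (a hard equality makes the QP
numerically brittle) and minimizes ½‖v‖² over *internal* reactions only —
penalizing exchanges would distort the boundary fluxes the profile pins
down. The QP is solved with SciPy's `trust-constr` (sparse stoichiometric
constraints, constant diagonal Hessian), started from the stage-1 vertex;
the objective is strictly convex on the internal fluxes, so the internal
solution is unique, and symmetric parallel routes split exactly evenly.

Flux sampling is COBRApy's artificial-centering hit-and-run with a
required seed; the polytope must be bounded (checked before sampling) and
every retained point satisfies the FVA envelope.

## Phenotyping

Flux splits pool the target species across compartments. For each
reaction the pooled production `Σᵢ Sᵢⱼ·vⱼ` is kept when positive; boundary
reactions and transport-like reactions — any reaction in which the pooled
species appears with both signs, such as an ATP/ADP antiporter — are
excluded before summation, and an explicit exclusion list can extend
this. Shares are normalized to 1; zero total production is flagged, not
silently zeroed. The ATP yield divides pooled ATP production by the
glucose uptake magnitude and is an *error* when glucose uptake is zero.

The energy class is decided by the identity of the top ATP producer
(phosphoglycerate-kinase-type → glycolytic, ATP-synthase-type → OxPhos);
the yield boundaries 4.21 / 7.26 are descriptive statistics of where that
switch falls, not the classifier. Subtypes I–VIII are looked up from the
(ATP, NADH, NADPH, FADH2) major-producer tuple in a configurable table;
the shipped defaults use conventional BiGG-style ids and any tuple
without a match is returned as "unclassified" with the tuple preserved.

The glucose-only ceiling check closes the uptake of every
carbon-containing exchange metabolite except glucose (by formula), opens
all exchange upper bounds, drops positive internal lower bounds (a forced
biomass drain would siphon ATP), fixes glucose uptake to 1 U and
maximizes ATP hydrolysis.

## Perturbation scans

Phase planes clamp two exchanges (lb = ub) per grid point and maximize
biomass; default ranges are oxygen 0→−1,000, glucose 0→−1,080, glutamine
0→−400, lactate 1,620→0 U at step 20 (51 points on the oxygen axis).
Infeasible points carry a NaN and a mask flag.

The oxotype rule: sweep the oxygen clamp, record the feasible window of
uptake magnitudes at the standing minimal-growth bound. Feasible across
the whole scan → *indifferent*; touching only the zero-uptake end →
*low*; touching only the high end → *high*. A window touching neither end
is resolved by comparing its midpoint with a configurable split
(default: scan midpoint). The published distinction was made visually
from solution-space shapes, so this interval rule is an explicit
interpretation, kept configurable.

Gene knockouts collapse transcript ids (trailing ``.N`` stripped,
overridable) and disable all transcripts of a base gene at once; reactions
whose GPR evaluates false are closed and biomass re-maximized. Classes are
relative to each model's own wild-type maximum: terminated < 5%, reduced
5–95%, unchanged ≥ 95%; an infeasible knockout counts as zero growth.
Reaction essentiality closes reactions one at a time under the same
thresholds.

Reductive carboxylation: FVA over the whole feasible space (minimal-growth
bound active, no objective optimality requirement) on isocitrate
dehydrogenase and aconitase, forward defined as oxidative; max < 0 ⇒
obligate reverse, min > 0 ⇒ forward only, otherwise optional, with an
optional oxygen clamp (e.g. lb = ub = −100 U) applied first to emulate
hypoxia or measured oxygen minima.

## Toy fixtures

The generators emulate the *structure* of the real problem — measured
exchanges, withheld-but-required exchanges, decoys, redox coupling,
oxygen dependence — at a scale where every answer follows from
stoichiometric bookkeeping:

- Energy fixtures use lumped textbook stoichiometry: glycolysis nets
  2 ATP + 2 NADH per glucose, one TCA turn per acetyl-CoA gives
  1 ATP + 3 NADH + 1 FADH2, respiration at P/O 2.5 / 1.5. Full oxidation
  therefore yields 2 + 2 + 10×2.5 + 2×1.5 = 32 ATP per glucose and the
  fermentative route 2; the 36/38-ATP conventions are deliberately not
  used. Internal reactions are audited for elemental-carbon balance
  (carbon-only formulas; reactions touching the lumped biomass species are
  exempt since biomass composition is unspecified).
- Completion fixtures withhold exactly the biomass-required exchanges, so
  the minimal completion is unique by construction and is re-derived by
  enumeration in the tests rather than trusted. Biomass drains are
  deliberately multi-metabolite so they never masquerade as boundary
  reactions and contaminate candidate sets.
- Synthetic profiles perturb a jointly feasible reference flux
  multiplicatively by 1 + U(−noise, +noise). Integration with allowance
  *a* is guaranteed to apply every pair when noise ≤ a/(1+a) (≈ 0.167 for
  a = 0.2): only then does the perturbed interval still contain the
  reference value. The default noise is 0.1, inside the guarantee; a
  deliberately corrupted entry exercises rollback.

What the toys do **not** emulate: genome-scale redundancy (thousands of
reactions, alternate pathways, compartmental duplicates), complex GPRs,
thermodynamically infeasible loops at scale, measurement-platform bias,
or medium-composition uncertainty. Passing tests therefore demonstrate
algorithmic correctness on networks with known answers, not biological
accuracy of any particular genome-scale reconstruction.

## Problem sizes and numerical choices

The shipped analyses run on networks of ≤ ~25 reactions, candidate sets of
≤ 8 for enumeration (the oracle refuses > 15), sampling chains of a few
hundred points, and phase-plane grids of at most a few hundred LPs — sizes
chosen so every property can be verified exhaustively and the whole suite
solves thousands of small LPs in seconds. Key constants: screening flux
10⁻⁴ U, active-component threshold 10⁻⁶ U, candidate cap 2,000 U,
blocked-reaction ε 10⁻⁴ U, pruning optimum preservation 10⁻⁶ relative,
LP tolerances 10⁻⁹, QP objective slack 10⁻⁶ relative.

## Known limitations

- The L1 relaxation plus one-at-a-time removal verification certifies an
  *irreducible* set; a strictly smaller set that requires swapping two or
  more exchanges simultaneously would not be detected. The enumeration
  oracle exists precisely to bound this risk on test instances.
- The oxotype boundary and the subtype table are configuration, not
  ground truth; defaults are documented interpretations.
- The hit-and-run sampler is not a mixing-time-certified uniform sampler;
  marginal checks in the tests use conservative effective-sample-size
  corrections.
- `trust-constr` QP accuracy is ~10⁻⁸ on these problem sizes; parsimonious
  flux comparisons should use tolerances no tighter than 10⁻⁶.
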