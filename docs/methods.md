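# Methods

## Model and assumptions

`transflux` predicts a steady-state flux distribution *v* for a genome-scale
metabolic model (stoichiometric matrix *N*, flux bounds *L ≤ v ≤ U*) from
absolute gene-expression data. The working hypothesis is that absolute,
cross-gene-comparable transcript abundances (RPKM or similar) are a usable
proxy for enzymatic capacity *when applied genome-wide and filtered through
the stoichiometric constraints*: individual transcript–flux relationships are
noisy (translation rates, protein stability and enzyme kinetics all
intervene), but requiring mass balance of every metabolite forces the
predicted pattern to be self-consistent, which suppresses much of that noise.
No biomass objective, biomass composition or measured uptake/excretion rate
enters the fit; measured exchange fluxes are reserved for validation.

## GPR mapping

Each reaction's gene association is parsed into a Boolean tree (leaves =
genes, `and` = complex, `or` = isoenzymes; `and` binds tighter than `or`
when parentheses are absent, the COBRA convention). Evaluation against the
expression profile follows two rules:

* **Complex (`and`)**: the assembled complex is limited by its scarcest
  component, so the weighting is the child with the minimal mean, carrying
  that child's standard deviation. When two children tie on the mean, the
  smaller sd is taken — the more confident bound on the complex. (Means
  always permutation-invariant; the sd tie-break makes the full result
  order-independent too.)
* **Isoenzymes (`or`)**: alternative catalysts add capacity; means are
  summed and variances added under an uncorrelated-errors assumption,
  sd = √(Σ sd²).

Missing data propagate structurally: an `or` drops unmeasured children (an
unobserved isoenzyme contributes nothing), an `and` with any unmeasured child
is itself unmeasured (a complex cannot be bounded by an unknown component),
and a reaction whose whole tree is unmeasured — or that has no GPR, such as
exchange, biomass and spontaneous reactions — carries no weighting and never
enters the objective. Promiscuous enzymes contribute their full expression
value to every reaction they catalyse; no partitioning is attempted.

Zero reported sds are floored at `sigma_floor` (default 10⁻⁶ expression
units) so the 1/σ confidence weight stays finite. Raw expression values are
mapped without renormalisation.

## The fit

The objective is the confidence-weighted absolute deviation
Z = Σᵢ (1/σᵢ)|vᵢ − dᵢ|, summed over reactions that are currently
irreversible (known flux direction) and carry data. Each term is linearised
as vᵢ = sᵢdᵢ + dᵢ⁺ − dᵢ⁻ with dᵢ⁺, dᵢ⁻ ≥ 0 and sᵢ ∈ {+1, −1} the committed
direction sign (a backward-only reaction is fitted to −dᵢ: the expression
magnitude applied along its feasible direction). Z is convex, and the
linearised problem is an LP solved with GLPK through optlang; GLPK's simplex
is deterministic for a fixed problem, making results reproducible
bit-for-bit on one platform.

Reversible-reaction directions are assigned iteratively:

1. minimise Z over the current scored set (initially: reactions irreversible
   by their bounds — L ≥ 0 forward, U ≤ 0 backward);
2. run FVA with the extra constraint Z ≤ Z\* + tol; a reversible reaction
   whose range satisfies min ≥ −tol is committed forward (max ≤ tol:
   backward), its opposing bound is clamped to 0, and if it carries data it
   joins the scored set with the committed sign;
3. repeat until no reaction is added. The irreversible set is non-decreasing,
   so the loop terminates; a cap of 100 iterations is a safety net only.

Each cycle re-solves the enlarged problem freely; earlier-iteration Z values
are not retained as constraints. `tol` (default 10⁻⁹, flux units) serves both
as absolute slack on Z ≤ Z\* and as the direction-classification threshold —
pure equality constraints are numerically brittle.

Reactions still reversible at termination never enter Z.

## Geometric centring

The optimal set {N·v = 0, bounds, Z ≤ Z\*} is generally a polytope of
alternate optima. A unique representative is chosen by iterative
range-midpoint projection over the full network: compute per-reaction flux
ranges [aᵢ, bᵢ] by FVA over the current polytope, L1-project the flux vector
onto the midpoint vector (a+b)/2, then tighten each reaction's bounds to the
interval spanned by its projected value and its midpoint. Each pass at least
halves every range, so convergence is geometric; iteration stops when all
ranges are below 10⁻⁶ (max 50 passes, after which the last projection is
returned with a warning). On a box-shaped optimal face this returns the exact
midpoint; on a symmetric futile cycle it returns zero net cycle flux. A
1e−9 margin is added when tightening bounds so solver round-off cannot render
the shrunken polytope empty.

## Units and glucose normalisation

The LP is solved in expression units (dᵢ in RPKM); flux bounds of ±1000 are
effectively non-binding at that scale. Physical units enter only at the end:
the whole vector is multiplied by measured_uptake / |predicted glucose
uptake|, so the reported exchange fluxes are in mmol/h/gDW and glucose uptake
matches the measurement exactly. This makes predictions invariant to a
common rescaling of all expression values (tested), which is why the RPKM
scale itself need not be calibrated to flux units.

The biomass pseudo-reaction has no gene and is therefore unscored; its bounds
stay at the model defaults (neither forced to zero nor maximised). Exchange
bounds are taken from the SBML as-is; no medium constraints are imposed.

## Baselines

* **Standard FBA** maximises the biomass reaction with glucose uptake capped
  at the measured rate, then geometrically centres the biomass-optimal
  polytope (so the prediction is unique; the biomass value is unaffected by
  centring, which is tested).
* **Fitted FBA** keeps biomass maximal and, in a second LP stage, minimises
  the L1 distance between model exchange fluxes and the measured values,
  then centres the remaining degeneracy. It is the best case achievable
  under the growth-maximisation assumption.
* **GIMME** minimises Σ max(0, threshold − dᵢ)|vᵢ| subject to biomass ≥
  fraction × maximum. Defaults: threshold = 25th percentile of the available
  reaction weightings, fraction 0.9; both overridable. |v| is split as
  v⁺ − v⁻.
* **iMAT** classifies weighted reactions into high/low expression by
  quantile (default tertiles) and solves a MILP maximising the count of high
  reactions with |v| ≥ ε (default ε = 1 flux unit) plus low reactions with
  v = 0, using the standard big-M activation constraints and GLPK's
  deterministic branch-and-bound.

Both expression-aware baselines consume the same GPR-mapped weightings as the
main method, so comparisons isolate the algorithm rather than the mapping.
The published comparisons do not disclose the exact GIMME/iMAT settings
behind their tables, so numeric reproduction of those columns is best-effort
by design; the defaults here follow common usage of the original methods.

## Evaluation

Predictions are compared on the exometabolome: measured excretion fluxes
(positive = excretion) mapped to exchange reactions by an explicit
user-supplied table — never name heuristics — and extracted from each
glucose-normalised flux vector. Goodness of fit is R² = 1 − SS_res/SS_tot
about the observed mean, computed on raw (non-log) normalised fluxes: 1 is a
perfect match, 0 is the mean predictor, negative is worse than the mean.
R² of published tables recomputed from their printed (rounded) values can
differ from the printed R² in the second decimal; tests therefore allow
±0.015 where rounded table values are the input.

## Synthetic data

The fixtures module generates everything the pipeline consumes:

* **Random toy networks**: a linear backbone M₀ → … → Mₖ with one nutrient
  and one product exchange (guaranteeing connectivity and feasibility),
  padded with random internal conversions, a chosen fraction reversible, and
  random GPR trees up to a depth cap. Depth-1 trees use one exclusive gene
  per reaction; deeper trees occasionally reuse genes to exercise
  promiscuity. Generation is a pure function of the seed.
* **Planted patterns**: a feasible flux v\* is drawn by maximising a random
  linear objective with the nutrient uptake pinned at 10 flux units, so
  N·v\* = 0 holds to LP precision. Each gene's expression mean is the
  largest |v\*| over its reactions (a promiscuous gene must cover its
  busiest reaction, and the max keeps the min/sum mapping a conservative
  upper bound) plus zero-truncated Gaussian noise; the reported sd is the
  noise width. With exclusive single-gene GPRs and zero noise the mapping
  returns dᵢ = |v\*ᵢ| exactly, making recovery tests sharp (10⁻⁶).
* **Overflow-metabolism toy**: a hand-built, carbon-balanced 17-reaction
  network (glycolysis, high-ATP respiration, fermentation, minor glycerol /
  acetate / lactate / trehalose branches, ATP-expensive biomass) with a
  planted fermentative state at glucose uptake 10. Biomass maximisation on
  this network provably routes all carbon to CO₂, reproducing the
  qualitative contrast between growth-maximising FBA and the
  expression-constrained fit. Expression sds are set to 5% of the mean
  (floored at 0.01), mimicking replicate scatter.

What the fixtures deliberately do not emulate: genome-scale network size and
topology statistics, compartmentalisation, cofactor coupling beyond a single
ATP pool, realistic RPKM dynamic range, or correlated measurement error.
Passing tests therefore demonstrate algorithmic correctness (objective,
direction assignment, centring, normalisation, baselines) — not that
transcript abundance predicts fluxes in any particular real organism or
condition.

## Numerical choices and limitations

* LP/MILP backend: GLPK via optlang; problems are rebuilt per fit stage and
  reused across FVA sweeps (objective swap only).
* Tolerances: fit/FVA slack 10⁻⁹; centring convergence 10⁻⁶, max 50 passes;
  steady-state residual asserted ≤ 10⁻⁶ on all outputs.
* Degenerate inputs: empty scored set returns Z\* = 0 with the zero vector
  when feasible; an all-identical observation vector makes R² undefined and
  raises; zero predicted glucose uptake cannot be normalised and raises.
* The FVA sweep is O(2 × reactions) LPs per iteration and the dominant cost;
  the implementation targets models up to genome scale but the bundled test
  problems are deliberately small (≤ 20 reactions) so the whole suite runs
  in seconds.
* No thermodynamic loop-law enforcement: futile cycles are handled only in
  so far as centring zeroes symmetric ones. No proteomics integration, no
  model gap-filling, no medium inference.
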