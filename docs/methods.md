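# Methods

## Model and procedure

A metabolic network is a stoichiometric matrix *S* (rows: internal
metabolites; boundary species are dropped) with flux bounds
`lb ≤ v ≤ ub`. Steady state `S v = 0` is imposed on internal metabolites
only. Exchange reactions are written secretion-positive, so an uptake cap
*U* is the exchange lower bound −*U*; desk-scale fixtures that model pure
sources (flux into the network with bounds `[0, c]`) are equivalent under a
sign flip and are kept in the orientation that makes their printed flux
values positive.

The design procedure searches the (growth rate GR, production rate PR)
rectangle `[0, TMGR] × [0, TMPR]`:

* **TMGR** — LP maximum of the biomass flux on the prepared model.
* **TMPR** — LP maximum of the target flux *with the biomass lower bound
  relaxed to 0*. The production optimum may sit at zero growth, and the
  first LP is allowed to explore sub-viable growth; only the final design
  must grow.
* The rectangle is tiled by `p_inv²` cells,
  `cell(i, j) = [TMGR·P·i, TMGR·P·(i+1)] × [TMPR·P·j, TMPR·P·(j+1)]` with
  `P = 1/p_inv` and `i, j = 0 … p_inv−1`. Zero-based indexing makes the
  cells tile the rectangle exactly; a one-based range with the `(i+1)`
  factor would shift the top row and column past the theoretical maxima
  and leave them permanently infeasible.
* **First LP** (per cell): minimize `Σⱼ |vⱼ|` over all reactions subject to
  the cell's GR and PR boxes. The absolute values are handled by the exact
  split `v = v⁺ − v⁻`, `v⁺, v⁻ ≥ 0`, minimizing `Σ(v⁺ + v⁻)`; at any
  optimum one part of each pair is zero, so the objective equals the total
  absolute flux. Exchanges are included in the sum ("all fluxes").
* **R_not_used**: reactions with `|v| < zero_tol` in the first-LP solution,
  excluding protected reactions. Protected are biomass, target and
  maintenance (removing them voids the design) and, by default, all
  exchange reactions — the medium, not the designed network, decides what
  crosses the boundary.
* **Second LP** (per cell): maximize growth with `R_not_used` fixed to zero
  and the cell boxes dropped. If the LP is feasible, the cell's production
  rate is the flux-variability value of the target at growth fixed to its
  maximum — the FVA *minimum* by default (the guaranteed, pessimistic
  rate; `criterion="fva_max"` gives the optimistic one). The score is
  stored when maximal growth reaches `min_growth`, else 0. (A literal
  reading of the storage rule gates on PR instead of GR; it contradicts
  the worked knockout example that discards a zero-growth design, so the
  growth gate is the default and `literal_pr_gate=True` restores the
  literal rule.)
* The winning cell is the lexicographically smallest `(i, j)` attaining the
  maximal stored score (determinism under ties). Its knockout set is
  re-evaluated once more to report both FVA bounds of the target at fixed
  maximal growth; a winning design whose maximal growth misses the
  viability gate reports zero production, consistent with its zero score.

Infeasibility is a routine outcome (cells below a forced influx, for
example, admit no flux at all) and is represented as a status value, never
an exception, except in flux variability analysis whose return type cannot
express emptiness.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `p_inv` | 25 | — | grid divisions per axis; production ability saturates near 25 on genome-scale screens |
| `zero_tol` | 1e−5 | flux | first-LP flux below which a reaction is "not used" |
| `producible_tol` | 1e−5 | flux | designed PR at or above which a target is producible |
| `glc_uptake` | 10 | mmol/gDW/h | glucose uptake cap (sole carbon source) |
| `o2_uptake` | 5 | mmol/gDW/h | oxygen uptake cap (microaerobic) |
| `atp_maintenance` | 8.39 | mmol/gDW/h | non-growth-associated maintenance, enforced as ATPM lower bound |
| `min_growth` | 0.05 | 1/h | viability gate on the designed network's maximal growth |

Medium preparation closes every other carbon-containing exchange to uptake
(carbon detected from metabolite formulas), leaving freely diffusing
externals (CO₂, bicarbonate by default) and non-carbon exchanges at the
file's own bounds; reaction-id dialects for glucose/oxygen/ATPM
(`EX_glc__D_e` vs `EX_glc(e)` etc.) are auto-detected and overridable.

## LP backend and numerics

cobrapy with optlang/GLPK performs all solves, single-threaded, feasibility
tolerance 1e−9. All LPs run inside cobrapy history contexts on one model
instance, so repeated cell evaluations do not copy the model and inputs are
never mutated. Growth is fixed at its maximum for FVA via
`v_growth ≥ g* − 1e−9·max(1, |g*|)`; tests compare equalities at 1e−6.
Alternate LP optima exist in principle (the first LP's argmin need not be
unique even when its value is); tests therefore pin only solver-independent
quantities — objective values, forced fluxes, infeasibility patterns — and
the tie-break rules above make reported designs deterministic for a fixed
solver.

## Fixtures and oracles

**Toy network.** Eight reactions, three metabolites, every quantitative
claim checkable by hand: TMGR = 10, TMPR = 8 (bottlenecked at 5 + 3 by the
two routes into the target's precursor), knocking out R3 yields the unique
growth-coupled optimum (GR, PR) = (1, 4). Upper bounds not determined by
the worked constraints (R3, R6, R7) are set to 10, the tightest value
consistent with the maximal-growth flow. The toy is also the procedure's
documented sharp case: in every grid cell the parsimonious flux routes
growth through R3 (e.g. at the exact point (GR, PR) = (1, 4) the R3 route
costs total flux 15 against 16 for the loop route), so R3 never enters
`R_not_used` and every cell stores 0 while the exhaustive optimum is 4.
The grid heuristic is not exact, and this network realizes the gap at desk
scale.

**Random networks.** Seeded generator: one throttleable source and one
*constant* source (lower bound = upper bound ∈ {1, 2, 3}) feeding M1, a
conversion chain M1 → … → Mn guaranteeing biomass and target reachability,
drains for biomass and target, plus random conversions with integer
coefficients in {1, 2} and integer capacities in [1, 10]. The constant
source plays the role forced influxes (maintenance, constitutive uptake)
play in real models: without a forced flux, maximal-growth solutions can
always throttle intake and no knockout forces secretion, making every
design score zero. Integer data keep LP vertices rational and tests
solver-stable. The generator does not emulate cofactor pools, reaction
reversibility, gene–reaction coupling or realistic network breadth, so
passing ensemble tests demonstrate algorithmic correctness (dominance,
invariances, trends) rather than biological fidelity.

**Oracles.** Two exhaustive references validate the implementation on small
networks. (1) Knockout enumeration: every subset of unprotected reactions
is scored by the same growth-then-FVA evaluation; the grid design must
never exceed its optimum (verified on the toy and a 20-seed ensemble of
≤ 12-reaction networks). (2) L1 enumeration: the parsimonious LP's optimum
is checked against a solver-free enumeration of candidate basic solutions —
every choice of `n − rank(S)` fluxes fixed at a bound (or at 0 where a
reversible flux kinks the objective) yields a candidate by solving the
remaining linear system; the minimum over feasible candidates is the exact
L1 minimum for bounded polytopes. Both are exponential and guarded
(≤ 20 unprotected reactions; ≲ 10 reactions respectively).

## Problem sizes

The test suite and examples run entirely on the toy network and random
ensembles of 8–12 reactions (3–4 internal metabolites): grids up to 25×25,
knockout enumerations up to 2⁹ subsets, L1 enumerations up to ~2·10³
candidate bases. These sizes were chosen so every oracle comparison is
exact and the full suite completes in well under a minute. Genome-scale
screens (thousands of reactions, dozens of targets) use the identical code
path via the CLI batch runner but require an externally obtained model
file (e.g. an *E. coli* reconstruction in SBML) and hours of LP solving;
their producibility counts are additionally sensitive to alternate LP
optima across solver versions by a few targets, and are not part of the
test suite.

## Known limitations

* Reaction-level designs only: no gene–protein–reaction mapping, so a
  knockout set need not be implementable gene-wise.
* No reaction additions beyond the target's diffusion transport; no
  heterologous pathways.
* The grid heuristic is not exact (see the toy sharp case); it trades
  optimality for `p_inv²` LP pairs of work.
* Single-objective, single-target designs; no Pareto exploration of the
  growth/production trade-off beyond the grid itself.
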