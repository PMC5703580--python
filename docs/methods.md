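# Methods

## Model and assumptions

The culture is a homogeneous cell population in a well-mixed tank with
constant medium exchange. Two balance equations govern the macroscopic
state: cell density grows at the effective rate μ and is removed at φD
(φ < 1 models a cell-retention device; only the bled fraction leaves), and
each culture concentration changes by cellular exchange −u_i X and dilution
−(s_i − c_i) D. Gas-phase transfer (oxygen limitation) is outside the
model's scope: it applies only while oxygen exchange is not limiting.

Intracellular metabolism is assumed to be at quasi-steady state and
growth-maximizing. The LP over split fluxes r_k = r_k⁺ − r_k⁻ maximizes the
biomass rate z subject to:

- metabolite balances Σ_k N_ik r_k + u_i = e_i + y_i z, with constant
  maintenance drains e_i (mmol/gDW/h) and biomass composition y_i
  (mmol/gDW); u_i exists only for external metabolites;
- a molecular-crowding budget Σ_k (α_k⁺ r_k⁺ + α_k⁻ r_k⁻) ≤ C modeling the
  cell's finite enzymatic capacity (α in cost units per flux, C in cost
  units);
- reversibility bounds lb_k ≤ r_k ≤ ub_k;
- exchange bounds −L_i ≤ u_i ≤ min{V_i, c_i/ξ}: V_i is the
  transporter-limited maximum uptake, c_i/ξ the steady-state supply limit,
  L_i ∈ {0, ∞} the secretion permission.

Among z-optimal vertices the minimum-cost one is selected: a second LP
re-solves with z pinned to the stage-one optimum (exactly; if the exact pin
is numerically infeasible, a relative slack of 1e-9 is allowed) and the
cost row as objective. This removes most alternate-optima degeneracy; no
further flux-variability analysis is attempted.

Toxic byproducts feed back on growth through one of two mechanisms: a
linear death rate μ = z − Σ_j τ_j s_j (τ in 1/h/mM; μ < 0 is meaningful
decay) or a multiplicative yield factor μ = z · Π_j (1 + s_j/K_j)⁻¹ (K_j in
mM, the half-inhibition concentrations). Both accept an arbitrary set of
metabolites.

## Steady states as functions of ξ

Every steady state is parameterized by ξ = X/D: solve the LP at ξ, then
s_i* = c_i − u_i* ξ, μ* from the toxicity feedback at s*, and
D* = μ*/φ, X* = ξ μ*/φ. Consequences used throughout:

- D_max = D*(0) is the washout rate; the ξ = 0 limit is evaluated with the
  bound convention u_i ≤ V_i when c_i > 0 and u_i ≤ 0 when c_i = 0
  (0/0 := 0 — a metabolite absent from the feed can never be consumed).
  Secreted byproducts are infinitely diluted at ξ → 0, so toxicity does not
  affect D_max. An infinite c_i (water, protons, oxygen) leaves V_i as the
  only bound.
- ξ_m, the medium depth, is the feasibility edge of the scan, found by
  doubling-then-bisection on LP feasibility to relative width 1e-6; if the
  model is still feasible at the configured upper probe (e.g. no
  maintenance), ξ_m = ∞ is reported.
- z*(ξ) is non-increasing (the feasible set shrinks with ξ), so any
  increase of μ*(ξ) — the fingerprint of multistability — must come from
  the toxicity feedback.
- u*, s*, μ* are independent of φ and (φD*, φX*) is a φ-invariant curve;
  the chemostat (φ = 1) therefore characterizes every perfusion system.

The scan grid is geometric from ξ_m·1e-4 to ξ_m plus the ξ = 0 limit point
(n = 80–120 by default); after a first pass, points are inserted around
detected phase boundaries and sign changes of dμ*/dξ. Points with μ* < 0
are kept and flagged — they correspond to no realizable steady state with
X > 0.

A phase signature per point records the secreted metabolites
(u_i < −ε_u) and the limiting nutrients (u_i within ε_u of the supply
bound c_i/ξ when that side of the bound is active), with the scale-aware
zero threshold ε_u = 1e-6 × max finite V. How "limiting" should be
thresholded is not canonical; this rule is the package's choice. Phase
boundaries between grid points with different signatures are localized by
bisection (re-solving the LP) to relative ξ-precision 1e-6, independent of
the grid.

## Stability and bifurcation

A steady state is unstable exactly where μ*(ξ) is locally increasing, and
stable otherwise; plateaus (|slope| ≤ ε_slope) count as stable, with the
scale-aware ε_slope = 1e-4 × μ*(0)/ξ_m. The center-manifold critical case
is not re-derived; its conclusion (plateau → stable) is adopted as an
invariant. Flags are φ-independent.

Folds of the X-vs-D diagram are sign changes of the discrete derivative of
D*(ξ), refined by bounded scalar search on μ* to relative ξ-precision 1e-5.
Branches are maximal ξ-runs of constant stability class (each branch is a
graph over ξ, so no continuation method is needed); multistable windows are
the D-intervals between fold D-values covered by more than one branch. The
washout branch (X = 0, any D; stable for D > D_max) is metadata, never
merged into the X > 0 branches.

As an independent cross-check, the Jacobian of the balance equations is
computed at a steady state by central differences (relative step 1e-6) and
its eigenvalues examined. Growth-limiting nutrients (s* = 0) sit on a
constraint boundary where the raw vector field is one-sided; they are
eliminated onto the slow manifold via u_i = c_i D/X, leaving a smooth
reduced system in X and the remaining concentrations. The washout
equilibrium is handled in closed form (rates μ(0) − φD and −D). On the
solvable network this eigenvalue test agrees with the μ*-slope
classification at every grid point away from the folds, where the leading
eigenvalue crosses zero.

## Dynamics

The integrator is an explicit adaptive Heun (Euler predictor, trapezoidal
corrector) with step rejection: the LP solution jumps between vertices as
bounds activate, so the right-hand side is only piecewise smooth and a
high-order smooth method would buy nothing. Steps halve on
negative-concentration overshoot or when the Euler/Heun discrepancy exceeds
a relative tolerance (1e-3 against a concentration scale set by the feed),
and grow by 1.3× after acceptance up to the output interval.

The steady-state supply bound c_i/ξ is an identity only at equilibrium.
During transients the uptake is capped by availability over the current
step h: u_i ≤ (s_i (1 − D h) + c_i D h)/(X h), the uptake that would drain
the metabolite exactly to zero in one explicit step counting feed inflow
and dilution outflow. As s_i → 0 this tends to the steady supply bound
c_i D/X, which makes substrate-limited quasi-steady operation smooth
instead of chattering; for s_i large it is inactive. An LP that goes
infeasible mid-run (maintenance unmet) switches to a cell-death branch —
z = 0, μ from the death-rate term or 0 under the yield-factor mechanism,
u = 0 — and is logged as an event rather than aborting. Other events:
washout (X below 1e-12 of the inoculum) and nutrient exhaustion (a fed
metabolite dropping below 1e-4 of its feed concentration — an absolute
zero is never reached once uptake stops).

The integrator is deterministic; no random numbers are used anywhere in
the library (fixture generation takes an explicit seed).

## The solvable test network

Four metabolites (substrate S and waste W external, intermediate P and
energy E internal) and three reactions: a fermentation-like step
S → P + N_F·E, a respiration-like step P → N_R·E capped at r_max, and waste
export P → W. Growth maximization saturates the uptake and respiration
bounds, so u = min{V, c/ξ}, r = min{u, r_max}, v = r − u,
z = (N_F u + N_R r − e)/y, s* = c − min{Vξ, c},
w* = max{0, c − s* − r_max ξ}, μ* = z − τw*, with thresholds ξ_0 = c/V
(nutrient excess ends), ξ_sec = c/r_max (secretion stops) and
ξ_m = c(N_F + N_R)/e (maintenance fails). Default constants: N_F = 2,
N_R = 38 (ATP yields of glycolysis and respiration), e = 1.0625 mmol/gDW/h,
r_max = 0.45 and V = 0.5 mmol/gDW/h, y = 348 mmol/gDW, τ = 0.0022 1/h/mM,
c = 15 mM, 0.9 ng dry weight per cell; these give a maximum growth rate of
1.175/day and slope signs of μ* that are negative on (0, ξ_0), positive on
(ξ_0, ξ_sec) and negative beyond ξ_sec — one multistable window bounded by
two folds, computed here as D ∈ [1.0958, 1.1681]/day.

In the generic encoding the respiratory cap is realized through the
crowding budget (cost C/r_max on respiration, everything else free), so the
ordinary pipeline exercises the cost constraint; an alternative hard-bound
encoding is kept for differential testing. A window-interior dilution rate
supports three coexisting states, and the dynamic protocols reproduce the
hysteresis: a constant-D start-up lands on the low-density overflow branch
while holding a low D before ramping lands on the high-density respiratory
branch. With these constants the growth-rate surplus at low D is small
(~0.2/day), so the hold phase of the ramp protocol must be several hundred
hours for the culture to grow up from a small inoculum before the ramp —
protocol shapes are qualitative, their time axes model-dependent.

## Synthetic fixtures

The fixture generator emulates the structural features the pipeline relies
on — irreversible single-substrate uptake, yield differences between
routes, a crowding-limited high-yield route, maintenance, optional linear
toxicity — in three topologies (the solvable network itself, linear chains
with a closed-form z*(ξ), and randomized overflow networks drawn under the
same ordering assumptions). They are deliberately small and noiseless:
passing tests demonstrate correctness of the machinery, not that a
genome-scale reconstruction with curated enzyme costs would reproduce any
particular culture's data. Real networks add alternate optima at a scale
the lexicographic rule only partially resolves, uncertain cost and kinetic
parameters, and metabolites (gases, protons) whose handling is a modeling
decision.

## Numerical choices

- LP front-end: scipy's HiGHS `linprog` behind a minimal solve contract;
  constraint-residual tolerance 1e-6 (absolute, model units) in
  validation. The LP tolerance itself is the solver's default.
- Internal units: h, mM, mmol/gDW/h, gDW/L; days and cell counts only at
  the I/O surface (dry weight per cell configurable: 0.9 ng default,
  350 pg for CHO).
- Files: COBRA JSON / SBML L3 FBC for the network; one tabular dialect
  (TSV, `.` decimals, `inf` literals) for all sidecars including the
  toxicity spec; floats written with 17 significant digits so curves
  round-trip bitwise. Missing cost entries default to the median of
  provided values; missing uptake entries to V = ∞ (or V_glc/10 for amino
  acids when that convention is enabled); infinite bounds are stored as
  ±1e6 in model files.
- Degenerate inputs: an infeasible model at ξ = 0 signals a medium that
  cannot sustain maintenance at all (medium depth ≤ 0) and raises; an
  unbounded LP names the unbounded exchanges and raises — it indicates a
  missing bound or cost, never a meaningful optimum.

## Known limitations

- No kinetic rate laws, regulation or thermodynamic ΔG bounds beyond flux
  signs; no oxygen/gas-phase transfer; no stochastic population effects.
- The availability-capped transient uptake makes trajectories near s = 0
  step-size dependent at the 1e-3 relative level (the error controller's
  tolerance); steady states are unaffected.
- Stability classification is slope-based on a finite grid: within one
  grid-refinement neighborhood of a fold the flag is ambiguous, as the
  leading eigenvalue vanishes there.
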