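# Methods

## Model and assumptions

The package models erythropoiesis as three well-mixed compartments: early
precursors `x1` (CFU-E and early erythroblasts, strongly EPO-responsive),
late precursors `x2` (late erythroblasts and reticulocytes), and the
circulating erythrocyte mass `x3` in grams of hemoglobin. EPO itself is
not a state; its negative feedback on early-precursor proliferation is
folded into `Fb(x3) = gamma * (1 - x3/B)`, which vanishes at the healthy
base value `B` and becomes suppressive above it. The model assumes the
fractional blood loss stays moderate: emergency responses such as
stress-reticulocyte release are outside its validity range, as are
EPO-modifying drugs and chemotherapy.

Polycythemia vera enters through a single burden parameter
`lambda_pv ∈ [0, 1]`: that fraction of the CFU-E pool proliferates at a
fixed rate `gamma_star` independent of EPO, the remainder behaves
normally. Transition and clearance rates are assumed unchanged by the
disease; in particular the erythrocyte lifespan `1/alpha` is kept at its
healthy value although it may in reality shorten with disease
progression.

The diseased steady state is available in closed form. Writing
`r = B_PV/B`, zeroing the dynamics gives the quadratic
`(1-λ)γ r² + (βk₁ - (1-λ)γ - λγ*) r - βk₁ = 0`, whose positive root is
taken; at `λ = 1` the feedback is fully bypassed and
`r = βk₁/(βk₁ - γ*)`, which exists only when `βk₁ > γ*` (otherwise the
affected pool grows without bound and the code raises). With the default
`γ* = β/10` and `k₁ = 1/8` the amplification is confined to `[1, 5]` and
is continuous and non-decreasing in the burden. For `q > 0` the root is
evaluated in the rationalized form `d/(q + sqrt(q² + d))` to avoid
cancellation as `λ → 1`. Approach to the steady state is a damped
oscillation — the precursor pools transiently overshoot their
fixed-point values whenever `x3` is held below `B_PV` — with overshoot in
`x3` on the order of 0.1–0.2%.

A phlebotomy of volume `v_max` (default 500 ml) removes the fraction
`v_max/v_pat` of `x3` instantaneously; bone-marrow precursors are not
withdrawn by venesection. In discretized form a treatment at grid index
`i` is applied after the integration step arriving at `i`. The continuous
(relaxed) counterpart scales the maximal withdrawal *rate*
`v_max/v_pat · x3` per day by a control `u(t) ∈ [0, 1]`.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `k1`, `k2` | precursor maturation rates | 1/day | 1/8, 1/6 |
| `alpha` | erythrocyte clearance (120-day lifespan) | 1/day | 1/120 |
| `beta` | EPO-independent proliferation factor | – | subject-specific |
| `gamma` | EPO-dependent proliferation factor | 1/day | subject-specific |
| `gamma_star` | growth rate of PV-affected cells | 1/day | `beta/10` |
| `lambda_pv` | affected CFU-E fraction | – | subject-specific |
| `B` | healthy steady-state erythrocyte mass | g | subject-specific |
| `V_pat` | total blood volume | ml | subject-specific |
| `V_max` | phlebotomy volume | ml | 500 |
| `dt` | integrator step | day | 1/6 |
| `X3_up`, `X3_lo` | safety corridor for `x3` | g | `1.1·B`, `0.85·B` |
| `i_dwell` | minimal spacing of bleeds | grid steps | one day |

The safety-bound defaults are a repository choice (they are inputs, not
biology): one standard 500 ml bleed at a typical 5.5 l blood volume
removes about 9% of `x3`, so a withdrawal triggered at `1.1·B` lands
comfortably above `0.85·B`. All computation is done numerically in
(day, gram, ml); unit annotations elsewhere are documentation only.

## Integration

A hand-rolled classic fixed-step RK4 is used rather than an adaptive
library integrator because every scheduler needs the same primitive:
deterministic stepping on the calendar grid composed with instantaneous
multiplicative treatment events and state-feedback controls, plus (for
the NLP) exact derivatives of the *discrete* scheme. Order ≥ 3.8 is
verified empirically against a `dt/100` reference. The default step of
1/6 day keeps event-timing error below the scale any reported metric
resolves; refill times are linearly interpolated at the crossing step.
Refill-time differences below one step are reported as zero (deadband) —
sub-step deviations carry no information.

## Estimation

`TotalHbModel` minimizes

    1/2 Σ (η_i − x3(t_i))²/σ_i² + Σ_j ((p_j − p_j^prior)/p_j^prior)²

over `p = (beta, gamma, lambda_pv, x1_0, x2_0)`, simulating from
`x(0) = (x1_0, x2_0, η_0)` with the known phlebotomy dates applied as
events. The base value `B` is not fitted; it is the mean of tHb samples
taken at hematocrit ≤ 45%. Optimization is bound-constrained L-BFGS-B in
prior-scaled units with five seeded multistarts; simulation blow-ups are
penalized finitely so line searches can back off. The lower bound 0.05 on
`beta` and `gamma` makes degenerate fits detectable — fits pinned there
signal that the data cannot separate the proliferation terms, which does
occur on noisy series. Treatment times are snapped to the *next*
simulation grid point so a bleed can never move ahead of a measurement
taken just before it.

The fit surface has a pronounced ridge: `beta`, `gamma` and `lambda_pv`
trade off against each other, and on noiseless data the truth is
recovered to better than 1% while at realistic noise the regularization
is what keeps estimates identifiable at all. Under the packaged recovery
experiment (weekly sampling for one year, noise 1% of `B`, priors
displaced +25%), the median absolute error of `lambda_pv` over twenty
replicates measures ≈ 0.06 — the global optimum of the prescribed
objective genuinely sits that far from the truth for some noise draws
(verified by descending from the truth itself), occasionally with `gamma`
at its lower bound. Weekly tHb at 1% noise therefore pins the PV burden
to roughly ±0.1, not better; denser sampling or deeper excursions below
the bound would be needed for tighter recovery.

## Schedulers

**Heuristic (H/HC).** Forward simulation; bleed at the first grid point
where `x3` crosses `X3_up` if that index is admissible and the dwell time
has passed, otherwise shift the bleed to the latest earlier unused
admissible index (dwell-compatible with every placed bleed) and
re-simulate from there. Each admissible index hosts at most one bleed; if
the same crossing re-triggers without progress the instance is declared
infeasible (this also guards the pseudocode's potential infinite loop).
The lower bound is not used while planning — crossings of it are detected
afterwards and reported as infeasibility.

**Relaxed optimal control.** The minimum-withdrawal continuous problem
has bang-path structure: `u = 0` off the bound and, on it, the path
control `u_path = β(k₂x₂ − αX3_up)·V_pat/(V_max·X3_up)` that zeroes the
erythrocyte balance. Two routes are provided. The closed-form feedback
law integrates cheaply on block-free calendars and raises when
`u_path > 1` would be required (withdrawal capacity insufficient — in
that regime daily bleeding cannot hold the bound either). The NLP route
discretizes one control per controllable day (zero on blocked days),
propagates exact forward sensitivities of the RK4 map, and solves with
SLSQP under per-day state constraints (tolerance `1e-6·B`); because the
constraints span blocked windows it withdraws pre-emptively before a
closure. The two routes agree in objective to well under 0.5% on
block-free calendars.

**Sum-up rounding (SUR).** The relaxed control is aggregated into per-day
withdrawal mass measured in days of full-rate withdrawal — one binary
phlebotomy is worth exactly one unit, since a bleed removes what the
maximal continuous rate removes in one day — and the textbook recursion
places a treatment at a day's slot when the accumulated mass minus the
placed treatments reaches the threshold. The default threshold is a small
ε (treat as soon as any mass accrues, since on the bound treatment cannot
wait); the textbook 1/2 is available. SUR ignores the state entirely:
its schedules save treatments relative to the heuristic but can violate
the upper bound for tens of days a year, and across the cohort the
violation days grow with the treatments saved (positive regression
slope). It should only be used with tightened bounds.

**Branch-and-bound CIA.** Branches forward in time over the admissible
indices; node cost is the running maximum, at opportunity boundaries, of
the accumulated deviation between relaxed mass and placed treatments
(same day units as SUR). The maximum never decreases along a path, so it
bounds every descendant; each node's state is forward-integrated and a
branch is pruned the moment `x3` leaves the safety corridor — the upper
bound at a decision point is judged *after* that point's treatment
decision, mirroring the simulation's event ordering. Children are
explored SUR-choice-first so good incumbents appear early; an iteration
cap returns the incumbent or reports no solution.

**Fixed-count search.** Starting from the constrained-heuristic count,
all dwell-respecting placements of exactly `u_sum` bleeds are enumerated
depth-first with the same feasibility pruning, keeping the placement
maximizing the refill time `T_f` (first post-horizon time `x3` reaches
`X3_up` again, integrating untreated, capped at 730 days); `u_sum` is
decremented while any feasible placement exists. Enumeration is guarded
to ≤ 25 admissible points and is anytime-correct under a node cap. On
instances small enough for brute force it is exact by construction and
verified against full enumeration.

**Dynamic programming.** The state space is discretized on a regular
3-D grid; the one-stage transition of every grid state under both
controls is tabulated once per distinct stage gap (the dynamics are
time-invariant) by vectorized RK4, and endpoints are rounded to the grid
as `i* = floor((x − min)/Δx + o + 0.5)`. The offset `o` shifts rounding
towards *higher* states, so the planner overestimates the erythrocyte
mass and treats earlier: `o = 0.4` is conservative (near-zero violations,
more treatments), `o = 0.0` commercial rounding (occasionally saves
treatments at the price of small violations). Cost-to-go (stage cost =
treatment indicator, infinite for states outside the corridor or the
grid) is computed backwards; ties prefer not treating. Default grid
ranges come from a pilot unconstrained-heuristic trajectory with 25%
margins — fixed-point-based boxes clip the reachable region because of
the precursor overshoot noted above — and the `x3` range spans the whole
corridor. The planner sees the bounds only at stage points on the rounded
grid, so extracted schedules can violate the true bounds slightly on
exact re-simulation; violations are always measured on re-simulation and
never hidden. A memory estimate is checked against a configurable cap
(default 2 GiB) before tabulation. Production-quality grids use 400
points per state; tests and cohort studies use 30–48.

## Synthetic data and what the tests show

The virtual cohort starts from 28 packaged healthy-subject parameter sets
and draws `lambda_pv ~ U(0,1)`, accepting a draw iff the unconstrained
heuristic implies 1–26 bleeds in 365 days under the default bounds —
sick enough to need treatment, not so sick that chemotherapy would be
chosen. Five accepted draws per subject give 140 configurations; a
10,000-draw limit guards non-termination. Synthetic tHb series add
i.i.d. Gaussian noise to simulated trajectories and carry their known
noise level as the per-point σ (unit σ when noiseless). Real clinical
series differ in ways the generator does not emulate: plasma-volume
fluctuations feeding through the blood counts, irregular sampling, drift
of patient parameters over the years, and treatment volumes that are not
exactly 500 ml. Passing tests therefore demonstrate correctness of the
algorithms and internal consistency of the model, not clinical validity.

Cohort-level experiments are run at sizes chosen to keep the default
suite quick while the statistics remain stable: the SUR/heuristic
regression uses the full 140 configurations on the general 365-day
calendar; the DP offset comparison uses one configuration per subject on
a Monday-only 103-day calendar at a 48-point grid; scheduler-vs-brute-
force checks use instances with ≤ 12 admissible points (≤ 4096
schedules).

## Known limitations

- Variable phlebotomy volumes, sub-daily slots and patient-preference
  weights are not implemented (fixed 500 ml, one slot per day).
- The DP planner does not track dwell inside a stage; it requires stage
  spacing of at least the dwell time, which every day-based calendar
  satisfies.
- The heuristic's shift rule looks back a single step; pathological
  calendars can make it declare infeasibility where a global method
  would succeed.
- Estimation assumes known treatment dates and a constant `B` over the
  fitted window; change-point segmentation of long series is out of
  scope.
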