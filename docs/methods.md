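# Methods

## The model

The simulator couples a prescribed chemoattractant field to discrete
sprout-tip agents through a conservative finite-difference scheme.

**VEGFA field.** The concentration is closed-form, not solved: in the
experimental system the VEGFA level at the sprouting site oscillates with
gradual attenuation, and at every time point it is higher near the
pre-existing vessel than near the arterial patch. Both features are
captured by

    c(x, t) = a {b + sin(2πσt) e^{−γt}} · {1 − (r0 − rp)²/ε²},   rp > R,

and `c = 0` inside the patch disc (`rp ≤ R`). The spatial factor increases
with the distance `rp` from the patch for `rp < r0`, encoding the inverted
gradient (low at the patch, high at the vessel). The literal offset
constant is exposed as a parameter `r0` (default 3) rather than hard-coded
because the default `ε = 2.9 = r0 − R` is plainly the choice that makes
the field vanish continuously at the patch boundary; keeping the coupling
explicit preserves that structure under reparameterisation.

**Chemotaxis by temporal change.** The transport velocity is
`v_m = ∇f` with potential `f = −β c_t` clamped to rising VEGFA
(`f = 0` where `c_t ≤ 0`). Because the spatial factor is time-independent,
`c_t` factorises, and its temporal factor changes sign at the roots of
`tan(2πσt) = 2πσ/γ` — closed-form *period boundaries* that partition time
into growth periods (patch-ward drift) and rest periods (pure random
motility). With the default σ = 0.115, γ = 0.15 these fall at
t ≈ 1.89, 6.24, 10.59 days, which is what produces the observed
fast–stall–regrow growth rhythm.

β formally appears both inside the potential and in the printed lattice
operator for `v_m`; applying it twice would square β and flip the sign.
Here β enters exactly once, inside `f`, and the lattice operator is the
pure averaged difference quotient — the two readings coincide at the
default β = 1.

**Scheme.** Density lives on cell centres ((i−½)h, (j−½)h), the potential
on cell corners, fluxes on faces. The velocity at a cell centre averages
the two adjacent corner difference quotients per direction (exact for
linear fields, first-order for smooth ones). Advection is upwinded via the
split `v± = max(0, ±v)`; diffusive and advective face fluxes are zeroed on
the domain boundary (zero-flux walls). The explicit update rearranges into
per-site weights

    stay  = 1 − 4dτ/h² − (τ/h)(vx⁺ + vx⁻ + vy⁺ + vy⁻)
    move  = dτ/h² + (τ/h)·(own split component toward that neighbour)

which are nonnegative and sum to one whenever
`τ ≤ h²/(4(d + h·v̂))`, `v̂` the largest split component anywhere. At
boundary sites the wall-facing move is folded into *stay* — the exact
probabilistic counterpart of the zero-flux closure. Both the flux form and
the probability form of the update are implemented as independent code
paths and agree to 1e−12 on random instances; the agents consume the same
tuples, which is the sense in which the hybrid is consistent.

**Agents.** Tips are seeded on distinct right-boundary cells (uniform
without replacement — shared sites would cause instant self-anastomosis at
t = 0). Per step, each active tip makes one movement draw from its site's
5-tuple; all tips use the field evaluated at the step's start. Moves are
processed in ascending tip id against a live occupancy map: stepping onto
a site first occupied by a *different* vessel terminates the mover
(anastomosis; the occupant survives), while a tip's own trail — including
staying put — is exempt. Two tips proposing the same empty cell in one
step are resolved by the same ordering: the lower id claims it, the other
fuses. After moves, any tip whose cell centre lies within `R + h` of the
patch centre becomes *arrived* and stops; the one-cell tolerance is needed
because no cell centre falls strictly inside the zero-concentration disc
at the default resolution. Finally, branching: a tip older than
`T_branching` whose local VEGFA is rising spawns a daughter at its own
site with the piecewise-constant probability 0 / 0.3 / 0.4 / 0.5 / 1 over
the concentration brackets [0, 0.25), [0.25, 0.45), [0.45, 0.60),
[0.60, 0.70), [0.70, ∞), at most one daughter per tip per step. Daughters
inherit only position; their age restarts at zero and they found their own
branch trajectory.

Randomness comes from a single `numpy` PCG64 generator seeded from the
config; draw order is fixed (placement, then per step: one movement draw
per active tip ascending id, one branching draw per eligible tip ascending
id), so identical (config, seed) reproduces a run bit-for-bit.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| d | 1.728e−4 | — | random motility of tips |
| β | 1 | — | chemotactic strength |
| a, b | 1, 0.39 | — | kinetic amplitude and baseline |
| σ | 0.115 | 1/day | VEGFA oscillation frequency |
| γ | 0.15 | 1/day | VEGFA attenuation rate |
| ε, r0 | 2.9, 3 | — | spatial shape (ε = r0 − R ⇒ continuity) |
| R | 0.1 | — | patch radius; patch centred at (0, 0.5) |
| N | 100 | — | lattice cells per side (h = 0.01) |
| n_tips | 20 | — | initial sprouts on the right boundary |
| horizon | 14 | day | simulated span |
| T_branching | 0.5 | day | minimum sprout age before branching |
| safety | 0.9 | — | fraction of the stability bound used for τ |
| length_scale_mm | 3.0 | mm | physical size of the unit domain |

One dimensionless time unit is one day throughout. The domain scale 3 mm
is the mean measured patch-to-vessel distance (0.3 ± 0.2 cm); it is a
pure output scaling, so the ±2 mm biological spread can be explored by
rescaling measurements without re-running. N is not dictated by the model;
100 makes the patch radius a clean 10 cells and resolves the velocity
field well, and the headline statistics are stable under N ∈ {50, 100,
200}. `T_branching` has no measured value; 0.5 day is used because it must
be shorter than the first growth period (1.89 days) for any early
branching to exist at all. The safety factor 0.9 keeps the stay weight
strictly positive at the stability edge.

With these defaults a 14-day run takes ~500 adaptive steps
(τ ≈ 0.004–0.005 day during growth periods, when the velocity dominates
the bound, and ≈ 0.13 day during rest, when only diffusion constrains it)
and well under a second of CPU.

## Vessel measurement

The histology protocol measures, per identified new blood vessel, the
straight-line distance from the outer circumference of the arteriole to
the vessel's farthest point — the measured object is the whole branched
structure sprouting from one point. The simulator mirrors that: a
*vessel* is an initial-sprout lineage (founder plus all descendants), its
*extent* the maximum distance of any visited cell centre from the lineage
origin, its *path* the total arc length of the lineage tree. Extent is the
headline metric; path exceeds it whenever the vessel meanders or branches.
Measuring each branch as its own vessel from its own branch point is also
supported (`per_branch=True`) but is not the protocol analogue: the
anastomosis-dominated regime produces many one-cell daughter branches that
the microscope would never count as separate vessels, and they drag the
per-branch mean extent to ~0.15 mm, far below any measured value.

Growth curves report the per-day mean extent over the 20 lineages; since
extent is a running maximum over a fixed cohort, the curve is
nondecreasing, and its increments expose the growth/rest rhythm
(deceleration after day 2, reacceleration after day 7). Replicate
summaries pool final extents across seeded runs and report sample mean and
SD (n−1).

## Kinetic fitting

`fit_vegf_params` fits the temporal factor `a{b + sin(2πσt)e^{−γt}}` to a
measured series at a fixed location (the spatial factor is absorbed into
`a`, because concentrations are measured at one tissue area). Damped
sinusoids are multimodal in frequency, so trust-region least squares is
multi-started over 10 σ values spanning 0.05–0.5 cycles/day; `a` starts at
the half-range, `b` at mean/amplitude, γ at 0.3/day, and the lowest
residual sum of squares wins. Bounds keep a > 0, σ > 0, γ ≥ 0. At least
8 distinct time points are required for the 4-parameter fit. A
zero-variance series is flagged degenerate (σ is unidentifiable) and the
baseline product a·b is returned. On noiseless series sampled at the in
vivo design the fit recovers all four parameters to < 1e−4 relative
error; at 5 % multiplicative noise with 3 replicates the median
worst-parameter error over 100 trials is ≈ 4 %.

## Synthetic data

`generate_fixture_series` emulates the in vivo sampling: times 1, 3, 6,
12, 18 h and days 1–7, three replicates per time point, multiplicative
Gaussian noise at 5 % relative level by default. It reproduces the
sampling design and noise scale, not the biology: real replicates are
different animals with shared-assay correlations, detection floors and
possible non-sinusoidal structure, so passing fit-recovery tests shows the
estimator works when the model is true, not that the model is true.
Likewise the simulation ensemble probes the model's own stochasticity
(movement, branching, anastomosis draws), not inter-animal variability.

## Numerical choices and edge cases

* Time steps land exactly on snapshot days (τ is shortened when it would
  overshoot the next snapshot), so daily measurements need no
  interpolation.
* `σ = 0` (constant kinetics) yields no period boundaries; `γ = 0`
  (undamped) yields the closed form t = (2k+1)/(4σ). Both are handled
  exactly rather than numerically.
* `d = 0` with zero velocity (e.g. β = 0 during a rest period at d = 0)
  is rejected: the stability bound degenerates and nothing can move.
* A time step violating the stability bound raises an error rather than
  silently producing negative weights.
* Runs whose tips all terminate before the horizon still report the
  remaining snapshots with frozen positions.
* Probability normalisation is exact by construction (stay is defined as
  one minus the moves); the validator tolerates 1e−12 rounding.

## Known limitations

* The VEGFA field is prescribed, not solved; there is no production,
  diffusion or uptake, and no feedback from vessels onto the field.
* No haptotaxis, endothelial proliferation, blood flow or 3-D extension.
* Branching probability is applied per adaptive step, so its effective
  per-day intensity depends on τ; during growth periods eligible tips
  branch at saturation and the vessel count is controlled by anastomosis
  rather than by the table values. This mirrors the published rule set; a
  rate-based (per-day) reading would change the tangle density.
* The arrival statistic has a heavy-tailed ensemble: most runs end with
  0–2 sprouts reaching the patch, but ~2 % of seeds produce 3, so the
  across-ensemble maximum is not a robust invariant even though the mode
  and median (1) are.
* At coarse N the one-cell arrival tolerance slightly advances recorded
  arrival times relative to finer lattices.
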