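# Model and methods

`melanosim` simulates the basal layer of human epidermis as an off-lattice
cell-centre model: non-deformable discs of 20 µm diameter on a walled
400 µm × 400 µm dish, advanced in 30-minute iterations.  Three agent types
live on the dish — stem keratinocytes, transit-amplifying (TA)
keratinocytes and melanocytes — and the question the model asks is which
kind of chemotactic guidance lets the melanocytes space themselves evenly
over the observed range of melanocyte densities (5–40% of basal cells).

## Guidance hypotheses

Exactly one mechanism is active per run:

* **Repellent R** — melanocytes secrete R at a constant rate and migrate
  down its gradient; R reports melanocyte crowding.
* **Binary attractant A** — keratinocytes secrete A at a constant rate
  *only* while no melanocyte sits within their immediate neighbourhood
  (25 µm centre-to-centre); melanocytes migrate up the A gradient.  Above
  roughly 15–20% melanocyte density every keratinocyte has melanocyte
  contact and production shuts off globally, which is this mechanism's
  built-in failure mode.
* **Continuous attractant A** — keratinocytes secrete A at a rate
  repressed by the local level of R, `G_max / (1 + (R/θ)^n)`; R is still
  produced by melanocytes but serves only as a distance proxy, not as a
  migration cue.  Production is half-maximal at `R = θ`.  We use `θ = 3`
  and `n = 2` by default: the exponent sharpens the distance response so
  that the production field varies on the length scale the migration rule
  can sense; with `n = 1` the field is too flat for guidance at low
  melanocyte density.  Both are configurable.

## Signal transport

Signals live in per-cell compartments (the cells themselves are the
compartments, standing in for gap-junction transport of small molecules).
Each iteration and substance, in order: production is added; every cell
with at least one neighbour within `diffusion_neighbor_radius` (25 µm)
emits `outflux_fraction` (0.4) of its current amount, split equally among
those neighbours; the addressed shares are added; then first-order
degradation removes `degradation_fraction` of the post-flux level.
Isolated cells emit nothing, so with production and degradation disabled
the scheme conserves total substance exactly (up to floating-point
summation).  Degradation after influx follows the scheduler's verbal phase
order; the alternative (before influx) differs only by a bounded
second-order term.  The decay length is roughly
`√(outflux/degradation)` cell spacings, and the two substances default to
different lifetimes: the repellent decays fast
(`degradation_fraction_R = 0.06`, decay length ≈ 2.6 spacings ≈ 50 µm) so
that it reports melanocyte positions sharply — both as a migration cue
and as the distance proxy repressing continuous attractant production —
while the attractant is long-lived (`degradation_fraction_A = 0.02`,
≈ 4.5 spacings ≈ 90 µm) so that unserved keratinocyte territory is
visible to melanocytes from afar.  The rim scenario's dish-scale gradient
is monotone for any of these settings.

Amounts are dimensionless per-cell quantities; cells are identical
spheres, so no volume normalisation is applied.

## Migration

Melanocyte chemotaxis follows a two-extreme-neighbour rule: among the
neighbours within the sensing radius (the diffusion adjacency), take the
one with the highest and the one with the lowest cue level; the step is
`migration_gain · Δ · (u_max − u_min)` for an attractant and its negation
for the repellent, where `Δ` is the level difference and `u` are unit
vectors toward those neighbours.  Level ties break toward the lowest cell
id for determinism.  The magnitude is therefore proportional to the local
signal contrast — this is deliberate, because the mechanisms' density
signatures (attractant contrast collapses at high melanocyte density,
repellent contrast grows) are carried by signal amplitude.  `max_step`
(8 µm/iteration) is a numerical guard, not the working regime.  In shallow
gradients the extreme neighbours are effectively arbitrary, so the walk
degrades gracefully into a weakly weighted random walk.

TA keratinocytes take a fixed-magnitude (0.5 µm) uniformly random step
each iteration; stem keratinocytes never move of their own accord
(substrate-anchored) and melanocytes never random-walk.

## Contact mechanics

Overlaps created by division and migration are resolved by position-based
relaxation: each overlapping pair is pushed apart along its centre line by
`repulsion_gain` (0.2 µm/µm²) times the circle–circle intersection area,
capped at half the pair's overlap depth per sweep.  Sweeps are synchronous
(Jacobi) so the result is independent of cell storage order; the half-depth
cap is required for stability — pushing pairs to full tangency in one
sweep oscillates whenever a cell overlaps several neighbours.  Up to 8
sweeps run per iteration, stopping early below a 0.1 µm residual.
Cell–cell adhesion pulls pairs with a surface gap in (0, 10] µm together
by `adhesion_gain · gap/range`, never past tangency; the cell–substrate
bond of the 3-D original reduces, in a strict monolayer, to an optional
global damping factor on all displacements (default 1, i.e. off).
Positions are finally clipped so every cell body stays inside the walls.

## Cell dynamics and homeostasis

Each cell carries an integer cycle counter; when it reaches the type's
threshold (stem and TA: 48 iterations ≈ 24 h; melanocyte: 72) the cell
divides, placing the daughter one radius away at a uniformly random angle
(mechanics separates them).  The counter only advances under contact
inhibition, which has two parts: at most `free_space_max_neighbors` (5)
cells within `free_space_radius` (25 µm), *and* no residual overlap deeper
than 1 µm — a cell still compressed after relaxation has no free space
whatever its neighbour count.  The dish walls count toward crowding via
mirror-image ghost cells; without this, boundary cells always look
uncrowded and divide without bound, over-packing the monolayer.

Stem keratinocytes are immortal; each division yields a TA daughter with
probability 0.5 (asymmetric division), else a stem daughter.  TA cells
divide at most `max_ta_divisions` (3) times — mother and daughter both
advance their division count — and, once exhausted, detach
(are deleted, representing stratification into suprabasal layers) as soon
as more than `crowding_removal_neighbors` (4) cells crowd their
contact-inhibition neighbourhood.  This detachment is the monolayer's
pressure valve: it converts the division influx at confluence into an
upward outflux, and its threshold sits one below the division bound so the
boundary-region influx is balanced too.  An exhausted TA with free space
simply stays.  Population counts equilibrate near confluence (~450–500
cells on the default dish) with ongoing turnover.

Melanocyte cycle progression additionally requires the guidance signal to
report melanocyte scarcity — own-compartment R below a ceiling (mechanism
R) or A above a floor (attractant mechanisms) — and a signal reporting
severe excess kills the cell outright (R at or above `DEATH_RATIO = 2.5`
times the proliferation ceiling, or A at or below the floor divided by
2.5).  Death is disabled for the first simulated day
(`death_warmup_iterations = 48`, about the signal relaxation time
`1/degradation_fraction`) so that the empty-field initial condition cannot
trigger spurious extinction.

### Density calibration

The equilibrium melanocyte density is set by the interplay of the signal
bands and the production rates.  We treat the bands as cell-intrinsic —
one proliferation/death pair per mechanism, fixed across all experiments,
anchored to the steady-state guidance level measured on a frozen
hexagonal packing at the 10% reference density — and tune only the
production rate per target density, the knob an experimenter would
actually turn between culture conditions.  `scripts/calibrate.py` finds
each production scale by log-space bisection against full live runs until
the endpoint density matches the target; density falls with production
under the repellent (the fixed ceiling is reached earlier) and rises
under the attractants (the fixed floor is cleared more easily), so the
scale decreases with target density for the repellent and increases for
the attractants.  An earlier variant calibrated the thresholds themselves
per density; that re-centres the signal scale at every density and, under
the repellent, keeps the migration amplitude growing with density so that
positional jitter hides the packing regularisation — fixed thresholds
with scaled production avoid both problems.  The resulting tables are
frozen into `melanosim/presets.py`; `presets.calibrated_setup()` returns
ready-made parameters for the reference densities 5, 10, 25 and 40%.

## Scenarios and initial conditions

`RANDOM_SEEDING` scatters `initial_cell_count` cells uniformly, relaxes
overlaps (synchronous depth-fraction sweeps with a 0.05 µm annealing
jitter, which unjams dense seedings), and assigns types independently:
melanocyte with the target fraction, otherwise stem with probability 0.1,
else TA.  Cycle counters start uniformly distributed below threshold and
TA division counts uniformly in [0, max] — a culture mid-growth rather
than a synchronized cohort; both choices prevent artificial division
bursts.  The reference experiments seed 380 cells (~75% coverage) so the
culture is near confluence within the first simulated day.

`RIM_RESTRICTED` pins melanocytes in a single ring against the wall with
keratinocytes hex-packed inside and freezes all cell dynamics
(signals-only mode): the configuration used to visualise each mechanism's
global gradient.  The steady R field decays monotonically from rim to
centre.

## Evenness statistics

Only melanocytes inside the central 300 µm × 300 µm observation window
enter the statistics, but neighbours and nearest cells are searched over
the whole dish — this removes the upward bias a window-only search places
on border cells' nearest-neighbour distances (verified against the naive
computation in the tests).

* **Neighbour ratio** — fraction of window melanocytes with more than
  three melanocyte neighbours (centre distance ≤ 20 µm).  The "three or
  more" counting variant is available via a flag
  (`neighbor_count_inclusive`); strict "more than three" is the default.
* **relsd** — population SD over mean of nearest-melanocyte distances,
  each time-averaged over the final 48 iterations (24 h) before the ratio
  is taken (ratio of window means, not mean of ratios).  Population SD
  (divisor n) is used throughout.  A perfect lattice gives 0; complete
  spatial randomness gives ≈ `√(4/π − 1) ≈ 0.52` for large counts, and
  somewhat less at the small counts of low-density runs, so comparisons
  use the package's own Monte-Carlo CSR baseline at matched melanocyte
  count rather than the asymptote.

Replicate groups are compared with the two-sample Kolmogorov–Smirnov test
(exact null for small groups), starred at p < 0.05 and p < 0.01.

## What the synthetic configurations do and do not show

The fixture generators (hexagonal packings, CSR placements, rim rings,
exact lattices) are hand-checkable geometries used as oracles: the lattice
pins relsd at zero, CSR pins it at the Rayleigh value, the uniform-quarter
hex packing realises the binary-production saturation regime exactly.
They emulate the geometry of a confluent monolayer, not its biology: real
basal layers have heterogeneous cell sizes and shapes, 3-D context,
signals other than the two modelled, and melanosome transfer, none of
which the model represents.  Passing tests therefore establish the
internal consistency of the hypotheses' logic, not that any specific
molecule behaves this way in skin.

## Numerical choices and problem sizes

All randomness flows from one `numpy` PCG64 generator per run, consumed in
a fixed phase/cell-id order; the population is canonically sorted by cell
id at the start of each step, so results are independent of storage order
and bit-reproducible per seed.  Daughters receive fresh, monotonically
increasing ids.  The per-step signal update is checked against an
explicitly built dense transfer matrix to 1e-12; conservation holds to
float summation accuracy (~1e-13 relative over 1000 steps).  NaN anywhere
aborts the run with the iteration and cell ids.

The reference experiment grid (3 mechanisms × 4 densities × 12 replicates
× 480 iterations at ~450 cells) runs in roughly 20–30 minutes on one core.
The test suite and the acceptance script use the same dish and iteration
count but fewer replicates (6–12) and three densities, sized to finish in
a few minutes each.

## Known limitations

* Strict 2-D monolayer: stratification is deletion, suprabasal feedback is
  absent by design.
* Keratinocyte lineage rules (thresholds, asymmetric-division probability,
  TA budget) are plausible defaults, not fitted values; the source
  literature for the underlying colony model does not pin them down.
* The binary-production saturation argument concerns uniform packings; in
  random arrangements at 25% a minority of keratinocytes can still lack
  melanocyte contact, so live binary-regime runs at high density retain
  weak residual signalling.
* The death rule is a sharp threshold with instantaneous removal; no
  apoptosis duration or probabilistic death.
* Melanocyte behaviour at densities above ~40% is outside the calibrated
  range.
* The continuous-attractant mechanism's density signature is only partly
  reproduced: its patterns are more even than random at every calibrated
  density, but its evenness does not degrade from 5% to 25% as the other
  mechanisms' contrast suggests it should.  The cause is geometric — the
  production dip around a melanocyte is smoothed twice (by the repellent
  plume that drives repression and again by attractant transport), so at
  low density the field within a melanocyte's 25 µm sensing radius is
  nearly flat and close pairs separate slowly.  None of the explored
  parameterisations (Hill sharpness, decay lengths, migration scaling)
  changed the sign of that slope without breaking the other two
  mechanisms' behaviour.
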