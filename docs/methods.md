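# Methods

`xylokinetics` reconstructs intra-experiment wood formation from cheap,
frequent measurements: daily stem-diameter series date the xylem cells found
in end-of-experiment sections, and simple steady-state identities convert
dated cell cohorts and cambial cell counts into developmental rates and
durations. This note records the models, the defaults and why, the numerical
conventions, and what the synthetic-data generator does and does not emulate.

## Cell dating (zonation)

Between two boundary days the tree adds a radial band of xylem of width

    w_i = max(0, Δdiameter_i / 2) · 1000   [μm]

Diameter change is halved (one radius) and negative changes are clamped to
zero: stem shrinkage under water deficit is elastic (reversible dehydration
of bark and immature tissue), not lost wood. Bark/phloem thickening is
ignored; a configurable `radius_scale` replaces the factor ½ if a different
allometry is preferred. Cumulative widths anchored at the cambium (youngest
tissue at depth 0) tile the experiment's growth; a cell with radial depth
`d = orientation · (centroid_y − cambium_y)` belongs to increment *i* iff
`cum_outer_i ≤ d < cum_inner_i` (half-open; a zero-width increment is an
empty interval and receives no cells). Cells deeper than the total growth
pre-date the experiment; negative depths lie on the phloem side and are left
unassigned. If no cambial y-coordinate is supplied, the extreme cell
centroid on the cambial side is used — adequate for dense detections, but
it shifts all depths by roughly half a cell spacing, so exact dating work
should pass the measured `cambium_y`.

Two boundary presets ship: every sampling interval (default step 3 days,
matching destructive-sampling cadence) and one boundary per
drought/watering cycle.

## Increment traits

* Wall thickness uses a concentric-circle model,
  `WT = √(A_cell/π) − √(A_lumen/π)`; only areas are exported by the
  detection software, so ring geometry is the least-assuming inversion.
* Fibre "diameter" is the equivalent-circle diameter `2√(A/π)` for the same
  reason.
* Vessel frequency for a period is `n / (w · 0.4)` vessels·mm⁻², where `w`
  is the period's radial growth in mm and 0.4 mm is the tangential width of
  the analysed image. A period with vessels but no measurable growth has no
  defined section area; NaN flags it rather than raising.
* Trend curves are lowess (locally linear) smooths of cell-level values
  against formation day, span 0.3, evaluated on a 200-point uniform grid
  with no extrapolation. Local-linear smoothing preserves constants and is
  exact on linear signals, which pins its behaviour in tests. Treatment
  contrasts interpolate both curves onto a shared grid over the overlapping
  day range and subtract pointwise (PI − CI), so `contrast(a,b) ≡
  −contrast(b,a)` by construction.

## Kinetics

For an analysis window of `t_i` days in which a radial file grew `g_i` μm of
cells with mean diameter `D_i`:

    φ_i    = g_i / (D_i · t_i)          cell production rate  [cells/day]
    t_φ    = η_c / φ_i                  cell-cycle duration   [days]
    t_σ    = η_x / φ_i                  phase duration        [days]
    rate   = (Size_end − Size_begin)/t_σ

`η_c` is the cambial-zone cell count (mean over three radial files, averaged
over the window's sampling days) and `η_x` the count of cells in the
enlargement or wall-thickening phase, both counted upstream on cambial
images and supplied as tables. The identities `t_φ·φ = η_c` and
`t_σ·φ = η_x` hold to machine precision for every estimate, by construction.
Windows need not align with dating boundaries: `g_i` pro-rates each
increment's width by its fractional day-overlap with the window, so growth
is neither dropped nor double-counted. Windows with no dated fibres, or no
growth, yield `φ = 0` with downstream durations flagged (NaN) rather than
an error — exactly the "almost no growth" case a severe drought produces.

Default analysis windows: Period 1 (days 18–28), in-between (29–59),
Period 2 (60–72).

## Statistics

* **Water potential.** Pre-dawn leaf water potential Ψ_PD is stored as
  negative MPa. The Gamma GLM with identity link needs positive support, so
  it is fitted on magnitudes |Ψ_PD| with `magnitude ~ Treatment + Cycle`; a
  positive treatment coefficient means more negative water potential. This
  sign convention is recorded in the result metadata.
* **Traits.** Cell-level values are modelled as
  `value ~ Treatment × Period` with a random intercept per sample
  (statsmodels MixedLM, REML). A per-cell random intercept is not
  identifiable with one observation per cell; a nested variance component
  is available behind a flag for data with repeated cell measurements. The
  headline interaction test is a joint Wald χ² on all interaction
  coefficients. If the mixed fit is singular or fails to converge the model
  refits as OLS and records a warning (the random structure is already
  minimal, so there is nothing smaller to drop to).
* **Windowed contrasts** compare per-sample mean trait values between
  treatments inside stated day windows with Welch t tests, estimate
  PI − CI. Multiple windows are reported unadjusted by default; Holm
  adjustment is a flag.
* **Relative increments**: per-tree end/start ratios of diameter and
  height, ANOVA first and then a two-sample t test. Two degenerate cases
  are defined explicitly: identical ratios everywhere give t = 0, p = 1,
  and a non-positive starting value is an error.

## Synthetic-data generator

The generator emulates a two-treatment greenhouse experiment — continuously
irrigated (CI) controls versus periodically irrigated (PI) trees under six
alternating drought/watering cycles in 75 days — with known ground truth.

Mechanism, per tree and day:

* **LWP**: CI fluctuates around `lwp_baseline` (−0.5 MPa, noise sd 0.05);
  PI declines linearly over each drought cycle toward a cycle minimum and
  rebounds on rewatering. Two cycles (the first and, when present, the
  fifth) are severe and reach `lwp_drought_min` (−2.4 MPa); the rest draw
  milder minima (50–90% of the way down).
* **Growth**: radial increment = `baseline_growth_rate` × f(LWP) ×
  lognormal noise (CV 0.1), where f is 1 above `lwp_threshold` (−2.0 MPa)
  and declines linearly to 0 at `lwp_drought_min`. The default rate is
  `cells_per_day × mean_fibre_diameter` = 2 × 10 = 20 μm/day, so the
  production-rate ground truth φ_true = 2 cells/day is exact by
  construction.
* **Shrinkage**: on sub-threshold days the *measured* diameter additionally
  carries a reversible elastic deficit of up to `shrinkage_amplitude`
  (0.15 mm, matching observed −0.07…−0.18 mm episodes); structural growth
  is unaffected. This reproduces the characteristic dendrometer signature:
  shrinkage during severe drought, sharp apparent recovery on rewatering.
* **Cells**: fibres tile one radial file at `growth/D` cells per day (a
  fractional accumulator keeps cell production and growth exactly
  consistent); vessels arrive as a Poisson process with intensity
  `vessel_frequency_true × image_width × daily growth`
  (138 mm⁻² × 0.4 mm). Areas are lognormal (CV 0.3) around the class means
  (fibre D = 10 μm, vessel D = 30 μm equivalent circle); fibre lumens come
  from a mean wall thickness of 1.5 μm (CV 0.1, capped below the cell
  radius); radial placement noise is Gaussian (sd 2 μm).
* **Drought trait effects**: multipliers (defaults 0.8 vessel CSA, 0.9
  fibre CSA, 0.9 wall) apply to cells whose *enlargement phase* overlaps a
  sub-threshold LWP episode — production days within ±t_σ (≈3) days of the
  episode. Final cell dimensions are set during enlargement, so cells
  produced shortly before a drought peak are caught by it, and cells
  produced just after rewatering still face depressed tissue water status.
  Together with the growth collapse below threshold, this reproduces the
  observed pattern that treatment differences in vessel CSA appear in
  tissue dated up to a week *after* the LWP minimum: the drought increments
  themselves are nearly empty (little growth, and elastic shrinkage makes
  their measured width zero), while the rebound increment collects the
  affected cohort.
* **Cambial/phase counts**: three radial files per sampling day (every 3
  days), each η ± at most 1 cell around the true values (η_c = 4, matching
  the observed ~3.9-cell cambial zone; η_x = 6).
* **Environment**: a 30-min logger with a sinusoidal diel temperature cycle
  around 21.8 °C and RH around 58%.

A single root seed is split per tree and per table; all outputs are
bit-identical for a fixed seed. `truth.json` records every parameter plus
the derived φ, t_φ and t_σ ground truth.

What the generator does **not** emulate: tangential position and vessel
grouping, section obliquity, bark growth, between-tree genetic variation in
baseline traits beyond random noise, drift or acclimation across successive
cycles, and measurement error in the diameter series itself. Passing tests
therefore demonstrate that the pipeline's logic is correct under the stated
mechanism, not that the biological effect sizes of any particular species
are recoverable from field data.

## Problem sizes and validation choices

* Kinetics recovery uses 20 control trees × 5 seeds; control trees are used
  because the nominal production rate applies to them throughout, whereas
  periodically irrigated trees genuinely depart from nominal during drought.
  Measured recovery error is ~1–2% for φ and t_φ.
* Exact dating recovery sets placement noise and shrinkage to zero: elastic
  shrinkage biases measured increment widths near severe droughts, so exact
  recovery is only defined without it (with the default 2 μm placement
  noise, ≥90% of cells are still dated correctly at ≥20 μm increments).
* Statistical calibration runs 200 null replicates at 6 trees/treatment
  (null = all multipliers 1 and no LWP excursions, making treatments fully
  exchangeable); both the interaction test and the GLM treatment test
  reject at 4–6%. Effect detection runs 50 replicates at the default 12
  trees/treatment; the drought-affected windows (derived from each
  replicate's own mean PI LWP trajectory, not from fixed calendar days) are
  all significant in ~86–88% of replicates.

## Known limitations

* The Δdiameter/2 conversion attributes all diameter change to xylem; real
  stems add bark and phloem too, biasing widths high by a roughly constant
  factor that cancels in φ (g and D scale together) but not in absolute
  trait-versus-depth alignment.
* Dating resolution is limited by the boundary cadence and by shrinkage:
  cells formed during a severe drought are systematically pushed into the
  rebound increment.
* The Wald interaction test is asymptotic; at very small sample counts
  (<4 per treatment) its calibration degrades and the OLS fallback becomes
  more frequent.
* The Gamma/identity GLM can in principle propose negative means during
  optimisation; with drought-scale magnitudes (0.05–2.5 MPa) this does not
  occur, but responses near zero would need a log link instead.
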