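# xylokinetics

Analysis pipeline for **xylogenesis under cyclic drought**: dating xylem
cells to their formation periods from daily stem-diameter measurements,
summarising vessel and fibre anatomy per growth increment, estimating
cambial kinetics, and testing treatment effects — with a synthetic-data
generator that emulates the full experimental data structure with known
ground truth.

It is aimed at quantitative wood-anatomy studies of the common greenhouse
design: seedlings split into continuously irrigated controls (CI) and
periodically irrigated trees (PI) cycled through drought (DT) and watering
(WT) phases, monitored with daily calliper/dendrometer readings, pre-dawn
leaf water potential (Ψ_PD), an environment logger, and end-of-experiment
transverse sections whose cells are detected and classified upstream (e.g.
in QuPath) and exported as CSV.

## The model

**Cell dating.** The diameter change between boundary days, halved and
clamped at zero (shrinkage is elastic, not lost tissue), gives each
period's radial width w_i in μm. Cumulative widths anchored at the cambium
(youngest tissue at depth 0) tile the experiment's growth, and a cell's
radial depth from the cambial boundary places it in exactly one period:
cell ∈ period i ⇔ cum_outer_i ≤ depth < cum_inner_i. Deeper than the total
growth ⇒ formed before the experiment.

**Traits per increment.** Vessel count and mean cross-sectional area (CSA),
vessel frequency VF = n / (w × 0.4 mm) in vessels·mm⁻², fibre CSA, and
fibre wall thickness WT = √(A_cell/π) − √(A_lumen/π) (concentric-circle
model). Cell-level trends over formation day are smoothed with local-linear
regression and contrasted between treatments (PI − CI) on a shared day grid.

**Cambial kinetics.** For a window of t_i days with radial growth g_i and
mean cell diameter D_i:

    φ_i = g_i / (D_i · t_i)      rate of cell production   [cells/day]
    t_φ = η_c / φ_i              cell-cycle duration       [days]
    t_σ = η_x / φ_i              enlargement/wall duration [days]
    rate = (Size_end − Size_begin) / t_σ

where η_c is the cambial-zone cell count and η_x the number of cells in the
enlargement or wall-thickening phase (counted along three radial files on
cambial images).

**Statistics.** Ψ_PD magnitudes: Gamma GLM, identity link,
`|Ψ_PD| ~ Treatment + Cycle`. Cell traits: linear mixed model
`value ~ Treatment × Period` with a random intercept per sample, plus
per-window Welch t tests of per-sample means. Whole-experiment growth:
relative increments (end/start) compared by ANOVA and t test.

## Worked example

Simulate a 75-day, six-cycle experiment with 6 trees per treatment and run
every stage:

```bash
cat > config.yaml <<EOF
simulate:
  n_trees_per_treatment: 6
seed: 11
boundaries: {step: 3}
EOF
xylokinetics run-all --config config.yaml --out out/
```

`out/` then holds `dated_cells.csv`, `increments.csv`, `traits.csv`,
`kinetics.csv`, `contrast.csv`, `stats.json` and a `manifest.json` with
hashes and seeds. Summarising `kinetics.csv` for this config prints:

```
                         phi  t_phi  t_sigma
treatment period_label
CI        Period 1      2.00   1.98     3.01
          Period 2      2.01   2.04     2.92
          in-between    2.03   1.95     2.91
PI        Period 1      1.94   2.13     3.11
          Period 2      2.05   1.91     2.93
          in-between    1.98   1.96     3.04
```

The generator's ground truth for this run is φ = 2 cells/day, t_φ = 2 days
and t_σ = 3 days: the estimator recovers all three to a few percent, and
the PI trees show the expected slight depression of φ (and lengthening of
t_φ) in Period 1, which contains a severe drought. In `stats.json` the
treatment term of the Ψ_PD GLM is 0.18 MPa on the magnitude scale
(p ≈ 3×10⁻³¹; PI more negative), the vessel-CSA Treatment × Period
interaction has p = 0.037, and the relative-increment t tests show the
control trees out-growing the droughted ones in both diameter and height
(p < 0.002). The mean realised vessel frequency across increments is
≈ 143 mm⁻², close to the generator's 138 mm⁻² target.

Every stage is also a library call (`xylokinetics.pipeline`) and an
individual subcommand (`simulate`, `zonate`, `traits`, `kinetics`,
`stats`).

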