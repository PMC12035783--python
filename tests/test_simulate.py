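"""Generator behaviour: schedules, tree series, cell cohorts, determinism."""

import numpy as np
import pandas as pd
import pytest

from xylokinetics.errors import PreconditionError, ScheduleSpanError
from xylokinetics.simulate import (
    SimulationParams,
    TreeSeries,
    affected_days,
    generate_schedule,
    simulate_cells,
    simulate_environment,
    simulate_experiment,
    simulate_tree,
)


def watered_schedule(n_days=10):
    """A schedule whose single drought cycle lies outside the window used."""
    return generate_schedule(1, (3, 3), (3, 3), seed=0, n_days=n_days)


class TestSchedule:
    def test_six_cycles_alternate_with_drought_lengths_in_range(self):
        sched = generate_schedule(6, (3, 7), (3, 7), seed=5)
        dts = [c for c in sched.cycles if c.status == "droughted"]
        wts = [c for c in sched.cycles if c.status == "watered"]
        assert len(dts) == 6 and len(wts) == 7  # WT0 lead-in plus WT1..WT6
        assert all(3 <= c.length <= 7 for c in dts)
        assert [c.label for c in dts] == [f"DT{i}" for i in range(1, 7)]
        statuses = [c.status for c in sched.cycles]
        assert all(a != b for a, b in zip(statuses, statuses[1:]))

    def test_degenerate_fixed_length_schedule_spans_nine_days(self):
        sched = generate_schedule(1, (3, 3), (3, 3), seed=1, n_days=9,
                                  extend_final=False)
        assert [c.label for c in sched.cycles] == ["WT0", "DT1", "WT1"]
        assert sched.span == 9

    def test_same_seed_reproduces_schedule(self):
        a = generate_schedule(6, (3, 7), (3, 7), seed=1)
        b = generate_schedule(6, (3, 7), (3, 7), seed=1)
        assert a == b

    def test_overrunning_schedule_raises_span_error(self):
        with pytest.raises(ScheduleSpanError):
            generate_schedule(6, (7, 7), (7, 7), seed=0, n_days=20)

    def test_final_watering_extended_to_cover_experiment(self):
        sched = generate_schedule(1, (3, 3), (3, 3), seed=1, n_days=30)
        assert sched.cycles[-1].end_day == 30


class TestTreeSeries:
    def test_control_tree_diameter_never_decreases(self):
        params = SimulationParams(n_days=30, shrinkage_amplitude=0.0, seed=3)
        sched = generate_schedule(2, (3, 5), (3, 5), seed=3, n_days=30)
        tree = simulate_tree(sched, params, "CI", seed=7)
        assert np.all(np.diff(tree.diameter) >= 0)

    def test_periodic_tree_reaches_configured_lwp_minimum(self):
        params = SimulationParams(n_days=75, lwp_drought_min=-2.4, seed=0)
        sched = generate_schedule(6, (3, 7), (3, 7), seed=11, n_days=75)
        minima = [
            simulate_tree(sched, params, "PI", seed=s).lwp.min() for s in range(8)
        ]
        assert np.mean(minima) == pytest.approx(-2.4, abs=0.15)

    def test_growth_conserved_between_increments_and_final_radius(self):
        params = SimulationParams(n_days=40, shrinkage_amplitude=0.0, seed=1)
        sched = generate_schedule(3, (3, 5), (3, 5), seed=2, n_days=40)
        tree = simulate_tree(sched, params, "PI", seed=4)
        total_radius_um = (tree.diameter[-1] - params.initial_diameter) / 2 * 1000
        # measured diameter carries no elastic term on the final (watered) day
        assert total_radius_um == pytest.approx(tree.radial_increment.sum(), abs=1e-6)

    def test_drought_days_grow_slower_than_watered_days(self):
        params = SimulationParams(n_days=75, seed=0)
        sched = generate_schedule(6, (5, 7), (3, 5), seed=13, n_days=75)
        tree = simulate_tree(sched, params, "PI", seed=5)
        sub = tree.lwp < params.lwp_threshold
        assert sub.any()
        assert tree.radial_increment[sub].mean() < tree.radial_increment[~sub].mean()

    def test_unknown_treatment_rejected(self):
        params = SimulationParams(n_days=10)
        with pytest.raises(PreconditionError):
            simulate_tree(watered_schedule(), params, "XX", seed=0)


def _noise_free_params(**kw):
    base = dict(
        n_days=10,
        growth_cv=0.0,
        placement_noise_sd=0.0,
        shrinkage_amplitude=0.0,
        vessel_frequency_true=1e-9,  # fibres only
        seed=0,
    )
    base.update(kw)
    return SimulationParams(**base)


class TestCells:
    def test_two_cells_per_day_tile_two_hundred_micrometres(self):
        # phi=2 cells/day at D=10 um over 10 days: 20 fibres spanning 200 um
        params = _noise_free_params()
        tree = simulate_tree(watered_schedule(), params, "CI", seed=1)
        cells = simulate_cells(tree, params, seed=2)
        fib = cells[cells.cell_class == "fibre"]
        assert len(fib) == 20
        assert fib.centroid_y.min() == pytest.approx(5.0)
        assert fib.centroid_y.max() == pytest.approx(195.0)

    def test_zero_growth_yields_empty_table_with_warning(self):
        params = SimulationParams(n_days=5)
        tree = TreeSeries(
            "T1", "A", "PI",
            days=np.arange(5),
            diameter=np.full(5, 5.0),
            height=np.full(5, 50.0),
            lwp=np.full(5, -0.5),
            radial_increment=np.zeros(5),
        )
        with pytest.warns(UserWarning, match="zero total growth"):
            cells = simulate_cells(tree, params, seed=0)
        assert len(cells) == 0

    def test_vessel_drought_multiplier_reaches_stated_mean_ratio(self):
        # generator self-consistency at large n: affected-day vessel areas
        # average ~0.8 of baseline
        params = SimulationParams(
            n_days=75, drought_effect_vessel_csa=0.8, placement_noise_sd=0.0,
            vessel_frequency_true=2000.0, seed=0,
        )
        sched = generate_schedule(6, (4, 7), (3, 5), seed=3, n_days=75)
        ratios = []
        for s in range(5):
            tree = simulate_tree(sched, params, "PI", seed=100 + s)
            cells = simulate_cells(tree, params, seed=200 + s)
            eff = affected_days(tree.lwp, params)
            ves = cells[cells.cell_class == "vessel"]
            on = ves[eff[ves.true_day.to_numpy()]]
            off = ves[~eff[ves.true_day.to_numpy()]]
            ratios.append(on.cell_area.mean() / off.cell_area.mean())
        assert np.mean(ratios) == pytest.approx(0.8, abs=0.04)

    def test_radial_ordering_strict_without_placement_noise(self):
        params = _noise_free_params(growth_cv=0.1)
        tree = simulate_tree(watered_schedule(), params, "CI", seed=3)
        cells = simulate_cells(tree, params, seed=4).sort_values("centroid_y")
        # shallow (young) first: production day non-increasing with depth
        assert (np.diff(cells.true_day.to_numpy()) <= 0).all()

    def test_lumen_always_smaller_than_cell_area(self, small_experiment):
        det = small_experiment.detections
        assert (det.lumen_area < det.cell_area).all()
        assert (det.lumen_area >= 0).all()


class TestExperiment:
    def test_same_seed_is_bit_identical(self):
        p = SimulationParams(n_trees_per_treatment=2, seed=9)
        a = simulate_experiment(p)
        b = simulate_experiment(p)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.growth, b.growth)
        pd.testing.assert_frame_equal(a.lwp, b.lwp)
        assert a.schedule == b.schedule

    def test_environment_log_cadence(self):
        env = simulate_environment(1, seed=0)
        assert len(env) == 48  # 30-min cadence over one day
        assert env.relative_humidity.between(0, 100).all()

    def test_truth_records_derived_kinetics(self, small_experiment):
        t = small_experiment.truth
        assert t["phi_true"] == pytest.approx(2.0)
        assert t["t_phi_true"] == pytest.approx(2.0)
        assert t["t_sigma_true"] == pytest.approx(3.0)

    def test_null_multipliers_leave_treatments_exchangeable(self):
        # with all drought multipliers at 1 (and no LWP excursions) the
        # PI and CI cell-area distributions are statistically indistinguishable
        from scipy.stats import ks_2samp

        p = SimulationParams(
            n_trees_per_treatment=4,
            drought_effect_vessel_csa=1.0,
            drought_effect_fibre_csa=1.0,
            drought_effect_wall=1.0,
            lwp_drought_min=-0.5,
            shrinkage_amplitude=0.0,
            seed=21,
        )
        exp = simulate_experiment(p)
        det = exp.detections
        pi = det[det.sample_id.str.startswith("PI")]
        ci = det[det.sample_id.str.startswith("CI")]
        for cls in ("fibre", "vessel"):
            _, pval = ks_2samp(
                pi[pi.cell_class == cls].cell_area,
                ci[ci.cell_class == cls].cell_area,
            )
            assert pval > 0.01


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_days": 1},
            {"mean_fibre_diameter": 0.0},
            {"drought_effect_vessel_csa": 0.0},
            {"drought_effect_wall": 2.0},
            {"lwp_baseline": 0.5},
            {"lwp_drought_min": -0.1, "lwp_baseline": -0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(PreconditionError):
            SimulationParams(**kw)
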