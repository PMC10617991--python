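"""Behavioral fitting: day mapping, normalization, cost-slope estimation."""

import numpy as np
import pytest

from stingmdp import (
    BehaviorDataset,
    DefenseConfig,
    GeneratorSpec,
    PredationMDP,
    fit_increasing_cost,
    fit_shared_cost,
    generate_behavior_dataset,
    goodness_of_fit,
    map_days_to_starvation,
    normalize_model_to_data,
)


class TestDayMapping:
    def test_deprivation_window_maps_to_half_axis(self):
        s = map_days_to_starvation(np.array([0, 5]), s_last=0.5)
        assert s == pytest.approx([0.0, 0.5])

    def test_single_day_degenerates_to_anchor(self):
        assert map_days_to_starvation(np.array([5]), 0.5) == pytest.approx([0.5])

    def test_evenly_spaced_days(self):
        s = map_days_to_starvation(np.arange(6), 0.5)
        assert s == pytest.approx(np.linspace(0, 0.5, 6))

    def test_snap_to_grid(self):
        grid = np.linspace(0, 1, 21)
        s = map_days_to_starvation(np.array([0, 1, 2]), 0.47, grid=grid)
        assert set(np.round(s, 3)) <= set(np.round(grid, 3))

    @pytest.mark.parametrize("s_last", [1.0, 1.3, 0.0, -0.5])
    def test_anchor_must_be_interior(self, s_last):
        with pytest.raises(ValueError):
            map_days_to_starvation(np.array([0, 5]), s_last)

    def test_days_must_increase(self):
        with pytest.raises(ValueError):
            map_days_to_starvation(np.array([0, 3, 2]), 0.5)


class TestNormalization:
    def test_identity(self):
        a = np.array([0.2, 0.4, 0.6])
        assert normalize_model_to_data(a, a) == pytest.approx(1.0)

    def test_exact_scalar_recovery(self):
        a = np.array([0.1, 0.2, 0.3])
        assert normalize_model_to_data(a, 2 * a) == pytest.approx(2.0)

    def test_weighted(self):
        a = np.array([0.5, 0.5])
        y = np.array([0.4, 0.8])
        w = np.array([1.0, 3.0])
        expected = np.sum(w * y * a) / np.sum(w * a * a)
        assert normalize_model_to_data(a, y, w) == pytest.approx(expected)

    def test_zero_model_rejected(self):
        with pytest.raises(ValueError):
            normalize_model_to_data(np.zeros(3), np.ones(3))


class TestDatasetValidation:
    def test_counts_cannot_exceed_scale(self):
        ds, _ = generate_behavior_dataset(GeneratorSpec(seed=0))
        bad = ds.data.copy()
        bad.loc[0, "discharged_count"] = bad.loc[0, "assay_scale"] + 1
        with pytest.raises(ValueError):
            BehaviorDataset(bad)

    def test_csv_roundtrip(self, tmp_path):
        ds, _ = generate_behavior_dataset(GeneratorSpec(seed=0))
        path = tmp_path / "behavior.csv"
        ds.to_csv(path)
        back = BehaviorDataset.read_csv(path)
        assert back.species == ds.species
        assert np.array_equal(
            back.data["discharged_count"].to_numpy(), ds.data["discharged_count"].to_numpy()
        )

    def test_condition_summary_shape(self):
        ds, _ = generate_behavior_dataset(GeneratorSpec(seed=0))
        summ = ds.condition_summary()
        assert list(summ["days_starved"]) == [0, 1, 2, 3, 4, 5]
        assert (summ["n_animals"] == 10).all()


class TestCostFit:
    def test_flat_data_needs_no_slope(self):
        ds, _ = generate_behavior_dataset(GeneratorSpec(species_profile="flat_defensive", seed=1))
        fit = fit_increasing_cost(ds, "defense", DefenseConfig(), fix_c0_base=1.0)
        assert fit.cost.slope <= 0.05

    def test_low_noise_slope_recovery(self):
        ds, truth = generate_behavior_dataset(GeneratorSpec(seed=7, dispersion=0.01))
        fit = fit_increasing_cost(ds, "defense", DefenseConfig(), fix_c0_base=1.0)
        assert fit.cost.slope == pytest.approx(truth["slope"], rel=0.25)
        assert fit.scale_lambda == pytest.approx(truth["scale_lambda"], rel=0.1)

    def test_rescaling_counts_is_absorbed_by_lambda(self):
        ds, _ = generate_behavior_dataset(GeneratorSpec(seed=1))
        doubled = BehaviorDataset(
            ds.data.assign(assay_scale=ds.data.assay_scale * 2), species=ds.species
        )
        f1 = fit_increasing_cost(ds, "defense", DefenseConfig(), fix_c0_base=1.0)
        f2 = fit_increasing_cost(doubled, "defense", DefenseConfig(), fix_c0_base=1.0)
        assert f2.cost.slope == pytest.approx(f1.cost.slope, abs=1e-6)
        assert f2.scale_lambda == pytest.approx(f1.scale_lambda / 2, rel=1e-6)

    def test_needs_three_conditions(self):
        ds, _ = generate_behavior_dataset(GeneratorSpec(days=(0, 5), seed=0))
        with pytest.raises(ValueError):
            fit_increasing_cost(ds, "defense", DefenseConfig())

    def test_defensive_fit_curve_decreases(self):
        ds, _ = generate_behavior_dataset(GeneratorSpec(seed=2))
        fit = fit_increasing_cost(ds, "defense", DefenseConfig(), fix_c0_base=1.0)
        report = goodness_of_fit(fit, ds)
        assert report["trend"] in ("decreasing", "flat")
        assert report["slope"] >= 0

    def test_predatory_fit_curve_increases(self):
        ds, _ = generate_behavior_dataset(
            GeneratorSpec(species_profile="increasing_predatory", seed=2)
        )
        base = PredationMDP()
        fit = fit_increasing_cost(
            ds, "predation", base, fix_c0_base=1.0, slope_max=1.0, n_grid=9
        )
        report = goodness_of_fit(fit, ds)
        assert report["trend"] == "increasing"

    def test_zero_residual_reports_zero_sse(self):
        ds, _ = generate_behavior_dataset(GeneratorSpec(seed=3))
        fit = fit_increasing_cost(ds, "defense", DefenseConfig(), fix_c0_base=1.0)
        fit.residuals = np.zeros_like(fit.residuals)
        assert goodness_of_fit(fit, ds)["sse"] == 0.0


def test_shared_cost_fit_binds_both_species():
    pred, _ = generate_behavior_dataset(
        GeneratorSpec(species_profile="increasing_predatory", seed=4)
    )
    defn, _ = generate_behavior_dataset(
        GeneratorSpec(species_profile="slightly_decreasing_defensive", seed=4)
    )
    fit_p, fit_d = fit_shared_cost(pred, defn, PredationMDP(), DefenseConfig(), n_grid=5)
    assert fit_p.cost == fit_d.cost  # one shared cost function
    assert fit_p.cost.slope >= 0
    assert fit_p.model == "predation" and fit_d.model == "defense"
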