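"""Titration-correction and decay-model fitting."""

import numpy as np
import pandas as pd
import pytest

from trnacharge.models import (
    DECAY_TIMEPOINTS_MIN,
    TITRATION_RATIOS,
    DecayModel,
    TitrationModel,
    decay_value,
    fit_decay,
    predict_titration_charge,
)
from trnacharge.simulate import simulate_decay, simulate_titration


class TestTitrationPrediction:
    def test_endpoints_exact(self):
        for f in (0.25, 1.0, 4.0):
            assert predict_titration_charge(100.0, 83.0, 7.0, f) == pytest.approx(83.0)
            assert predict_titration_charge(0.0, 83.0, 7.0, f) == pytest.approx(7.0)

    def test_worked_arithmetic(self):
        # p=50, T_A=90, T_B=10, F=2: (50*90 + 50*10*2) / (50 + 50*2) = 5500/150
        assert predict_titration_charge(50.0, 90.0, 10.0, 2.0) == pytest.approx(5500 / 150)

    def test_f_one_reduces_to_linear_mixture(self):
        p = np.linspace(0, 100, 21)
        pred = predict_titration_charge(p, 90.0, 10.0, 1.0)
        assert np.allclose(pred, (p * 90.0 + (100 - p) * 10.0) / 100.0)

    def test_monotone_in_p(self):
        p = np.linspace(0, 100, 201)
        for f in (0.25, 0.5, 1.0, 2.0, 4.0):
            pred = predict_titration_charge(p, 90.0, 10.0, f)
            assert (np.diff(pred) > 0).all()


class TestTitrationFit:
    def _data(self, f_true, noise_sd, seed=0, bias=None, n_reps=4):
        data, _ = simulate_titration(
            transcripts=["t1"],
            f_true={"t1": f_true},
            t_a_true={"t1": 85.0},
            t_b_true={"t1": 6.0},
            n_reps=n_reps,
            noise_sd=noise_sd,
            adapter_bias_pp=bias,
            seed=seed,
        )
        return data

    def test_noise_free_recovery_exact(self):
        for f_true in (0.5, 1.0, 2.0):
            model = TitrationModel().fit(self._data(f_true, noise_sd=0.0))
            assert model.fits_["t1"].f == pytest.approx(f_true, abs=1e-6)

    def test_noisy_recovery_within_tolerance(self):
        for f_true in (0.5, 1.0, 2.0):
            model = TitrationModel().fit(self._data(f_true, noise_sd=1.0, seed=31))
            assert abs(model.fits_["t1"].f - f_true) <= 0.15

    def test_out_of_bounds_truth_clipped_and_flagged(self):
        data, _ = simulate_titration(
            transcripts=["t1"],
            f_true={"t1": 10.0},
            t_a_true={"t1": 85.0},
            t_b_true={"t1": 6.0},
            noise_sd=0.0,
        )
        fit = TitrationModel().fit(data).fits_["t1"]
        assert fit.f == pytest.approx(4.0)
        assert fit.at_bound

    def test_requires_interior_ratio(self):
        data = pd.DataFrame(
            {
                "transcript": ["t1"] * 2,
                "ratio_p": [100.0, 0.0],
                "replicate": [0, 0],
                "measured_charge": [85.0, 6.0],
            }
        )
        with pytest.raises(ValueError, match="interior"):
            TitrationModel().fit(data)

    def test_default_design_has_eight_ratios(self):
        assert len(TITRATION_RATIOS) == 8
        assert TITRATION_RATIOS[0] == 100.0 and TITRATION_RATIOS[-1] == 0.0


class TestErrorReport:
    def test_zero_noise_medians_zero(self):
        data, _ = simulate_titration(
            ["t1", "t2"],
            {"t1": 1.5, "t2": 0.7},
            {"t1": 85.0, "t2": 60.0},
            {"t1": 6.0, "t2": 3.0},
            noise_sd=0.0,
        )
        model = TitrationModel().fit(data)
        report = model.error_report("adapter")
        assert np.allclose(report["median"], 0.0, atol=1e-6)

    def test_planted_adapter_bias_recovered(self):
        data, _ = simulate_titration(
            ["t1", "t2", "t3"],
            {t: 1.0 for t in ("t1", "t2", "t3")},
            {t: 85.0 for t in ("t1", "t2", "t3")},
            {t: 6.0 for t in ("t1", "t2", "t3")},
            n_reps=8,
            noise_sd=1.0,
            adapter_bias_pp={"I2Sp": 3.0},
            seed=7,
        )
        report = TitrationModel().fit(data).error_report("adapter").set_index("bin")
        assert 2.0 <= report.loc["I2Sp", "median"] <= 4.0

    def test_bins_partition_measurements(self):
        data, _ = simulate_titration(
            ["t1"], {"t1": 1.0}, {"t1": 85.0}, {"t1": 6.0}, n_reps=4, noise_sd=0.5
        )
        report = TitrationModel().fit(data).error_report("adapter")
        n_interior = len(data[(data.ratio_p != 100.0) & (data.ratio_p != 0.0)])
        assert report["count"].sum() == n_interior


class TestDecayValue:
    def test_closed_form_points(self):
        assert decay_value(0.0, 90.0, 120.0, 2.0) == pytest.approx(92.0)
        assert decay_value(120.0, 90.0, 120.0, 2.0) == pytest.approx(47.0)
        assert decay_value(20 * 120.0, 90.0, 120.0, 2.0) == pytest.approx(2.0000858, abs=1e-6)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 5000, 400)
        v = decay_value(t, 90.0, 120.0, 2.0)
        assert (np.diff(v) < 0).all()


class TestDecayFit:
    def test_noise_free_recovery(self):
        series, _ = simulate_decay({"g": (90.0, 120.0, 2.0)}, noise_sd=0.0)
        fit = fit_decay(series)["g"]
        assert fit.n0 == pytest.approx(90.0, rel=1e-4)
        assert fit.t_half == pytest.approx(120.0, rel=1e-4)
        assert fit.n_inf == pytest.approx(2.0, rel=1e-3, abs=1e-4)
        assert fit.charge_at_t0 == pytest.approx(92.0, rel=1e-4)

    def test_default_design_dimensions(self):
        series, _ = simulate_decay({"g": (90.0, 120.0, 2.0)}, noise_sd=0.0)
        assert series.time_min.nunique() == 11  # t=0 plus the 10 sampled times
        assert series.groupby("time_min").size().eq(4).all()

    def test_noisy_t_half_within_10pct(self):
        series, _ = simulate_decay({"g": (90.0, 120.0, 2.0)}, noise_sd=1.0, seed=13)
        fit = fit_decay(series)["g"]
        assert fit.t_half == pytest.approx(120.0, rel=0.10)

    def test_objective_no_worse_than_truth(self):
        series, _ = simulate_decay({"g": (80.0, 300.0, 1.0)}, noise_sd=0.0)
        fit = fit_decay(series)["g"]
        t = series.time_min.to_numpy()
        y = series.charge.to_numpy()
        rss_truth = float(np.sum((decay_value(t, 80.0, 300.0, 1.0) - y) ** 2))
        assert fit.rss <= rss_truth + 1e-9

    def test_non_decaying_series_pins_t_half(self):
        series, _ = simulate_decay({"g": (90.0, 1e5, 2.0)}, noise_sd=0.0)
        fit = fit_decay(series)["g"]
        assert fit.t_half >= 1e4  # effectively unidentifiable, near the bound

    def test_requires_three_timepoints(self):
        series = pd.DataFrame(
            {"group": ["g"] * 4, "time_min": [0, 0, 60, 60], "replicate": [0, 1, 0, 1],
             "charge": [90, 90, 50, 50]}
        )
        with pytest.raises(ValueError, match="timepoints"):
            fit_decay(series)


class TestBootstrap:
    def test_zero_noise_zero_width(self):
        series, _ = simulate_decay({"g": (90.0, 120.0, 2.0)}, noise_sd=0.0)
        ci = DecayModel(n_boot=50, seed=1).fit(series).fits_["g"].ci95
        for lo, hi in ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_fixed_seed_reproducible(self):
        series, _ = simulate_decay({"g": (90.0, 120.0, 2.0)}, noise_sd=1.0, seed=3)
        a = DecayModel(n_boot=100, seed=5).fit(series).fits_["g"].ci95
        b = DecayModel(n_boot=100, seed=5).fit(series).fits_["g"].ci95
        assert a == b

    def test_ci_covers_truth_in_most_groups(self):
        """t_half CI covers the generating value for >= 90% of groups."""
        truth_vals = {f"g{i}": (85.0, 60.0 * (1.5 ** (i % 6)), 1.5) for i in range(20)}
        series, _ = simulate_decay(truth_vals, noise_sd=1.0, seed=29)
        model = DecayModel(n_boot=200, seed=11).fit(series)
        covered = sum(
            1
            for gid, (n0, th, ninf) in truth_vals.items()
            if model.fits_[gid].ci95["t_half"][0] <= th <= model.fits_[gid].ci95["t_half"][1]
        )
        assert covered / len(truth_vals) >= 0.9
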