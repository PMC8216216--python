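"""Psi interpolation, PGD normalisation, plateau logic, sigmoid fitting, traits."""

import math
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import pneumatron as pn
from pneumatron.errors import (
    DegenerateNormalizationError,
    FormatError,
    InsufficientDataError,
    PlateauWarning,
)

T0 = datetime(2024, 1, 1, 8, 0, 0)


def psi_frame(hours, psis):
    return pd.DataFrame({
        "datetime": [T0 + timedelta(hours=h) for h in hours],
        "psy": psis,
    })


class TestPsiCsv:
    def test_reads_the_documented_format(self, tmp_path):
        p = tmp_path / "psi.csv"
        p.write_text("date,hour,psy\n01/01/2024,08:00,-0.5\n01/01/2024,10:30,-1.2\n")
        df = pn.read_psi_csv(p)
        assert list(df.columns) == ["datetime", "psy"]
        assert df["datetime"].iloc[1] == pd.Timestamp("2024-01-01 10:30")
        assert df["psy"].iloc[1] == -1.2

    def test_wrong_headers_error_names_the_contract(self, tmp_path):
        p = tmp_path / "psi.csv"
        p.write_text("day,time,wp\n01/01/2024,08:00,-0.5\n")
        with pytest.raises(FormatError, match='"date", "hour", "psy"'):
            pn.read_psi_csv(p)

    def test_positive_water_potential_rejected(self, tmp_path):
        p = tmp_path / "psi.csv"
        p.write_text("date,hour,psy\n01/01/2024,08:00,0.5\n")
        with pytest.raises(FormatError, match="<= 0"):
            pn.read_psi_csv(p)

    def test_wrong_date_format_rejected(self, tmp_path):
        p = tmp_path / "psi.csv"
        p.write_text("date,hour,psy\n2024-01-01,08:00,-0.5\n")
        with pytest.raises(FormatError, match="dd/mm/yyyy"):
            pn.read_psi_csv(p)


class TestInterpolatePsi:
    def test_midpoint(self):
        grid = pn.interpolate_psi(psi_frame([0, 2], [-1.0, -2.0]))
        at_1h = grid[grid["datetime"] == T0 + timedelta(hours=1)]
        assert at_1h["psi"].iloc[0] == pytest.approx(-1.5)

    def test_default_grid_spacing_is_15_min(self):
        grid = pn.interpolate_psi(psi_frame([0, 2], [-1.0, -2.0]))
        spacing = grid["datetime"].diff().dropna().unique()
        assert list(spacing) == [pd.Timedelta(minutes=15)]
        assert len(grid) == 9  # 2 h inclusive

    def test_no_extrapolation_outside_observations(self):
        grid = pn.interpolate_psi(psi_frame([1, 3], [-1.0, -2.0]))
        assert grid["datetime"].min() == T0 + timedelta(hours=1)
        assert grid["datetime"].max() <= T0 + timedelta(hours=3)

    def test_affine_schedule_reproduced_exactly(self):
        # psi(t) = -0.4 - 0.3 t(h), sampled irregularly
        hours = [0, 0.7, 2.3, 5.0, 9.0]
        psis = [-0.4 - 0.3 * h for h in hours]
        grid = pn.interpolate_psi(psi_frame(hours, psis))
        t_h = (grid["datetime"] - T0).dt.total_seconds() / 3600.0
        assert np.allclose(grid["psi"], -0.4 - 0.3 * t_h, atol=1e-12)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(FormatError):
            pn.interpolate_psi(psi_frame([1, 1], [-1.0, -2.0]))

    def test_too_few_measurements(self):
        with pytest.raises(InsufficientDataError):
            pn.interpolate_psi(psi_frame([1], [-1.0]))


class TestMatchPsiToCycles:
    def _gd(self, minutes):
        return pd.DataFrame({
            "measurement_id": range(1, len(minutes) + 1),
            "datetime": [T0 + timedelta(minutes=m) for m in minutes],
            "gd": np.linspace(10, 100, len(minutes)),
        })

    def test_cycle_on_grid_point_pairs_exactly(self):
        grid = pn.interpolate_psi(psi_frame([0, 2], [-1.0, -2.0]))
        matched, dropped = pn.match_psi_to_cycles(grid, self._gd([15, 30]))
        assert dropped == 0
        assert matched["psi"].tolist() == pytest.approx([-1.125, -1.25])

    def test_cycle_beyond_tolerance_dropped(self):
        grid = pn.interpolate_psi(psi_frame([0, 1], [-1.0, -2.0]))
        with pytest.warns(UserWarning, match="dropped"):
            matched, dropped = pn.match_psi_to_cycles(grid, self._gd([30, 80]))
        assert dropped == 1 and len(matched) == 1

    def test_partial_coverage_counts(self):
        # 40 cycles every 15 min; psi record covers only the first ~7.5 h
        grid = pn.interpolate_psi(psi_frame([0, 7.35], [-1.0, -4.0]))
        gd = self._gd([15 * c for c in range(40)])
        with pytest.warns(UserWarning):
            matched, dropped = pn.match_psi_to_cycles(grid, gd)
        assert len(matched) == 30 and dropped == 10


class TestPlateaus:
    def test_rising_then_flat_tail_accepted(self):
        gd = np.concatenate([np.linspace(10, 100, 10),
                             100 * (1 + 0.005 * np.sin(np.arange(8)))])
        res = pn.detect_plateaus(gd)
        assert res.plateau_ok
        assert res.gd_min == pytest.approx(gd[:3].mean())
        assert res.gd_max == pytest.approx(gd[-8:].mean(), rel=0.02)

    def test_strictly_rising_series_flags_premature_stop(self):
        gd = np.linspace(10, 100, 12)
        with pytest.warns(PlateauWarning, match="prematurely"):
            res = pn.detect_plateaus(gd)
        assert not res.plateau_ok
        assert res.gd_max == pytest.approx(100.0)

    def test_constant_series_degenerates_at_normalisation(self):
        gd = np.full(10, 50.0)
        res = pn.detect_plateaus(gd)
        assert res.gd_max == res.gd_min
        with pytest.raises(DegenerateNormalizationError):
            pn.normalize_pgd(gd, res.gd_min, res.gd_max)

    def test_too_few_cycles(self):
        with pytest.raises(InsufficientDataError):
            pn.detect_plateaus([1, 2, 3, 4, 5])


class TestNormalizePgd:
    @pytest.mark.parametrize("gd, expected", [(10.0, 0.0), (110.0, 100.0), (35.0, 25.0)])
    def test_endpoints_and_interior(self, gd, expected):
        assert pn.normalize_pgd(gd, 10.0, 110.0) == pytest.approx(expected)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(DegenerateNormalizationError):
            pn.normalize_pgd(5.0, 10.0, 10.0)

    def test_clamping_is_display_only(self):
        raw = pn.normalize_pgd(np.array([5.0, 60.0, 115.0]), 10.0, 110.0)
        clipped, mask = pn.clamp_pgd(raw)
        assert raw[0] < 0 and clipped[0] == 0.0
        assert mask.tolist() == [True, False, True]


class TestSigmoidFit:
    def test_noiseless_curve_matches_logit_closed_form(self):
        a_true, psi50_true = 2.0, -3.0
        psi = np.linspace(-6.0, -0.5, 25)
        pgd = pn.sigmoid_pgd(psi, a_true, psi50_true)
        # independent oracle: straight-line logit regression, closed form
        y = np.log((100.0 - pgd) / pgd)
        slope, intercept = np.polyfit(psi, y, 1)
        a_oracle, psi50_oracle = slope, -intercept / slope
        fit = pn.fit_sigmoid(psi, pgd)
        assert fit.a == pytest.approx(a_oracle, abs=1e-6)
        assert fit.psi50 == pytest.approx(psi50_oracle, abs=1e-6)
        assert fit.a == pytest.approx(a_true, abs=1e-6)

    def test_model_value_at_psi50_is_50(self):
        fit_val = pn.sigmoid_pgd(-2.2, 1.7, -2.2)
        assert fit_val == pytest.approx(50.0)

    def test_noisy_recovery_within_band(self):
        rng = np.random.default_rng(3)
        psi = np.linspace(-6.5, -0.5, 40)
        pgd = pn.sigmoid_pgd(psi, 2.0, -3.0) + rng.normal(0, 2.0, psi.size)
        fit = pn.fit_sigmoid(psi, pgd)
        assert fit.psi50 == pytest.approx(-3.0, abs=0.15)
        assert fit.a == pytest.approx(2.0, rel=0.15)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            pn.fit_sigmoid([-1, -2, -3, -4], [10, 30, 70, 90])

    def test_missing_tail_warns(self):
        psi = np.linspace(-2.5, -0.5, 10)
        pgd = pn.sigmoid_pgd(psi, 2.0, -3.0)  # never exceeds 80%
        with pytest.warns(UserWarning, match="tail"):
            pn.fit_sigmoid(psi, pgd)


class TestTraits:
    def test_hand_computed_p12_p88(self):
        p12, p88 = pn.traits_from_fit(2.0, -3.0)
        assert p12 == pytest.approx(-3.0 + math.log(88 / 12) / 2.0)
        assert p12 == pytest.approx(-2.004, abs=1e-3)
        assert p88 == pytest.approx(-3.996, abs=1e-3)

    @given(a=st.floats(0.2, 20.0), psi50=st.floats(-10.0, -0.5))
    def test_symmetry_and_ordering(self, a, psi50):
        p12, p88 = pn.traits_from_fit(a, psi50)
        assert p12 >= psi50 >= p88
        assert (p12 - psi50) == pytest.approx(psi50 - p88, rel=1e-9)

    def test_steep_curve_collapses_to_psi50(self):
        p12, p88 = pn.traits_from_fit(1e9, -3.0)
        assert p12 == pytest.approx(-3.0, abs=1e-6)
        assert p88 == pytest.approx(-3.0, abs=1e-6)

    def test_non_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            pn.traits_from_fit(0.0, -3.0)


class TestNearestTraits:
    def test_exact_pgd_values_present(self):
        pts = pd.DataFrame({"psi": [-1.0, -2.0, -3.0], "pgd": [12.0, 50.0, 88.0]})
        near = pn.nearest_traits(pts)
        assert near == {"p12_near": -1.0, "p50_near": -2.0, "p88_near": -3.0}

    def test_tie_breaks_toward_less_negative_psi(self):
        pts = pd.DataFrame({"psi": [-1.5, -2.5], "pgd": [40.0, 60.0]})
        assert pn.nearest_traits(pts)["p50_near"] == -1.5

    def test_dense_sampling_agrees_with_fitted_traits(self):
        psi = np.linspace(-6.0, -0.5, 200)
        pts = pd.DataFrame({"psi": psi, "pgd": pn.sigmoid_pgd(psi, 2.0, -3.0)})
        near = pn.nearest_traits(pts)
        p12, p88 = pn.traits_from_fit(2.0, -3.0)
        step = psi[1] - psi[0]
        assert abs(near["p50_near"] - (-3.0)) <= step
        assert abs(near["p12_near"] - p12) <= step
        assert abs(near["p88_near"] - p88) <= step


class TestResultsFile:
    def _result(self, plateau_ok=True):
        return pn.VCResult(gd_min=10.0, gd_max=110.0, a=2.0,
                           p50_pad=-3.0, p12_pad=-2.0, p88_pad=-4.0,
                           p50_near=-2.9, p12_near=-2.1, p88_near=-3.9,
                           plateau_ok=plateau_ok, residual_se=1.5, n_points=40)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "results.csv"
        pn.write_results(self._result(), path, provenance={"config_hash": "abc"})
        back = pn.read_results(path)
        assert back["p50.pad"].iloc[0] == -3.0
        assert back["a"].iloc[0] == 2.0
        assert bool(back["plateau_ok"].iloc[0]) is True
        assert "config_hash" in path.read_text()

    def test_exact_column_contract(self, tmp_path):
        path = tmp_path / "results.csv"
        pn.write_results(self._result(plateau_ok=False), path)
        back = pn.read_results(path)
        assert list(back.columns) == ["p50.pad", "p12.pad", "p88.pad",
                                      "p50_near", "p12_near", "p88_near",
                                      "a", "gd_min", "gd_max", "plateau_ok"]
        assert bool(back["plateau_ok"].iloc[0]) is False

    def test_trait_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            pn.VCResult(gd_min=10.0, gd_max=110.0, a=2.0,
                        p50_pad=-3.0, p12_pad=-4.0, p88_pad=-2.0,
                        p50_near=-3.0, p12_near=-2.0, p88_near=-4.0,
                        plateau_ok=True, residual_se=1.0, n_points=10)
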