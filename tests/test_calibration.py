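"""1/x-weighted calibration: oracle equivalence, linearity review, PAR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmrm.calibration import (
    CalibrationError,
    compute_par,
    fit_calibration,
    par_table,
    review_linearity,
)
from soilmrm.model import DEFAULT_CAL_LEVELS

from conftest import make_small_config


def wls_normal_equations(x, y, w):
    """Independent weighted least-squares oracle via the normal equations."""
    x, y, w = map(np.asarray, (x, y, w))
    sw, swx = w.sum(), (w * x).sum()
    swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    denom = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy * swxx - swx * swxy) / denom
    return intercept, slope


def _measurement_rows(sample_id, areas):
    rows = []
    for sid, area in areas.items():
        for role, a in (("quantifier", area), ("qualifier", area * 0.4)):
            rows.append(
                {
                    "sample_id": sample_id,
                    "species_id": sid,
                    "transition_role": role,
                    "peak_area": a,
                    "snr": a / 100.0,
                    "rt": 8.0,
                }
            )
    return rows


class TestPeakAreaRatio:
    def test_equal_areas_give_unit_par(self, small_config):
        meas = pd.DataFrame(
            _measurement_rows("s1", {"anA": 5000.0, "anB": 1.0, "ilA": 5000.0, "ilB": 1.0})
        )
        par, defined = compute_par(meas, small_config, "s1", "anA")
        assert defined and par == pytest.approx(1.0)

    def test_stereoisomer_areas_are_summed(self):
        config = make_small_config()
        # make anA and anB a stereoisomer pair quantified against ilA
        analytes = [
            a.model_copy(update={"stereoisomer_group": "g1", "si_ilis_id": None,
                                 "assigned_ilis_id": "ilA"})
            for a in config.analytes
        ]
        config = config.model_copy(update={"analytes": analytes})
        meas = pd.DataFrame(
            _measurement_rows("s1", {"anA": 3000.0, "anB": 2000.0, "ilA": 10000.0, "ilB": 1.0})
        )
        par, defined = compute_par(meas, config, "s1", "anA")
        assert defined and par == pytest.approx(0.5)

    def test_zero_ilis_area_flags_undefined(self, small_config):
        meas = pd.DataFrame(
            _measurement_rows("s1", {"anA": 5000.0, "anB": 1.0, "ilA": 0.0, "ilB": 1.0})
        )
        par, defined = compute_par(meas, small_config, "s1", "anA")
        assert not defined and np.isnan(par)


class TestWeightedFit:
    def test_exact_line_recovered(self):
        x = np.array(DEFAULT_CAL_LEVELS)
        curve = fit_calibration(x, 0.1 * x, analyte_id="a")
        assert curve.slope == pytest.approx(0.1, rel=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = np.array(DEFAULT_CAL_LEVELS)
        y = 0.1 * x * np.exp(rng.normal(0, 0.05, len(x)))  # heteroscedastic
        curve = fit_calibration(x, y, analyte_id="a")
        a0, b0 = wls_normal_equations(x, y, 1.0 / x)
        assert curve.slope == pytest.approx(b0, rel=1e-10)
        assert curve.intercept == pytest.approx(a0, rel=1e-10, abs=1e-14)

    def test_duplicate_standards_enter_individually(self):
        x = np.repeat(DEFAULT_CAL_LEVELS, 2)
        rng = np.random.default_rng(1)
        y = 0.1 * x + rng.normal(0, 0.001, len(x))
        curve = fit_calibration(x, y, analyte_id="a")
        assert len(curve.level_backcalc) == 24
        assert curve.n_levels_used == 12

    def test_too_few_levels_rejected(self):
        with pytest.raises(CalibrationError, match="usable levels"):
            fit_calibration([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])

    def test_zero_level_rejected(self):
        with pytest.raises(CalibrationError, match="non-positive"):
            fit_calibration([0, 1, 2, 3, 4, 5], [0, 0.1, 0.2, 0.3, 0.4, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(c=st.floats(0.01, 100), seed=st.integers(0, 10))
    def test_scale_equivariance(self, c, seed):
        """PAR x c scales slope/intercept by c; R^2 and backcalc unchanged."""
        rng = np.random.default_rng(seed)
        x = np.array(DEFAULT_CAL_LEVELS)
        y = 0.2 * x * np.exp(rng.normal(0, 0.03, len(x)))
        base = fit_calibration(x, y, analyte_id="a")
        scaled = fit_calibration(x, c * y, analyte_id="a")
        assert scaled.slope == pytest.approx(c * base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(c * base.intercept, rel=1e-9, abs=1e-12)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)
        np.testing.assert_allclose(
            scaled.level_backcalc["backcalc"], base.level_backcalc["backcalc"], rtol=1e-9
        )


class TestLinearityReview:
    def _curve_with_backcalc(self, nominal, backcalc):
        curve = fit_calibration(
            np.array(DEFAULT_CAL_LEVELS), 0.1 * np.array(DEFAULT_CAL_LEVELS), "a"
        )
        curve.level_backcalc = pd.DataFrame(
            {"nominal": nominal, "par": 0.1 * np.array(backcalc), "backcalc": backcalc,
             "deviation_pct": 100 * (np.array(backcalc) / np.array(nominal) - 1)}
        )
        return curve

    def test_twenty_percent_boundary_inclusive(self):
        nominal = list(DEFAULT_CAL_LEVELS)
        backcalc = list(DEFAULT_CAL_LEVELS)
        backcalc[1] = 0.12  # +20% at the 0.1 level: still passes
        curve = self._curve_with_backcalc(nominal, backcalc)
        per_level = review_linearity(curve)
        assert bool(per_level.set_index("nominal").loc[0.1, "passes"])

    def test_beyond_tolerance_fails_and_trims_edge(self):
        nominal = list(DEFAULT_CAL_LEVELS)
        backcalc = list(DEFAULT_CAL_LEVELS)
        backcalc[0] = 0.063  # +26% at the lowest level
        curve = self._curve_with_backcalc(nominal, backcalc)
        per_level = review_linearity(curve)
        assert not bool(per_level.set_index("nominal").loc[0.05, "passes"])
        assert curve.linear_low == pytest.approx(0.1)
        assert curve.linear_high == pytest.approx(50.0)

    def test_interior_failure_flagged_not_trimmed(self):
        nominal = list(DEFAULT_CAL_LEVELS)
        backcalc = list(DEFAULT_CAL_LEVELS)
        backcalc[5] = 2.5 * 1.3  # interior level off by +30%
        curve = self._curve_with_backcalc(nominal, backcalc)
        review_linearity(curve)
        assert curve.interior_failures == [2.5]
        assert (curve.linear_low, curve.linear_high) == (0.05, 50.0)

    def test_noise_free_range_spans_all_levels(self):
        curve = fit_calibration(
            np.array(DEFAULT_CAL_LEVELS), 0.1 * np.array(DEFAULT_CAL_LEVELS), "a"
        )
        review_linearity(curve)
        assert (curve.linear_low, curve.linear_high) == (0.05, 50.0)

    def test_all_levels_failing_raises(self):
        nominal = list(DEFAULT_CAL_LEVELS)
        backcalc = [n * 2.0 for n in nominal]
        curve = self._curve_with_backcalc(nominal, backcalc)
        with pytest.raises(CalibrationError, match="no calibration level"):
            review_linearity(curve)
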