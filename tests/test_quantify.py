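"""Concentration conversion, censoring, summaries and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from soilmrm.calibration import CalibrationCurve
from soilmrm.model import SampleRecord, SoilMeta
from soilmrm.io import design_frame
from soilmrm.quantify import (
    compare_groups,
    percentage_difference,
    quantify,
    summarize_site,
)

from conftest import make_small_config


def _curve(slope=0.1, low=0.05, high=50.0):
    return CalibrationCurve(
        analyte_id="anA", slope=slope, intercept=0.0, r_squared=1.0,
        r_squared_unweighted=1.0, linear_low=low, linear_high=high,
    )


def _inputs(par, soil_mass_g=5.0, extract_volume_mL=5.0, mloq=0.2,
            rt_pass=True, ratio_pass=True, par_defined=True, water_pct=0.0):
    pars = pd.DataFrame(
        {
            "sample_id": ["f1"],
            "analyte_id": ["anA"],
            "ilis_id": ["ilA"],
            "analyte_area": [1.0],
            "ilis_area": [1.0],
            "par": [par],
            "par_defined": [par_defined],
        }
    )
    qc = pd.DataFrame(
        {
            "sample_id": ["f1"],
            "analyte_id": ["anA"],
            "rt_pass": [rt_pass],
            "ratio_pass": [ratio_pass],
        }
    )
    mloqs = pd.DataFrame(
        {
            "analyte_id": ["anA"],
            "iloq_ng_mL": [0.025],
            "base_mloq_ng_g": [mloq / 2],
            "corrected_mloq_ng_g": [mloq],
            "factor_used": [2.0],
        }
    )
    design = design_frame(
        [
            SampleRecord(
                sample_id="f1",
                soil_id="S1",
                role="field",
                soil_mass_g=soil_mass_g,
                extract_volume_mL=extract_volume_mL,
            )
        ]
    )
    soils = {"S1": SoilMeta(soil_id="S1", c_org_pct=2.0, ph=7.0, water_content_pct=water_pct)}
    return pars, qc, mloqs, design, soils


class TestQuantify:
    def _run(self, par, curve=None, **kw):
        config = make_small_config()
        pars, qc, mloqs, design, soils = _inputs(par, **kw)
        return quantify(pars, {"anA": curve or _curve()}, qc, mloqs, design, config, soils)

    def test_unit_identity_at_one_gram_per_ml(self):
        # PAR on the fitted line at 2.5 ng/mL, 5 g / 5 mL -> 2.5 ng/g
        out = self._run(0.1 * 2.5)
        assert out.loc[0, "censor"] == "quantified"
        assert out.loc[0, "conc_ng_g"] == pytest.approx(2.5, rel=1e-12)

    def test_below_mloq_censored(self):
        out = self._run(0.1 * 0.12, mloq=0.2)
        assert out.loc[0, "censor"] == "below_mloq"
        assert np.isnan(out.loc[0, "conc_ng_g"])

    def test_above_linear_range_flagged_for_redilution(self):
        out = self._run(0.1 * 60.0)
        assert out.loc[0, "censor"] == "above_linear_range"

    def test_failed_identification_is_unconfirmed(self):
        out = self._run(0.1 * 2.5, ratio_pass=False)
        assert out.loc[0, "censor"] == "unconfirmed"

    def test_undefined_par_is_ilis_missing(self):
        out = self._run(np.nan, par_defined=False)
        assert out.loc[0, "censor"] == "ilis_missing"

    def test_doubling_soil_mass_halves_concentration(self):
        c1 = self._run(0.1 * 2.5).loc[0, "conc_ng_g"]
        c2 = self._run(0.1 * 2.5, soil_mass_g=10.0).loc[0, "conc_ng_g"]
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)

    def test_undried_soil_uses_dry_weight(self):
        # 6.25 g at 20% water = 5 g dry weight: same result as dried 5 g
        c1 = self._run(0.1 * 2.5).loc[0, "conc_ng_g"]
        c2 = self._run(0.1 * 2.5, soil_mass_g=6.25, water_pct=20.0).loc[0, "conc_ng_g"]
        assert c2 == pytest.approx(c1, rel=1e-12)

    def test_censoring_monotone_in_mloq(self):
        """Raising the MLOQ never increases the detection count or sum."""
        detections, sums = [], []
        for mloq in (0.1, 1.0, 3.0, 10.0):
            out = self._run(0.1 * 2.5, mloq=mloq)
            s = summarize_site(out)
            detections.append(s["n_detected"])
            sums.append(s["sum_conc_ng_g"])
        assert detections == sorted(detections, reverse=True)
        assert sums == sorted(sums, reverse=True)


class TestSummaries:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["analyte_id", "censor", "substituted_ng_g"]
        )

    def test_all_censored_empty_summary(self):
        recs = self._records([["a", "below_mloq", 0.0], ["b", "below_mloq", 0.0]])
        s = summarize_site(recs)
        assert (s["n_detected"], s["sum_conc_ng_g"]) == (0, 0.0)

    def test_detects_sum_and_censored_contribute_zero(self):
        recs = self._records(
            [["a", "quantified", 2.0], ["b", "quantified", 3.0], ["c", "below_mloq", 0.0]]
        )
        s = summarize_site(recs)
        assert s["n_detected"] == 2
        assert s["sum_conc_ng_g"] == pytest.approx(5.0)


class TestGroupComparisons:
    @pytest.mark.parametrize(
        "x,y,expected", [(10.0, 10.0, 0.0), (10.0, 8.7, 13.0), (8.0, 10.0, -25.0)]
    )
    def test_percentage_difference(self, x, y, expected):
        assert percentage_difference(x, y) == pytest.approx(expected)

    def test_percentage_difference_undefined_at_zero(self):
        assert np.isnan(percentage_difference(0.0, 5.0))

    def test_identical_groups_not_significant(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert not res["significant"]

    def test_clear_shift_is_significant(self):
        res = compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res["significant"] and res["t_p"] < 0.001

    def test_t_statistic_matches_pooled_variance_formula(self):
        a = np.array([1.2, 2.9, 3.1])
        b = np.array([2.0, 2.5, 4.4])
        res = compare_groups(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res["t_stat"] == pytest.approx(t_hand, rel=1e-12)

    def test_zero_variance_equal_means_convention(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert res["t_p"] == 1.0 and not res["significant"]
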