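"""Matrix-effect arithmetic, the global correction factor, and LOQ rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmrm.matrix_effects import (
    correction_factor,
    derive_global_factor,
    determine_iloq,
    determine_mloq,
    matrix_effect,
    summarize_matrix_effects,
)


def matrix_effect_oracle(spiked, unspiked, reference):
    """Independently coded arithmetic for the matrix-effect definition."""
    return -100.0 * (1.0 - (spiked - unspiked) / reference)


class TestMatrixEffect:
    @pytest.mark.parametrize(
        "spiked,unspiked,ref,expected",
        [
            (1000.0, 0.0, 1000.0, 0.0),
            (600.0, 100.0, 1000.0, -50.0),
            (1300.0, 100.0, 1000.0, 20.0),
        ],
    )
    def test_hand_substitution(self, spiked, unspiked, ref, expected):
        assert matrix_effect(spiked, unspiked, ref) == pytest.approx(expected, abs=1e-12)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            matrix_effect(100.0, 0.0, 0.0)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        spiked = rng.uniform(1, 1e6, 10_000)
        unspiked = rng.uniform(0, 1e5, 10_000)
        ref = rng.uniform(1, 1e6, 10_000)
        got = matrix_effect(spiked, unspiked, ref)
        np.testing.assert_allclose(got, matrix_effect_oracle(spiked, unspiked, ref), rtol=1e-12)

    def test_self_reference_is_exactly_zero(self):
        # case (ii) applied to the reference soil itself
        assert matrix_effect(900.0, 150.0, 900.0 - 150.0) == 0.0

    def test_summary(self):
        effects = pd.DataFrame(
            {"analyte_id": list("abc"), "soil_id": "S1",
             "matrix_effect_pct": [0.0, -10.0, -20.0], "reference_case": "s2_extract"}
        )
        summary = summarize_matrix_effects(effects)
        assert summary.loc[0, "median"] == pytest.approx(-10.0)


def _effects(values, soil="S3"):
    return pd.DataFrame(
        {
            "analyte_id": [f"a{k}" for k in range(len(values))],
            "soil_id": soil,
            "matrix_effect_pct": values,
            "reference_case": "s2_extract",
        }
    )


class TestGlobalFactor:
    def test_fifty_percent_suppression_gives_factor_two(self):
        assert correction_factor(50.0) == 2.0

    def test_moderate_suppression_rounds_up(self):
        # many analytes between -20% and -5%: s = 20 is the first grid value
        # leaving <= 3 exceedances; 1/(1 - 0.2) = 1.25 rounds up to 1.5
        values = [-18.0] * 10 + [-2.0] * 10
        res = derive_global_factor(_effects(values), max_exceedances=3)
        assert res.max_suppression_pct == 20.0
        assert res.factor == 1.5

    def test_zero_suppression_gives_factor_one(self):
        res = derive_global_factor(_effects([0.0, 5.0, 12.0]))
        assert res.factor == 1.0

    def test_exceeding_analytes_are_flagged(self):
        # three analytes beyond -50%, the rest spread up to -49%
        values = [-60.0, -55.0, -52.0] + list(np.linspace(-49.0, -1.0, 143))
        res = derive_global_factor(_effects(values), max_exceedances=3)
        assert res.max_suppression_pct == 50.0
        assert res.factor == 2.0
        assert res.exceeding_analytes == ["a0", "a1", "a2"]

    def test_wrong_reference_case_rejected(self):
        eff = _effects([-10.0])
        eff["reference_case"] = "solvent_standard"
        with pytest.raises(ValueError, match="case ii"):
            derive_global_factor(eff)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        values=st.lists(st.floats(-90, 50), min_size=5, max_size=40),
        shift=st.floats(0, 20),
        k1=st.integers(0, 5),
        k2=st.integers(0, 5),
    )
    def test_monotonicity(self, values, shift, k1, k2):
        """Factor is non-decreasing in suppression magnitude and
        non-increasing in the allowed exceedance count."""
        base = derive_global_factor(_effects(values), max_exceedances=k1).factor
        worse = derive_global_factor(
            _effects([v - shift for v in values]), max_exceedances=k1
        ).factor
        assert worse >= base
        lo, hi = sorted([k1, k2])
        f_strict = derive_global_factor(_effects(values), max_exceedances=lo).factor
        f_loose = derive_global_factor(_effects(values), max_exceedances=hi).factor
        assert f_loose <= f_strict


class TestLoqs:
    def test_iloq_proportional_snr(self):
        levels = [0.005, 0.01, 0.025, 0.05]
        snr_q = [2.0, 4.0, 10.0, 20.0]
        snr_l = [1.0, 2.0, 5.0, 10.0]
        assert determine_iloq(levels, snr_q, snr_l) == pytest.approx(0.025)

    def test_iloq_qualifier_never_reaches_three(self):
        assert np.isnan(determine_iloq([0.1, 1.0], [50.0, 500.0], [1.0, 2.0]))

    def test_iloq_boundary_inclusive(self):
        assert determine_iloq([0.1], [10.0], [3.0]) == pytest.approx(0.1)

    def test_mloq_correction(self):
        rec = determine_mloq([0.05, 0.1, 0.25], [5.0, 12.0, 30.0], [2.0, 6.0, 15.0],
                             [True, True, True], factor=2.0, analyte_id="a")
        assert rec.base_mloq_ng_g == pytest.approx(0.1)
        assert rec.corrected_mloq_ng_g == pytest.approx(0.2)

    def test_mloq_factor_one_keeps_base(self):
        rec = determine_mloq([5.0], [100.0], [30.0], [True], factor=1.0)
        assert rec.corrected_mloq_ng_g == rec.base_mloq_ng_g == pytest.approx(5.0)

    def test_mloq_high_base_with_factor_two(self):
        rec = determine_mloq([5.0], [100.0], [30.0], [True], factor=2.0)
        assert rec.corrected_mloq_ng_g == pytest.approx(10.0)

    def test_mloq_requires_ratio_match(self):
        rec = determine_mloq([0.1, 0.25], [12.0, 30.0], [6.0, 15.0], [False, True], 2.0)
        assert rec.base_mloq_ng_g == pytest.approx(0.25)

    def test_mloq_none_qualify(self):
        rec = determine_mloq([0.1], [5.0], [1.0], [True], 2.0)
        assert np.isnan(rec.base_mloq_ng_g) and np.isnan(rec.corrected_mloq_ng_g)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            determine_mloq([0.1], [12.0], [6.0], [True], factor=0.5)
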