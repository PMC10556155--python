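"""Domain-type invariants and config/measurement round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmrm.io import (
    read_measurements,
    read_method_config,
    validate_measurements,
    write_measurements,
    write_method_config,
    ValidationError,
)
import pydantic

from soilmrm.model import (
    MethodConfig,
    SampleRecord,
    dry_weight_equivalent,
    ilis_spike_concentration,
)
from soilmrm.presets import default_scenario, full_method_config

from conftest import make_small_config


class TestMethodConfig:
    def test_species_and_transition_counts(self, small_config):
        assert len(small_config.species_ids) == 4
        assert len(small_config.transitions) == 8

    def test_full_method_has_two_transitions_per_species(self):
        config = full_method_config(default_scenario(0))
        assert len(config.analytes) == 146
        assert len(config.ilis) == 95
        # (146 + 95) species x 2 transitions
        assert len(config.transitions) == 482

    def test_unknown_si_ilis_reference_rejected(self):
        with pytest.raises(pydantic.ValidationError, match="unknown ILIS"):
            make_small_config(
                analytes=[
                    make_small_config().analytes[0].model_copy(
                        update={"si_ilis_id": "A-d5", "assigned_ilis_id": "A-d5"}
                    )
                ]
            )

    def test_duplicate_species_id_rejected(self):
        cfg = make_small_config()
        with pytest.raises(pydantic.ValidationError, match="duplicate"):
            MethodConfig(
                analytes=cfg.analytes + [cfg.analytes[0]],
                ilis=cfg.ilis,
                transitions=cfg.transitions,
            )

    def test_polarity_mismatch_rejected(self):
        cfg = make_small_config()
        bad_ilis = [i.model_copy(update={"polarity": "negative"}) if i.ilis_id == "ilA" else i
                    for i in cfg.ilis]
        with pytest.raises(pydantic.ValidationError, match="polarity"):
            MethodConfig(analytes=cfg.analytes, ilis=bad_ilis, transitions=cfg.transitions)

    def test_single_transition_rejected(self):
        cfg = make_small_config()
        with pytest.raises(pydantic.ValidationError, match="quantifier"):
            MethodConfig(
                analytes=cfg.analytes, ilis=cfg.ilis, transitions=cfg.transitions[:-1]
            )

    def test_cal_levels_must_increase(self):
        with pytest.raises(pydantic.ValidationError, match="increasing"):
            make_small_config(cal_levels=[1.0, 0.5, 2.0])

    def test_config_round_trip(self, small_config, tmp_path):
        path = tmp_path / "method.yaml"
        write_method_config(small_config, path)
        loaded = read_method_config(path)
        assert loaded == small_config

    def test_cal_standard_requires_level(self):
        with pytest.raises(pydantic.ValidationError, match="nominal_level"):
            SampleRecord(sample_id="s1", soil_id="S2", role="cal_standard")


class TestMeasurementTable:
    def _table(self, config, n_samples=3):
        rows = []
        for s in range(n_samples):
            for sid in config.species_ids:
                for role in ("quantifier", "qualifier"):
                    rows.append(
                        {
                            "sample_id": f"s{s}",
                            "species_id": sid,
                            "transition_role": role,
                            "peak_area": 1000.0,
                            "snr": 50.0,
                            "rt": 8.0,
                        }
                    )
        return pd.DataFrame(rows)

    def test_row_count(self, small_config):
        table = validate_measurements(self._table(small_config), small_config)
        assert len(table) == 3 * 4 * 2

    def test_negative_area_rejected(self, small_config):
        t = self._table(small_config)
        t.loc[0, "peak_area"] = -5.0
        with pytest.raises(ValidationError, match="negative peak area"):
            validate_measurements(t, small_config)

    def test_duplicate_row_rejected(self, small_config):
        t = self._table(small_config)
        t = pd.concat([t, t.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicated"):
            validate_measurements(t, small_config)

    def test_unknown_species_rejected(self, small_config):
        t = self._table(small_config)
        t.loc[0, "species_id"] = "ghost"
        with pytest.raises(ValidationError, match="unknown species"):
            validate_measurements(t, small_config)

    def test_orphan_sample_rejected(self, small_config):
        t = self._table(small_config)
        design = pd.DataFrame({"sample_id": ["s0", "s1"]})
        with pytest.raises(ValidationError, match="absent from design"):
            validate_measurements(t, small_config, design)

    def test_csv_round_trip(self, small_config, tmp_path):
        t = validate_measurements(self._table(small_config), small_config)
        path = tmp_path / "meas.csv"
        write_measurements(t, path)
        loaded = read_measurements(path, small_config)
        pd.testing.assert_frame_equal(loaded, t)


class TestDryWeight:
    @pytest.mark.parametrize(
        "mass,wc,expected",
        [(5.0, 0.0, 5.0), (5.0, 20.0, 4.0), (6.25, 20.0, 5.0)],
    )
    def test_known_values(self, mass, wc, expected):
        assert dry_weight_equivalent(mass, wc) == pytest.approx(expected, abs=1e-12)

    def test_saturated_water_content_rejected(self):
        with pytest.raises(ValueError):
            dry_weight_equivalent(5.0, 100.0)

    @settings(deadline=None, derandomize=True)
    @given(
        mass=st.floats(0.1, 100),
        wc1=st.floats(0, 90),
        wc2=st.floats(0, 90),
        c=st.floats(0.1, 10),
    )
    def test_linear_in_mass_and_decreasing_in_water(self, mass, wc1, wc2, c):
        assert dry_weight_equivalent(c * mass, wc1) == pytest.approx(
            c * dry_weight_equivalent(mass, wc1)
        )
        lo, hi = sorted([wc1, wc2])
        if hi > lo:
            assert dry_weight_equivalent(mass, hi) < dry_weight_equivalent(mass, lo)


def test_ilis_spike_concentration_tiers():
    # 100 uL of each MIX tier into 5 mL: 1, 5, 15 ng/mL
    assert ilis_spike_concentration(50.0) == pytest.approx(1.0)
    assert ilis_spike_concentration(250.0) == pytest.approx(5.0)
    assert ilis_spike_concentration(750.0) == pytest.approx(15.0)
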