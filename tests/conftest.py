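import pytest

from soilmrm.model import (
    AnalyteDef,
    IlisDef,
    MethodConfig,
    TransitionDef,
)


def _transitions(species_id, polarity, rt, prec=300.0):
    return [
        TransitionDef(
            species_id=species_id,
            role=role,
            precursor_mz=prec,
            product_mz=prec * frac,
            polarity=polarity,
            expected_rt=rt,
        )
        for role, frac in (("quantifier", 0.6), ("qualifier", 0.4))
    ]


def make_small_config(**overrides) -> MethodConfig:
    """Two analytes (one with si-ILIS), two ILIS, eight transitions."""
    analytes = [
        AnalyteDef(
            analyte_id="anA",
            name="analyte-A",
            pesticide_class="fungicide",
            polarity="positive",
            expected_rt=8.0,
            si_ilis_id="ilA",
        ),
        AnalyteDef(
            analyte_id="anB",
            name="analyte-B",
            pesticide_class="herbicide",
            polarity="positive",
            expected_rt=12.0,
            assigned_ilis_id="ilB",
        ),
    ]
    ilis = [
        IlisDef(ilis_id="ilA", name="A-label", polarity="positive", expected_rt=8.02,
                tier_concentration=750.0),
        IlisDef(ilis_id="ilB", name="B-label", polarity="positive", expected_rt=11.5,
                tier_concentration=250.0),
    ]
    transitions = (
        _transitions("anA", "positive", 8.0)
        + _transitions("anB", "positive", 12.0)
        + _transitions("ilA", "positive", 8.02)
        + _transitions("ilB", "positive", 11.5)
    )
    params = dict(analytes=analytes, ilis=ilis, transitions=transitions)
    params.update(overrides)
    return MethodConfig(**params)


@pytest.fixture
def small_config() -> MethodConfig:
    return make_small_config()


@pytest.fixture(scope="session")
def batch_result():
    """One fully processed synthetic validation batch (146 analytes)."""
    from soilmrm.pipeline import run_validation_batch

    return run_validation_batch(seed=1)
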