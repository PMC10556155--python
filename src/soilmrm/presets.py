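"""Ready-made scenarios, catalogs and batch designs.

`full_method_config` builds a synthetic catalog with the structure of the
reference soil multi-residue method: 146 analytes (60 fungicides, 30
herbicides, 26 insecticides, 4 acaricides, 4 rodenticides, 2 growth
regulators, 1 synergist, 19 transformation products), 95 ILIS each
structure-identical to one analyte, two MRM transitions per species, and a
12-level matrix-matched calibration from 0.05 to 50 ng/mL.  Negative-mode
electrospray covers 11 analytes without si-ILIS and 8 ILIS; everything
else ionises positive.

`validation_design` assembles the full validation batch: duplicate
calibration standards, matrix blanks, pre-extraction spikes in five soils,
the post-extraction-spike matrix-effect experiment, a solvent-standard
dilution series for instrumental LOQs, and the partly aged reference soil
measured in duplicate on eight days by two operators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import design_frame
from .model import (
    AnalyteDef,
    IlisAddition,
    IlisDef,
    MethodConfig,
    PesticideClass,
    Polarity,
    SampleRecord,
    SampleRole,
    SoilMeta,
    TransitionDef,
    DEFAULT_CAL_LEVELS,
    DEFAULT_ILIS_TIERS,
)
from .simulate import SimScenario, _stream

#: instrumental-LOQ solvent standard series, ng/mL
ILOQ_LEVELS = (0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.5)

_CLASS_COUNTS = [
    (PesticideClass.fungicide, 60),
    (PesticideClass.herbicide, 30),
    (PesticideClass.insecticide, 26),
    (PesticideClass.acaricide, 4),
    (PesticideClass.rodenticide, 4),
    (PesticideClass.growth_regulator, 2),
    (PesticideClass.synergist, 1),
    (PesticideClass.transformation_product, 19),
]


def default_soils() -> list[SoilMeta]:
    """Method-development soils: organic carbon spanning ~1-5%."""
    return [
        SoilMeta(soil_id="S1", c_org_pct=0.89, ph=7.4, texture="loamy sand"),
        SoilMeta(soil_id="S2", c_org_pct=2.0, ph=7.4, texture="clayey loam"),
        SoilMeta(soil_id="S2.1", c_org_pct=2.0, ph=7.4, texture="clayey loam (aged reference)"),
        SoilMeta(soil_id="S3", c_org_pct=5.1, ph=3.6, texture="forest sandy soil"),
        SoilMeta(soil_id="S4", c_org_pct=3.9, ph=4.4, texture="loamy soil"),
        SoilMeta(soil_id="S5", c_org_pct=2.8, ph=6.8, texture="loamy clay"),
    ]


def _classes(n: int) -> list[PesticideClass]:
    out: list[PesticideClass] = []
    for cls, count in _CLASS_COUNTS:
        out.extend([cls] * count)
    if len(out) >= n:
        return out[:n]
    k = 0
    while len(out) < n:
        out.append(_CLASS_COUNTS[k % len(_CLASS_COUNTS)][0])
        k += 1
    return out


def full_method_config(scenario: SimScenario) -> MethodConfig:
    """Deterministic synthetic catalog for the scenario (keyed on its seed)."""
    rng = _stream(scenario.seed, "catalog")
    n_an, n_ilis = scenario.n_analytes, scenario.n_ilis
    n_si = int(round(scenario.frac_with_si_ilis * n_an))
    n_nsi = n_an - n_si
    n_neg_si = int(round(n_si * 8 / 95))
    n_neg_nsi = int(round(n_nsi * 11 / 51)) if n_nsi else 0

    rts = rng.uniform(2.0, 27.0, n_an)
    classes = _classes(n_an)
    analytes: list[AnalyteDef] = []
    ilis: list[IlisDef] = []
    transitions: list[TransitionDef] = []
    tiers = list(DEFAULT_ILIS_TIERS)

    # indices: first n_si analytes have an si-ILIS; negatives spread evenly
    si_neg_idx = set(np.linspace(0, n_si - 1, n_neg_si, dtype=int)) if n_neg_si else set()
    nsi_neg_idx = (
        set(n_si + np.linspace(0, n_nsi - 1, n_neg_nsi, dtype=int)) if n_neg_nsi else set()
    )

    def add_transitions(sid: str, pol: Polarity, rt: float) -> None:
        prec = float(rng.uniform(150, 500))
        for role, frag in (("quantifier", rng.uniform(0.3, 0.8)), ("qualifier", rng.uniform(0.3, 0.8))):
            transitions.append(
                TransitionDef(
                    species_id=sid,
                    role=role,
                    precursor_mz=prec,
                    product_mz=prec * float(frag),
                    polarity=pol,
                    expected_rt=rt,
                )
            )

    for k in range(n_an):
        has_si = k < n_si
        pol = (
            Polarity.negative
            if (has_si and k in si_neg_idx) or (not has_si and k in nsi_neg_idx)
            else Polarity.positive
        )
        aid = f"an{k + 1:03d}"
        si_id = f"il{k + 1:03d}" if has_si else None
        analytes.append(
            AnalyteDef(
                analyte_id=aid,
                name=f"pesticide-{k + 1:03d}",
                pesticide_class=classes[k],
                polarity=pol,
                expected_rt=float(rts[k]),
                si_ilis_id=si_id,
            )
        )
        add_transitions(aid, pol, float(rts[k]))
        if has_si:
            ilis_rt = float(rts[k] + rng.normal(0.0, 0.07))
            ilis.append(
                IlisDef(
                    ilis_id=si_id,
                    name=f"pesticide-{k + 1:03d}-label",
                    polarity=pol,
                    expected_rt=ilis_rt,
                    tier_concentration=tiers[k % 3],
                )
            )
            add_transitions(si_id, pol, ilis_rt)

    # surrogate-only ILIS beyond the structure-identical ones, if requested
    for k in range(n_si, n_ilis):
        iid = f"il{k + 1:03d}"
        rt = float(rng.uniform(2.0, 27.0))
        ilis.append(
            IlisDef(
                ilis_id=iid,
                name=f"surrogate-label-{k + 1:03d}",
                polarity=Polarity.positive,
                expected_rt=rt,
                tier_concentration=tiers[k % 3],
            )
        )
        add_transitions(iid, Polarity.positive, rt)

    return MethodConfig(
        analytes=analytes,
        ilis=ilis,
        transitions=transitions,
        cal_levels=list(DEFAULT_CAL_LEVELS),
    )


def default_scenario(seed: int = 0, **overrides) -> SimScenario:
    params = dict(soils=default_soils(), seed=seed)
    params.update(overrides)
    return SimScenario(**params)


# ---------------------------------------------------------------------------
# batch designs
# ---------------------------------------------------------------------------

def calibration_records(
    config: MethodConfig, soil_id: str = "S2", n_replicates: int = 2, day_id: str = "d1"
) -> list[SampleRecord]:
    """Matrix-matched calibration standards, ILIS spiked post-extraction."""
    recs = []
    for level in config.cal_levels:
        for r in range(1, n_replicates + 1):
            recs.append(
                SampleRecord(
                    sample_id=f"cal_{level:g}_{r}",
                    soil_id=soil_id,
                    role=SampleRole.cal_standard,
                    nominal_level=level,
                    replicate_id=f"r{r}",
                    day_id=day_id,
                    ilis_addition=IlisAddition.post_extraction,
                )
            )
    return recs


def validation_design(
    config: MethodConfig,
    spike_level_ng_g: float = 2.5,
    spike_soils: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5"),
    n_spike_replicates: int = 4,
    n_unspiked_replicates: int = 2,
    aged_days: int = 8,
) -> pd.DataFrame:
    """Full validation batch design (see module docstring)."""
    recs = calibration_records(config)
    for r in range(1, 3):
        recs.append(
            SampleRecord(
                sample_id=f"blank_S2_{r}",
                soil_id="S2",
                role=SampleRole.matrix_blank,
                replicate_id=f"r{r}",
            )
        )
    for soil in spike_soils:
        for r in range(1, n_spike_replicates + 1):
            recs.append(
                SampleRecord(
                    sample_id=f"spike_{soil}_{r}",
                    soil_id=soil,
                    role=SampleRole.spike_pre_extraction,
                    nominal_level=spike_level_ng_g,
                    replicate_id=f"r{r}",
                )
            )
        for r in range(1, n_unspiked_replicates + 1):
            recs.append(
                SampleRecord(
                    sample_id=f"unspiked_{soil}_{r}",
                    soil_id=soil,
                    role=SampleRole.field,
                    replicate_id=f"r{r}",
                )
            )
        # matrix-effect experiment: post-extraction spikes and unspiked
        # extracts, ILIS always added after extraction
        for r in range(1, 3):
            recs.append(
                SampleRecord(
                    sample_id=f"post_{soil}_{r}",
                    soil_id=soil,
                    role=SampleRole.spike_post_extraction,
                    nominal_level=spike_level_ng_g,
                    replicate_id=f"r{r}",
                    ilis_addition=IlisAddition.post_extraction,
                )
            )
            recs.append(
                SampleRecord(
                    sample_id=f"postblank_{soil}_{r}",
                    soil_id=soil,
                    role=SampleRole.spike_post_extraction,
                    nominal_level=0.0,
                    replicate_id=f"r{r}",
                    ilis_addition=IlisAddition.post_extraction,
                )
            )
    # solvent reference standards for matrix-effect case (i)
    for r in range(1, 3):
        recs.append(
            SampleRecord(
                sample_id=f"solv_ref_{r}",
                role=SampleRole.solvent_standard,
                nominal_level=spike_level_ng_g,
                replicate_id=f"r{r}",
                ilis_addition=IlisAddition.post_extraction,
            )
        )
    # instrumental-LOQ series
    for level in ILOQ_LEVELS:
        recs.append(
            SampleRecord(
                sample_id=f"iloq_{level:g}",
                role=SampleRole.solvent_standard,
                nominal_level=level,
                ilis_addition=IlisAddition.post_extraction,
            )
        )
    # partly aged reference soil: duplicate preparations across days/operators
    for d in range(1, aged_days + 1):
        op = "op1" if d <= aged_days // 2 else "op2"
        for r in range(1, 3):
            recs.append(
                SampleRecord(
                    sample_id=f"aged_d{d}_{r}",
                    soil_id="S2.1",
                    role=SampleRole.reference_aged,
                    replicate_id=f"r{r}",
                    day_id=f"d{d}",
                    operator_id=op,
                )
            )
    return design_frame(recs)


# ---------------------------------------------------------------------------
# ILIS-assignment experiment
# ---------------------------------------------------------------------------

def assignment_config(seed: int = 0) -> MethodConfig:
    """Small catalog for the surrogate-ILIS selection experiment.

    One positive-mode analyte without structure-identical ILIS plus four
    same-polarity candidate ILIS: one close in retention time (|dRT| 0.07
    min, the typical offset of a well-chosen surrogate) and three distant
    ones (|dRT| >= 1.5 min).  Matrix-effect and recovery-shock correlations
    decay with |dRT|, so the nearest candidate compensates best on average;
    the geometry keeps that correlation contrast large relative to the
    sampling variability of a five-soil recovery profile, so the experiment
    actually resolves the mechanism it probes.
    """
    rng = _stream(seed, "catalog", "assignment")
    analyte_rt = 10.0
    candidate_rts = [10.07, 8.5, 11.7, 8.1]
    analytes = [
        AnalyteDef(
            analyte_id="anX",
            name="orphan-analyte",
            pesticide_class=PesticideClass.fungicide,
            polarity=Polarity.positive,
            expected_rt=analyte_rt,
        )
    ]
    ilis = []
    transitions = []

    def add_tr(sid: str, rt: float) -> None:
        prec = float(rng.uniform(150, 500))
        for role in ("quantifier", "qualifier"):
            transitions.append(
                TransitionDef(
                    species_id=sid,
                    role=role,
                    precursor_mz=prec,
                    product_mz=prec * float(rng.uniform(0.3, 0.8)),
                    polarity=Polarity.positive,
                    expected_rt=rt,
                )
            )

    add_tr("anX", analyte_rt)
    for k, rt in enumerate(candidate_rts):
        iid = f"cand{k + 1}"
        ilis.append(
            IlisDef(
                ilis_id=iid,
                name=f"candidate-ilis-{k + 1}",
                polarity=Polarity.positive,
                expected_rt=rt,
                tier_concentration=DEFAULT_ILIS_TIERS[k % 3],
            )
        )
        add_tr(iid, rt)
    return MethodConfig(analytes=analytes, ilis=ilis, transitions=transitions)


def assignment_design(config: MethodConfig, spike_level_ng_g: float = 2.5) -> pd.DataFrame:
    """Spiked/unspiked S1-S5 plus calibration for ILIS selection."""
    recs = calibration_records(config, n_replicates=1)
    for soil in ("S1", "S2", "S3", "S4", "S5"):
        for r in range(1, 5):
            recs.append(
                SampleRecord(
                    sample_id=f"spike_{soil}_{r}",
                    soil_id=soil,
                    role=SampleRole.spike_pre_extraction,
                    nominal_level=spike_level_ng_g,
                    replicate_id=f"r{r}",
                )
            )
        for r in range(1, 3):
            recs.append(
                SampleRecord(
                    sample_id=f"unspiked_{soil}_{r}",
                    soil_id=soil,
                    role=SampleRole.field,
                    replicate_id=f"r{r}",
                )
            )
    return design_frame(recs)
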