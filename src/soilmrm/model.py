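"""Domain model for targeted MRM pesticide quantification in soils.

The central object is :class:`MethodConfig`, the analytical method catalog:
analytes, isotope-labelled internal standards (ILIS), their MRM transitions,
the matrix-matched calibration design, and the quality-control thresholds
(S/N minima, retention-time tolerance, recovery band, linearity tolerance).

Concentrations are tracked in ng/mL of extract internally and converted to
ng/g dry weight at the reporting boundary; with the method's 5 g soil / 5 mL
extract design the two scales coincide numerically.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator


class Polarity(str, Enum):
    positive = "positive"
    negative = "negative"


class TransitionRole(str, Enum):
    quantifier = "quantifier"
    qualifier = "qualifier"


class PesticideClass(str, Enum):
    fungicide = "fungicide"
    herbicide = "herbicide"
    insecticide = "insecticide"
    acaricide = "acaricide"
    rodenticide = "rodenticide"
    growth_regulator = "growth_regulator"
    synergist = "synergist"
    transformation_product = "transformation_product"


class SampleRole(str, Enum):
    cal_standard = "cal_standard"
    matrix_blank = "matrix_blank"
    field = "field"
    spike_pre_extraction = "spike_pre_extraction"
    spike_post_extraction = "spike_post_extraction"
    reference_aged = "reference_aged"
    #: pure-solvent standard (instrumental LOQ series, matrix-effect reference)
    solvent_standard = "solvent_standard"


class IlisAddition(str, Enum):
    """When the ILIS MIX is spiked relative to extraction."""

    pre_extraction = "pre_extraction"
    post_extraction = "post_extraction"
    none = "none"


class ConfigurationError(ValueError):
    """Inconsistent or unresolvable method configuration."""


class TransitionDef(BaseModel):
    species_id: str
    role: TransitionRole
    precursor_mz: float = Field(gt=0)
    product_mz: float = Field(gt=0)
    polarity: Polarity
    expected_rt: float = Field(gt=0, description="minutes")


class AnalyteDef(BaseModel):
    analyte_id: str
    name: str
    pesticide_class: PesticideClass
    polarity: Polarity
    expected_rt: float = Field(gt=0)
    stereoisomer_group: Optional[str] = None
    #: structure-identical ILIS, when one exists
    si_ilis_id: Optional[str] = None
    #: ILIS actually used for quantification (== si_ilis_id when present,
    #: otherwise filled in by the systematic assignment procedure)
    assigned_ilis_id: Optional[str] = None

    @model_validator(mode="after")
    def _si_consistency(self) -> "AnalyteDef":
        if self.si_ilis_id is not None and self.assigned_ilis_id is None:
            self.assigned_ilis_id = self.si_ilis_id
        if self.si_ilis_id is not None and self.assigned_ilis_id != self.si_ilis_id:
            raise ConfigurationError(
                f"{self.analyte_id}: assigned ILIS {self.assigned_ilis_id!r} "
                f"conflicts with structure-identical ILIS {self.si_ilis_id!r}"
            )
        return self


class IlisDef(BaseModel):
    ilis_id: str
    name: str
    polarity: Polarity
    expected_rt: float = Field(gt=0)
    tier_concentration: float = Field(gt=0, description="ng/mL in the ILIS MIX")


class SoilMeta(BaseModel):
    soil_id: str
    c_org_pct: float = Field(ge=0)
    ph: float
    water_content_pct: float = Field(default=0.0, ge=0, lt=100)
    texture: str = ""


class SampleRecord(BaseModel):
    sample_id: str
    soil_id: Optional[str] = None
    role: SampleRole
    #: ng/mL for calibration/solvent standards and post-extraction spikes,
    #: ng/g for pre-extraction spikes; absent otherwise
    nominal_level: Optional[float] = None
    replicate_id: str = "r1"
    day_id: str = "d1"
    operator_id: str = "op1"
    soil_mass_g: float = Field(default=5.0, gt=0)
    extract_volume_mL: float = Field(default=5.0, gt=0)
    ilis_addition: IlisAddition = IlisAddition.pre_extraction

    @model_validator(mode="after")
    def _level_required(self) -> "SampleRecord":
        needs_level = {
            SampleRole.cal_standard,
            SampleRole.spike_pre_extraction,
            SampleRole.spike_post_extraction,
            SampleRole.solvent_standard,
        }
        if self.role in needs_level and self.nominal_level is None:
            raise ConfigurationError(
                f"sample {self.sample_id}: role {self.role.value} requires nominal_level"
            )
        return self


#: matrix-matched calibration levels of the reference method, ng/mL
DEFAULT_CAL_LEVELS = (0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 17.5, 25.0, 35.0, 50.0)

#: ILIS MIX tier concentrations, ng/mL
DEFAULT_ILIS_TIERS = (50.0, 250.0, 750.0)


class MethodConfig(BaseModel):
    analytes: list[AnalyteDef]
    ilis: list[IlisDef]
    transitions: list[TransitionDef]
    cal_levels: list[float] = Field(default_factory=lambda: list(DEFAULT_CAL_LEVELS))
    ilis_tier_set: list[float] = Field(default_factory=lambda: list(DEFAULT_ILIS_TIERS))
    ilis_spike_volume_uL: float = Field(default=100.0, ge=0)
    rt_match_tol_min: float = 0.05
    recovery_band: tuple[float, float] = (70.0, 120.0)
    linearity_tol_pct: float = 20.0
    snr_quant_min: float = 10.0
    snr_qual_min: float = 3.0
    global_matrix_correction_factor: float = Field(default=2.0, ge=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "MethodConfig":
        ids = [a.analyte_id for a in self.analytes] + [i.ilis_id for i in self.ilis]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate species ids: {sorted(dupes)}")
        ilis_by_id = {i.ilis_id: i for i in self.ilis}
        for a in self.analytes:
            for ref in (a.si_ilis_id, a.assigned_ilis_id):
                if ref is None:
                    continue
                if ref not in ilis_by_id:
                    raise ConfigurationError(
                        f"analyte {a.analyte_id} references unknown ILIS {ref!r}"
                    )
                if ilis_by_id[ref].polarity != a.polarity:
                    raise ConfigurationError(
                        f"analyte {a.analyte_id} ({a.polarity.value}) assigned "
                        f"ILIS {ref} of opposite polarity"
                    )
        for i in self.ilis:
            if i.tier_concentration not in set(self.ilis_tier_set):
                raise ConfigurationError(
                    f"ILIS {i.ilis_id}: tier {i.tier_concentration} ng/mL not in "
                    f"configured tier set {self.ilis_tier_set}"
                )
        known = set(ids)
        by_species: dict[str, list[TransitionDef]] = {}
        for t in self.transitions:
            if t.species_id not in known:
                raise ConfigurationError(f"transition references unknown species {t.species_id!r}")
            by_species.setdefault(t.species_id, []).append(t)
        for sid, trs in by_species.items():
            roles = sorted(t.role.value for t in trs)
            if roles != ["qualifier", "quantifier"]:
                raise ConfigurationError(
                    f"species {sid}: expected exactly one quantifier and one "
                    f"qualifier transition, got roles {roles}"
                )
        missing = known - set(by_species)
        if missing:
            raise ConfigurationError(f"species without transitions: {sorted(missing)}")
        if sorted(self.cal_levels) != self.cal_levels or len(set(self.cal_levels)) != len(
            self.cal_levels
        ):
            raise ConfigurationError("cal_levels must be strictly increasing")
        lo, hi = self.recovery_band
        if not lo < hi:
            raise ConfigurationError("recovery_band low must be < high")
        return self

    # -- lookup helpers -------------------------------------------------
    @property
    def analyte_map(self) -> dict[str, AnalyteDef]:
        return {a.analyte_id: a for a in self.analytes}

    @property
    def ilis_map(self) -> dict[str, IlisDef]:
        return {i.ilis_id: i for i in self.ilis}

    @property
    def species_ids(self) -> list[str]:
        return [a.analyte_id for a in self.analytes] + [i.ilis_id for i in self.ilis]

    def ilis_for(self, analyte_id: str) -> Optional[str]:
        a = self.analyte_map[analyte_id]
        return a.assigned_ilis_id or a.si_ilis_id

    def stereo_members(self, analyte_id: str) -> list[str]:
        """Analytes sharing a stereoisomer group (peak areas are summed)."""
        a = self.analyte_map[analyte_id]
        if a.stereoisomer_group is None:
            return [analyte_id]
        return [
            x.analyte_id
            for x in self.analytes
            if x.stereoisomer_group == a.stereoisomer_group
        ]


def dry_weight_equivalent(mass_g: float, water_content_pct: float) -> float:
    """Dry-weight mass of a (possibly undried) soil aliquot.

    Undried field samples are weighed in at a larger mass so that the
    dry-weight basis matches the nominal aliquot; quantification always
    reports per gram dry weight.
    """
    if not 0 <= water_content_pct < 100:
        raise ValueError(f"water content {water_content_pct}% outside [0, 100)")
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    return mass_g * (1.0 - water_content_pct / 100.0)


def ilis_spike_concentration(
    tier_ng_mL: float, spike_volume_uL: float = 100.0, extract_volume_mL: float = 5.0
) -> float:
    """Final ILIS concentration (ng/mL) in the extract or standard.

    Spiking 100 uL of the 50/250/750 ng/mL ILIS MIX into a 5 mL extract
    yields 1, 5 or 15 ng/mL.
    """
    if extract_volume_mL <= 0:
        raise ValueError("extract volume must be positive")
    if spike_volume_uL < 0 or tier_ng_mL < 0:
        raise ValueError("spike volume and tier concentration must be non-negative")
    return tier_ng_mL * (spike_volume_uL / 1000.0) / extract_volume_mL
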