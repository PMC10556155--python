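"""Synthetic MRM batch generator with known ground truth.

The generator emulates the statistical structure a soil multi-residue
LC-ESI-MS/MS method has to cope with:

* extraction losses (per-sample recovery shocks shared between an analyte
  and its pre-extraction-spiked ILIS),
* electrospray matrix effects that grow with soil organic carbon and are
  correlated between species with similar retention times,
* partly aged reference material (per-analyte aging losses),
* multiplicative replicate noise on peak areas and a per-species noise
  floor that determines signal-to-noise ratios.

Matrix effects and recovery shocks are realised as Ornstein-Uhlenbeck
fields over retention time, so the correlation between two species decays
as ``exp(-|dRT| / rt_corr_scale)``.  A structure-identical ILIS copies its
analyte's field values exactly (correlation 1) - the mechanism that makes
internal-standard compensation, and hence the ILIS-assignment procedure,
meaningful.  Fields are drawn from named substreams of a single seed, so
adding species or samples does not perturb existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.signal import lfilter

from .model import (
    IlisAddition,
    MethodConfig,
    SampleRole,
    SoilMeta,
    dry_weight_equivalent,
    ilis_spike_concentration,
)

_RT_GRID_MAX = 35.0
_RT_GRID_STEP = 0.05

_STREAMS = {"params": 1, "me": 2, "recovery": 3, "noise": 4, "day": 5, "aging": 6, "catalog": 7}

_EXTRACTED_ROLES = {
    SampleRole.matrix_blank.value,
    SampleRole.field.value,
    SampleRole.spike_pre_extraction.value,
    SampleRole.spike_post_extraction.value,
    SampleRole.reference_aged.value,
}


class DesignError(ValueError):
    """Batch design incompatible with the scenario or method."""


def _crc(s: str) -> int:
    return zlib.crc32(s.encode()) & 0x7FFFFFFF


def _stream(seed: int, name: str, *keys: str) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF, _STREAMS[name], *(_crc(k) for k in keys)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _ou_path(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) path; lag-k correlation rho**k."""
    e = rng.standard_normal(n)
    drive = np.concatenate(([e[0]], np.sqrt(1.0 - rho**2) * e[1:]))
    return lfilter([1.0], [1.0, -rho], drive)


def _lognormal_factor(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


class SimScenario(BaseModel):
    """Study conditions for a synthetic batch.

    Defaults mirror the reference method: 146 analytes of which 65% have a
    structure-identical ILIS, 95 ILIS, soils spanning roughly 1-5% organic
    carbon with ion suppression increasing by 8 percentage points per %
    C_org, 3% replicate noise, and a 95 +/- 5% extraction recovery.
    """

    n_analytes: int = Field(default=146, gt=0)
    frac_with_si_ilis: float = Field(default=0.65, ge=0, le=1)
    n_ilis: int = Field(default=95, gt=0)
    soils: list[SoilMeta] = Field(default_factory=list)

    # matrix-effect model: ME% = intercept + slope * c_org + sd * field(rt)
    suppression_slope: float = -8.0
    suppression_intercept: float = 8.0
    suppression_sd: float = Field(default=8.0, ge=0)
    rt_corr_scale: float = Field(default=1.0, gt=0)

    extraction_recovery_mean: float = Field(default=0.95, gt=0)
    extraction_recovery_sd: float = Field(default=0.05, ge=0)

    noise_cv: float = Field(default=0.03, ge=0)
    noise_floor_median: float = Field(default=120.0, gt=0)
    noise_floor_gsd: float = Field(default=2.5, ge=1)
    #: solvent standards see a cleaner baseline than matrix extracts
    solvent_noise_floor_divisor: float = Field(default=4.0, ge=1)

    response_slope_median: float = Field(default=2.0e4, gt=0)
    response_slope_gsd: float = Field(default=2.0, ge=1)
    qualifier_fraction_mean: float = Field(default=0.45, gt=0)
    qualifier_fraction_sd: float = Field(default=0.15, ge=0)
    rt_jitter_sd_min: float = Field(default=0.01, ge=0)
    day_effect_cv: float = Field(default=0.05, ge=0)

    #: native residues, soil_id -> analyte_id -> ng/g dry weight
    native_conc: dict[str, dict[str, float]] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimScenario":
        if round(self.frac_with_si_ilis * self.n_analytes) > self.n_ilis:
            raise ValueError("more structure-identical analytes than ILIS")
        return self

    def soil_map(self) -> dict[str, SoilMeta]:
        return {s.soil_id: s for s in self.soils}


@dataclass
class SimTruth:
    """Ground truth stored alongside every generated batch."""

    #: species_id, kind, expected_rt, response_slope, qualifier_fraction, noise_floor_area
    species: pd.DataFrame
    #: soil_id x species_id -> injected matrix effect [%]
    matrix_effects: pd.DataFrame
    #: soil_id x analyte_id -> native/aged true concentration [ng/g dw]
    true_conc: pd.DataFrame
    #: sample_id x species_id -> realised extraction recovery (1.0 where n/a)
    recovery: pd.DataFrame


def _species_params(config: MethodConfig, scenario: SimScenario) -> pd.DataFrame:
    rows = []
    for sid, kind, rt in [(a.analyte_id, "analyte", a.expected_rt) for a in config.analytes] + [
        (i.ilis_id, "ilis", i.expected_rt) for i in config.ilis
    ]:
        rng = _stream(scenario.seed, "params", sid)
        slope = scenario.response_slope_median * np.exp(
            rng.normal(0.0, np.log(scenario.response_slope_gsd))
        )
        qf = float(
            np.clip(
                rng.normal(scenario.qualifier_fraction_mean, scenario.qualifier_fraction_sd),
                0.05,
                0.95,
            )
        )
        floor = scenario.noise_floor_median * np.exp(
            rng.normal(0.0, np.log(scenario.noise_floor_gsd))
        )
        rows.append(
            {
                "species_id": sid,
                "kind": kind,
                "expected_rt": rt,
                "response_slope": slope,
                "qualifier_fraction": qf,
                "noise_floor_area": floor,
            }
        )
    return pd.DataFrame(rows)


def _si_pairs(config: MethodConfig) -> list[tuple[int, int]]:
    """(analyte_index, ilis_index) positions for structure-identical pairs."""
    order = {sid: k for k, sid in enumerate(config.species_ids)}
    pairs = []
    for a in config.analytes:
        if a.si_ilis_id is not None:
            pairs.append((order[a.analyte_id], order[a.si_ilis_id]))
    return pairs


def _field_values(
    rng: np.random.Generator,
    grid_idx: np.ndarray,
    si_pairs: list[tuple[int, int]],
    rt_corr_scale: float,
) -> np.ndarray:
    rho = float(np.exp(-_RT_GRID_STEP / rt_corr_scale))
    n_grid = int(_RT_GRID_MAX / _RT_GRID_STEP) + 1
    path = _ou_path(rng, n_grid, rho)
    vals = path[grid_idx]
    for a_pos, i_pos in si_pairs:
        vals[i_pos] = vals[a_pos]  # structure-identical: correlation 1
    return vals


def simulate_batch(
    scenario: SimScenario,
    design: pd.DataFrame,
    config: MethodConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a long-format measurement table plus its ground truth.

    The signal model per analyte a and sample s (extract concentration c in
    ng/mL) is ``area = c * response_slope * (1 + ME/100) * day_factor *
    lognormal(1, noise_cv)``; the qualifier transition is the (noisy)
    quantifier area times the analyte's qualifier fraction times its own
    lognormal factor; ``S/N = area / noise_floor``.  ILIS areas follow the
    same model from the known spike amounts, with the extraction recovery
    applied only when the ILIS is spiked before extraction.
    """
    soil_map = scenario.soil_map()
    species = _species_params(config, scenario)
    sids = species["species_id"].tolist()
    n_sp = len(sids)
    n_an = sum(species["kind"] == "analyte")
    analyte_ids = sids[:n_an]
    rts = species["expected_rt"].to_numpy()
    grid_idx = np.clip(np.round(rts / _RT_GRID_STEP).astype(int), 0, int(_RT_GRID_MAX / _RT_GRID_STEP))
    si_pairs = _si_pairs(config)

    design = design.reset_index(drop=True)
    missing_soils = {
        s for s in design["soil_id"].dropna() if s not in soil_map
    }
    if missing_soils:
        raise DesignError(f"design references soils not in scenario: {sorted(missing_soils)}")

    # matrix-effect field per soil
    me_by_soil: dict[str, np.ndarray] = {}
    for soil in scenario.soils:
        vals = _field_values(
            _stream(scenario.seed, "me", soil.soil_id), grid_idx, si_pairs, scenario.rt_corr_scale
        )
        me_by_soil[soil.soil_id] = (
            scenario.suppression_intercept
            + scenario.suppression_slope * soil.c_org_pct
            + scenario.suppression_sd * vals
        )

    # per-species noise streams drawn over the sample axis
    n_samples = len(design)
    noise_q = np.ones((n_sp, n_samples))
    noise_qual = np.ones((n_sp, n_samples))
    rt_jit = np.zeros((n_sp, n_samples))
    day_ids = sorted(design["day_id"].astype(str).unique())
    day_pos = design["day_id"].astype(str).map({d: k for k, d in enumerate(day_ids)}).to_numpy()
    day_fx = np.ones((n_sp, len(day_ids)))
    # noise_cv parameterises the replicate CV of the analyte/ILIS area
    # *ratio* (the measured response); each individual area receives
    # cv/sqrt(2) so that the shared injection variability, which cancels in
    # the ratio, is not double-counted.
    cv_area = scenario.noise_cv / np.sqrt(2.0)
    for k, sid in enumerate(sids):
        rng = _stream(scenario.seed, "noise", sid)
        noise_q[k] = _lognormal_factor(rng, n_samples, cv_area)
        noise_qual[k] = _lognormal_factor(rng, n_samples, cv_area)
        if scenario.rt_jitter_sd_min > 0:
            rt_jit[k] = rng.normal(0.0, scenario.rt_jitter_sd_min, n_samples)
        if k < n_an and scenario.day_effect_cv > 0:
            day_fx[k] = _lognormal_factor(
                _stream(scenario.seed, "day", sid), len(day_ids), scenario.day_effect_cv
            )

    ilis_tiers = np.array([i.tier_concentration for i in config.ilis])

    conc = np.zeros((n_sp, n_samples))  # ng/mL in the measured extract
    me = np.zeros((n_sp, n_samples))
    recovery = np.ones((n_sp, n_samples))
    true_conc_rows: dict[tuple[str, str], float] = {}

    for j, row in design.iterrows():
        role = row["role"]
        soil_id = row["soil_id"]
        extracted = role in _EXTRACTED_ROLES
        if extracted or role == SampleRole.cal_standard.value:
            if soil_id is None or (isinstance(soil_id, float) and np.isnan(soil_id)):
                raise DesignError(f"sample {row['sample_id']}: role {role} requires a soil")
            me[:, j] = me_by_soil[soil_id]

        if extracted:
            soil = soil_map[soil_id]
            dm = dry_weight_equivalent(row["soil_mass_g"], soil.water_content_pct)
            vol = row["extract_volume_mL"]
            if scenario.extraction_recovery_sd > 0:
                vals = _field_values(
                    _stream(scenario.seed, "recovery", str(row["sample_id"])),
                    grid_idx,
                    si_pairs,
                    scenario.rt_corr_scale,
                )
                rec = np.clip(
                    scenario.extraction_recovery_mean + scenario.extraction_recovery_sd * vals,
                    0.01,
                    None,
                )
            else:
                rec = np.full(n_sp, scenario.extraction_recovery_mean)
            recovery[:, j] = rec
            native = scenario.native_conc.get(soil_id, {})
            tc = np.array([native.get(a, 0.0) for a in analyte_ids])
            for a, v in zip(analyte_ids, tc):
                if v > 0:
                    true_conc_rows[(soil_id, a)] = v
            if role == SampleRole.spike_pre_extraction.value:
                tc = tc + row["nominal_level"]  # ng/g spiked before extraction
            conc[:n_an, j] = tc * dm / vol * rec[:n_an]
            if role == SampleRole.spike_post_extraction.value:
                conc[:n_an, j] += row["nominal_level"]  # ng/mL added to the extract
        elif role in (SampleRole.cal_standard.value, SampleRole.solvent_standard.value):
            conc[:n_an, j] = row["nominal_level"]
        else:
            raise DesignError(f"unknown sample role {role!r}")

        # ILIS from the known spike amount
        addition = row.get("ilis_addition", IlisAddition.pre_extraction.value)
        if addition != IlisAddition.none.value:
            if config.ilis_spike_volume_uL <= 0 and addition == IlisAddition.pre_extraction.value:
                raise DesignError(
                    f"sample {row['sample_id']}: pre-extraction ILIS spike with zero spike volume"
                )
            c_i = (
                ilis_tiers
                * (config.ilis_spike_volume_uL / 1000.0)
                / row["extract_volume_mL"]
            )
            if addition == IlisAddition.pre_extraction.value and extracted:
                c_i = c_i * recovery[n_an:, j]
            conc[n_an:, j] = c_i

    slopes = species["response_slope"].to_numpy()[:, None]
    floors = species["noise_floor_area"].to_numpy()[:, None]
    qf = species["qualifier_fraction"].to_numpy()[:, None]
    solvent_mask = (design["role"] == SampleRole.solvent_standard.value).to_numpy()
    floor_mat = np.where(
        solvent_mask[None, :], floors / scenario.solvent_noise_floor_divisor, floors
    )

    signal = conc * slopes * (1.0 + me / 100.0) * day_fx[:, day_pos]
    area_q = signal * noise_q
    area_qual = area_q * qf * noise_qual
    snr_q = area_q / floor_mat
    snr_qual = area_qual / floor_mat
    rt_obs = rts[:, None] + rt_jit

    sample_ids = design["sample_id"].astype(str).to_numpy()
    frames = []
    for role_name, areas, snrs in (
        ("quantifier", area_q, snr_q),
        ("qualifier", area_qual, snr_qual),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sample_ids, n_sp),
                    "species_id": np.tile(sids, n_samples),
                    "transition_role": role_name,
                    "peak_area": areas.T.ravel(),
                    "snr": snrs.T.ravel(),
                    "rt": rt_obs.T.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    me_frames = [
        pd.DataFrame(
            {"soil_id": soil_id, "species_id": sids, "matrix_effect_pct": vals}
        )
        for soil_id, vals in me_by_soil.items()
    ]
    truth = SimTruth(
        species=species,
        matrix_effects=pd.concat(me_frames, ignore_index=True)
        if me_frames
        else pd.DataFrame(columns=["soil_id", "species_id", "matrix_effect_pct"]),
        true_conc=pd.DataFrame(
            [
                {"soil_id": s, "analyte_id": a, "true_conc_ng_g": v}
                for (s, a), v in sorted(true_conc_rows.items())
            ],
            columns=["soil_id", "analyte_id", "true_conc_ng_g"],
        ),
        recovery=pd.DataFrame(
            {
                "sample_id": np.repeat(sample_ids, n_sp),
                "species_id": np.tile(sids, n_samples),
                "recovery": recovery.T.ravel(),
            }
        ),
    )
    return table, truth


def draw_aging_losses(
    analyte_ids: list[str], seed: int, median_loss: float = 0.07, log_sd: float = 1.56
) -> dict[str, float]:
    """Per-analyte aging loss fractions for the partly aged reference soil.

    Lognormal around ``median_loss`` with a heavy upper tail (clipped at
    0.98) so that most analytes lose little while a few degradation-prone
    ones lose almost everything - the qualitative pattern seen when a
    spiked soil is equilibrated, aged and re-analysed.
    """
    out = {}
    for a in analyte_ids:
        rng = _stream(seed, "aging", a)
        loss = median_loss * np.exp(rng.normal(0.0, log_sd))
        out[a] = float(np.clip(loss, 0.0, 0.98))
    return out


def make_reference_aged(
    scenario: SimScenario,
    spike_ng_g: float = 10.0,
    aging_loss: Optional[Mapping[str, float]] = None,
    analyte_ids: Optional[list[str]] = None,
    soil_id: str = "S2.1",
) -> tuple[SimScenario, pd.DataFrame]:
    """Install a partly aged reference soil in the scenario.

    True concentrations are ``spike_ng_g * (1 - aging_loss)`` per analyte.
    Returns the updated scenario and the ground-truth table.
    """
    if spike_ng_g <= 0:
        raise ValueError("spike level must be positive")
    if aging_loss is None:
        if analyte_ids is None:
            raise ValueError("need aging_loss or analyte_ids")
        aging_loss = draw_aging_losses(analyte_ids, scenario.seed)
    bad = {a: l for a, l in aging_loss.items() if not 0 <= l <= 1}
    if bad:
        raise ValueError(f"aging losses outside [0, 1]: {bad}")
    conc = {a: spike_ng_g * (1.0 - l) for a, l in aging_loss.items()}
    native = dict(scenario.native_conc)
    native[soil_id] = conc
    new_scenario = scenario.model_copy(update={"native_conc": native})
    truth = pd.DataFrame(
        {"soil_id": soil_id, "analyte_id": list(conc), "true_conc_ng_g": list(conc.values())}
    )
    return new_scenario, truth
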