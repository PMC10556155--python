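"""End-to-end batch processing and figures-of-merit aggregation.

`run_validation_batch` generates (or accepts) a full validation batch -
calibration standards, matrix blanks, pre- and post-extraction spikes in
five soils, a solvent dilution series and the partly aged reference soil -
and runs the complete pipeline: PAR computation, 1/x-weighted calibration,
identification gating, LOQ derivation, quantification and censoring.
`figures_of_merit` condenses the result into the method's summary table
(median recoveries, precision tiers, trueness, LOQs, matrix effects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, calibrate_batch, curves_frame, par_table
from .identification import ion_ratio_reference, qc_table
from .ilis_assignment import assign_ilis
from .matrix_effects import (
    GlobalFactorResult,
    derive_global_factor,
    matrix_effect_table,
    mloq_table,
    summarize_matrix_effects,
)
from .model import MethodConfig, SampleRole
from .presets import default_scenario, full_method_config, validation_design
from .quantify import quantify
from .simulate import SimScenario, SimTruth, make_reference_aged, simulate_batch
from .validation import absolute_recovery_quechers, precision, relative_recovery


@dataclass
class BatchResult:
    scenario: SimScenario
    config: MethodConfig
    design: pd.DataFrame
    measurements: pd.DataFrame
    truth: SimTruth
    aged_truth: pd.DataFrame
    ilis_audit: pd.DataFrame
    curves: dict[str, CalibrationCurve]
    references: pd.DataFrame
    qc: pd.DataFrame
    effects_case_i: pd.DataFrame
    effects_case_ii: pd.DataFrame
    global_factor: GlobalFactorResult
    mloqs: pd.DataFrame
    pars: pd.DataFrame
    quant: pd.DataFrame

    @property
    def curve_table(self) -> pd.DataFrame:
        return curves_frame(self.curves)


def run_validation_batch(
    seed: int = 0,
    scenario: Optional[SimScenario] = None,
    spike_level_ng_g: float = 2.5,
    aged_spike_ng_g: float = 10.0,
) -> BatchResult:
    """Simulate and fully process one validation batch."""
    if scenario is None:
        scenario = default_scenario(seed)
    config = full_method_config(scenario)
    scenario, aged_truth = make_reference_aged(
        scenario,
        spike_ng_g=aged_spike_ng_g,
        analyte_ids=[a.analyte_id for a in config.analytes],
    )
    design = validation_design(config, spike_level_ng_g=spike_level_ng_g)
    measurements, truth = simulate_batch(scenario, design, config)

    # surrogate-ILIS selection for analytes without a structure-identical
    # ILIS, from the spiked/unspiked evaluation soils of this batch
    config, ilis_audit = assign_ilis(
        measurements, design, config, spike_level_ng_g=spike_level_ng_g
    )

    curves = calibrate_batch(measurements, design, config)
    references = ion_ratio_reference(measurements, design, config)
    qc = qc_table(measurements, design, config, references)
    effects_i = matrix_effect_table(measurements, design, config, "solvent_standard")
    effects_ii = matrix_effect_table(measurements, design, config, "s2_extract")
    gf = derive_global_factor(effects_ii[effects_ii["soil_id"] != "S2"])
    mloqs = mloq_table(measurements, design, config, references, factor=gf.factor)
    pars = par_table(measurements, config)
    quant = quantify(pars, curves, qc, mloqs, design, config, soils=scenario.soil_map())
    return BatchResult(
        scenario=scenario,
        config=config,
        design=design,
        measurements=measurements,
        truth=truth,
        aged_truth=aged_truth,
        ilis_audit=ilis_audit,
        curves=curves,
        references=references,
        qc=qc,
        effects_case_i=effects_i,
        effects_case_ii=effects_ii,
        global_factor=gf,
        mloqs=mloqs,
        pars=pars,
        quant=quant,
    )


def assignment_experiment(
    n_runs: int = 200,
    base_seed: int = 0,
    spike_level_ng_g: float = 2.5,
) -> dict:
    """Repeated surrogate-ILIS selection under RT-decaying ME correlation.

    Runs ``n_runs`` independently seeded simulations of the selection
    experiment (one orphan analyte, candidates at graded RT offsets, soils
    S1-S5 spiked and unspiked) and reports how often the minimum-|dRT|
    same-polarity candidate is selected.
    """
    from .ilis_assignment import candidate_recoveries, enumerate_candidates, score_and_select
    from .presets import assignment_config, assignment_design, default_soils

    config = assignment_config(base_seed)
    design = assignment_design(config, spike_level_ng_g)
    soils = [s for s in default_soils() if s.soil_id != "S2.1"]
    analyte = config.analytes[0]
    wins = 0
    chosen_ids = []
    for k in range(n_runs):
        scenario = SimScenario(
            n_analytes=1,
            frac_with_si_ilis=0.0,
            n_ilis=len(config.ilis),
            soils=soils,
            seed=(base_seed + k) & 0x7FFFFFFF,
        )
        measurements, _ = simulate_batch(scenario, design, config)
        cands = enumerate_candidates(analyte, config)
        for c in cands:
            c.per_soil_recovery = candidate_recoveries(
                measurements, design, config, analyte.analyte_id, c.ilis_id, spike_level_ng_g
            )
        chosen, _ = score_and_select(cands, config.recovery_band)
        nearest = min(cands, key=lambda c: abs(c.delta_rt)).ilis_id
        wins += chosen.ilis_id == nearest
        chosen_ids.append(chosen.ilis_id)
    return {
        "n_runs": n_runs,
        "n_nearest_selected": wins,
        "fraction_nearest_selected": wins / n_runs,
        "chosen_ids": chosen_ids,
    }


# ---------------------------------------------------------------------------
# figures of merit
# ---------------------------------------------------------------------------

def _spike_concentrations(result: BatchResult) -> pd.DataFrame:
    """Uncensored quantified concentrations of the pre-extraction spikes."""
    q = result.quant
    return q[q["role"] == SampleRole.spike_pre_extraction.value]


def relative_recovery_table(
    result: BatchResult, spike_level_ng_g: float = 2.5
) -> pd.DataFrame:
    """Mean relative recovery per analyte x soil (spiked minus unspiked)."""
    q = result.quant
    spiked = _spike_concentrations(result)
    unspiked = q[q["role"] == SampleRole.field.value]
    c_sp = spiked.groupby(["analyte_id", "soil_id"])["conc_uncensored_ng_g"].mean()
    c_un = unspiked.groupby(["analyte_id", "soil_id"])["conc_uncensored_ng_g"].mean()
    rows = []
    for (aid, soil), sp in c_sp.items():
        un = c_un.get((aid, soil), 0.0)
        if not np.isfinite(un):
            un = 0.0
        rows.append(
            {
                "analyte_id": aid,
                "soil_id": soil,
                "relative_recovery_pct": relative_recovery(sp, un, spike_level_ng_g),
            }
        )
    return pd.DataFrame(rows)


def absolute_recovery_table(result: BatchResult) -> pd.DataFrame:
    """Extraction efficiency per analyte x soil from raw quantifier areas."""
    meas = result.measurements
    design = result.design
    quant_areas = meas[meas["transition_role"] == "quantifier"].merge(
        design[["sample_id", "role", "soil_id", "nominal_level"]], on="sample_id"
    )
    analyte_ids = {a.analyte_id for a in result.config.analytes}
    quant_areas = quant_areas[quant_areas["species_id"].isin(analyte_ids)]

    def mean_by(role: str, positive_level: Optional[bool] = None) -> pd.Series:
        sel = quant_areas[quant_areas["role"] == role]
        if positive_level is True:
            sel = sel[sel["nominal_level"] > 0]
        elif positive_level is False:
            sel = sel[sel["nominal_level"] == 0]
        return sel.groupby(["species_id", "soil_id"])["peak_area"].mean()

    pre = mean_by(SampleRole.spike_pre_extraction.value)
    post = mean_by(SampleRole.spike_post_extraction.value, positive_level=True)
    blank = mean_by(SampleRole.field.value)
    rows = []
    for key, pa_pre in pre.items():
        if key not in post.index:
            continue
        rows.append(
            {
                "analyte_id": key[0],
                "soil_id": key[1],
                "absolute_recovery_pct": absolute_recovery_quechers(
                    pa_pre, post.loc[key], blank.get(key, 0.0)
                ),
            }
        )
    return pd.DataFrame(rows)


def precision_tables(result: BatchResult) -> pd.DataFrame:
    """Intra-day (spiked soils), inter-day and inter-person (aged soil) RSDs."""
    q = result.quant.merge(
        result.design[["sample_id", "day_id", "operator_id"]], on="sample_id"
    )
    rows = []
    spiked = q[q["role"] == SampleRole.spike_pre_extraction.value]
    for (aid, soil), grp in spiked.groupby(["analyte_id", "soil_id"]):
        if len(grp) < 3:
            continue
        rec = precision(grp["conc_uncensored_ng_g"], "intra_day", analyte_id=aid)
        rows.append({"analyte_id": aid, "soil_id": soil, "tier": "intra_day", "rsd_pct": rec.rsd_pct})
    aged = q[q["role"] == SampleRole.reference_aged.value]
    for aid, grp in aged.groupby("analyte_id"):
        vals = grp["conc_uncensored_ng_g"]
        if grp["day_id"].nunique() >= 3:
            rec = precision(vals, "inter_day", grouping=grp["day_id"], analyte_id=aid)
            rows.append({"analyte_id": aid, "soil_id": "S2.1", "tier": "inter_day", "rsd_pct": rec.rsd_pct})
        if grp["operator_id"].nunique() >= 2:
            rec = precision(vals, "inter_person", grouping=grp["operator_id"], analyte_id=aid)
            rows.append({"analyte_id": aid, "soil_id": "S2.1", "tier": "inter_person", "rsd_pct": rec.rsd_pct})
    return pd.DataFrame(rows)


def figures_of_merit(result: BatchResult, spike_level_ng_g: float = 2.5) -> dict:
    """Summary figures of merit for the batch (medians across analytes)."""
    rel = relative_recovery_table(result, spike_level_ng_g)
    absr = absolute_recovery_table(result)
    prec = precision_tables(result)
    lo, hi = result.config.recovery_band

    spiked = _spike_concentrations(result)
    bias = (
        spiked.groupby("analyte_id")["conc_uncensored_ng_g"].mean() / spike_level_ng_g - 1.0
    ) * 100.0

    aged = result.quant[result.quant["role"] == SampleRole.reference_aged.value]
    aged_mean = aged.groupby("analyte_id")["conc_uncensored_ng_g"].mean()
    aged_dev = 100.0 * (aged_mean - 10.0) / 10.0

    r2 = pd.Series({aid: c.r_squared for aid, c in result.curves.items()})
    intra = prec.loc[prec["tier"] == "intra_day", "rsd_pct"]
    inter = prec.loc[prec["tier"] == "inter_day", "rsd_pct"]
    person = prec.loc[prec["tier"] == "inter_person", "rsd_pct"]
    eff_i = result.effects_case_i

    return {
        "median_r_squared": float(r2.median()),
        "min_r_squared": float(r2.min()),
        "median_relative_recovery_pct": float(rel["relative_recovery_pct"].median()),
        "fraction_recovery_in_band": float(
            rel["relative_recovery_pct"].between(lo, hi).mean()
        ),
        "median_absolute_recovery_pct": float(absr["absolute_recovery_pct"].median()),
        "median_intra_day_rsd_pct": float(intra.median()),
        "median_inter_day_rsd_pct": float(inter.median()) if len(inter) else float("nan"),
        "median_inter_person_rsd_pct": float(person.median()) if len(person) else float("nan"),
        "median_bias_pct": float(bias.abs().median()),
        "median_aged_conc_ng_g": float(aged_mean.median()),
        "fraction_aged_beyond_20pct": float((aged_dev.abs() > 20).mean()),
        "median_iloq_ng_mL": float(result.mloqs["iloq_ng_mL"].median()),
        "median_mloq_ng_g": float(result.mloqs["corrected_mloq_ng_g"].median()),
        "global_matrix_correction_factor": float(result.global_factor.factor),
        "matrix_effect_medians_case_i": {
            r["soil_id"]: float(r["median"])
            for _, r in summarize_matrix_effects(eff_i).iterrows()
        },
    }
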