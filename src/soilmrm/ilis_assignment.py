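"""Systematic surrogate-ILIS selection for analytes without a
structure-identical internal standard.

Candidates are all same-polarity ILIS; in positive mode the candidate's
retention time must lie within +/- 2 min of the analyte's (negative mode is
unrestricted because only a handful of negative-mode ILIS exist).  Each
candidate is scored by the relative recoveries it produces in the spiked
evaluation soils (spiked-minus-unspiked, so native residues do not bias
selection):

1. maximise the number of soils with recovery inside the 70-120% band,
2. tie-break: minimise the dispersion sum(|recovery - 100|),
3. tie-break: minimise |dRT|,
4. tie-break: lexicographic ILIS id (determinism).

Analytes with a structure-identical ILIS are never reassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .calibration import fit_calibration, par_table
from .model import AnalyteDef, MethodConfig, Polarity, SampleRole
from .validation import relative_recovery


class AssignmentError(ValueError):
    """No admissible ILIS candidate exists for an analyte."""


@dataclass
class AssignmentCandidate:
    analyte_id: str
    ilis_id: str
    delta_rt: float  # analyte RT - ILIS RT, minutes
    per_soil_recovery: dict[str, float] = field(default_factory=dict)
    n_soils_in_band: int = 0
    dispersion: float = float("inf")


def enumerate_candidates(
    analyte: AnalyteDef,
    config: MethodConfig,
    rt_window_min: float = 2.0,
) -> list[AssignmentCandidate]:
    """Admissible ILIS candidates for an analyte lacking a si-ILIS.

    Positive mode: |dRT| <= window (inclusive).  Negative mode: no RT
    restriction.  Raises when the candidate set is empty.
    """
    if analyte.si_ilis_id is not None:
        raise AssignmentError(f"{analyte.analyte_id} has a structure-identical ILIS")
    out = []
    for i in config.ilis:
        if i.polarity != analyte.polarity:
            continue
        drt = analyte.expected_rt - i.expected_rt
        if analyte.polarity == Polarity.positive and abs(drt) > rt_window_min + 1e-12:
            continue
        out.append(AssignmentCandidate(analyte.analyte_id, i.ilis_id, drt))
    if not out:
        raise AssignmentError(
            f"no admissible ILIS candidate for {analyte.analyte_id} "
            f"({analyte.polarity.value}, RT {analyte.expected_rt:.2f} min)"
        )
    return out


def candidate_recoveries(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
    analyte_id: str,
    ilis_id: str,
    spike_level_ng_g: float,
) -> dict[str, float]:
    """Per-soil relative recoveries for one analyte-ILIS pairing.

    Rebuilds the analyte's calibration with the candidate ILIS, quantifies
    the spiked and unspiked evaluation samples (uncensored back-calculated
    concentrations averaged over replicates), and computes the relative
    recovery per soil as 100 * (spiked - unspiked) / spike level.
    """
    override = {analyte_id: ilis_id}
    cal = design[design["role"] == SampleRole.cal_standard.value]
    cal_pars = par_table(
        measurements[measurements["sample_id"].isin(cal["sample_id"])],
        config,
        ilis_override=override,
        analyte_ids=[analyte_id],
    )
    levels = cal.set_index("sample_id")["nominal_level"].reindex(cal_pars["sample_id"])
    curve = fit_calibration(
        levels.to_numpy(), cal_pars["par"].to_numpy(), analyte_id=analyte_id
    )
    spiked = design[
        (design["role"] == SampleRole.spike_pre_extraction.value)
        & np.isclose(design["nominal_level"].astype(float), spike_level_ng_g)
    ]
    unspiked = design[design["role"] == SampleRole.field.value]
    eval_ids = pd.concat([spiked, unspiked])["sample_id"]
    pars = par_table(
        measurements[measurements["sample_id"].isin(eval_ids)],
        config,
        ilis_override=override,
        analyte_ids=[analyte_id],
    )
    pars = pars.merge(
        design[["sample_id", "soil_id", "role"]], on="sample_id"
    )
    pars["conc"] = curve.concentration(pars["par"].to_numpy())
    out = {}
    for soil_id, grp in pars.groupby("soil_id"):
        c_sp = grp.loc[grp["role"] == SampleRole.spike_pre_extraction.value, "conc"].mean()
        c_un = grp.loc[grp["role"] == SampleRole.field.value, "conc"].mean()
        if np.isnan(c_un):
            c_un = 0.0
        out[soil_id] = relative_recovery(c_sp, c_un, spike_level_ng_g)
    return out


def score_and_select(
    candidates: list[AssignmentCandidate],
    band: tuple[float, float] = (70.0, 120.0),
) -> tuple[AssignmentCandidate, pd.DataFrame]:
    """Rank candidates and select the winner; returns (chosen, audit trail).

    Scoring is a strict total order - band count, then dispersion, then
    |dRT|, then ILIS id - so the assignment is deterministic given inputs.
    """
    lo, hi = band
    for c in candidates:
        recs = np.array(list(c.per_soil_recovery.values()), dtype=float)
        ok = np.isfinite(recs)
        c.n_soils_in_band = int(np.sum((recs[ok] >= lo) & (recs[ok] <= hi)))
        c.dispersion = float(np.sum(np.abs(recs[ok] - 100.0))) if ok.any() else float("inf")
    ranked = sorted(
        candidates, key=lambda c: (-c.n_soils_in_band, c.dispersion, abs(c.delta_rt), c.ilis_id)
    )
    audit = pd.DataFrame(
        [
            {
                "rank": k + 1,
                "analyte_id": c.analyte_id,
                "ilis_id": c.ilis_id,
                "delta_rt": c.delta_rt,
                "n_soils_in_band": c.n_soils_in_band,
                "dispersion": c.dispersion,
                **{f"recovery_{s}": v for s, v in sorted(c.per_soil_recovery.items())},
            }
            for k, c in enumerate(ranked)
        ]
    )
    return ranked[0], audit


def assign_ilis(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
    spike_level_ng_g: float = 2.5,
    rt_window_min: float = 2.0,
    band: Optional[tuple[float, float]] = None,
) -> tuple[MethodConfig, pd.DataFrame]:
    """Assign a surrogate ILIS to every analyte lacking a si-ILIS.

    Returns a new MethodConfig with ``assigned_ilis_id`` frozen in, plus
    the full candidate audit table.  Analytes whose best candidate misses
    the band in at least one soil are flagged in the audit
    (``all_soils_in_band`` False), not rejected.
    """
    if band is None:
        band = config.recovery_band
    audits = []
    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    for a in config.analytes:
        if a.si_ilis_id is not None:
            continue
        try:
            cands = enumerate_candidates(a, config, rt_window_min)
        except AssignmentError:
            unassigned.append(a.analyte_id)
            continue
        for c in cands:
            c.per_soil_recovery = candidate_recoveries(
                measurements, design, config, a.analyte_id, c.ilis_id, spike_level_ng_g
            )
        chosen, audit = score_and_select(cands, band)
        n_soils = len(chosen.per_soil_recovery)
        audit["chosen"] = audit["ilis_id"] == chosen.ilis_id
        audit["all_soils_in_band"] = audit["n_soils_in_band"] == n_soils
        audits.append(audit)
        assignments[a.analyte_id] = chosen.ilis_id
    new_analytes = [
        a.model_copy(update={"assigned_ilis_id": assignments.get(a.analyte_id, a.assigned_ilis_id)})
        for a in config.analytes
    ]
    new_config = config.model_copy(update={"analytes": new_analytes})
    audit_df = (
        pd.concat(audits, ignore_index=True)
        if audits
        else pd.DataFrame(columns=["rank", "analyte_id", "ilis_id"])
    )
    audit_df.attrs["unassigned"] = unassigned
    return MethodConfig.model_validate(new_config.model_dump()), audit_df
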