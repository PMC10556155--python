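"""Electrospray matrix effects, the global correction factor, and LOQs.

The matrix effect of an analyte in a soil extract is quantified from
post-extraction spikes:

    ME [%] = (1 - (PA_spiked - PA_unspiked) / reference) * (-100)

where the reference is either the mean peak area in a solvent standard
(case i) or the spiked-minus-unspiked mean in the S2 calibration matrix
(case ii).  Positive values indicate ion enhancement, negative values ion
suppression.

Method LOQs are defined on the calibration-level grid: the lowest
matrix-matched standard whose quantifier and qualifier reach S/N >= 10 and
>= 3 and whose ion ratio matches the batch reference.  Because field soils
can suppress more than the S2 calibration matrix, S2-based MLOQs are
multiplied by a global matrix correction factor derived from the case (ii)
suppression distribution across soils.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import MethodConfig, SampleRole

NOT_DETERMINED = float("nan")


def matrix_effect(
    pa_spiked: float | np.ndarray,
    pa_unspiked: float | np.ndarray,
    pa_reference: float | np.ndarray,
) -> float | np.ndarray:
    """Matrix effect [%]; negative = ion suppression, positive = enhancement."""
    ref = np.asarray(pa_reference, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference peak area must be positive")
    out = (1.0 - (np.asarray(pa_spiked, float) - np.asarray(pa_unspiked, float)) / ref) * (-100.0)
    return float(out) if np.ndim(out) == 0 else out


def matrix_effect_table(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
    reference_case: str = "solvent_standard",
    reference_soil: str = "S2",
) -> pd.DataFrame:
    """Per analyte x soil matrix effects from the post-extraction experiment.

    Spiked extracts are ``spike_post_extraction`` samples with a positive
    nominal level; unspiked extracts are the same role at level 0.  Case
    ``solvent_standard`` references the mean solvent-standard area at the
    matching level; case ``s2_extract`` references the spiked-minus-unspiked
    mean of ``reference_soil``.
    """
    if reference_case not in ("solvent_standard", "s2_extract"):
        raise ValueError(f"unknown reference case {reference_case!r}")
    quant = measurements[measurements["transition_role"] == "quantifier"]
    areas = quant.set_index(["sample_id", "species_id"])["peak_area"]
    post = design[design["role"] == SampleRole.spike_post_extraction.value]
    analyte_ids = [a.analyte_id for a in config.analytes]

    def mean_areas(sample_ids: Iterable[str]) -> pd.Series:
        sel = areas.loc[list(sample_ids)]
        return sel.groupby(level="species_id").mean().reindex(analyte_ids)

    by_soil: dict[str, tuple[pd.Series, pd.Series]] = {}
    for soil_id, grp in post.groupby("soil_id"):
        spiked = grp[grp["nominal_level"] > 0]["sample_id"]
        unspiked = grp[grp["nominal_level"] == 0]["sample_id"]
        if spiked.empty or unspiked.empty:
            raise ValueError(f"soil {soil_id}: need spiked and unspiked post-extraction samples")
        by_soil[soil_id] = (mean_areas(spiked), mean_areas(unspiked))

    if reference_case == "solvent_standard":
        solv = design[design["role"] == SampleRole.solvent_standard.value]
        level = post[post["nominal_level"] > 0]["nominal_level"].iloc[0]
        ref_ids = solv[np.isclose(solv["nominal_level"], level)]["sample_id"]
        if ref_ids.empty:
            raise ValueError("no solvent reference standards at the spike level")
        reference = mean_areas(ref_ids)
    else:
        if reference_soil not in by_soil:
            raise ValueError(f"reference soil {reference_soil} missing from the experiment")
        sp, un = by_soil[reference_soil]
        reference = sp - un

    rows = []
    for soil_id, (sp, un) in sorted(by_soil.items()):
        me = matrix_effect(sp.to_numpy(), un.to_numpy(), reference.to_numpy())
        rows.append(
            pd.DataFrame(
                {
                    "analyte_id": analyte_ids,
                    "soil_id": soil_id,
                    "matrix_effect_pct": me,
                    "reference_case": reference_case,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def summarize_matrix_effects(effects: pd.DataFrame) -> pd.DataFrame:
    """Median / min / max matrix effect per soil."""
    return (
        effects.groupby("soil_id")["matrix_effect_pct"]
        .agg(["median", "min", "max", "count"])
        .reset_index()
    )


def correction_factor(max_suppression_pct: float, granularity: float = 0.5) -> float:
    """MLOQ correction factor for a maximal allowed ion suppression.

    ``1 / (1 - s/100)`` rounded *up* to the configured granularity - the
    conservative direction, since the factor only ever raises MLOQs.
    A maximal suppression of 50% gives exactly 2.
    """
    if not 0 <= max_suppression_pct < 100:
        raise ValueError("suppression magnitude must be in [0, 100)")
    raw = 1.0 / (1.0 - max_suppression_pct / 100.0)
    return math.ceil(raw / granularity - 1e-9) * granularity


@dataclass
class GlobalFactorResult:
    factor: float
    max_suppression_pct: float
    n_exceeding: int
    exceeding_analytes: list[str]
    warning: str = ""


def derive_global_factor(
    effects: pd.DataFrame,
    max_exceedances: int = 3,
    candidate_suppressions: Sequence[float] = tuple(range(0, 100, 5)),
    granularity: float = 0.5,
    per_analyte: bool = True,
) -> GlobalFactorResult:
    """Choose the global matrix correction factor from case (ii) effects.

    Selects the smallest suppression magnitude ``s`` on the candidate grid
    such that at most ``max_exceedances`` suppressions are more negative
    than ``-s``, then converts it with :func:`correction_factor`.  With
    ``per_analyte`` (the default) an analyte counts once via its worst
    suppression over all soils; otherwise analyte x soil pairs are pooled.
    Analytes still exceeding the chosen ``-s`` are reported for flagging.
    """
    if (effects["reference_case"] != "s2_extract").any():
        raise ValueError("global factor must be derived from s2_extract (case ii) effects")
    if per_analyte:
        worst = effects.groupby("analyte_id")["matrix_effect_pct"].min()
    else:
        worst = effects.set_index("analyte_id")["matrix_effect_pct"]
    for s in sorted(candidate_suppressions):
        exceed = worst[worst < -s]
        if len(exceed) <= max_exceedances:
            return GlobalFactorResult(
                factor=correction_factor(s, granularity),
                max_suppression_pct=float(s),
                n_exceeding=len(exceed),
                exceeding_analytes=sorted(set(exceed.index)),
            )
    s = max(candidate_suppressions)
    exceed = worst[worst < -s]
    return GlobalFactorResult(
        factor=correction_factor(s, granularity),
        max_suppression_pct=float(s),
        n_exceeding=len(exceed),
        exceeding_analytes=sorted(set(exceed.index)),
        warning=f"no grid value leaves <= {max_exceedances} exceedances; largest factor reported",
    )


# ---------------------------------------------------------------------------
# limits of quantification
# ---------------------------------------------------------------------------

def determine_iloq(
    levels: Sequence[float],
    snr_quantifier: Sequence[float],
    snr_qualifier: Sequence[float],
    snr_quant_min: float = 10.0,
    snr_qual_min: float = 3.0,
) -> float:
    """Instrumental LOQ: lowest solvent-standard level meeting the S/N rules.

    Thresholds are inclusive.  Returns NaN (not determined) when no level
    qualifies.
    """
    order = np.argsort(np.asarray(levels, dtype=float))
    for i in order:
        if snr_quantifier[i] >= snr_quant_min and snr_qualifier[i] >= snr_qual_min:
            return float(levels[i])
    return NOT_DETERMINED


@dataclass
class MloqRecord:
    analyte_id: str
    iloq_ng_mL: float
    base_mloq_ng_g: float  # S2-matrix based; snaps to the calibration-level grid
    corrected_mloq_ng_g: float
    factor_used: float


def determine_mloq(
    levels: Sequence[float],
    snr_quantifier: Sequence[float],
    snr_qualifier: Sequence[float],
    ratio_pass: Sequence[bool],
    factor: float,
    analyte_id: str = "",
    iloq_ng_mL: float = NOT_DETERMINED,
    snr_quant_min: float = 10.0,
    snr_qual_min: float = 3.0,
) -> MloqRecord:
    """Method LOQ from a matrix-matched series: S/N rules plus ion-ratio match.

    The base MLOQ is the lowest qualifying calibration level (ng/mL in
    extract, equivalent to ng/g at the 5 g / 5 mL design); the corrected
    MLOQ multiplies it by the global matrix correction factor (>= 1).
    """
    if factor < 1:
        raise ValueError("correction factor must be >= 1")
    order = np.argsort(np.asarray(levels, dtype=float))
    base = NOT_DETERMINED
    for i in order:
        if (
            snr_quantifier[i] >= snr_quant_min
            and snr_qualifier[i] >= snr_qual_min
            and bool(ratio_pass[i])
        ):
            base = float(levels[i])
            break
    corrected = base * factor if np.isfinite(base) else NOT_DETERMINED
    return MloqRecord(analyte_id, iloq_ng_mL, base, corrected, factor)


def mloq_table(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
    references: pd.DataFrame,
    factor: Optional[float] = None,
) -> pd.DataFrame:
    """ILOQ and MLOQ per analyte from the batch's standards.

    MLOQs come from the matrix-matched calibration standards (level means
    of S/N, ion ratio checked against the batch reference); ILOQs from the
    solvent-standard series when present.
    """
    if factor is None:
        factor = config.global_matrix_correction_factor
    cal = design[design["role"] == SampleRole.cal_standard.value]
    solv = design[design["role"] == SampleRole.solvent_standard.value]
    m = measurements.merge(
        design[["sample_id", "role", "nominal_level"]], on="sample_id", how="left"
    )
    records = []
    for a in config.analytes:
        sp = m[m["species_id"] == a.analyte_id]
        ref = references.loc[a.analyte_id]

        def series_for(sample_ids: pd.Series) -> pd.DataFrame:
            sel = sp[sp["sample_id"].isin(sample_ids)]
            wide = sel.pivot_table(
                index="nominal_level", columns="transition_role",
                values=["snr", "peak_area"], aggfunc="mean",
            )
            return wide

        iloq = NOT_DETERMINED
        if not solv.empty:
            wide = series_for(solv["sample_id"])
            if not wide.empty:
                iloq = determine_iloq(
                    wide.index.to_numpy(),
                    wide[("snr", "quantifier")].to_numpy(),
                    wide[("snr", "qualifier")].to_numpy(),
                    config.snr_quant_min,
                    config.snr_qual_min,
                )
        wide = series_for(cal["sample_id"])
        ratios = wide[("peak_area", "qualifier")] / wide[("peak_area", "quantifier")]
        if np.isfinite(ref["mean_ratio"]) and ref["mean_ratio"] > 0:
            from .identification import ratio_tolerance

            tol = ratio_tolerance(float(ref["mean_ratio"]))
            ratio_ok = (
                (ratios - ref["mean_ratio"]).abs() / ref["mean_ratio"] <= tol / 100.0 + 1e-12
            ).to_numpy()
        else:
            ratio_ok = np.zeros(len(wide), dtype=bool)
        rec = determine_mloq(
            wide.index.to_numpy(),
            wide[("snr", "quantifier")].to_numpy(),
            wide[("snr", "qualifier")].to_numpy(),
            ratio_ok,
            factor,
            analyte_id=a.analyte_id,
            iloq_ng_mL=iloq,
            snr_quant_min=config.snr_quant_min,
            snr_qual_min=config.snr_qual_min,
        )
        records.append(rec.__dict__)
    return pd.DataFrame(records)
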