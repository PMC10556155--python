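"""Concentration calculation, censoring and site-level summaries.

Gated PARs are converted to extract concentrations through the calibration
curve, then to ng/g dry weight via the sample's extract volume and
dry-weight soil mass.  Each analyte x sample result carries a censoring
state: ``quantified``, ``below_mloq``, ``above_linear_range`` (flagged for
re-dilution, never extrapolated), ``unconfirmed`` (identification failed
at a reportable level), or ``ilis_missing`` (undefined PAR).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationCurve
from .model import MethodConfig, SampleRole, SoilMeta, dry_weight_equivalent

CENSOR_ORDER = ["quantified", "below_mloq", "above_linear_range", "unconfirmed", "ilis_missing"]


class QuantificationError(ValueError):
    pass


def quantify(
    pars: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    qc: pd.DataFrame,
    mloqs: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
    soils: Optional[Mapping[str, SoilMeta]] = None,
    censored_substitution: float = 0.0,
) -> pd.DataFrame:
    """Quantify every analyte x sample and apply censoring.

    ``pars`` is the output of :func:`soilmrm.calibration.par_table`, ``qc``
    of :func:`soilmrm.identification.qc_table`, ``mloqs`` of
    :func:`soilmrm.matrix_effects.mloq_table`.  ``censored_substitution``
    (a fraction of the MLOQ, default 0) is what censored values contribute
    to sums downstream.
    """
    soils = soils or {}
    dinfo = design.set_index("sample_id")
    qc_idx = qc.set_index(["sample_id", "analyte_id"])
    mloq_idx = mloqs.set_index("analyte_id")
    rows = []
    sample_roles = dinfo["role"]
    for (sample_id, analyte_id), row in pars.set_index(["sample_id", "analyte_id"]).iterrows():
        role = sample_roles.get(sample_id)
        if role in (SampleRole.cal_standard.value, SampleRole.solvent_standard.value):
            continue
        curve = curves.get(analyte_id)
        if curve is None:
            continue
        if curve.slope <= 0:
            raise QuantificationError(f"{analyte_id}: non-positive calibration slope")
        d = dinfo.loc[sample_id]
        soil = soils.get(d["soil_id"])
        wc = soil.water_content_pct if soil is not None else 0.0
        dm = dry_weight_equivalent(d["soil_mass_g"], wc)
        mloq = mloq_idx.loc[analyte_id]
        mloq_ng_g = float(mloq["corrected_mloq_ng_g"])
        factor_scale = d["extract_volume_mL"] / dm

        if not row["par_defined"]:
            censor, extract_conc, conc = "ilis_missing", np.nan, np.nan
        else:
            extract_conc = float(curve.concentration(row["par"]))
            conc = extract_conc * factor_scale
            flags = qc_idx.loc[(sample_id, analyte_id)]
            id_ok = bool(flags["rt_pass"]) and bool(flags["ratio_pass"])
            low = curve.linear_low if curve.linear_low is not None else -np.inf
            high = curve.linear_high if curve.linear_high is not None else np.inf
            if np.isfinite(mloq_ng_g) and conc < mloq_ng_g or extract_conc < low:
                censor = "below_mloq"
            elif not id_ok:
                censor = "unconfirmed"
            elif extract_conc > high:
                censor = "above_linear_range"
            else:
                censor = "quantified"
        rows.append(
            {
                "analyte_id": analyte_id,
                "sample_id": sample_id,
                "soil_id": d["soil_id"],
                "role": role,
                "conc_ng_g": conc if censor == "quantified" else np.nan,
                "conc_uncensored_ng_g": conc,
                "extract_conc_ng_mL": extract_conc,
                "censor": censor,
                "mloq_applied_ng_g": mloq_ng_g,
                "substituted_ng_g": (
                    conc
                    if censor == "quantified"
                    else (censored_substitution * mloq_ng_g if np.isfinite(mloq_ng_g) else 0.0)
                ),
            }
        )
    return pd.DataFrame(rows)


def summarize_site(records: pd.DataFrame, config: Optional[MethodConfig] = None) -> dict:
    """Detection count, sum concentration and per-class counts for one site.

    Replicates of an analyte are averaged before summing; censored results
    contribute their substitution value (0 by default).
    """
    per_analyte = records.groupby("analyte_id").agg(
        detected=("censor", lambda c: (c == "quantified").any()),
        mean_conc=("substituted_ng_g", "mean"),
    )
    detected = per_analyte[per_analyte["detected"]]
    n_detected = int(len(detected))
    sum_conc = float(detected["mean_conc"].sum())
    class_counts: dict[str, int] = {}
    if config is not None and n_detected:
        amap = config.analyte_map
        for aid in detected.index:
            cls = amap[aid].pesticide_class.value
            class_counts[cls] = class_counts.get(cls, 0) + 1
    return {"n_detected": n_detected, "sum_conc_ng_g": sum_conc, "class_counts": class_counts}


def screen_blanks(records: pd.DataFrame) -> list[str]:
    """Batch blank control: analytes quantifiable above MLOQ in any matrix
    blank void their results for the whole batch.

    Returns the offending analyte ids; callers drop or flag their records.
    """
    blanks = records[records["role"] == SampleRole.matrix_blank.value]
    voided = blanks.loc[blanks["censor"] == "quantified", "analyte_id"]
    return sorted(voided.unique())


def percentage_difference(x: float, y: float) -> float:
    """Signed percentage difference of two group summaries, relative to x.

    ``(x - y) / x * 100``; undefined (NaN) when x is 0.
    """
    if x == 0:
        return float("nan")
    return (x - y) / x * 100.0


def compare_groups(a, b, alpha: float = 0.05) -> dict:
    """Two-sided F-test for variance equality plus homoscedastic t-test.

    Both groups need n >= 2.  The degenerate case of zero variance in both
    groups with equal means returns p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"f_p": 1.0, "t_p": 1.0, "t_stat": 0.0, "significant": False}
        return {"f_p": 1.0, "t_p": 0.0, "t_stat": np.inf, "significant": True}
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    f_p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "f_p": float(f_p),
        "t_p": float(t_p),
        "t_stat": float(t_stat),
        "significant": bool(t_p < alpha),
    }
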