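"""Identification gating: retention time and qualifier/quantifier ion ratio.

A candidate detection is reportable only when (i) its retention time
matches the batch's calibration standards within +/- 0.05 min and (ii) its
qualifier-to-quantifier ion ratio falls within the banded relative
tolerance of EC Directive 2002/657/EC around the batch-mean reference
ratio:

    ratio > 0.5         +/- 20%
    0.2 < ratio <= 0.5  +/- 25%
    0.1 < ratio <= 0.2  +/- 30%
    ratio <= 0.1        +/- 50%

Band boundaries are assigned to the lower band (a reference ratio of
exactly 0.5 gets +/- 25%); the Directive's text is ambiguous here and the
convention is configurable via a custom band table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import MethodConfig, SampleRole

#: (exclusive lower bound on the reference ratio, tolerance %)
DEFAULT_RATIO_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 20.0),
    (0.2, 25.0),
    (0.1, 30.0),
    (0.0, 50.0),
)


@dataclass
class IdFlags:
    rt_pass: bool
    ratio_pass: bool
    ratio_observed: float
    ratio_reference: float
    ratio_tolerance_pct: float
    delta_rt: float
    reason: str = ""

    @property
    def reportable(self) -> bool:
        return self.rt_pass and self.ratio_pass


def ratio_tolerance(
    mean_ratio: float, bands: Sequence[tuple[float, float]] = DEFAULT_RATIO_BANDS
) -> float:
    """Banded relative tolerance (+/- %) for a reference ion ratio."""
    if not mean_ratio > 0:
        raise ValueError(f"reference ion ratio must be positive, got {mean_ratio}")
    for lower, tol in bands:
        if mean_ratio > lower:
            return tol
    return bands[-1][1]


def ion_ratio_reference(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
) -> pd.DataFrame:
    """Batch reference per analyte: mean ion ratio and mean standard RT.

    Averages over all calibration standards in the sequence in which both
    transitions were detected (area > 0).
    """
    cal_ids = design.loc[design["role"] == SampleRole.cal_standard.value, "sample_id"]
    cal = measurements[measurements["sample_id"].isin(cal_ids)]
    wide = cal.pivot_table(
        index=["sample_id", "species_id"], columns="transition_role", values=["peak_area", "rt"]
    )
    area_q = wide[("peak_area", "quantifier")]
    area_l = wide[("peak_area", "qualifier")]
    both = (area_q > 0) & (area_l > 0)
    ratio = (area_l / area_q)[both]
    rt_std = wide[("rt", "quantifier")][area_q > 0]
    out = pd.DataFrame(
        {
            "mean_ratio": ratio.groupby(level="species_id").mean(),
            "n_standards": ratio.groupby(level="species_id").size(),
            "rt_reference": rt_std.groupby(level="species_id").mean(),
        }
    )
    out.index.name = "analyte_id"
    analyte_ids = [a.analyte_id for a in config.analytes]
    return out.reindex(analyte_ids)


def check_identification(
    ratio_observed: float,
    rt_observed: float,
    reference: pd.Series,
    rt_tol_min: float = 0.05,
    bands: Sequence[tuple[float, float]] = DEFAULT_RATIO_BANDS,
) -> IdFlags:
    """Gate one candidate detection against the batch reference.

    ``reference`` needs ``mean_ratio`` and ``rt_reference``.  A missing
    qualifier (observed ratio 0 or NaN) fails the ratio gate with a
    "qualifier absent" reason rather than raising.
    """
    mean_ratio = float(reference["mean_ratio"])
    rt_ref = float(reference["rt_reference"])
    delta_rt = rt_observed - rt_ref
    rt_pass = abs(delta_rt) <= rt_tol_min + 1e-12
    tol = ratio_tolerance(mean_ratio, bands)
    if not np.isfinite(ratio_observed) or ratio_observed <= 0:
        return IdFlags(rt_pass, False, float(ratio_observed), mean_ratio, tol, delta_rt,
                       reason="qualifier absent")
    rel_dev = abs(ratio_observed - mean_ratio) / mean_ratio
    ratio_pass = rel_dev <= tol / 100.0 + 1e-12
    reason = "" if ratio_pass else "ion ratio outside tolerance"
    return IdFlags(rt_pass, ratio_pass, ratio_observed, mean_ratio, tol, delta_rt, reason)


def qc_table(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
    references: Optional[pd.DataFrame] = None,
    rt_tol_min: Optional[float] = None,
    bands: Sequence[tuple[float, float]] = DEFAULT_RATIO_BANDS,
) -> pd.DataFrame:
    """Identification flags for every analyte x non-standard sample."""
    if references is None:
        references = ion_ratio_reference(measurements, design, config)
    if rt_tol_min is None:
        rt_tol_min = config.rt_match_tol_min
    cal_ids = set(design.loc[design["role"] == SampleRole.cal_standard.value, "sample_id"])
    samples = measurements[~measurements["sample_id"].isin(cal_ids)]
    wide = samples.pivot_table(
        index=["sample_id", "species_id"], columns="transition_role", values=["peak_area", "rt"]
    )
    rows = []
    for a in config.analytes:
        ref = references.loc[a.analyte_id]
        for sample_id in wide.index.get_level_values("sample_id").unique():
            try:
                rec = wide.loc[(sample_id, a.analyte_id)]
            except KeyError:
                continue
            area_q = rec[("peak_area", "quantifier")]
            area_l = rec[("peak_area", "qualifier")]
            ratio = area_l / area_q if area_q > 0 else np.nan
            if not np.isfinite(ref["mean_ratio"]):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "analyte_id": a.analyte_id,
                        "rt_pass": False,
                        "ratio_pass": False,
                        "ratio_observed": ratio,
                        "ratio_reference": np.nan,
                        "ratio_tolerance_pct": np.nan,
                        "delta_rt": np.nan,
                        "reason": "no batch reference",
                    }
                )
                continue
            flags = check_identification(
                ratio, rec[("rt", "quantifier")], ref, rt_tol_min, bands
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "analyte_id": a.analyte_id,
                    "rt_pass": flags.rt_pass,
                    "ratio_pass": flags.ratio_pass,
                    "ratio_observed": flags.ratio_observed,
                    "ratio_reference": flags.ratio_reference,
                    "ratio_tolerance_pct": flags.ratio_tolerance_pct,
                    "delta_rt": flags.delta_rt,
                    "reason": flags.reason,
                }
            )
    return pd.DataFrame(rows)
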