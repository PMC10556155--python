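"""Matrix-matched internal-standard calibration with 1/x weighting.

The calibration response is the peak area ratio (PAR): the analyte's
quantifier peak area (summed over chromatographically separated
stereoisomers) divided by the quantifier peak area of its assigned ILIS.
Curves are fitted by weighted linear least squares with weights 1/x, the
standard choice for heteroscedastic MS calibration spanning three orders
of magnitude.  Linearity is reviewed by back-calculating every calibration
level; a level passes when the back-calculated concentration deviates at
most 20% (inclusive) from nominal, and the linear range is trimmed only at
the edges (contiguously), with interior failures flagged for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import MethodConfig, SampleRole


class CalibrationError(ValueError):
    """Calibration cannot be fitted from the provided levels."""


@dataclass
class CalibrationCurve:
    analyte_id: str
    slope: float
    intercept: float
    r_squared: float  # weighted (consistent with the 1/x fit)
    r_squared_unweighted: float
    weighting: str = "one_over_x"
    #: per fit point: nominal, par, backcalc, deviation_pct
    level_backcalc: pd.DataFrame = field(default_factory=pd.DataFrame)
    linear_low: Optional[float] = None
    linear_high: Optional[float] = None
    n_levels_used: int = 0
    interior_failures: list[float] = field(default_factory=list)

    def concentration(self, par: float | np.ndarray) -> float | np.ndarray:
        """Back-calculate an extract concentration (ng/mL) from a PAR."""
        return (par - self.intercept) / self.slope


# ---------------------------------------------------------------------------
# peak area ratios
# ---------------------------------------------------------------------------

def _quantifier_areas(measurements: pd.DataFrame) -> pd.DataFrame:
    q = measurements[measurements["transition_role"] == "quantifier"]
    return q.pivot(index="sample_id", columns="species_id", values="peak_area")


def par_table(
    measurements: pd.DataFrame,
    config: MethodConfig,
    ilis_override: Optional[Mapping[str, str]] = None,
    analyte_ids: Optional[list[str]] = None,
) -> pd.DataFrame:
    """PAR per sample x analyte.

    Stereoisomer groups are pre-summed on the analyte side.  A zero or
    missing ILIS area yields an undefined PAR (``par`` NaN,
    ``par_defined`` False); the sample is excluded from downstream fits
    rather than raising.

    ``ilis_override`` maps analyte_id -> ilis_id and is used by the
    surrogate-ILIS selection to evaluate alternative pairings.
    """
    areas = _quantifier_areas(measurements)
    rows = []
    selected = config.analytes
    if analyte_ids is not None:
        wanted = set(analyte_ids)
        selected = [a for a in config.analytes if a.analyte_id in wanted]
    for a in selected:
        ilis_id = (ilis_override or {}).get(a.analyte_id) or config.ilis_for(a.analyte_id)
        members = config.stereo_members(a.analyte_id)
        analyte_area = areas[[m for m in members if m in areas.columns]].sum(axis=1)
        if ilis_id is None or ilis_id not in areas.columns:
            ilis_area = pd.Series(np.nan, index=areas.index)
        else:
            ilis_area = areas[ilis_id]
        defined = ilis_area.notna() & (ilis_area > 0)
        par = analyte_area.where(defined) / ilis_area.where(defined)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": areas.index,
                    "analyte_id": a.analyte_id,
                    "ilis_id": ilis_id,
                    "analyte_area": analyte_area.to_numpy(),
                    "ilis_area": ilis_area.to_numpy(),
                    "par": par.to_numpy(),
                    "par_defined": defined.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def compute_par(
    measurements: pd.DataFrame,
    config: MethodConfig,
    sample_id: str,
    analyte_id: str,
    ilis_override: Optional[Mapping[str, str]] = None,
) -> tuple[float, bool]:
    """Single-sample PAR; returns (value, defined)."""
    table = par_table(
        measurements[measurements["sample_id"] == sample_id], config, ilis_override
    )
    row = table[table["analyte_id"] == analyte_id].iloc[0]
    return float(row["par"]), bool(row["par_defined"])


# ---------------------------------------------------------------------------
# weighted fit
# ---------------------------------------------------------------------------

def fit_calibration(
    levels: np.ndarray | list[float],
    pars: np.ndarray | list[float],
    analyte_id: str = "",
    min_levels: int = 5,
) -> CalibrationCurve:
    """1/x-weighted linear least-squares calibration fit.

    Minimises ``sum(w_i * (PAR_i - a - b x_i)^2)`` with ``w_i = 1/x_i``.
    Replicate standards at a level enter as individual fit points.
    Requires at least ``min_levels`` distinct levels with defined PAR.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(pars, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    x, y = x[ok], y[ok]
    if (x <= 0).any():
        raise CalibrationError(f"{analyte_id}: non-positive level under 1/x weighting")
    n_distinct = len(np.unique(x))
    if n_distinct < min_levels:
        raise CalibrationError(
            f"{analyte_id}: only {n_distinct} usable levels (< {min_levels})"
        )
    w = 1.0 / x
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = model.params
    backcalc = (y - intercept) / slope
    dev_pct = 100.0 * (backcalc - x) / x
    # unweighted R^2 on the same points, for reporting
    ybar = y.mean()
    ss_res = float(np.sum((y - model.fittedvalues) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2_unw = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(
        analyte_id=analyte_id,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(model.rsquared),
        r_squared_unweighted=r2_unw,
        level_backcalc=pd.DataFrame(
            {"nominal": x, "par": y, "backcalc": backcalc, "deviation_pct": dev_pct}
        ),
        n_levels_used=n_distinct,
    )


def review_linearity(
    curve: CalibrationCurve,
    tol_pct: float = 20.0,
    qualifying_low: Optional[float] = None,
) -> pd.DataFrame:
    """Per-level pass/fail and contiguous edge trimming of the linear range.

    A level passes when the mean back-calculated concentration of its
    replicates deviates at most ``tol_pct`` % from nominal (boundary
    inclusive).  The linear range runs from the lowest passing level - no
    lower than ``qualifying_low``, the lowest level that also meets the
    S/N and ion-ratio rules - to the highest passing level.  Interior
    failures do not truncate the range; they are recorded in
    ``curve.interior_failures``.
    """
    lb = curve.level_backcalc
    per_level = (
        lb.groupby("nominal", sort=True)
        .agg(backcalc=("backcalc", "mean"))
        .reset_index()
    )
    per_level["deviation_pct"] = (
        100.0 * (per_level["backcalc"] - per_level["nominal"]) / per_level["nominal"]
    )
    per_level["passes"] = per_level["deviation_pct"].abs() <= tol_pct + 1e-12
    passing = per_level[per_level["passes"]]["nominal"]
    if passing.empty:
        raise CalibrationError(f"{curve.analyte_id}: no calibration level within linearity")
    low, high = float(passing.min()), float(passing.max())
    inside = per_level[(per_level["nominal"] >= low) & (per_level["nominal"] <= high)]
    curve.interior_failures = inside[~inside["passes"]]["nominal"].tolist()
    if qualifying_low is not None:
        low = max(low, qualifying_low)
    curve.linear_low, curve.linear_high = low, high
    return per_level


def calibrate_batch(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    config: MethodConfig,
    ilis_override: Optional[Mapping[str, str]] = None,
) -> dict[str, CalibrationCurve]:
    """Fit and linearity-review curves for every analyte in the batch."""
    cal = design[design["role"] == SampleRole.cal_standard.value]
    levels = cal.set_index("sample_id")["nominal_level"]
    pars = par_table(
        measurements[measurements["sample_id"].isin(cal["sample_id"])], config, ilis_override
    )
    curves: dict[str, CalibrationCurve] = {}
    for analyte_id, grp in pars.groupby("analyte_id"):
        if config.ilis_for(analyte_id) is None and not (ilis_override or {}).get(analyte_id):
            continue  # unassigned analyte: no PAR, flagged upstream
        x = levels.reindex(grp["sample_id"]).to_numpy()
        curve = fit_calibration(x, grp["par"].to_numpy(), analyte_id=analyte_id)
        review_linearity(curve, tol_pct=config.linearity_tol_pct)
        curves[analyte_id] = curve
    return curves


def curves_frame(curves: Mapping[str, CalibrationCurve]) -> pd.DataFrame:
    """One row per analyte, stable column order."""
    return pd.DataFrame(
        [
            {
                "analyte_id": c.analyte_id,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "linear_low": c.linear_low,
                "linear_high": c.linear_high,
                "n_levels_used": c.n_levels_used,
            }
            for c in curves.values()
        ]
    ).sort_values("analyte_id", ignore_index=True)
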