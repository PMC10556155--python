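"""Figures of merit: recoveries, precision tiers, trueness, z-scores.

Two recovery notions are kept strictly apart.  The *relative* recovery is
ILIS-corrected (quantified concentration of a freshly spiked soil, minus
the unspiked native level, over the spike); with a pre-extraction-spiked
internal standard it measures how well the ILIS compensates losses and
matrix effects, and sits near 100% even when extraction is lossy.  The
*absolute* recovery compares uncorrected analyte responses of a
pre-extraction spike against a post-extraction spike and measures the
extraction efficiency itself.  The gap between the two is the rationale
for spiking the ILIS before extraction.

Precision is the relative standard deviation (sample sd, n-1) on the
tier's aggregation level: raw replicates for instrumental and intra-day
precision, day means for inter-day, operator means for inter-person.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


def relative_recovery(
    conc_spiked_ng_g: float, conc_unspiked_ng_g: float, spike_level_ng_g: float
) -> float:
    """ILIS-corrected recovery [%] of a freshly spiked soil."""
    if spike_level_ng_g <= 0:
        raise ValueError("spike level must be positive")
    return 100.0 * (conc_spiked_ng_g - conc_unspiked_ng_g) / spike_level_ng_g


def absolute_recovery_quechers(
    pre_spike_response: float,
    post_spike_response: float,
    blank_response: float = 0.0,
) -> float:
    """Extraction efficiency [%] from uncorrected analyte peak areas.

    Pre- and post-extraction spikes at matched nominal concentration;
    blank subtraction removes native residues.  Returns NaN (flagged)
    when the post spike does not exceed the blank.
    """
    denom = post_spike_response - blank_response
    if denom <= 0:
        return float("nan")
    return 100.0 * (pre_spike_response - blank_response) / denom


@dataclass
class PrecisionRecord:
    analyte_id: str
    tier: str  # instrumental | intra_day | inter_day | inter_person
    rsd_pct: float
    n_groups: int
    n_values: int


_TIER_MIN = {"instrumental": 3, "intra_day": 3, "inter_day": 3, "inter_person": 2}


def precision(
    values: Sequence[float],
    tier: str,
    grouping: Optional[Sequence[str]] = None,
    analyte_id: str = "",
) -> PrecisionRecord:
    """RSD [%] at the tier's aggregation level.

    ``grouping`` holds day labels (inter_day) or operator labels
    (inter_person); those tiers first average within groups and compute
    the RSD across group means.  A zero mean yields an undefined RSD.
    """
    if tier not in _TIER_MIN:
        raise ValueError(f"unknown precision tier {tier!r}")
    v = pd.Series(np.asarray(values, dtype=float)).dropna()
    if tier in ("inter_day", "inter_person"):
        if grouping is None:
            raise ValueError(f"{tier} precision requires a grouping")
        g = pd.Series(list(grouping))[v.index]
        agg = v.groupby(g.to_numpy()).mean()
    else:
        agg = v
    if len(agg) < _TIER_MIN[tier]:
        raise ValueError(f"{tier}: need >= {_TIER_MIN[tier]} groups, got {len(agg)}")
    mean = agg.mean()
    rsd = float("nan") if mean == 0 else 100.0 * agg.std(ddof=1) / mean
    return PrecisionRecord(analyte_id, tier, float(rsd), len(agg), len(v))


def trueness_vs_reference(
    measured: Mapping[str, float],
    target: Mapping[str, float] | float,
    band_pct: float = 20.0,
) -> pd.DataFrame:
    """Per-analyte deviation [%] from the reference-soil target.

    ``target`` is a per-analyte mapping or a single nominal spike level.
    The summary fraction of analytes beyond +/- band_pct is attached as
    ``.attrs['fraction_beyond_band']``.
    """
    rows = []
    for aid, m in measured.items():
        t = target[aid] if isinstance(target, Mapping) else float(target)
        dev = 100.0 * (m - t) / t
        rows.append({"analyte_id": aid, "measured_ng_g": m, "target_ng_g": t, "deviation_pct": dev})
    df = pd.DataFrame(rows)
    df.attrs["fraction_beyond_band"] = float((df["deviation_pct"].abs() > band_pct).mean())
    return df


def z_scores(
    lab_values: Mapping[str, float],
    peer_values: Mapping[str, Sequence[float]],
    min_peers: int = 4,
) -> pd.DataFrame:
    """Proficiency z-scores with robust assigned value and dispersion.

    ``z = (x_lab - median(peers)) / (1.4826 * MAD(peers))`` - the
    median/MADe simplification of the robust proficiency statistics.
    |z| <= 1 good, <= 2 satisfactory, <= 3 questionable, else
    unsatisfactory.  Panels smaller than 8 peers are flagged
    (``small_panel``): very small panels call for dedicated small-n
    procedures.
    """
    rows = []
    for aid, x in lab_values.items():
        peers = np.asarray(peer_values[aid], dtype=float)
        if len(peers) < min_peers:
            raise ValueError(f"{aid}: need >= {min_peers} peer values")
        assigned = float(np.median(peers))
        sigma_pt = 1.4826 * float(np.median(np.abs(peers - assigned)))
        z = (x - assigned) / sigma_pt if sigma_pt > 0 else float("nan")
        az = abs(z)
        label = (
            "undefined"
            if not np.isfinite(z)
            else "good"
            if az <= 1
            else "satisfactory"
            if az <= 2
            else "questionable"
            if az <= 3
            else "unsatisfactory"
        )
        rows.append(
            {
                "analyte_id": aid,
                "z": z,
                "assigned": assigned,
                "sigma_pt": sigma_pt,
                "label": label,
                "small_panel": len(peers) < 8,
            }
        )
    return pd.DataFrame(rows)
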