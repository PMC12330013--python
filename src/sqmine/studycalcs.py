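"""Downstream decision rules on externally produced cohort tables.

Three small calculations that post-process results computed elsewhere:

* responder calling on per-ASV differential-abundance tables (log2 fold
  change + BH-adjusted p, e.g. from DESeq2), under either a dual-control
  intersection rule or a control-exclusion rule;
* absolute ASV abundance, scaling relative read abundances by qPCR-derived
  total 16S rRNA gene copy numbers;
* 13CO2 breath production rate from paired atom-percent-excess (APE)
  measurements taken 30 s and 90 s after closing the breath container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BreathSample",
    "call_responders_dual_control",
    "call_responders_excluding_control",
    "absolute_abundance",
    "co2_production_rate",
    "breath_rate_table",
    "peak_rate_timepoint",
]

REQUIRED_DA_COLUMNS = ("asv_id", "log2_fold_change", "adjusted_p")


def _check_da(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = set(REQUIRED_DA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    p = df["adjusted_p"].astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError(f"{name}: adjusted_p outside [0, 1]")
    return df


def _enriched(df: pd.DataFrame, alpha: float) -> set[str]:
    """ASVs with increased abundance: log2 fold change > 0 and adjusted
    p strictly below alpha."""
    mask = (df["log2_fold_change"].astype(float) > 0) & (
        df["adjusted_p"].astype(float) < alpha
    )
    return set(df.loc[mask, "asv_id"])


def call_responders_dual_control(
    res_vs_baseline: pd.DataFrame,
    res_vs_low_dose_control: pd.DataFrame,
    alpha: float = 0.01,
) -> set[str]:
    """ASVs significantly enriched in BOTH comparisons.

    Used when a treatment is judged against two controls at once (its 0 h
    baseline and a minimal-dose control at the same time point): only ASVs
    enriched (lfc > 0, adjusted p < alpha) in both tables respond to the
    amendment. ASVs absent from either table are excluded.
    """
    a = _enriched(_check_da(res_vs_baseline, "res_vs_baseline"), alpha)
    b = _enriched(_check_da(res_vs_low_dose_control, "res_vs_low_dose_control"), alpha)
    return a & b


def call_responders_excluding_control(
    res_treatment_vs_t0: pd.DataFrame,
    res_control_vs_t0: pd.DataFrame,
    alpha: float = 0.01,
) -> set[str]:
    """ASVs enriched over time in the treatment but NOT in the unamended
    control — removes taxa that bloom regardless of the amendment."""
    treat = _enriched(_check_da(res_treatment_vs_t0, "res_treatment_vs_t0"), alpha)
    ctrl = _enriched(_check_da(res_control_vs_t0, "res_control_vs_t0"), alpha)
    return treat - ctrl


def absolute_abundance(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``absolute_copies = relative_abundance * total_copies``.

    ``records`` needs columns ``relative_abundance`` (fraction of reads,
    in [0, 1]) and ``total_copies`` (total 16S rRNA gene copies per gram
    from qPCR); vectorized over any number of ASV/sample/time rows.
    """
    missing = {"relative_abundance", "total_copies"} - set(records.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    rel = records["relative_abundance"].astype(float)
    if ((rel < 0) | (rel > 1)).any():
        bad = records.loc[(rel < 0) | (rel > 1)]
        raise ValueError(
            f"relative_abundance outside [0, 1] in {len(bad)} row(s)"
        )
    total = records["total_copies"].astype(float)
    if (total <= 0).any():
        raise ValueError("total_copies must be positive")
    out = records.copy()
    out["absolute_copies"] = rel * total
    return out


@dataclass(frozen=True)
class BreathSample:
    """Paired breath-gas draws from one mouse at one time point.

    ``ape_30s``/``ape_90s`` are atom percent excess 13C of CO2 in the two
    draws; ``co2_mass_in_container`` is the CO2 mass (µg) in the sealed
    1-l container, a parameter of the experimental setup.
    """

    mouse_id: str
    time_point_h: float
    ape_30s: float
    ape_90s: float
    co2_mass_in_container: float

    def __post_init__(self) -> None:
        for name in ("ape_30s", "ape_90s"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"{self.mouse_id}: missing/invalid {name}")
            if v < 0:
                raise ValueError(f"{self.mouse_id}: {name} must be >= 0")


def co2_production_rate(sample: BreathSample, delta_t_min: float = 1.0) -> float:
    """µg 13CO2 produced per minute between the 30 s and 90 s draws.

    rate = ((ape_90s − ape_30s) / 100 × CO2 mass in container) / Δt,
    with Δt = 1 min (90 s − 30 s). A negative APE difference is returned
    as-is with a warning (it indicates a sampling problem, not uptake).
    """
    diff = sample.ape_90s - sample.ape_30s
    if diff < 0:
        warnings.warn(
            f"{sample.mouse_id} @ {sample.time_point_h} h: APE decreased "
            "between draws; rate reported as negative",
            stacklevel=2,
        )
    return (diff / 100.0) * sample.co2_mass_in_container / delta_t_min


def breath_rate_table(samples: Iterable[BreathSample]) -> pd.DataFrame:
    rows = [
        {
            "mouse_id": s.mouse_id,
            "time_point_h": s.time_point_h,
            "rate_ug_13co2_per_min": co2_production_rate(s),
        }
        for s in samples
    ]
    return pd.DataFrame(
        rows, columns=["mouse_id", "time_point_h", "rate_ug_13co2_per_min"]
    )


def peak_rate_timepoint(rates: pd.DataFrame) -> tuple[float, float]:
    """(time point, mean rate) of the maximum mean rate across mice."""
    if rates.empty:
        raise ValueError("empty rate table")
    mean = rates.groupby("time_point_h")["rate_ug_13co2_per_min"].mean()
    t = float(mean.idxmax())
    return t, float(mean.loc[t])
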