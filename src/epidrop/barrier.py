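"""Epithelial barrier function: TEER and FITC-dextran permeability.

Transepithelial electrical resistance (TEER) is measured with chopstick
electrodes across a Transwell insert; the cell-free (blank) insert
resistance is subtracted and the remainder multiplied by the membrane area,
giving Ω·cm² (0.33 cm² nominal for a 6.5 mm insert).

Paracellular permeability is probed by loading FITC-dextran apically and
sampling the basal compartment hourly; the least-squares slope of basal
amount vs. time is the flux rate, optionally normalized to the apical load
(fraction of load per hour). A tight epithelium transports far less tracer
than a bare membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_MEMBRANE_AREA_CM2",
    "TEERRecord",
    "PermeabilitySeries",
    "FluxResult",
    "teer",
    "teer_timecourse",
    "flux_rate",
]

#: Nominal growth area of a 6.5 mm Transwell insert.
DEFAULT_MEMBRANE_AREA_CM2 = 0.33


@dataclass(frozen=True)
class TEERRecord:
    """One raw TEER reading with its blank and membrane geometry."""

    raw_resistance: float
    blank_resistance: float
    membrane_area: float = DEFAULT_MEMBRANE_AREA_CM2
    day: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.raw_resistance < 0 or self.blank_resistance < 0:
            raise ValueError("resistances must be non-negative")
        if not self.membrane_area > 0:
            raise ValueError("membrane_area must be positive")


@dataclass(frozen=True)
class PermeabilitySeries:
    """Cumulative basal tracer amounts sampled over time for one insert."""

    times: np.ndarray
    basal_amounts: np.ndarray
    apical_concentration: float = 10.0  # mg/ml dextran load
    apical_volume_ml: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amounts = np.asarray(self.basal_amounts, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "basal_amounts", amounts)
        if times.size != amounts.size:
            raise ValueError("times and basal_amounts differ in length")
        if times.size < 3:
            raise ValueError("need >= 3 time points for a flux slope")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class FluxResult:
    """Flux regression output: slope (amount/h) and normalized rate."""

    slope: float
    intercept: float
    stderr: float
    normalized_flux: float | None


def teer(record: TEERRecord) -> float:
    """Blank-subtracted, area-normalized resistance in Ω·cm².

    ``(raw − blank) · membrane_area``. A raw reading below its blank yields
    a negative value, returned as-is with a warning — measurement noise
    near zero resistance should stay visible, not be clipped away.
    """
    value = (record.raw_resistance - record.blank_resistance) * record.membrane_area
    if value < 0:
        warnings.warn(
            f"raw resistance {record.raw_resistance} Ω below blank "
            f"{record.blank_resistance} Ω (condition={record.condition!r}, "
            f"day={record.day}); returning negative TEER",
            stacklevel=2,
        )
    return value


def teer_timecourse(records: Iterable[TEERRecord]) -> pd.DataFrame:
    """Mean ± SD TEER per condition per day, ready for time-course plots.

    All replicates within one (condition, day) cell must share the same
    membrane area, otherwise their Ω·cm² values are not commensurate.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "condition": rec.condition,
                "day": rec.day,
                "area": rec.membrane_area,
                "teer": teer(rec),
            }
        )
    if not rows:
        raise ValueError("no TEER records")
    frame = pd.DataFrame(rows)
    if (frame.groupby(["condition", "day"])["area"].nunique() > 1).any():
        raise ValueError("mixed membrane areas within a condition/day group")
    out = (
        frame.groupby(["condition", "day"])["teer"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def flux_rate(series: PermeabilitySeries) -> FluxResult:
    """Least-squares tracer flux through the insert.

    ``slope`` is the regression slope of basal amount vs. time (amount per
    hour). When the apical volume is known, ``normalized_flux`` expresses
    the slope as a fraction of the apical load (concentration × volume)
    transported per hour. Decreasing cumulative amounts are physically
    impossible and flagged as sampling noise, but the slope is still
    returned.
    """
    if np.any(np.diff(series.basal_amounts) < 0):
        warnings.warn(
            "cumulative basal amounts decrease between samples "
            f"(condition={series.condition!r}); treating as sampling noise",
            stacklevel=2,
        )
    fit = stats.linregress(series.times, series.basal_amounts)
    normalized = None
    if series.apical_volume_ml is not None:
        load = series.apical_concentration * series.apical_volume_ml
        if load <= 0:
            raise ValueError("apical load must be positive for normalization")
        normalized = fit.slope / load
    return FluxResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr) if np.isfinite(fit.stderr) else 0.0,
        normalized_flux=normalized,
    )
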