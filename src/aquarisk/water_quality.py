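"""Data model and descriptive statistics for well measurements.

Covers the pre-simulation half of the pipeline: per-parameter summary
statistics over a well network (with explicit left-censoring policy),
screening of those summaries against drinking-water guideline values,
and the between-campaign percent-change arithmetic used to compare
monitoring rounds decades apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .censoring import CensorPolicy, substitute

log = logging.getLogger(__name__)

#: canonical internal concentration unit
MG_PER_L = "mg/L"
UG_PER_L = "ug/L"

#: conversion factors into mg/L for the units the package accepts;
#: unit strings not listed here are carried through unconverted
#: (pH units, uS/cm, mgCaCO3/L) and are rejected by the exposure engine
UNIT_TO_MG_L = {MG_PER_L: 1.0, UG_PER_L: 1e-3, "μg/L": 1e-3}

MEASUREMENT_COLUMNS = ["well_id", "governorate", "parameter", "value", "units", "censored"]


@dataclass(frozen=True)
class ParameterProfile:
    """Identity and reference values for one water-quality parameter.

    ``guideline`` is the drinking-water guideline value in the display
    units; ``rfd`` is the chronic oral reference dose in mg per kg body
    weight per day.  Either may be absent (``None``) — a parameter
    without a guideline is "not screenable", one without an RfD is "not
    assessable" for hazard quotients.
    """

    id: str
    units: str
    detection_limit: float | None = None
    guideline: float | None = None
    rfd: float | None = None
    rfd_source: str = "USEPA"

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError(f"{self.id}: units must be declared")
        for name in ("detection_limit", "guideline", "rfd"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.id}: {name} must be positive, got {v}")

    @property
    def convertible(self) -> bool:
        return self.units in UNIT_TO_MG_L

    def to_mg_per_l(self, value: float) -> float:
        """Convert a value in this parameter's display units to mg/L."""
        try:
            factor = UNIT_TO_MG_L[self.units]
        except KeyError:
            raise ValueError(
                f"{self.id}: units {self.units!r} are not a mass concentration; "
                "cannot convert to mg/L"
            ) from None
        if factor != 1.0:
            log.debug("%s: converting %s -> mg/L (factor %g)", self.id, self.units, factor)
        return value * factor


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics of one parameter over the well network."""

    n: int
    max: float
    min: float
    mean: float
    median: float
    sd: float
    fraction_censored: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.min <= self.median <= self.max:
            raise ValueError(
                f"order violated: min {self.min} <= median {self.median} <= max {self.max}"
            )
        if not self.min <= self.mean <= self.max:
            raise ValueError(f"mean {self.mean} outside [{self.min}, {self.max}]")
        if not 0 <= self.fraction_censored <= 1:
            raise ValueError("fraction_censored must lie in [0, 1]")

    @property
    def all_censored(self) -> bool:
        return self.fraction_censored == 1.0


@dataclass(frozen=True)
class ScreeningRecord:
    """Outcome of comparing a parameter against its guideline value."""

    parameter: str
    status: str  # "screened" | "not_screenable"
    guideline: float | None = None
    mean: float | None = None
    mean_above_guideline: bool | None = None
    exceedance_fraction: float | None = None  # fraction of wells above, if well data given


def summarize(
    values,
    censored=None,
    censor_policy: CensorPolicy | str = CensorPolicy.HALF_LOD,
) -> SummaryStats:
    """Summary statistics after applying the censoring policy.

    ``values`` hold the detection limit wherever ``censored`` is true.
    Statistics are computed on the substituted values except min/max of
    a fully censored parameter, which keep the detection limit so the
    summary row reads like the source table ("<LOD" everywhere).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("summarize requires at least one measurement")
    if np.any(values < 0):
        raise ValueError("concentrations must be non-negative")
    if censored is None:
        censored = np.zeros(values.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    frac = float(censored.mean())
    if frac == 1.0:
        # keep the detection limit itself so the row mirrors "<LOD"
        lod = float(values[0])
        return SummaryStats(
            n=values.size, max=lod, min=lod, mean=lod, median=lod, sd=0.0,
            fraction_censored=1.0,
        )
    subs = substitute(values, censored, censor_policy)
    return SummaryStats(
        n=int(values.size),
        max=float(subs.max()),
        min=float(subs.min()),
        mean=float(subs.mean()),
        median=float(np.median(subs)),
        sd=float(subs.std(ddof=1)) if subs.size > 1 else 0.0,
        fraction_censored=frac,
    )


def summary_table(
    measurements: pd.DataFrame,
    censor_policy: CensorPolicy | str = CensorPolicy.HALF_LOD,
) -> pd.DataFrame:
    """Per-parameter summary of a long-format measurement table.

    Expects the measurement CSV schema (``well_id, governorate,
    parameter, value, units, censored``) and returns one row per
    parameter in first-appearance order, shaped like a water-quality
    summary table.
    """
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    rows = []
    for param in measurements["parameter"].drop_duplicates():
        sub = measurements[measurements["parameter"] == param]
        units = sub["units"].unique()
        if len(units) > 1:
            raise ValueError(f"{param}: mixed units {sorted(units)}")
        s = summarize(sub["value"].to_numpy(), sub["censored"].to_numpy(), censor_policy)
        rows.append(
            {
                "parameter": param,
                "units": units[0],
                "n": s.n,
                "max": s.max,
                "min": s.min,
                "mean": s.mean,
                "median": s.median,
                "sd": s.sd,
                "fraction_censored": s.fraction_censored,
                "all_censored": s.all_censored,
            }
        )
    return pd.DataFrame(rows)


def screen_guidelines(
    profile: ParameterProfile,
    stats: SummaryStats | None = None,
    values=None,
) -> ScreeningRecord:
    """Compare a parameter against its drinking-water guideline.

    Exceedance is strict (``>``): a mean exactly at the guideline is not
    flagged.  With well-level ``values`` the fraction of wells above the
    guideline is also reported.  A profile without a guideline yields an
    explicit ``not_screenable`` record rather than a silent pass.
    """
    if profile.guideline is None:
        return ScreeningRecord(parameter=profile.id, status="not_screenable")
    if stats is None and values is None:
        raise ValueError("provide summary stats or well-level values")
    mean = stats.mean if stats is not None else float(np.mean(values))
    frac = None
    if values is not None:
        values = np.asarray(values, dtype=float)
        frac = float((values > profile.guideline).mean())
    return ScreeningRecord(
        parameter=profile.id,
        status="screened",
        guideline=profile.guideline,
        mean=mean,
        mean_above_guideline=bool(mean > profile.guideline),
        exceedance_fraction=frac,
    )


def percent_change(old_mean: float, new_mean: float) -> float:
    """Signed percent change between two campaign means: 100*(new-old)/old."""
    if old_mean <= 0:
        raise ValueError(f"old mean must be positive, got {old_mean}")
    return 100.0 * (new_mean - old_mean) / old_mean


# ---------------------------------------------------------------------------
# CSV I/O

def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a long-format well-measurement CSV (comment lines allowed)."""
    df = pd.read_csv(path, comment="#")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_summary_csv(
    table: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a summary table, optionally prefixed with '#' provenance lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)
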