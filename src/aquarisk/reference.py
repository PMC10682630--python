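"""Packaged reference tables for the Gaza Strip groundwater study system.

Ships, as plain CSV inside the package, everything needed to run the
full risk assessment with zero downloads:

* the 2022 per-parameter well-summary table for the 115-well municipal
  network (max/min/mean/median/SD, WHO guideline values, censoring
  status, single-well point-source anomalies);
* the USEPA chronic oral reference doses used for hazard quotients;
* alternate health-based thresholds (WHO/EFSA nitrate ADI, EFSA
  fluoride adequate intake) reported alongside — never silently
  substituted for — the USEPA values.
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

from .water_quality import ParameterProfile, SummaryStats

log = logging.getLogger(__name__)

_DATA = resources.files("aquarisk") / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path)


def load_summary_table() -> pd.DataFrame:
    """The 2022 well-network summary table (one row per parameter)."""
    df = _read("gaza_well_summary_2022.csv")
    if (df["parameter"] == "Mn").any():
        log.warning(
            "Mn guideline stored as printed in the source summary (0.8 on the "
            "ug/L row); its magnitude is inconsistent with WHO practice — "
            "override the profile if screening Mn matters."
        )
    return df


def load_rfd_table() -> dict[str, float]:
    """USEPA chronic oral reference doses, mg/kg/day, keyed by parameter."""
    df = _read("oral_reference_doses.csv")
    if (df["parameter"] == "Ag").any():
        log.warning(
            "Ag oral reference dose taken as 5.0e-3 mg/kg/day (standard USEPA "
            "value); the source table prints an inconsistent exponent. "
            "Override via the run config if needed."
        )
    return dict(zip(df["parameter"], df["rfd_mg_kg_day"].astype(float)))


def load_alternate_thresholds() -> pd.DataFrame:
    """WHO/EFSA intake benchmarks reported alongside the USEPA RfDs."""
    return _read("alternate_thresholds.csv")


def load_profiles(rfd_overrides: dict[str, float] | None = None) -> dict[str, ParameterProfile]:
    """Parameter profiles merging units, detection limits, guidelines and RfDs."""
    summary = load_summary_table()
    rfds = load_rfd_table()
    if rfd_overrides:
        rfds.update(rfd_overrides)
    profiles: dict[str, ParameterProfile] = {}
    for row in summary.itertuples(index=False):
        profiles[row.parameter] = ParameterProfile(
            id=row.parameter,
            units=row.units,
            detection_limit=None if pd.isna(row.detection_limit) else float(row.detection_limit),
            guideline=None if pd.isna(row.who_guideline) else float(row.who_guideline),
            rfd=rfds.get(row.parameter),
        )
    return profiles


def summary_stats_for(parameter: str, summary: pd.DataFrame | None = None) -> SummaryStats:
    """SummaryStats for one parameter of the packaged summary table."""
    if summary is None:
        summary = load_summary_table()
    sub = summary[summary["parameter"] == parameter]
    if sub.empty:
        known = ", ".join(summary["parameter"])
        raise KeyError(f"unknown parameter {parameter!r}; known: {known}")
    row = sub.iloc[0]
    frac = 1.0 if row["status"] == "all_censored" else 0.0
    return SummaryStats(
        n=115,
        max=float(row["max"]),
        min=float(row["min"]),
        mean=float(row["mean"]),
        median=float(row["median"]),
        sd=float(row["sd"]),
        fraction_censored=frac,
    )
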