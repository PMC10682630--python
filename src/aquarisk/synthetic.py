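"""Synthetic well-level measurement tables for the Gaza groundwater network.

The published record of the 115-well 2022 campaign is a per-parameter
summary table; the well-level observations themselves are not openly
deposited.  This module generates well-level tables with the statistical
structure the downstream analysis assumes — independent lognormal
marginals matched to each parameter's mean/SD, fully-censored trace
metals emitted at their detection limits, and single-well point-source
anomalies (PO4, Cu) — so every stage of the pipeline can be exercised
and validated end to end.

What it deliberately does not emulate: spatial gradients across
governorates, inter-parameter correlation (real wells correlate, e.g.
Cl with Na under seawater intrusion), and paired multi-campaign
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distributions import lognormal_from_mean_sd
from .water_quality import MEASUREMENT_COLUMNS

__all__ = [
    "GOVERNORATES",
    "DEFAULT_GOVERNORATE_COUNTS",
    "ParameterTarget",
    "GeneratorConfig",
    "generate_wells",
    "config_from_summary",
    "write_measurements_csv",
]

GOVERNORATES = ("Northern", "Gaza", "Deir al-Balah", "Khan Yunis", "Rafah")

#: well counts of the five governorates in the 2022 campaign (sum 115)
DEFAULT_GOVERNORATE_COUNTS: dict[str, int] = {
    "Northern": 30,
    "Gaza": 34,
    "Deir al-Balah": 18,
    "Khan Yunis": 22,
    "Rafah": 11,
}


@dataclass(frozen=True)
class ParameterTarget:
    """Generation target for one parameter.

    ``mode`` selects the emission rule:

    * ``lognormal`` — draw from the lognormal moment-matched to
      (mean, sd); ``min``/``max`` are only used by the clip policy;
    * ``all_censored`` — every well below the detection limit;
    * ``point_source`` — one detected well at ``point_value``, all
      others censored at the detection limit.
    """

    id: str
    units: str
    mode: str = "lognormal"
    mean: float | None = None
    sd: float | None = None
    min: float | None = None
    max: float | None = None
    detection_limit: float | None = None
    point_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("lognormal", "all_censored", "point_source"):
            raise ValueError(f"{self.id}: unknown mode {self.mode!r}")
        if self.mode == "lognormal":
            if self.mean is None or self.mean <= 0:
                raise ValueError(f"{self.id}: lognormal target needs a positive mean")
            if self.sd is None or self.sd < 0:
                raise ValueError(f"{self.id}: lognormal target needs a non-negative sd")
        if self.mode in ("all_censored", "point_source"):
            if self.detection_limit is None or self.detection_limit <= 0:
                raise ValueError(
                    f"{self.id}: mode {self.mode!r} emits censored rows and "
                    "needs a positive detection limit"
                )
        if self.mode == "point_source" and (self.point_value is None or self.point_value <= 0):
            raise ValueError(f"{self.id}: point_source needs a positive point_value")


@dataclass
class GeneratorConfig:
    """Full configuration of a synthetic campaign."""

    parameters: list[ParameterTarget] = field(default_factory=list)
    governorate_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GOVERNORATE_COUNTS)
    )
    n_wells: int | None = None  # default: sum of governorate counts
    clip: str = "none"  # "none" | "minmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip not in ("none", "minmax"):
            raise ValueError(f"clip policy must be 'none' or 'minmax', got {self.clip!r}")
        unknown = set(self.governorate_counts) - set(GOVERNORATES)
        if unknown:
            raise ValueError(f"unknown governorates: {sorted(unknown)}")
        if any(c < 0 for c in self.governorate_counts.values()):
            raise ValueError("governorate counts must be non-negative")
        total = sum(self.governorate_counts.values())
        if self.n_wells is None:
            self.n_wells = total
        elif self.n_wells != total:
            raise ValueError(
                f"governorate counts sum to {total}, not the configured {self.n_wells} wells"
            )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "clip": self.clip,
            "governorate_counts": dict(self.governorate_counts),
            "parameters": [
                {k: v for k, v in vars(t).items() if v is not None}
                for t in self.parameters
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        params = [ParameterTarget(**p) for p in d.pop("parameters", [])]
        return cls(parameters=params, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _assign_governorates(counts: dict[str, int]) -> list[str]:
    """Quota-limited round robin over the governorates, by well index."""
    remaining = {g: counts.get(g, 0) for g in GOVERNORATES}
    order = [g for g in GOVERNORATES if remaining[g] > 0]
    out: list[str] = []
    while order:
        for g in list(order):
            out.append(g)
            remaining[g] -= 1
            if remaining[g] == 0:
                order.remove(g)
    return out


def generate_wells(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the long-format well-measurement table.

    One row per (well, parameter); fixed seed gives a byte-identical
    table.  Parameters are generated from independent child random
    streams in configuration order.
    """
    n = config.n_wells
    governorates = _assign_governorates(config.governorate_counts)
    width = max(3, len(str(n)))
    well_ids = [f"W{i + 1:0{width}d}" for i in range(n)]

    frames = []
    children = np.random.SeedSequence(config.seed).spawn(max(len(config.parameters), 1))
    for target, child in zip(config.parameters, children):
        rng = np.random.default_rng(child)
        if target.mode == "all_censored":
            values = np.full(n, float(target.detection_limit))
            censored = np.ones(n, dtype=bool)
        elif target.mode == "point_source":
            values = np.full(n, float(target.detection_limit))
            censored = np.ones(n, dtype=bool)
            hit = int(rng.integers(n))
            values[hit] = float(target.point_value)
            censored[hit] = False
        else:
            spec = lognormal_from_mean_sd(target.mean, target.sd)
            values = spec.sample(n, rng)
            if config.clip == "minmax":
                lo = target.min if target.min is not None else -np.inf
                hi = target.max if target.max is not None else np.inf
                values = np.clip(values, lo, hi)
            censored = np.zeros(n, dtype=bool)
        frames.append(
            pd.DataFrame(
                {
                    "well_id": well_ids,
                    "governorate": governorates,
                    "parameter": target.id,
                    "value": values,
                    "units": target.units,
                    "censored": censored,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def config_from_summary(
    summary: pd.DataFrame, seed: int = 0, clip: str = "none"
) -> GeneratorConfig:
    """Build a generator config from a summary table in the packaged schema.

    Rows flagged ``all_censored`` / ``point_source`` map to the matching
    emission modes; everything else becomes a moment-matched lognormal
    target.
    """
    targets = []
    for row in summary.itertuples(index=False):
        status = getattr(row, "status", "detected")
        dl = getattr(row, "detection_limit", None)
        dl = None if dl is None or pd.isna(dl) else float(dl)
        if status == "all_censored":
            targets.append(
                ParameterTarget(id=row.parameter, units=row.units,
                                mode="all_censored", detection_limit=dl)
            )
        elif status == "point_source":
            targets.append(
                ParameterTarget(id=row.parameter, units=row.units, mode="point_source",
                                detection_limit=dl, point_value=float(row.point_value))
            )
        else:
            targets.append(
                ParameterTarget(id=row.parameter, units=row.units, mode="lognormal",
                                mean=float(row.mean), sd=float(row.sd),
                                min=float(row.min), max=float(row.max),
                                detection_limit=dl)
            )
    return GeneratorConfig(parameters=targets, seed=seed, clip=clip)


def write_measurements_csv(
    table: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write the measurement table as CSV (deterministic formatting)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)
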