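"""Hazard quotients and exceedance probabilities for drinking-water exposure.

The hazard quotient of chemical *i* is the ratio of its simulated
chronic daily intake to a health-based reference dose:

    HQ_i = Exp_i / RfD_i

HQ below 1 indicates exposure below the level considered safe for
lifelong intake.  Because division by a positive constant is monotone,
every HQ percentile is the matching exposure percentile divided by the
RfD — an identity this module relies on and the test suite asserts.

Exceedance probabilities (the fraction of Monte Carlo trials strictly
above a threshold dose) are reported with a binomial standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import DistributionSpec
from .exposure import (
    DEFAULT_N_ITER,
    DEFAULT_SEED,
    ExposureResult,
    ExposureScenario,
    sample_exposure,
)

__all__ = [
    "RiskResult",
    "ExceedanceEstimate",
    "hazard_quotient",
    "exceedance_probability",
    "hq_table",
    "relative_exposure",
    "format_hq_report",
    "HQ_PERCENTILES",
]

HQ_PERCENTILES = (25, 50, 75, 90, 95, 99)


@dataclass
class RiskResult:
    """Hazard-quotient draws for one (parameter, scenario) pair."""

    parameter: str
    scenario: str
    rfd: float
    rfd_source: str
    n_iter: int
    seed: object
    draws: np.ndarray = field(repr=False)  # HQ = exposure / rfd, elementwise

    @property
    def exceedance_fraction(self) -> float:
        """Pr(HQ > 1), strict: ties count as non-exceeding."""
        return float((self.draws > 1.0).mean())

    def percentile(self, p, method: str = "linear"):
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        if np.any((p_arr <= 0) | (p_arr >= 100)):
            raise ValueError(f"percentiles must lie strictly in (0, 100), got {p}")
        out = np.percentile(self.draws, p_arr, method=method)
        return float(out[0]) if np.isscalar(p) else out


@dataclass(frozen=True)
class ExceedanceEstimate:
    """Empirical exceedance fraction with its binomial standard error."""

    fraction: float
    se: float
    n: int
    threshold: float


def hazard_quotient(
    exposure: ExposureResult, rfd: float, rfd_source: str = "USEPA"
) -> RiskResult:
    """Divide exposure draws by a positive oral reference dose."""
    if rfd is None or not rfd > 0:
        raise ValueError(f"oral reference dose must be positive, got {rfd}")
    return RiskResult(
        parameter=exposure.parameter,
        scenario=exposure.scenario,
        rfd=float(rfd),
        rfd_source=rfd_source,
        n_iter=exposure.n_iter,
        seed=exposure.seed,
        draws=exposure.draws / rfd,
    )


def exceedance_probability(
    exposure: ExposureResult, threshold: float
) -> ExceedanceEstimate:
    """Fraction of exposure draws strictly above a threshold dose."""
    if threshold is None or not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    n = exposure.n_iter
    p = float((exposure.draws > threshold).mean())
    return ExceedanceEstimate(
        fraction=p, se=float(np.sqrt(p * (1 - p) / n)), n=n, threshold=float(threshold)
    )


def hq_table(
    conc_specs: dict[str, DistributionSpec],
    scenarios: list[ExposureScenario],
    rfd_table: dict[str, float],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = DEFAULT_SEED,
    percentiles=HQ_PERCENTILES,
    rfd_sources: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hazard-quotient summary: one block per scenario, one row per parameter.

    Parameters without an RfD appear with status ``not_assessable`` and
    empty percentile columns rather than being dropped silently.  Each
    parameter uses a seed derived from (seed, parameter index), shared
    across scenarios, so cross-population contrasts are matched on the
    underlying random stream.
    """
    rows = []
    params = list(conc_specs)
    for scenario in scenarios:
        for idx, param in enumerate(params):
            rfd = rfd_table.get(param)
            row = {"scenario": scenario.name, "parameter": param}
            if rfd is None:
                row["status"] = "not_assessable"
                for p in percentiles:
                    row[f"p{p:g}"] = np.nan
                row.update(exceedance=np.nan, rfd=np.nan, rfd_source="")
            else:
                exp = sample_exposure(
                    conc_specs[param], scenario, n_iter=n_iter,
                    seed=[seed, idx], parameter=param,
                )
                hq = hazard_quotient(
                    exp, rfd, (rfd_sources or {}).get(param, "USEPA")
                )
                row["status"] = "assessed"
                for p in percentiles:
                    row[f"p{p:g}"] = hq.percentile(p)
                row.update(
                    exceedance=hq.exceedance_fraction,
                    rfd=hq.rfd,
                    rfd_source=hq.rfd_source,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def relative_exposure(
    scenario_a: ExposureScenario,
    scenario_b: ExposureScenario,
    conc: DistributionSpec,
    statistic="median",
    n_iter: int = DEFAULT_N_ITER,
    seed: int = DEFAULT_SEED,
) -> float:
    """Signed percent change in an exposure statistic from scenario A to B.

    Both simulations run on the same seed (matched random streams), so
    the contrast isolates the scenario parameters from sampling noise.
    ``statistic`` is ``"median"``, ``"mean"`` or a percentile in (0, 100).
    """
    a = sample_exposure(conc, scenario_a, n_iter=n_iter, seed=seed)
    b = sample_exposure(conc, scenario_b, n_iter=n_iter, seed=seed)
    stat_a, stat_b = (_statistic(r, statistic) for r in (a, b))
    if stat_a == 0:
        raise ValueError("reference-scenario statistic is zero; relative change undefined")
    return 100.0 * (stat_b - stat_a) / stat_a


def _statistic(result: ExposureResult, statistic) -> float:
    if statistic == "median":
        return result.percentile(50)
    if statistic == "mean":
        return float(result.draws.mean())
    return result.percentile(float(statistic))


def format_hq_report(table: pd.DataFrame, small: float = 0.01) -> str:
    """Plain-text HQ report rendering values below ``small`` as "<0.01".

    The CSV written by the pipeline keeps full precision; this rendering
    is for the human-readable report only.
    """
    pcols = [c for c in table.columns if c.startswith("p") and c[1:].replace(".", "").isdigit()]
    lines = []
    for scenario, block in table.groupby("scenario", sort=False):
        lines.append(f"=== {scenario} ===")
        header = ["parameter"] + [c.upper() for c in pcols] + ["Pr(HQ>1)", "RfD"]
        lines.append("  ".join(f"{h:>9}" for h in header))
        for row in block.itertuples(index=False):
            if getattr(row, "status", "assessed") != "assessed":
                cells = [row.parameter] + ["n/a"] * (len(pcols) + 2)
            else:
                cells = [row.parameter]
                for c in pcols:
                    v = getattr(row, c)
                    cells.append(f"<{small:g}" if v < small else f"{v:.2f}")
                cells.append(f"{row.exceedance:.3f}")
                cells.append(f"{row.rfd:g}")
            lines.append("  ".join(f"{c:>9}" for c in cells))
        lines.append("")
    return "\n".join(lines)
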