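"""Handling of left-censored (below detection limit) measurements.

Environmental laboratories report a value below the instrumental
detection limit only as "<LOD".  Before any statistic can be computed
such values must be replaced by a number; the substitution rule is a
policy decision, not a property of the data, so it is explicit
everywhere in this package.
"""

from __future__ import annotations

from enum import Enum

import numpy as np


class CensorPolicy(str, Enum):
    """Substitution rule for left-censored values.

    Censored entries carry the detection limit as their numeric value;
    the policy decides what number enters the statistics.
    """

    HALF_LOD = "half_lod"  # LOD/2, the common environmental default
    FULL_LOD = "full_lod"  # keep the detection limit itself
    ZERO = "zero"          # treat non-detects as zero


def substitute(
    values: np.ndarray,
    censored: np.ndarray,
    policy: CensorPolicy | str = CensorPolicy.HALF_LOD,
) -> np.ndarray:
    """Return a copy of ``values`` with censored entries substituted.

    ``values`` holds the detection limit wherever ``censored`` is true.
    """
    policy = CensorPolicy(policy)
    values = np.asarray(values, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if values.shape != censored.shape:
        raise ValueError("values and censored flags must have the same shape")
    out = values.copy()
    if policy is CensorPolicy.HALF_LOD:
        out[censored] = values[censored] / 2.0
    elif policy is CensorPolicy.ZERO:
        out[censored] = 0.0
    # FULL_LOD keeps the detection limit as-is
    return out
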