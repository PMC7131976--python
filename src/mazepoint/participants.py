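"""Cohort scoring and filtering: Raw-TLX, visible-error exclusion, SOD split.

Three cohort-level rules precede any error analysis. Raw TLX condenses the
six workload subscales into their arithmetic mean. Participants whose mean
error on the *visible* pointing trials -- trials so easy they index task
compliance rather than spatial knowledge -- falls above Q3 + 1.5 IQR of the
pool are excluded. The remaining participants are split into low and high
sense-of-direction (SOD) halves at the median SOD score of their
experiment pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantProfile",
    "raw_tlx",
    "exclude_by_visible_error",
    "sod_median_split",
]

TLX_SCALE = (1.0, 10.0)   # the study used a 10-point scale per subscale


@dataclass
class ParticipantProfile:
    """One participant's scores and derived labels."""

    participant: str
    group: str                       # "G" | "G+E" | "E"
    experiment: int
    sod_score: float
    sod_level: str | None = None     # assigned by the median split
    tlx_items: dict[int, tuple[float, ...]] = field(default_factory=dict)
    mean_visible_error: dict[int, float] = field(default_factory=dict)
    excluded: bool = False


def raw_tlx(items) -> float:
    """Raw TLX: the mean of the six workload subscale ratings."""
    items = tuple(float(x) for x in items)
    if len(items) != 6:
        raise ValueError(f"Raw TLX needs exactly six ratings, got {len(items)}")
    lo, hi = TLX_SCALE
    if any(not (lo <= x <= hi) for x in items):
        raise ValueError(f"TLX ratings must lie in [{lo}, {hi}]")
    return sum(items) / 6.0


def exclude_by_visible_error(mean_visible_errors: dict[str, float]
                             ) -> set[str]:
    """Participants whose mean visible-trial error is an upper outlier.

    Uses the Tukey fence Q3 + 1.5 IQR over the pooled per-participant means,
    with linear-interpolation quartiles; only values strictly above the
    fence are excluded. Needs at least four participants for the quartiles
    to be meaningful.
    """
    if len(mean_visible_errors) < 4:
        raise ValueError("need at least 4 participants to estimate quartiles")
    vals = np.array(list(mean_visible_errors.values()), dtype=float)
    q1, q3 = np.percentile(vals, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return {p for p, v in mean_visible_errors.items() if v > fence}


def sod_median_split(profiles: pd.DataFrame,
                     pool_column: str = "experiment") -> pd.DataFrame:
    """Assign low/high SOD levels within each experiment pool.

    Participants in each pool are ordered by (sod_score, participant id) --
    the id breaks median ties deterministically -- and the lower half is
    labeled ``low``, the upper half ``high``. Sizes differ by at most one
    (the extra participant, at odd pool size, goes to the low half). A pool
    whose scores are all identical still splits, with a warning.

    ``profiles`` needs ``participant``, ``sod_score`` and the pool column;
    the frame is returned with a ``sod_level`` column added.
    """
    out = profiles.copy()
    out["sod_level"] = pd.Series(dtype=object)
    for pool, grp in out.groupby(pool_column):
        if len(grp) < 2:
            raise ValueError(f"pool {pool!r} needs at least 2 participants")
        if grp["sod_score"].nunique() == 1:
            warnings.warn(f"all SOD scores identical in pool {pool!r}; "
                          "splitting by participant id", stacklevel=2)
        order = grp.sort_values(["sod_score", "participant"]).index
        n_low = (len(order) + 1) // 2
        out.loc[order[:n_low], "sod_level"] = "low"
        out.loc[order[n_low:], "sod_level"] = "high"
    return out
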