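"""EQ-5D-3L utilities under the Dutch national tariff.

The EQ-5D describes a health state by five dimensions (mobility, self-care,
usual daily activities, pain/discomfort, anxiety/depression), each at one of
three levels: 1 = no problems, 2 = some/moderate problems, 3 = extreme
problems. A national value set maps each of the 243 states onto a utility,
anchored at 1 (full health, state 11111) and 0 (dead); states worse than dead
are negative. Under the Dutch tariff the attainable range is -0.33 to 1.00
(two-decimal reporting), the worst state being 33333.

The Dutch tariff is additive: full health keeps utility 1; any departure from
it subtracts a constant, plus per-dimension decrements for levels 2 and 3,
plus an extra "N3" decrement once any dimension is at level 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EQ5D_COLS", "DutchTariff", "eq5d_utility", "eq5d_utility_series"]

EQ5D_COLS = [
    "eq_mobility",
    "eq_self_care",
    "eq_daily_activities",
    "eq_pain_discomfort",
    "eq_anxiety_depression",
]

_DUTCH_DECREMENTS = {
    "eq_mobility": (0.036, 0.161),
    "eq_self_care": (0.082, 0.152),
    "eq_daily_activities": (0.032, 0.057),
    "eq_pain_discomfort": (0.086, 0.329),
    "eq_anxiety_depression": (0.124, 0.325),
}


@dataclass(frozen=True)
class DutchTariff:
    """Published Dutch EQ-5D-3L value-set constants.

    ``constant`` is subtracted for any state other than full health,
    ``decrements[dim]`` holds the (level 2, level 3) losses for each
    dimension, and ``n3`` is the additional loss once any dimension reaches
    level 3.
    """

    constant: float = 0.071
    decrements: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DUTCH_DECREMENTS)
    )
    n3: float = 0.234

    def utility(self, levels: dict[str, int] | tuple[int, ...]) -> float:
        """Utility of one fully described health state."""
        if not isinstance(levels, dict):
            levels = dict(zip(EQ5D_COLS, levels))
        vals = [levels[d] for d in EQ5D_COLS]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            raise ValueError("all five EQ-5D dimensions are required")
        if any(v not in (1, 2, 3) for v in vals):
            raise ValueError(f"EQ-5D levels must be 1, 2 or 3; got {vals}")
        u = 1.0
        if any(v > 1 for v in vals):
            u -= self.constant
        for dim, v in zip(EQ5D_COLS, vals):
            if v == 2:
                u -= self.decrements[dim][0]
            elif v == 3:
                u -= self.decrements[dim][1]
        if any(v == 3 for v in vals):
            u -= self.n3
        return u

    @property
    def minimum(self) -> float:
        """Utility of the worst state 33333 (rounds to -0.33)."""
        return self.utility((3, 3, 3, 3, 3))


def eq5d_utility(levels, tariff: DutchTariff | None = None) -> float:
    """Utility of a single response; see :class:`DutchTariff`."""
    return (tariff or DutchTariff()).utility(levels)


def eq5d_utility_series(df: pd.DataFrame, tariff: DutchTariff | None = None) -> pd.Series:
    """Utilities for a respondent table; incomplete rows yield NaN.

    Values are kept at full precision; rounding to the tariff's two-decimal
    reporting convention is left to the reporting layer.
    """
    tariff = tariff or DutchTariff()
    levels = df[EQ5D_COLS].apply(pd.to_numeric, errors="coerce")
    bad = levels.notna() & ~levels.isin([1, 2, 3])
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        idx = bad[col].idxmax()
        raise ValueError(
            f"respondent {idx!r}, dimension {col!r}: level {df[col][idx]!r} not in {{1,2,3}}"
        )
    complete = levels.notna().all(axis=1)
    u = pd.Series(np.nan, index=df.index)
    any_dev = (levels > 1).any(axis=1)
    any_n3 = (levels == 3).any(axis=1)
    total = pd.Series(1.0, index=df.index)
    total -= np.where(any_dev, tariff.constant, 0.0)
    for dim in EQ5D_COLS:
        lo, hi = tariff.decrements[dim]
        total -= np.where(levels[dim] == 2, lo, 0.0)
        total -= np.where(levels[dim] == 3, hi, 0.0)
    total -= np.where(any_n3, tariff.n3, 0.0)
    u[complete] = total[complete]
    return u
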