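"""Feasibility, distribution and floor/ceiling summaries per outcome.

Floor and ceiling effects are the proportions of respondents at an
instrument's theoretical minimum and maximum; more than 15% at either bound
is conventionally considered unacceptable for an evaluative measure, since
change can then no longer be detected in that tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OutcomeSummary", "OUTCOME_BOUNDS", "summarize_outcome", "summarize_dataset"]

#: Theoretical score ranges: composite 0–10, ladder 0–10, Dutch EQ-5D
#: utility -0.33 to 1.00 (two-decimal reporting convention).
OUTCOME_BOUNDS: dict[str, tuple[float, float]] = {
    "indexed_cep": (0.0, 10.0),
    "cantril": (0.0, 10.0),
    "eq5d_utility": (-0.33, 1.00),
}


@dataclass(frozen=True)
class OutcomeSummary:
    outcome: str
    n: int
    n_complete: int
    mean: float
    sd: float
    observed_min: float
    observed_max: float
    floor_n: int
    floor_pct: float
    ceiling_n: int
    ceiling_pct: float
    floor_flag: bool
    ceiling_flag: bool
    threshold: float = 15.0


def summarize_outcome(
    scores: pd.Series,
    theoretical_min: float,
    theoretical_max: float,
    threshold: float = 15.0,
    decimals: int | None = None,
    name: str | None = None,
) -> OutcomeSummary:
    """Distribution summary with floor/ceiling counts at the theoretical bounds.

    Bound membership is tested after rounding to ``decimals`` when given
    (e.g. 2 for the EQ-5D utility, whose tariff is published to two
    decimals); percentages are taken over non-missing scores and flagged
    when strictly above ``threshold`` percent.
    """
    s = pd.to_numeric(scores, errors="coerce")
    complete = s.dropna()
    if complete.empty:
        raise ValueError("no non-missing scores to summarize")
    compare = complete.round(decimals) if decimals is not None else complete
    floor_n = int((compare == round(theoretical_min, decimals) if decimals is not None
                   else compare == theoretical_min).sum())
    ceiling_n = int((compare == round(theoretical_max, decimals) if decimals is not None
                     else compare == theoretical_max).sum())
    floor_pct = floor_n / len(complete) * 100.0
    ceiling_pct = ceiling_n / len(complete) * 100.0
    return OutcomeSummary(
        outcome=name or (scores.name or "outcome"),
        n=len(s),
        n_complete=len(complete),
        mean=float(complete.mean()),
        sd=float(complete.std(ddof=1)) if len(complete) > 1 else 0.0,
        observed_min=float(complete.min()),
        observed_max=float(complete.max()),
        floor_n=floor_n,
        floor_pct=floor_pct,
        ceiling_n=ceiling_n,
        ceiling_pct=ceiling_pct,
        floor_flag=floor_pct > threshold,
        ceiling_flag=ceiling_pct > threshold,
        threshold=threshold,
    )


def summarize_dataset(
    dataset: pd.DataFrame,
    outcomes: dict[str, tuple[float, float]] | None = None,
    by: str | None = None,
    threshold: float = 15.0,
) -> pd.DataFrame:
    """Per-outcome (optionally per-stratum) summary table.

    The EQ-5D utility is compared to its bounds after two-decimal rounding;
    the two 0–10 scales are compared exactly.
    """
    outcomes = outcomes or {
        k: v for k, v in OUTCOME_BOUNDS.items() if k in dataset.columns
    }
    rows = []
    groups = [("all", dataset)] if by is None else list(dataset.groupby(by, observed=True))
    for stratum, grp in groups:
        for outcome, (lo, hi) in outcomes.items():
            decimals = 2 if outcome == "eq5d_utility" else None
            summ = summarize_outcome(
                grp[outcome], lo, hi, threshold=threshold, decimals=decimals, name=outcome
            )
            rows.append({"stratum": stratum, **summ.__dict__})
    return pd.DataFrame(rows)
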