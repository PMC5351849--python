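"""Convergent validity via random-effects meta-correlation.

In a pooled multi-project dataset a single sample-wide Pearson correlation
ignores clustering, so convergent validity is assessed the meta-analytic
way: a Pearson correlation per contributing project, Fisher z-transformed
(variance ``1/(n-3)``), pooled under a random-effects model with the
DerSimonian–Laird between-project variance estimate, and back-transformed.
Pooled correlations below 0.3 are called weak, between 0.3 and 0.5 moderate
(boundaries inclusive), and above 0.5 strong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProjectCorrelation",
    "PooledCorrelation",
    "StrengthThresholds",
    "project_correlations",
    "pool_random_effects",
    "classify_strength",
    "meta_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProjectCorrelation:
    """One project's Pearson correlation over complete pairs."""

    project_id: str
    r: float
    n: int

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.n < 4:
            raise ValueError(f"project {self.project_id}: n={self.n} < 4")


@dataclass(frozen=True)
class PooledCorrelation:
    """DerSimonian–Laird pooled correlation with its 95% CI.

    ``tau2`` is the between-project variance on the Fisher-z scale; ``k`` the
    number of pooled projects.
    """

    r: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int

    def __post_init__(self):
        if not self.ci_low <= self.r <= self.ci_high:
            raise ValueError("CI does not bracket the pooled estimate")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


@dataclass(frozen=True)
class StrengthThresholds:
    weak_below: float = 0.3
    strong_above: float = 0.5

    def __post_init__(self):
        if not 0 < self.weak_below < self.strong_above < 1:
            raise ValueError("need 0 < weak_below < strong_above < 1")


def project_correlations(
    dataset: pd.DataFrame,
    outcome_pair: tuple[str, str],
    min_n: int = 4,
    project_col: str = "project_id",
) -> list[ProjectCorrelation]:
    """Per-project Pearson correlations with pairwise-complete deletion.

    Projects with fewer than ``min_n`` complete pairs, or with zero variance
    in either outcome, are excluded with a logged warning.
    """
    x_col, y_col = outcome_pair
    for col in (project_col, x_col, y_col):
        if col not in dataset.columns:
            raise KeyError(f"dataset lacks column {col!r}")
    min_n = max(min_n, 4)  # Fisher variance 1/(n-3) needs n > 3
    out: list[ProjectCorrelation] = []
    for pid, grp in dataset.groupby(project_col, observed=True, sort=True):
        pairs = grp[[x_col, y_col]].dropna()
        n = len(pairs)
        if n < min_n:
            logger.warning("project %s: only %d complete pairs, excluded", pid, n)
            continue
        x = pairs[x_col].to_numpy(dtype=float)
        y = pairs[y_col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("project %s: zero variance in an outcome, excluded", pid)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out.append(ProjectCorrelation(str(pid), r, n))
    if not out:
        raise ValueError(f"no project eligible for correlation {x_col!r} vs {y_col!r}")
    return out


def pool_random_effects(correlations: list[ProjectCorrelation]) -> PooledCorrelation:
    """Pool per-project correlations under a random-effects model.

    Each correlation is Fisher z-transformed with sampling variance
    ``1/(n-3)``; the between-project variance tau² comes from the
    DerSimonian–Laird moment estimator

        tau² = max(0, (Q - (k-1)) / (sum w - sum w² / sum w)),

    with fixed-effect weights ``w = n-3`` and Cochran's Q. The pooled z uses
    weights ``1/(1/(n-3) + tau²)``; estimate and 95% Wald CI are
    back-transformed to the correlation scale.
    """
    if not correlations:
        raise ValueError("at least one project correlation is required")
    bad = [c for c in correlations if c.n <= 3]
    if bad:
        raise ValueError(f"projects with n <= 3 cannot be pooled: {bad}")
    z = np.arctanh(np.clip([c.r for c in correlations], -0.999999999, 0.999999999))
    v = np.array([1.0 / (c.n - 3) for c in correlations])
    k = len(correlations)

    w_fixed = 1.0 / v
    z_fixed = float(np.sum(w_fixed * z) / np.sum(w_fixed))
    q = float(np.sum(w_fixed * (z - z_fixed) ** 2))
    if k > 1:
        denom = np.sum(w_fixed) - np.sum(w_fixed**2) / np.sum(w_fixed)
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = 0.0

    w = 1.0 / (v + tau2)
    z_pooled = float(np.sum(w * z) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    lo, hi = z_pooled - 1.959963984540054 * se, z_pooled + 1.959963984540054 * se
    return PooledCorrelation(
        r=float(np.tanh(z_pooled)),
        ci_low=float(np.tanh(lo)),
        ci_high=float(np.tanh(hi)),
        tau2=tau2,
        k=k,
    )


def classify_strength(r: float, thresholds: StrengthThresholds | None = None) -> str:
    """Label |r| as ``weak`` (< 0.3), ``moderate`` (0.3–0.5) or ``strong`` (> 0.5)."""
    thresholds = thresholds or StrengthThresholds()
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| = {a} exceeds 1")
    if a < thresholds.weak_below:
        return "weak"
    if a > thresholds.strong_above:
        return "strong"
    return "moderate"


def meta_correlation(
    dataset: pd.DataFrame,
    outcome_pair: tuple[str, str],
    min_n: int = 4,
    project_col: str = "project_id",
) -> PooledCorrelation:
    """Convenience composition: per-project correlations, then DL pooling."""
    return pool_random_effects(
        project_correlations(dataset, outcome_pair, min_n=min_n, project_col=project_col)
    )
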