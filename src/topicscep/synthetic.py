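"""Synthetic multi-project cohorts of older persons.

Pooled minimum-dataset initiatives combine respondent-level data from many
research projects that differ in sampling frame and size. The generator
emulates that structure so the whole validation pipeline — scoring,
meta-correlation, mixed models, floor/ceiling — can be exercised end to end
without a restricted data extract:

* respondents are nested in projects with Normal project-level intercepts;
* each respondent carries covariates (age, gender, marital status, living
  arrangement, education, dementia, depression, dizziness with falls) drawn
  from configurable prevalences;
* latent wellbeing = grand mean + project intercept + configured group
  effects + residual, expressed on the 0–10 composite scale;
* the three outcomes (composite score, Cantril ladder, EQ-5D utility) follow
  the configured within-project correlation matrix *exactly in expectation*,
  including when group effects are active: the standardized systematic part
  of the composite is embedded as part of the first coordinate of a
  trivariate standard normal, and the other two coordinates are drawn
  conditionally on it.

Two modes exist. *Outcome-level* mode emits ready-scored outcome columns and
is what the statistical machinery is tested on. *Item-level* mode works the
latent wellbeing back through graded thresholds into the 42 raw items, the
five EQ-5D dimensions and an integer ladder score, optionally masking items
completely at random, so the scorer itself can be tested on realistic input.

Ground-truth columns (``_latent_wellbeing``, ``_project_intercept``) are
prefixed with an underscore and stripped by :func:`public_columns` before the
table is used as pipeline input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import (
    EMOTIONAL_COLS,
    FUNCTIONAL_COLS,
    ITEM_COLS,
    MORBIDITY_COLS,
    CodingScheme,
)

__all__ = ["GeneratorConfig", "generate_outcomes", "generate_items", "public_columns"]

OUTCOME_COLS = ["indexed_cep", "cantril", "eq5d_utility"]

# Default cohort calibration: 28 contributing projects, pooled n of 17,603,
# mean (SD) age 79 (7), 61.5% women, dementia 5.6%, depression 9.1%,
# dizziness with falls 14.6%; composite mean 7.37 (SD ~1.2), ladder 7.12
# (1.40), EQ-5D utility 0.63 (0.29); within-project outcome correlations
# 0.43 (composite/ladder), 0.63 (composite/EQ-5D), 0.34 (ladder/EQ-5D).
_DEFAULT_CORR = np.array(
    [
        [1.00, 0.43, 0.63],
        [0.43, 1.00, 0.34],
        [0.63, 0.34, 1.00],
    ]
)

_DEFAULT_BINARY_PREVALENCES = {
    "female": 0.615,
    "dementia": 0.056,
    "depression": 0.091,
    "dizziness_falls": 0.146,
}

_DEFAULT_CATEGORICALS = {
    "marital_status": {
        "married_cohabiting": 0.467,
        "partner_deceased": 0.400,
        "other": 0.133,
    },
    "living_arrangement": {
        "independent_alone": 0.400,
        "independent_with_others": 0.449,
        "dependent": 0.151,
    },
    "education": {"primary": 0.350, "secondary": 0.467, "university": 0.183},
}

# True group contrasts on the composite scale (points), keyed either by a
# binary covariate name or "factor:level" for categorical levels.
_DEFAULT_EFFECTS = {
    "female": -0.39,
    "dementia": -1.13,
    "depression": -1.16,
    "dizziness_falls": -1.07,
    "marital_status:partner_deceased": -0.37,
    "marital_status:other": -0.22,
    "living_arrangement:independent_with_others": 0.19,
    "living_arrangement:dependent": -1.01,
    "education:secondary": 0.27,
    "education:university": 0.44,
    "age_per_year": 0.03,
}

# Oriented-level marginal distributions used by the graded-threshold item
# generator (0 = best state).
_ITEM_MARGINALS: dict[str, list[float]] = {
    **{c: [0.75, 0.25] for c in MORBIDITY_COLS},
    **{c: [0.70, 0.30] for c in FUNCTIONAL_COLS},
    **{c: [0.30, 0.28, 0.18, 0.12, 0.07, 0.05] for c in EMOTIONAL_COLS},
    "pain": [0.45, 0.45, 0.10],
    "cognition": [0.60, 0.33, 0.07],
    "social_functioning": [0.45, 0.25, 0.15, 0.10, 0.05],
    "self_perceived_health": [0.15, 0.35, 0.30, 0.15, 0.05],
    "self_perceived_qol": [0.15, 0.35, 0.30, 0.15, 0.05],
}

_EQ5D_MARGINALS: dict[str, list[float]] = {
    "eq_mobility": [0.55, 0.40, 0.05],
    "eq_self_care": [0.78, 0.17, 0.05],
    "eq_daily_activities": [0.55, 0.35, 0.10],
    "eq_pain_discomfort": [0.40, 0.45, 0.15],
    "eq_anxiety_depression": [0.62, 0.28, 0.10],
}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic multi-project cohort."""

    n_projects: int = 28
    total_n: int = 17603
    project_sizes: list[int] | None = None
    project_intercept_sd: float = 0.5
    grand_mean: float = 7.37
    residual_sd: float = 1.1
    cantril_mean: float = 7.12
    cantril_sd: float = 1.40
    eq5d_mean: float = 0.63
    eq5d_sd: float = 0.29
    outcome_correlations: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    group_effects: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BINARY_PREVALENCES)
    )
    categorical_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CATEGORICALS.items()}
    )
    age_mean: float = 79.0
    age_sd: float = 7.0
    missingness_rate: float | dict[str, float] = 0.02
    item_loading: float = 0.7
    discretize: bool = False
    seed: int = 0

    def __post_init__(self):
        R = np.asarray(self.outcome_correlations, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("outcome_correlations must be a symmetric 3x3 with unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            raise ValueError("outcome_correlations is not positive semi-definite")
        self.outcome_correlations = R
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        for factor, dist in self.categorical_distributions.items():
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"level probabilities of {factor!r} sum to {total}, not 1")
        if self.project_sizes is not None:
            if len(self.project_sizes) != self.n_projects:
                raise ValueError("project_sizes length must equal n_projects")
            if min(self.project_sizes) < 4:
                raise ValueError("every project needs at least 4 respondents")
        rates = (
            self.missingness_rate.values()
            if isinstance(self.missingness_rate, dict)
            else [self.missingness_rate]
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("missingness rates must lie in [0, 1]")
        if not 0.0 < self.item_loading < 1.0:
            raise ValueError("item_loading must lie in (0, 1)")

    # -- systematic (covariate) part of the composite -----------------------
    def systematic_moments(self) -> tuple[float, float]:
        """Theoretical mean and variance of the summed group effects.

        Covariates are drawn independently, so variances add: Bernoulli terms
        contribute ``b^2 p (1-p)``, categorical factors the variance of their
        effect over the level distribution, and age ``(b_age * age_sd)^2``.
        """
        mean = 0.0
        var = 0.0
        for name, p in self.covariate_prevalences.items():
            b = self.group_effects.get(name, 0.0)
            mean += b * p
            var += b * b * p * (1 - p)
        for factor, dist in self.categorical_distributions.items():
            effs = np.array(
                [self.group_effects.get(f"{factor}:{lvl}", 0.0) for lvl in dist]
            )
            probs = np.array(list(dist.values()))
            m = float(effs @ probs)
            mean += m
            var += float((effs - m) ** 2 @ probs)
        b_age = self.group_effects.get("age_per_year", 0.0)
        var += (b_age * self.age_sd) ** 2
        return mean, var


def _project_sizes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if config.project_sizes is not None:
        return np.asarray(config.project_sizes, dtype=int)
    # Contributing projects differ strongly in size; a lognormal weight gives
    # the familiar few-large / many-small pattern.
    w = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_projects)
    sizes = np.maximum(4, np.round(w / w.sum() * config.total_n).astype(int))
    # nudge the largest project so the total matches exactly
    sizes[np.argmax(sizes)] += config.total_n - sizes.sum()
    return sizes


def _draw_covariates(
    config: GeneratorConfig, rng: np.random.Generator, n: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw covariates and return them with each respondent's summed effect."""
    cov = pd.DataFrame(index=range(n))
    s = np.zeros(n)
    for name, p in config.covariate_prevalences.items():
        x = (rng.random(n) < p).astype(int)
        cov[name] = x
        s += config.group_effects.get(name, 0.0) * x
    for factor, dist in config.categorical_distributions.items():
        levels = list(dist)
        draw = rng.choice(len(levels), size=n, p=list(dist.values()))
        cov[factor] = pd.Categorical.from_codes(draw, categories=levels)
        effs = np.array([config.group_effects.get(f"{factor}:{lvl}", 0.0) for lvl in levels])
        s += effs[draw]
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    cov["age"] = np.round(age).clip(min=65)
    s += config.group_effects.get("age_per_year", 0.0) * (cov["age"].to_numpy() - config.age_mean)
    return cov, s


def _generate_core(
    config: GeneratorConfig, seed: int | None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Shared machinery: covariates, project structure and the latent triple."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = _project_sizes(config, rng)
    n = int(sizes.sum())
    project = np.repeat([f"P{i + 1:02d}" for i in range(len(sizes))], sizes)
    u_by_project = rng.normal(0.0, config.project_intercept_sd, size=len(sizes))
    u = np.repeat(u_by_project, sizes)

    cov, s = _draw_covariates(config, rng, n)
    mean_s, var_s = config.systematic_moments()
    sigma_total = np.sqrt(var_s + config.residual_sd**2)

    # Trivariate standard normal whose first coordinate carries the
    # standardized systematic part; T2, T3 drawn conditionally on T1 so all
    # three pairwise correlations match the configured matrix exactly.
    R = config.outcome_correlations
    r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
    z1 = rng.standard_normal(n)
    t1 = (s - mean_s) / sigma_total + (config.residual_sd / sigma_total) * z1
    cond_cov = np.array(
        [[1 - r12**2, r23 - r12 * r13], [r23 - r12 * r13, 1 - r13**2]]
    )
    L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(2))
    eta = rng.standard_normal((2, n))
    t2 = r12 * t1 + L[0, 0] * eta[0]
    t3 = r13 * t1 + L[1, 0] * eta[0] + L[1, 1] * eta[1]

    df = pd.DataFrame({"project_id": project})
    df = pd.concat([df, cov.reset_index(drop=True)], axis=1)
    latent = config.grand_mean + u + sigma_total * t1
    df["_latent_wellbeing"] = latent
    df["_project_intercept"] = u
    return df, t1, t2, t3


def generate_outcomes(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Outcome-level synthetic dataset with ready-scored outcome columns.

    With ``config.discretize`` the outcomes are put on their reported scales
    (composite clipped to 0–10, integer ladder 0–10, utility rounded to two
    decimals and capped at the tariff bounds); otherwise they stay continuous
    so that generating moments and correlations hold exactly.
    """
    config = config or GeneratorConfig()
    df, t1, t2, t3 = _generate_core(config, seed)
    cep = df["_latent_wellbeing"].to_numpy()
    cantril = config.cantril_mean + config.cantril_sd * t2
    eq5d = config.eq5d_mean + config.eq5d_sd * t3
    if config.discretize:
        cep = np.clip(cep, 0.0, 10.0)
        cantril = np.clip(np.round(cantril), 0, 10)
        eq5d = np.clip(np.round(eq5d, 2), -0.33, 1.00)
    df["indexed_cep"] = cep
    df["cantril"] = cantril
    df["eq5d_utility"] = eq5d
    return df


def _graded_items(
    rng: np.random.Generator,
    latent: np.ndarray,
    marginals: dict[str, list[float]],
    loading: float,
) -> pd.DataFrame:
    """Draw ordinal items from a one-factor graded-threshold model.

    Each item's latent response is ``-loading * latent + noise`` (high latent
    wellbeing means low, i.e. good, oriented levels); fixed normal-quantile
    cutpoints reproduce the requested marginal level distribution.
    """
    n = len(latent)
    out = {}
    noise_sd = np.sqrt(1.0 - loading**2)
    for col, probs in marginals.items():
        cuts = stats.norm.ppf(np.cumsum(probs[:-1]))
        y = -loading * latent + noise_sd * rng.standard_normal(n)
        out[col] = np.searchsorted(cuts, y)
    return pd.DataFrame(out)


def generate_items(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Item-level synthetic dataset: raw questionnaire answers per respondent.

    The 42 composite items are driven by the respondent's standardized latent
    wellbeing, the EQ-5D dimensions by the EQ-5D latent, and the ladder by
    the life-satisfaction latent, preserving the configured outcome
    correlation structure at the latent level. Items (the 42 composite
    entries) are then masked completely at random at ``missingness_rate``.
    """
    config = config or GeneratorConfig()
    core, t1, t2, t3 = _generate_core(config, seed)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed if seed is None else seed, 1))
    )
    scheme = CodingScheme.default()

    oriented = _graded_items(rng, t1, _ITEM_MARGINALS, config.item_loading)
    native = pd.DataFrame(
        {col: scheme.items[col].deorient(oriented[col].to_numpy()) for col in ITEM_COLS}
    )
    rates = config.missingness_rate
    if isinstance(rates, dict):
        rate_vec = np.array([rates.get(c, 0.0) for c in native.columns])
    else:
        rate_vec = np.full(native.shape[1], float(rates))
    if rate_vec.any():
        mask = rng.random(native.shape) < rate_vec
        native = native.mask(pd.DataFrame(mask, columns=native.columns))

    eq = _graded_items(rng, t3, _EQ5D_MARGINALS, config.item_loading) + 1
    cantril = np.clip(np.round(config.cantril_mean + config.cantril_sd * t2), 0, 10)

    df = pd.concat([core.reset_index(drop=True), native, eq], axis=1)
    df["cantril"] = cantril
    return df


def public_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Drop ground-truth columns (underscore-prefixed) for pipeline input mode."""
    return df.loc[:, [c for c in df.columns if not c.startswith("_")]]
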