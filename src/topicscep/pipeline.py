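"""Orchestration of the full validation pipeline.

``score -> describe -> converge -> knowngroups`` on respondent-level CSV
input (or a freshly generated synthetic cohort), writing the scored data,
the three report tables (distribution/floor-ceiling, pooled correlations,
known-group contrasts) and a run log that reconciles exclusion counts with
the input row count. Outputs are deterministic given input and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .descriptives import summarize_dataset
from .eq5d import EQ5D_COLS, DutchTariff, eq5d_utility_series
from .knowngroups import known_group_analysis
from .meta import classify_strength, meta_correlation
from .scoring import (
    ITEM_COLS,
    CodingScheme,
    PreferenceWeights,
    ProRatingPolicy,
    score_cep,
    validate_cantril_series,
)
from .synthetic import GeneratorConfig, generate_items, generate_outcomes, public_columns

__all__ = ["PipelineConfig", "score_table", "convergent_table", "known_groups_table", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = [
    ("indexed_cep", "eq5d_utility"),
    ("indexed_cep", "cantril"),
    ("cantril", "eq5d_utility"),
]

#: Per-characteristic known-group factors with their reference levels.
DEFAULT_FACTORS: dict[str, str | int] = {
    "marital_status": "married_cohabiting",
    "living_arrangement": "independent_alone",
    "education": "primary",
    "dementia": 0,
    "depression": 0,
    "dizziness_falls": 0,
}


@dataclass
class PipelineConfig:
    """Input source, stratification and output location for one run."""

    input_csv: str | Path | None = None
    generator: GeneratorConfig | None = None
    generator_mode: str = "items"  # "items" | "outcomes"
    out_dir: str | Path = "topicscep_out"
    stratify: str | None = None
    seed: int = 0
    pairs: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    factors: dict[str, str | int] = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    adjusters: tuple[str, ...] = ("age", "female")
    change_threshold: float = 15.0
    floor_ceiling_threshold: float = 15.0

    def __post_init__(self):
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("exactly one of input_csv or generator must be given")
        if self.generator_mode not in ("items", "outcomes"):
            raise ValueError("generator_mode must be 'items' or 'outcomes'")


def read_respondents(path: str | Path) -> pd.DataFrame:
    """Read a respondent-level CSV (UTF-8, header row, empty cell = missing)."""
    df = pd.read_csv(path)
    if "project_id" not in df.columns:
        raise ValueError("input lacks required column 'project_id'")
    return df


def score_table(
    df: pd.DataFrame,
    scheme: CodingScheme | None = None,
    policy: ProRatingPolicy | None = None,
    weights: PreferenceWeights | None = None,
    tariff: DutchTariff | None = None,
) -> pd.DataFrame:
    """Append ``raw_cep``, ``indexed_cep``, ``eq5d_utility``, ``cantril`` and
    ``scoreable`` to an item-level respondent table."""
    scheme = scheme or CodingScheme.default()
    scored = score_cep(df[ITEM_COLS], scheme=scheme, policy=policy, weights=weights)
    out = df.copy()
    out["raw_cep"] = scored["raw_cep"]
    out["indexed_cep"] = scored["indexed_cep"]
    out["scoreable"] = scored["scoreable"]
    if set(EQ5D_COLS).issubset(df.columns):
        out["eq5d_utility"] = eq5d_utility_series(df, tariff)
    if "cantril" in df.columns:
        out["cantril"] = validate_cantril_series(df["cantril"])
    return out


def convergent_table(
    df: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    by: str | None = None,
) -> pd.DataFrame:
    """Pooled correlation per outcome pair (overall plus optional strata)."""
    pairs = pairs or DEFAULT_PAIRS
    rows = []
    strata = [("all", df)] + (list(df.groupby(by, observed=True)) if by else [])
    for stratum, grp in strata:
        for pair in pairs:
            if not set(pair).issubset(grp.columns):
                continue
            pooled = meta_correlation(grp, pair)
            rows.append(
                {
                    "stratum": stratum,
                    "pair": f"{pair[0]}:{pair[1]}",
                    "r": pooled.r,
                    "ci_low": pooled.ci_low,
                    "ci_high": pooled.ci_high,
                    "tau2": pooled.tau2,
                    "k": pooled.k,
                    "strength": classify_strength(pooled.r),
                }
            )
    return pd.DataFrame(rows)


def known_groups_table(
    df: pd.DataFrame,
    factors: dict[str, str | int] | None = None,
    adjusters: tuple[str, ...] = ("age", "female"),
    threshold: float = 15.0,
) -> pd.DataFrame:
    """Per-characteristic contrasts, unadjusted and adjusted, with % change."""
    factors = factors or DEFAULT_FACTORS
    rows = []
    for factor, reference in factors.items():
        if factor not in df.columns:
            logger.warning("factor %s not in data; skipped", factor)
            continue
        unadj, adj, cmp = known_group_analysis(
            df, factor, reference=reference, adjusters=adjusters, threshold=threshold
        )
        ad = {e.level: e for e in adj.effects}
        for e in unadj.effects:
            a = ad[e.level]
            rows.append(
                {
                    "factor": factor,
                    "reference": unadj.reference_level,
                    "reference_mean": unadj.reference_mean,
                    "level": e.level,
                    "estimate": e.estimate,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_value": e.p_value,
                    "adj_estimate": a.estimate,
                    "adj_ci_low": a.ci_low,
                    "adj_ci_high": a.ci_high,
                    "adj_p_value": a.p_value,
                    "pct_change": cmp.pct_change[e.level],
                    "exceeds_threshold": cmp.exceeds_threshold[e.level],
                }
            )
    return pd.DataFrame(rows)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Returns a mapping from artifact name to written path. Any stage failure
    raises with the stage named in the message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }

    # -- stage: input -------------------------------------------------------
    try:
        if config.input_csv is not None:
            data = read_respondents(config.input_csv)
            log["input"] = str(config.input_csv)
        else:
            gen = config.generator
            if config.generator_mode == "items":
                data = generate_items(gen, seed=config.seed)
            else:
                data = generate_outcomes(gen, seed=config.seed)
            data = public_columns(data)
            log["input"] = f"synthetic:{config.generator_mode}"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed: {exc}") from exc
    log["n_input_rows"] = int(len(data))

    # -- stage: score -------------------------------------------------------
    try:
        if set(ITEM_COLS).issubset(data.columns):
            scored = score_table(data)
        else:  # already outcome-level
            missing = [c for c in ("indexed_cep",) if c not in data.columns]
            if missing:
                raise ValueError(f"outcome-level input lacks {missing}")
            scored = data.copy()
            scored["scoreable"] = scored["indexed_cep"].notna()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'score' failed: {exc}") from exc
    n_scoreable = int(scored["scoreable"].sum())
    log["n_scoreable"] = n_scoreable
    log["n_not_scoreable"] = int(len(scored) - n_scoreable)
    log["pct_scoreable"] = round(n_scoreable / len(scored) * 100, 1)

    analysis = scored[scored["scoreable"]].copy()

    # -- stage: describe ----------------------------------------------------
    try:
        desc = summarize_dataset(
            analysis, by=config.stratify, threshold=config.floor_ceiling_threshold
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'describe' failed: {exc}") from exc

    # -- stage: converge ----------------------------------------------------
    try:
        conv = convergent_table(analysis, pairs=config.pairs, by=config.stratify)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'converge' failed: {exc}") from exc

    # -- stage: knowngroups -------------------------------------------------
    try:
        kg = known_groups_table(
            analysis,
            factors=config.factors,
            adjusters=config.adjusters,
            threshold=config.change_threshold,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'knowngroups' failed: {exc}") from exc

    paths = {
        "scored": out_dir / "scored.csv",
        "descriptives": out_dir / "descriptives.csv",
        "convergent": out_dir / "convergent.csv",
        "known_groups": out_dir / "known_groups.csv",
        "run_log": out_dir / "run_log.json",
    }
    scored.to_csv(paths["scored"], index=False)
    desc.to_csv(paths["descriptives"], index=False)
    conv.to_csv(paths["convergent"], index=False)
    kg.to_csv(paths["known_groups"], index=False)
    with open(paths["run_log"], "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return paths
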