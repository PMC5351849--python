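"""Scoring of the TOPICS composite endpoint (TOPICS-CEP).

The composite endpoint condenses 42 questionnaire data points covering eight
health/wellbeing domains of older persons into a single preference-weighted
index from 0 (worst imaginable state) to 10 (best). Scoring proceeds in four
steps:

1. *reverse coding* — every item is oriented so that 0 is the best state;
2. *aggregation* — the 17 morbidity items, 15 functional-limitation items and
   5 emotional-wellbeing items are summed into one component each (pro-rated
   when a tolerable number of items is missing); the remaining five domains
   are single items;
3. *raw score* — the preference weights of the Dutch population aged 65+ are
   applied::

       raw = 9.00 - 0.18*morbidities - 0.12*functional_limitations
                  - 0.03*emotional_wellbeing - 0.03*pain - 0.14*cognition
                  - 0.01*social_functioning - 0.17*self_perceived_health
                  - 0.02*self_perceived_qol

4. *index transformation* — the raw score is mapped affinely onto 0–10 using
   the minimum attainable raw score and the raw score range implied by the
   component maxima.

Respondents with more missing items than the pro-rating policy tolerates
receive no score at all (``scoreable = False``) and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MORBIDITY_COLS",
    "FUNCTIONAL_COLS",
    "EMOTIONAL_COLS",
    "SINGLE_ITEM_COLS",
    "ITEM_COLS",
    "COMPONENT_COLS",
    "ItemSpec",
    "CodingScheme",
    "ProRatingPolicy",
    "PreferenceWeights",
    "ItemValidationError",
    "flip_levels",
    "reverse_code",
    "prorate_component",
    "aggregate_components",
    "raw_cep",
    "index_cep",
    "score_cep",
    "cantril_validate",
    "validate_cantril_series",
]

MORBIDITY_COLS = [f"morb_{i:02d}" for i in range(1, 18)]
FUNCTIONAL_COLS = [f"func_{i:02d}" for i in range(1, 16)]
EMOTIONAL_COLS = [f"emo_{i:02d}" for i in range(1, 6)]
SINGLE_ITEM_COLS = [
    "pain",
    "cognition",
    "social_functioning",
    "self_perceived_health",
    "self_perceived_qol",
]
ITEM_COLS = MORBIDITY_COLS + FUNCTIONAL_COLS + EMOTIONAL_COLS + SINGLE_ITEM_COLS

COMPONENT_COLS = [
    "morbidities",
    "functional_limitations",
    "emotional_wellbeing",
    "pain",
    "cognition",
    "social_functioning",
    "self_perceived_health",
    "self_perceived_qol",
]


class ItemValidationError(ValueError):
    """An item response lies outside its declared level range."""


def flip_levels(values, n_levels: int):
    """Reverse 0-based item levels: ``x -> (n_levels - 1) - x``.

    The map is an involution on ``{0, ..., n_levels - 1}`` (applying it twice
    restores the original values). Missing values pass through unchanged.
    """
    return (n_levels - 1) - np.asarray(values, dtype=float)


@dataclass(frozen=True)
class ItemSpec:
    """Native coding of one questionnaire item.

    ``higher_is_better`` marks items whose native scale runs from bad to good
    (e.g. "none of the time" for a negative mood); those are reverse coded so
    that 0 is always the best state after orientation.
    """

    native_min: int
    native_max: int
    higher_is_better: bool = False

    @property
    def n_levels(self) -> int:
        return self.native_max - self.native_min + 1

    @property
    def oriented_max(self) -> int:
        return self.native_max - self.native_min

    def orient(self, values):
        """Map native levels onto the 0-is-best oriented scale."""
        shifted = np.asarray(values, dtype=float) - self.native_min
        if self.higher_is_better:
            return flip_levels(shifted, self.n_levels)
        return shifted

    def deorient(self, oriented):
        """Inverse of :meth:`orient` (used by the synthetic item generator)."""
        oriented = np.asarray(oriented, dtype=float)
        if self.higher_is_better:
            oriented = flip_levels(oriented, self.n_levels)
        return oriented + self.native_min


def _default_items() -> dict[str, ItemSpec]:
    items: dict[str, ItemSpec] = {}
    # 17 pre-defined chronic conditions, 1 = present (worse).
    for c in MORBIDITY_COLS:
        items[c] = ItemSpec(0, 1)
    # Katz-index derived limitations, 1 = limited (worse).
    for c in FUNCTIONAL_COLS:
        items[c] = ItemSpec(0, 1)
    # RAND-36 mental-health subscale, native 1-6 "all of the time" .. "none of
    # the time". Items 1, 2 and 4 ask about negative moods (nervous, down in
    # the dumps, downhearted), so a high native level is good; items 3 and 5
    # ask about positive moods (calm and peaceful, happy).
    items["emo_01"] = ItemSpec(1, 6, higher_is_better=True)
    items["emo_02"] = ItemSpec(1, 6, higher_is_better=True)
    items["emo_03"] = ItemSpec(1, 6)
    items["emo_04"] = ItemSpec(1, 6, higher_is_better=True)
    items["emo_05"] = ItemSpec(1, 6)
    # EQ-5D pain and EQ-5D+C cognition dimensions: 1 = no problems.
    items["pain"] = ItemSpec(1, 3)
    items["cognition"] = ItemSpec(1, 3)
    # RAND-36 item 10 (social functioning): 1 = interference all of the time.
    items["social_functioning"] = ItemSpec(1, 5, higher_is_better=True)
    # Self-perceived health / quality of life: 1 = excellent .. 5 = poor.
    items["self_perceived_health"] = ItemSpec(1, 5)
    items["self_perceived_qol"] = ItemSpec(1, 5)
    return items


@dataclass(frozen=True)
class CodingScheme:
    """Per-item native ranges and reverse-coding directions.

    The exact native codings are instrument conventions rather than part of
    the composite's definition, so they live in a replaceable configuration
    object; :meth:`default` ships the standard TOPICS item set. The component
    maxima that fix the index transformation (morbidities 17, functional
    limitations 15, emotional wellbeing 25, pain 2, cognition 2, social
    functioning 4, self-perceived health 4, self-perceived QOL 4) derive from
    the oriented item ranges.
    """

    items: dict[str, ItemSpec] = field(default_factory=_default_items)

    def __post_init__(self):
        missing = [c for c in ITEM_COLS if c not in self.items]
        if missing:
            raise ValueError(f"coding scheme lacks items: {missing}")
        for name, spec in self.items.items():
            if spec.native_max <= spec.native_min:
                raise ValueError(f"degenerate level range for item {name!r}")

    @classmethod
    def default(cls) -> "CodingScheme":
        return cls()

    def component_max(self, component: str) -> float:
        group = _COMPONENT_ITEMS[component]
        return float(sum(self.items[c].oriented_max for c in group))

    @property
    def component_maxima(self) -> dict[str, float]:
        return {comp: self.component_max(comp) for comp in COMPONENT_COLS}


_COMPONENT_ITEMS: dict[str, list[str]] = {
    "morbidities": MORBIDITY_COLS,
    "functional_limitations": FUNCTIONAL_COLS,
    "emotional_wellbeing": EMOTIONAL_COLS,
    **{c: [c] for c in SINGLE_ITEM_COLS},
}

MULTI_ITEM_COMPONENTS = ["morbidities", "functional_limitations", "emotional_wellbeing"]


@dataclass(frozen=True)
class ProRatingPolicy:
    """Missing-item tolerance per aggregated component.

    Defaults encode "fewer than 5" missing morbidity and functional items and
    "fewer than 2" missing emotional-wellbeing items; any single-item domain
    must be answered.
    """

    max_missing_morbidities: int = 4
    max_missing_functional: int = 4
    max_missing_emotional: int = 1

    def __post_init__(self):
        limits = {
            "max_missing_morbidities": (self.max_missing_morbidities, 17),
            "max_missing_functional": (self.max_missing_functional, 15),
            "max_missing_emotional": (self.max_missing_emotional, 5),
        }
        for name, (value, n_items) in limits.items():
            if not 0 <= value < n_items:
                raise ValueError(f"{name}={value} must lie in [0, {n_items})")

    def max_missing(self, component: str) -> int:
        return {
            "morbidities": self.max_missing_morbidities,
            "functional_limitations": self.max_missing_functional,
            "emotional_wellbeing": self.max_missing_emotional,
        }[component]


#: Preference weights of the Dutch population aged 65+, points of general
#: wellbeing lost per unit of each (0-is-best) component.
DEFAULT_WEIGHTS: dict[str, float] = {
    "morbidities": 0.18,
    "functional_limitations": 0.12,
    "emotional_wellbeing": 0.03,
    "pain": 0.03,
    "cognition": 0.14,
    "social_functioning": 0.01,
    "self_perceived_health": 0.17,
    "self_perceived_qol": 0.02,
}


@dataclass(frozen=True)
class PreferenceWeights:
    """Intercept and component weights of the raw-score formula.

    ``raw_max`` equals the intercept (all components at their best value 0);
    ``raw_min`` is the intercept minus the weighted component maxima of the
    active coding scheme. Both are computed, never hard-coded, so alternative
    codings stay internally consistent.
    """

    intercept: float = 9.00
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    component_maxima: dict[str, float] = field(
        default_factory=lambda: CodingScheme.default().component_maxima
    )

    def __post_init__(self):
        missing = [c for c in COMPONENT_COLS if c not in self.weights]
        if missing:
            raise ValueError(f"missing weights for components: {missing}")
        if self.raw_range <= 0:
            raise ValueError("raw score range must be positive")

    @classmethod
    def for_scheme(cls, scheme: CodingScheme, **kwargs) -> "PreferenceWeights":
        return cls(component_maxima=scheme.component_maxima, **kwargs)

    @property
    def raw_max(self) -> float:
        return self.intercept

    @property
    def raw_min(self) -> float:
        return self.intercept - sum(
            self.weights[c] * self.component_maxima[c] for c in COMPONENT_COLS
        )

    @property
    def raw_range(self) -> float:
        return self.raw_max - self.raw_min


def reverse_code(items: pd.DataFrame, scheme: CodingScheme | None = None) -> pd.DataFrame:
    """Orient all 42 items so that 0 is the best state.

    Parameters
    ----------
    items
        Respondent-level table with the 42 item columns in native coding;
        missing answers are NaN and are preserved.
    scheme
        Native ranges and reverse-coding directions; defaults to the standard
        TOPICS coding.

    Raises
    ------
    ItemValidationError
        If any non-missing value lies outside its declared level range; the
        message names the respondent (index label), item and offending value.
    """
    scheme = scheme or CodingScheme.default()
    oriented = pd.DataFrame(index=items.index)
    for col in ITEM_COLS:
        if col not in items.columns:
            raise ItemValidationError(f"missing item column {col!r}")
        spec = scheme.items[col]
        values = pd.to_numeric(items[col], errors="coerce")
        bad = values.notna() & ((values < spec.native_min) | (values > spec.native_max))
        if bad.any():
            idx = bad.idxmax()
            raise ItemValidationError(
                f"respondent {idx!r}, item {col!r}: value {items[col][idx]!r} "
                f"outside levels [{spec.native_min}, {spec.native_max}]"
            )
        oriented[col] = spec.orient(values.to_numpy())
    return oriented


def prorate_component(answered_sum: float, n_answered: int, n_items: int) -> float:
    """Estimate a partially missing component as ``answered_sum / n_answered * n_items``.

    E.g. 12 of the 15 functional-limitation items answered with sum 6 gives
    ``(6 / 12) * 15 = 7.5``. A fully answered component is returned unchanged.
    """
    if n_answered == 0:
        raise ValueError("component not pro-ratable: no items answered")
    if not 1 <= n_answered <= n_items:
        raise ValueError(f"n_answered={n_answered} outside [1, {n_items}]")
    if answered_sum < 0:
        raise ValueError("answered_sum must be non-negative")
    return answered_sum / n_answered * n_items


def aggregate_components(
    oriented: pd.DataFrame,
    policy: ProRatingPolicy | None = None,
    scheme: CodingScheme | None = None,
) -> pd.DataFrame:
    """Aggregate oriented items into the eight components, pro-rating gaps.

    Returns a frame with the eight component columns, per-multi-item-component
    ``prorated_*`` flags, and a boolean ``scoreable`` column. A respondent is
    not scoreable when a multi-item component has more missing items than the
    policy tolerates or when any single-item domain is missing; such rows have
    NaN components.
    """
    policy = policy or ProRatingPolicy()
    scheme = scheme or CodingScheme.default()
    out = pd.DataFrame(index=oriented.index)
    scoreable = pd.Series(True, index=oriented.index)

    for comp in MULTI_ITEM_COMPONENTS:
        cols = _COMPONENT_ITEMS[comp]
        block = oriented[cols]
        n_missing = block.isna().sum(axis=1)
        n_answered = len(cols) - n_missing
        ok = n_missing <= policy.max_missing(comp)
        answered_sum = block.sum(axis=1, min_count=1)
        value = answered_sum / n_answered * len(cols)
        out[comp] = value.where(ok)
        out[f"prorated_{comp}"] = ok & (n_missing > 0)
        scoreable &= ok

    for comp in SINGLE_ITEM_COLS:
        present = oriented[comp].notna()
        out[comp] = oriented[comp]
        scoreable &= present

    out.loc[~scoreable, COMPONENT_COLS] = np.nan
    out["scoreable"] = scoreable
    return out


def raw_cep(components: pd.DataFrame | pd.Series | dict, w: PreferenceWeights | None = None):
    """Raw composite score: intercept minus the preference-weighted components."""
    w = w or PreferenceWeights()
    if isinstance(components, dict):
        components = pd.Series(components)
    if isinstance(components, pd.Series):
        return float(w.intercept - sum(w.weights[c] * components[c] for c in COMPONENT_COLS))
    total = pd.Series(w.intercept, index=components.index)
    for c in COMPONENT_COLS:
        total = total - w.weights[c] * components[c]
    return total


def index_cep(raw, w: PreferenceWeights | None = None):
    """Affine map of the raw score onto the 0–10 index.

    ``indexed = (raw - raw_min) / raw_range * 10``. A raw value outside
    [raw_min, raw_max] signals a mismatch between weights and coding scheme
    and raises ``ValueError`` (NaN passes through).
    """
    w = w or PreferenceWeights()
    arr = np.asarray(raw, dtype=float)
    tol = 1e-9
    bad = ~np.isnan(arr) & ((arr < w.raw_min - tol) | (arr > w.raw_max + tol))
    if np.any(bad):
        offending = arr[bad].flat[0]
        raise ValueError(
            f"raw score {offending} outside [{w.raw_min}, {w.raw_max}]: "
            "weights and coding scheme are inconsistent"
        )
    # raw already validated against [raw_min, raw_max]; clipping only removes
    # sub-epsilon float spill at the anchors
    indexed = np.clip((arr - w.raw_min) / w.raw_range * 10.0, 0.0, 10.0)
    if np.isscalar(raw) or arr.ndim == 0:
        return float(indexed)
    return pd.Series(indexed, index=raw.index) if isinstance(raw, pd.Series) else indexed


def score_cep(
    items: pd.DataFrame,
    scheme: CodingScheme | None = None,
    policy: ProRatingPolicy | None = None,
    weights: PreferenceWeights | None = None,
) -> pd.DataFrame:
    """Full four-step scoring of respondent-level item data.

    Returns the component frame of :func:`aggregate_components` extended with
    ``raw_cep`` and ``indexed_cep`` (NaN where not scoreable).
    """
    scheme = scheme or CodingScheme.default()
    weights = weights or PreferenceWeights.for_scheme(scheme)
    oriented = reverse_code(items, scheme)
    comps = aggregate_components(oriented, policy, scheme)
    comps["raw_cep"] = raw_cep(comps[COMPONENT_COLS], weights)
    comps["indexed_cep"] = index_cep(comps["raw_cep"], weights)
    return comps


def cantril_validate(value):
    """Validate one ladder answer: integers 0–10 pass, missing stays missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    v = float(value)
    if not 0 <= v <= 10:
        raise ValueError(f"Cantril ladder value {value!r} outside [0, 10]")
    return v


def validate_cantril_series(values: pd.Series) -> pd.Series:
    """Vectorised ladder validation; raises on the first out-of-range value."""
    v = pd.to_numeric(values, errors="coerce")
    bad = v.notna() & ((v < 0) | (v > 10))
    if bad.any():
        idx = bad.idxmax()
        raise ValueError(f"respondent {idx!r}: Cantril value {values[idx]!r} outside [0, 10]")
    return v
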