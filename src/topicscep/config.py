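"""YAML configuration for coding scheme, pro-rating policy, weights and generator.

All sections are optional; anything omitted keeps the package defaults. A
minimal file overriding one emotional item and the missingness tolerance::

    coding_scheme:
      items:
        emo_01: {native_min: 1, native_max: 6, higher_is_better: true}
    prorating:
      max_missing_emotional: 1
    weights:
      intercept: 9.00
    generator:
      n_projects: 28
      total_n: 5000
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .scoring import CodingScheme, ItemSpec, PreferenceWeights, ProRatingPolicy
from .synthetic import GeneratorConfig

__all__ = [
    "load_config",
    "scheme_from_dict",
    "policy_from_dict",
    "weights_from_dict",
    "generator_from_dict",
]


def scheme_from_dict(d: dict | None) -> CodingScheme:
    base = CodingScheme.default()
    if not d:
        return base
    items = dict(base.items)
    for name, spec in (d.get("items") or {}).items():
        items[name] = ItemSpec(
            native_min=int(spec["native_min"]),
            native_max=int(spec["native_max"]),
            higher_is_better=bool(spec.get("higher_is_better", False)),
        )
    return CodingScheme(items=items)


def policy_from_dict(d: dict | None) -> ProRatingPolicy:
    return ProRatingPolicy(**(d or {}))


def weights_from_dict(d: dict | None, scheme: CodingScheme) -> PreferenceWeights:
    d = d or {}
    kwargs = {}
    if "intercept" in d:
        kwargs["intercept"] = float(d["intercept"])
    if "weights" in d:
        base = dict(PreferenceWeights().weights)
        base.update({k: float(v) for k, v in d["weights"].items()})
        kwargs["weights"] = base
    return PreferenceWeights.for_scheme(scheme, **kwargs)


def generator_from_dict(d: dict | None) -> GeneratorConfig:
    d = dict(d or {})
    if "outcome_correlations" in d:
        d["outcome_correlations"] = np.asarray(d["outcome_correlations"], dtype=float)
    return GeneratorConfig(**d)


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config file into ready-made component objects.

    Returns a dict with keys ``scheme``, ``policy``, ``weights``,
    ``generator`` and the raw ``data`` mapping.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    scheme = scheme_from_dict(raw.get("coding_scheme"))
    return {
        "scheme": scheme,
        "policy": policy_from_dict(raw.get("prorating")),
        "weights": weights_from_dict(raw.get("weights"), scheme),
        "generator": generator_from_dict(raw.get("generator")),
        "data": raw,
    }
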