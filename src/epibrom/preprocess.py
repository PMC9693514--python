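"""Trait transformations feeding the clustering and discriminant steps.

Per-trait recipes: most clustering traits are log10-transformed; leaf
nitrogen content (N) and δ15N stay on the raw scale; tank capacity gets a
0.5 mL offset before the log so zero-capacity species remain defined;
δ13C is folded to its absolute value first (which inverts the ordering of
the all-negative field values, putting C3-like signatures at the high
end); the binary pseudobulb flag passes through untouched.  Every column
is finally min-max rescaled to [0, 1] on the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trait_db import TraitTable

__all__ = ["TransformSpec", "default_transform_spec", "transform",
           "inverse_report", "inverse_transform"]

RECIPES = ("none", "log10", "offset_then_log10", "abs_then_log10")


@dataclass
class TransformSpec:
    """Per-trait transformation recipes, all ending in 0–1 rescale.

    ``recipes`` maps trait abbreviation to one of ``none``, ``log10``,
    ``offset_then_log10``, ``abs_then_log10``; ``offsets`` gives the
    additive offset (mL for TC) used by ``offset_then_log10``.
    """

    recipes: dict[str, str] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)
    rescale: bool = True

    def recipe(self, trait: str) -> str:
        return self.recipes.get(trait, "log10")

    def validate(self) -> None:
        for trait, r in self.recipes.items():
            if r not in RECIPES:
                raise ValueError(f"unknown recipe {r!r} for {trait}")


def default_transform_spec(include_pb: bool = True) -> TransformSpec:
    """The default stack for the 16 clustering traits.

    All traits log10 except N and δ15N (raw) and PB (binary pass-through);
    TC offset by +0.5 mL before the log; δ13C |x| before the log.
    """
    recipes = {
        "Height": "log10", "LA": "log10", "LI": "log10", "LL": "log10",
        "LT": "log10", "TD": "log10", "LWA": "log10", "LW": "log10",
        "SLA": "log10", "SD": "log10", "LWC": "log10",
        "N": "none", "d15N": "none",
        "TC": "offset_then_log10",
        "d13C": "abs_then_log10",
    }
    if include_pb:
        recipes["PB"] = "none"
    return TransformSpec(recipes=recipes, offsets={"TC": 0.5})


def _apply_recipe(col: pd.Series, recipe: str, offset: float,
                  trait: str) -> pd.Series:
    if col.isna().any():
        bad = list(col.index[col.isna()])
        raise ValueError(
            f"missing cell(s) entering transform for trait {trait}: {bad} "
            "(imputation must run first)")
    x = col.astype(float)
    if recipe == "none":
        return x
    if recipe == "offset_then_log10":
        x = x + offset
    elif recipe == "abs_then_log10":
        x = x.abs()
    nonpos = x <= 0
    if nonpos.any():
        bad = list(x.index[nonpos])
        raise ValueError(
            f"non-positive value entering log10 for trait {trait}: {bad}")
    return np.log10(x)


def transform(t: TraitTable | pd.DataFrame, spec: TransformSpec | None = None
              ) -> pd.DataFrame:
    """Apply per-trait recipes then min-max rescale each column to [0, 1].

    Constant columns map to all zeros.  Binary 0/1 columns are unchanged
    by the rescale.
    """
    spec = spec if spec is not None else default_transform_spec()
    spec.validate()
    values = t.values if isinstance(t, TraitTable) else t
    out = pd.DataFrame(index=values.index, dtype=float)
    for trait in values.columns:
        y = _apply_recipe(values[trait], spec.recipe(trait),
                          spec.offsets.get(trait, 0.0), trait)
        if spec.rescale:
            lo, hi = y.min(), y.max()
            y = (y - lo) / (hi - lo) if hi > lo else y * 0.0
        out[trait] = y
    return out


def inverse_report(t: TraitTable | pd.DataFrame,
                   spec: TransformSpec | None = None) -> pd.DataFrame:
    """Per-trait (min, max, recipe, offset) on the post-recipe scale,
    i.e. the parameters needed to map 0–1 coordinates back to raw units."""
    spec = spec if spec is not None else default_transform_spec()
    values = t.values if isinstance(t, TraitTable) else t
    rows = []
    for trait in values.columns:
        y = _apply_recipe(values[trait], spec.recipe(trait),
                          spec.offsets.get(trait, 0.0), trait)
        recipe = spec.recipe(trait)
        if recipe in ("log10", "offset_then_log10", "abs_then_log10"):
            lo, hi = 10 ** y.min(), 10 ** y.max()
        else:
            lo, hi = y.min(), y.max()
        rows.append({"trait": trait, "min": lo, "max": hi,
                     "recipe": recipe,
                     "offset": spec.offsets.get(trait, 0.0)})
    return pd.DataFrame(rows).set_index("trait")


def inverse_transform(scaled: pd.DataFrame, report: pd.DataFrame
                      ) -> pd.DataFrame:
    """Map 0–1 coordinates back to raw trait units using ``inverse_report``.

    For ``abs_then_log10`` the sign is not recoverable; values return on
    the |x| scale.
    """
    out = pd.DataFrame(index=scaled.index, dtype=float)
    for trait in scaled.columns:
        lo = report.at[trait, "min"]
        hi = report.at[trait, "max"]
        recipe = report.at[trait, "recipe"]
        offset = report.at[trait, "offset"]
        y = scaled[trait].astype(float)
        if recipe == "none":
            out[trait] = lo + y * (hi - lo) if hi > lo else lo
            continue
        logy = np.log10(lo) + y * (np.log10(hi) - np.log10(lo)) \
            if hi > lo else np.full(len(y), np.log10(lo))
        raw = 10 ** logy
        if recipe == "offset_then_log10":
            raw = raw - offset
        out[trait] = raw
    return out
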