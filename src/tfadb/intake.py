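"""Per-subject intake estimation from multi-day semi-weighed diet records.

Daily energy, total fat and TFA are summed per recording day and averaged
over a subject's recorded days (nominally 16: 4 non-consecutive days in
each season). Percent-of-energy expressions use the ratio of the
multi-day means, not the mean of daily ratios, so low-energy days do not
inflate them. Venue matters only for TFA: commercial foods (fast foods,
baked goods, confectionaries) keep the values of the products themselves,
while composed restaurant dishes are decomposed into their raw materials
through recipes before TFA look-up.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._types import (
    DietRecordEntry,
    FoodItem,
    Recipe,
    Subject,
    SubjectIntake,
    TfaAssignment,
    ValidationError,
)
from .config import EstimationConfig

log = logging.getLogger(__name__)

__all__ = [
    "resolve_entry",
    "flatten_recipe",
    "subject_mean_intake",
    "estimate_intakes",
    "exclude_outliers",
    "bmi",
    "ResolutionError",
]


class ResolutionError(ValueError):
    pass


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index: weight (kg) / height (m) squared."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValidationError("height and weight must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def flatten_recipe(
    food_id: str,
    recipes: Mapping[str, Recipe],
    _stack: frozenset[str] = frozenset(),
) -> list[tuple[str, float]]:
    """Leaf-level (ingredient, grams per 100 g) decomposition of a dish."""
    if food_id in _stack:
        raise ResolutionError(f"cyclic recipe involving {food_id!r}")
    recipe = recipes.get(food_id)
    if recipe is None:
        return [(food_id, 100.0)]
    leaves: list[tuple[str, float]] = []
    for ing, grams in recipe.ingredients:
        for leaf, leaf_grams in flatten_recipe(ing, recipes, _stack | {food_id}):
            leaves.append((leaf, grams * leaf_grams / 100.0))
    return leaves


def resolve_entry(
    entry: DietRecordEntry,
    recipes: Mapping[str, Recipe],
    composed_ids: set[str] | None = None,
) -> list[tuple[str, float]]:
    """Map one consumption event to the foods whose TFA values apply.

    Home-cooked and commercial items pass through unchanged. Composed
    restaurant dishes — for which product nutrient information does not
    exist — are replaced by their raw materials, scaled to the consumed
    amount. *composed_ids* optionally declares which foods are composed
    dishes so that a missing restaurant recipe is an error rather than a
    silent pass-through.
    """
    if entry.venue != "restaurant":
        return [(entry.food_id, entry.grams)]
    if entry.food_id in recipes:
        return [
            (leaf, entry.grams * g / 100.0)
            for leaf, g in flatten_recipe(entry.food_id, recipes)
        ]
    if composed_ids and entry.food_id in composed_ids:
        raise ResolutionError(
            f"restaurant entry for composed food {entry.food_id!r} has no recipe"
        )
    return [(entry.food_id, entry.grams)]


def subject_mean_intake(
    entries: Sequence[DietRecordEntry],
    foods_by_id: Mapping[str, FoodItem],
    assignments: Mapping[str, TfaAssignment],
    recipes: Mapping[str, Recipe] | None = None,
    subject: Subject | None = None,
    cfg: EstimationConfig | None = None,
) -> SubjectIntake:
    """Mean daily intake of one subject over their recorded days.

    Energy and fat come from the foods as recorded; TFA is computed after
    venue resolution. Raises on zero total energy.
    """
    cfg = cfg or EstimationConfig()
    recipes = recipes or {}
    if not entries:
        raise ValidationError("subject has no recorded days")
    subject_id = entries[0].subject_id
    days: dict[int, list[float]] = {}
    for e in entries:
        food = foods_by_id[e.food_id]
        energy = e.grams * food.energy_kcal_100g / 100.0
        fat = e.grams * food.fat_g_100g / 100.0
        tfa = sum(
            grams * assignments[fid].tfa_g_100g / 100.0
            for fid, grams in resolve_entry(e, recipes)
        )
        day = days.setdefault(e.day_index, [0.0, 0.0, 0.0])
        day[0] += energy
        day[1] += fat
        day[2] += tfa
    n_days = len(days)
    if n_days < cfg.expected_days:
        warnings.warn(
            f"subject {subject_id!r}: only {n_days} of {cfg.expected_days} days "
            "recorded; averaging over available days",
            stacklevel=2,
        )
    totals = np.array(list(days.values()))
    energy_day, fat_day, tfa_day = totals.mean(axis=0)
    if energy_day <= 0:
        raise ValidationError(f"subject {subject_id!r}: zero total energy intake")
    k = cfg.energy_per_gram_fat
    return SubjectIntake(
        subject_id=subject_id,
        n_days=n_days,
        energy_kcal_day=float(energy_day),
        fat_g_day=float(fat_day),
        tfa_g_day=float(tfa_day),
        tfa_pct_energy=float(100.0 * tfa_day * k / energy_day),
        fat_pct_energy=float(100.0 * fat_day * k / energy_day),
        tfa_pct_fat=float(100.0 * tfa_day / fat_day) if fat_day > 0 else 0.0,
        bmi_kg_m2=bmi(subject.weight_kg, subject.height_cm) if subject else None,
    )


def estimate_intakes(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    foods: pd.DataFrame,
    assignments: pd.DataFrame,
    recipes: Mapping[str, Recipe] | None = None,
    cfg: EstimationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised cohort-level estimation.

    Returns ``(intakes, group_tfa)``: one row per subject with all intake
    expressions plus BMI, and the per-subject mean daily TFA by food-group
    label (the input of the contribution decomposition). Foods missing
    from *assignments* contribute zero TFA — this is what restricting the
    database to a base food list means.
    """
    cfg = cfg or EstimationConfig()
    recipes = recipes or {}
    foods_ix = foods.set_index("food_id")
    tfa100 = assignments.set_index("food_id")["tfa_g_100g"]

    rec = records.copy()
    # energy/fat from the foods as recorded
    rec["energy"] = rec["grams"].to_numpy() * foods_ix["energy_kcal_100g"].reindex(rec["food_id"]).to_numpy() / 100.0
    rec["fat"] = rec["grams"].to_numpy() * foods_ix["fat_g_100g"].reindex(rec["food_id"]).to_numpy() / 100.0
    if rec["energy"].isna().any():
        bad = rec.loc[rec["energy"].isna(), "food_id"].unique()
        raise ValidationError(f"diet records refer to unknown foods: {sorted(bad)[:10]}")

    # TFA after venue resolution: expand composed restaurant dishes
    leaf_map = {fid: flatten_recipe(fid, recipes) for fid in recipes}
    is_expanded = (rec["venue"] == "restaurant") & rec["food_id"].isin(leaf_map)
    plain = rec.loc[~is_expanded, ["subject_id", "day_index", "food_id", "grams"]]
    expanded_rows = []
    for row in rec.loc[is_expanded, ["subject_id", "day_index", "food_id", "grams"]].itertuples(index=False):
        for leaf, g100 in leaf_map[row.food_id]:
            expanded_rows.append((row.subject_id, row.day_index, leaf, row.grams * g100 / 100.0))
    resolved = pd.concat(
        [plain, pd.DataFrame(expanded_rows, columns=plain.columns)],
        ignore_index=True,
    )
    resolved["tfa"] = resolved["grams"].to_numpy() * tfa100.reindex(resolved["food_id"]).fillna(0.0).to_numpy() / 100.0
    resolved["group_label"] = _group_labels(foods_ix).reindex(resolved["food_id"]).to_numpy()

    n_days = rec.groupby("subject_id")["day_index"].nunique()
    short = n_days[n_days < cfg.expected_days]
    if len(short):
        warnings.warn(
            f"{len(short)} subjects have fewer than {cfg.expected_days} recorded days; "
            "averaging over available days",
            stacklevel=2,
        )

    day_ef = rec.groupby(["subject_id", "day_index"])[["energy", "fat"]].sum()
    day_tfa = resolved.groupby(["subject_id", "day_index"])["tfa"].sum()
    daily = day_ef.join(day_tfa).fillna({"tfa": 0.0})
    per_subject = daily.groupby("subject_id").mean()
    if (per_subject["energy"] <= 0).any():
        bad = per_subject.index[per_subject["energy"] <= 0].tolist()
        raise ValidationError(f"zero total energy for subjects: {bad}")

    k = cfg.energy_per_gram_fat
    out = per_subject.rename(
        columns={"energy": "energy_kcal_day", "fat": "fat_g_day", "tfa": "tfa_g_day"}
    )
    out["tfa_pct_energy"] = 100.0 * out["tfa_g_day"] * k / out["energy_kcal_day"]
    out["fat_pct_energy"] = 100.0 * out["fat_g_day"] * k / out["energy_kcal_day"]
    out["tfa_pct_fat"] = np.where(
        out["fat_g_day"] > 0, 100.0 * out["tfa_g_day"] / out["fat_g_day"], 0.0
    )
    out["n_days"] = n_days

    subj = subjects.set_index("subject_id")
    out = out.join(subj[["sex", "age_years", "area", "height_cm", "weight_kg"]], how="left")
    out["bmi_kg_m2"] = out["weight_kg"] / (out["height_cm"] / 100.0) ** 2
    out = out.reset_index()

    group_tfa = (
        resolved.groupby(["subject_id", "group_label"])["tfa"].sum().reset_index()
    )
    group_tfa = group_tfa.merge(n_days.rename("n_days"), on="subject_id")
    group_tfa["tfa_g_day"] = group_tfa["tfa"] / group_tfa["n_days"]
    group_tfa = group_tfa[["subject_id", "group_label", "tfa_g_day"]]

    log.info("estimated intakes for %d subjects (%d record rows)", len(out), len(rec))
    return out, group_tfa


def _group_labels(foods_ix: pd.DataFrame) -> pd.Series:
    flag = np.where(foods_ix["origin"].to_numpy() == "industrial", "I", "N")
    labels = foods_ix["group"].astype(str) + " (" + flag + ")"
    labels = labels.where(foods_ix["group"] != "no-TFA", "no-TFA")
    return labels


def exclude_outliers(
    intakes: pd.DataFrame, k: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-pass, within-sex exclusion of extreme TFA intakes.

    A subject is excluded when their TFA intake in g/day *or* in % of
    total energy lies outside the sex group's mean +/- k SD (sample SD,
    computed once from the full group). Groups with zero or undefined SD
    exclude nobody.
    """
    flags = pd.Series(False, index=intakes.index)
    for _, grp in intakes.groupby("sex"):
        for col in ("tfa_g_day", "tfa_pct_energy"):
            m, s = grp[col].mean(), grp[col].std(ddof=1)
            if not np.isfinite(s) or s == 0:
                continue
            flags.loc[grp.index] |= (grp[col] < m - k * s) | (grp[col] > m + k * s)
    kept = intakes.loc[~flags].reset_index(drop=True)
    excluded = intakes.loc[flags].reset_index(drop=True)
    if len(excluded):
        log.info("excluded %d outlying subjects (+/- %g SD rule)", len(excluded), k)
    return kept, excluded
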