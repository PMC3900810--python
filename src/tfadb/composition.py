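"""Construction of a complete TFA composition database.

Every food in the table receives exactly one TFA value with a provenance
label, through a strict precedence of rules:

1. the zero rule — foods with no/trace fat and neither partially
   hydrogenated oils nor ruminant-derived ingredients contain no TFA;
2. Step 1 — pooling of analytic literature values (single value, single
   article's mean, or sample-size-weighted mean over articles);
3. Step 2 — transfer of a resolved food's TFA expressed as % of total fat
   to a similar food (same-category/same-group path for general foods, a
   five-level cascade for meat cuts), rescaled by the recipient's own fat;
4. Step 3 — foreign-database values for same-manufacturer products whose
   macronutrient composition matches the domestic food;
5. Step 4 — linear imputation from recipes.

The output provenance table counts foods per group x step and is the
machine-checkable analogue of a published database-development summary.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._types import (
    PROVENANCE_COLUMNS,
    STEP1_STEPS,
    STEP_TO_COLUMN,
    Basis,
    FoodItem,
    ForeignFoodRecord,
    Recipe,
    ReferenceRecord,
    Step,
    TfaAssignment,
    ValidationError,
)
from .config import CompositionConfig

log = logging.getLogger(__name__)

__all__ = [
    "zero_rule",
    "convert_reference",
    "reference_pct_fat",
    "pool_step1",
    "nutrient_distance",
    "assign_step2",
    "assign_step3",
    "assign_step4",
    "build_database",
    "build_assignments",
    "assignments_to_frame",
    "PoolingError",
    "DatabaseBuildError",
]


class PoolingError(ValueError):
    """Literature pooling cannot be resolved automatically."""


class DatabaseBuildError(RuntimeError):
    """The hierarchy left foods without a value."""


# ---------------------------------------------------------------- zero rule


def zero_rule(food: FoodItem, fat_threshold: float = 0.1) -> bool:
    """True iff *food* contains no TFA by construction.

    A food is TFA-free when it has at most a trace amount of fat
    (``fat_threshold`` g/100 g) or contains neither partially hydrogenated
    oils nor ruminant-derived ingredients (the only two TFA sources).
    """
    fat = food.fat_g_100g
    if fat is None or (isinstance(fat, float) and np.isnan(fat)):
        raise ValidationError(f"food {food.food_id!r}: missing fat content")
    if fat <= fat_threshold:
        return True
    return not (food.contains_hydrogenated_oil or food.contains_ruminant)


# ------------------------------------------------------ reference conversion


def convert_reference(ref: ReferenceRecord, food: FoodItem) -> float:
    """Convert one analytic record to grams TFA per 100 g of *food*.

    TFA (g)/100 g food = [TFA (g)/total fat (g) in the reference] x
    [total fat (g)/100 g food in the composition table]. References on a
    g/100 g-of-food basis that state their own fat content are rescaled
    through it; those that do not fall back on the table's fat content
    (which makes the conversion the identity).
    """
    fat = food.fat_g_100g
    if fat == 0 and ref.mean_value != 0:
        raise ValidationError(
            f"food {food.food_id!r} has zero fat but reference "
            f"{ref.article_id!r} reports nonzero TFA"
        )
    if ref.basis is Basis.PERCENT_OF_FAT:
        return ref.mean_value / 100.0 * fat
    ref_fat = ref.ref_fat_g_100g if ref.ref_fat_g_100g else fat
    if ref_fat == 0:
        return 0.0
    return ref.mean_value / ref_fat * fat


def reference_pct_fat(ref: ReferenceRecord, food: FoodItem) -> float:
    """The record's TFA value expressed as % of total fat."""
    if ref.basis is Basis.PERCENT_OF_FAT:
        return float(ref.mean_value)
    ref_fat = ref.ref_fat_g_100g if ref.ref_fat_g_100g else food.fat_g_100g
    if ref_fat == 0:
        if ref.mean_value != 0:
            raise ValidationError(
                f"food {food.food_id!r}: reference {ref.article_id!r} reports "
                "nonzero TFA with zero fat"
            )
        return 0.0
    return float(ref.mean_value) / ref_fat * 100.0


# ----------------------------------------------------------------- pooling


def pool_step1(
    records: Sequence[ReferenceRecord], food: FoodItem
) -> tuple[float, Step]:
    """Pool one food's analytic records into a single % -of-fat value.

    One article with one sample -> that value (S1_SINGLE); one article with
    several samples -> its mean (S1_MEAN); several articles -> mean of the
    article means weighted by the number of samples each analysed
    (S1_WEIGHTED). An article that does not state its sample count is used
    when it is the sole source but excluded from weighted pooling.
    """
    if not records:
        raise PoolingError(f"no records for food {food.food_id!r}")
    if any(r.food_id != food.food_id for r in records):
        raise PoolingError("records must all refer to the pooled food")

    if len(records) > 1:
        retained = [r for r in records if r.n_samples is not None]
        if not retained:
            raise PoolingError(
                f"food {food.food_id!r}: multiple articles, none with a known "
                "sample count — manual resolution required"
            )
    else:
        retained = list(records)

    values = np.array([reference_pct_fat(r, food) for r in retained])
    if len(retained) == 1:
        r = retained[0]
        step = Step.S1_SINGLE if (r.n_samples is None or r.n_samples == 1) else Step.S1_MEAN
        return float(values[0]), step
    weights = np.array([r.n_samples for r in retained], dtype=float)
    return float(np.average(values, weights=weights)), Step.S1_WEIGHTED


# ------------------------------------------------------- nutrient similarity


def _nutrient_vector(x) -> np.ndarray:
    if isinstance(x, (FoodItem, ForeignFoodRecord)):
        return np.array(
            [x.energy_kcal_100g, x.fat_g_100g, x.protein_g_100g, x.carb_g_100g],
            dtype=float,
        )
    v = np.asarray(x, dtype=float)
    if v.shape != (4,):
        raise ValidationError("nutrient vector must have 4 components")
    return v


def nutrient_distance(a, b, floor: float = 1.0) -> float:
    """Max relative macronutrient deviation of *a* from reference *b*.

    Components are (energy kcal, fat g, protein g, carbohydrate g) per
    100 g. Each absolute difference is normalised by the reference value
    floored at *floor* to keep near-zero components from dominating. Zero
    iff identical; two profiles are "similar" when the score is at most
    the configured similarity threshold.
    """
    va, vb = _nutrient_vector(a), _nutrient_vector(b)
    denom = np.maximum(np.abs(vb), floor)
    return float(np.max(np.abs(va - vb) / denom))


def _nearest_donor(
    food: FoodItem,
    candidates: Iterable[FoodItem],
    cfg: CompositionConfig,
    thresholded: bool,
) -> FoodItem | None:
    """Nearest candidate by nutrient distance; lowest food_id breaks ties."""
    best: tuple[float, str, FoodItem] | None = None
    for cand in candidates:
        d = nutrient_distance(food, cand, floor=cfg.similarity_floor)
        if thresholded and d > cfg.similarity_threshold:
            continue
        key = (d, cand.food_id)
        if best is None or key < (best[0], best[1]):
            best = (d, cand.food_id, cand)
    return best[2] if best else None


# ------------------------------------------------------------------- step 2


def _transfer(food: FoodItem, donor_assignment: TfaAssignment, step: Step) -> TfaAssignment:
    """Transfer the donor's % of fat and rescale by the recipient's fat.

    Recipients flagged as TFA sources but with zero fat get 0.0 under the
    matched step label (%-of-fat transfer is undefined at zero fat).
    """
    pct = donor_assignment.tfa_pct_fat
    if food.fat_g_100g == 0:
        return TfaAssignment(food.food_id, 0.0, 0.0, step, donor_assignment.food_id)
    g = pct * food.fat_g_100g / 100.0
    return TfaAssignment(food.food_id, g, pct, step, donor_assignment.food_id)


def assign_step2(
    food: FoodItem,
    resolved: Mapping[str, TfaAssignment],
    foods_by_id: Mapping[str, FoodItem],
    cfg: CompositionConfig,
) -> TfaAssignment | None:
    """Similarity transfer from a Step-1-resolved donor, or None.

    General foods try the same category of the same group (2-1A) then the
    same group (2-1B). Meat cuts (foods of the meat group carrying a
    species label) run the cascade: same species and part (2-2A), similar
    part of the same species (2-2B), similar animal per the species
    adjacency (2-2C), different species per the fallback map (2-2D), and
    finally the same meat category (2-2E). Whether each sub-step demands
    nutrient similarity is configurable; within a pool the nearest donor
    by nutrient distance wins.
    """
    donors = [
        foods_by_id[a.food_id]
        for a in resolved.values()
        if a.step in STEP1_STEPS and a.food_id in foods_by_id
    ]
    donors.sort(key=lambda f: f.food_id)

    is_meat_cut = food.group == cfg.meat_group and bool(food.species)
    if is_meat_cut:
        meat_donors = [d for d in donors if d.group == cfg.meat_group]
        sp, pt = food.species, food.part
        similar_parts = set(cfg.parts_adjacency.get(pt or "", ()))
        similar_species = set(cfg.species_adjacency.get(sp or "", ()))
        fallback_species = set(cfg.species_fallback.get(sp or "", ()))
        pools: list[tuple[Step, list[FoodItem]]] = [
            (Step.S2_2A, [d for d in meat_donors if d.species == sp and d.part == pt]),
            (Step.S2_2B, [d for d in meat_donors if d.species == sp and d.part in similar_parts]),
            (Step.S2_2C, [d for d in meat_donors if d.species in similar_species]),
            (Step.S2_2D, [d for d in meat_donors if d.species in fallback_species]),
            (Step.S2_2E, [d for d in meat_donors if d.category == food.category]),
        ]
    else:
        group_donors = [d for d in donors if d.group == food.group and d.origin == food.origin]
        pools = [
            (Step.S2_1A, [d for d in group_donors if d.category == food.category]),
            (Step.S2_1B, group_donors),
        ]

    for step, pool in pools:
        donor = _nearest_donor(food, pool, cfg, thresholded=step.value in cfg.thresholded_steps)
        if donor is not None:
            return _transfer(food, resolved[donor.food_id], step)
    return None


# ------------------------------------------------------------------- step 3


def assign_step3(
    food: FoodItem,
    foreign: Sequence[ForeignFoodRecord],
    cfg: CompositionConfig,
) -> TfaAssignment | None:
    """Adopt a matched foreign product's value when compositions agree.

    Only same-manufacturer products qualify; among those within the
    similarity threshold the closest match is used.
    """
    best: tuple[float, ForeignFoodRecord] | None = None
    for rec in foreign:
        if not rec.same_manufacturer or rec.food_id != food.food_id:
            continue
        d = nutrient_distance(food, rec, floor=cfg.similarity_floor)
        if d > cfg.similarity_threshold:
            continue
        if best is None or d < best[0]:
            best = (d, rec)
    if best is None:
        return None
    g = best[1].foreign_tfa_g_100g
    pct = 100.0 * g / food.fat_g_100g if food.fat_g_100g > 0 else 0.0
    return TfaAssignment(food.food_id, g, pct, Step.S3)


# ------------------------------------------------------------------- step 4


def assign_step4(
    food: FoodItem,
    recipe: Recipe,
    assignments: Mapping[str, TfaAssignment],
) -> TfaAssignment:
    """Impute a composed food's TFA as the gram-weighted sum over its recipe."""
    missing = [ing for ing, _ in recipe.ingredients if ing not in assignments]
    if missing:
        raise DatabaseBuildError(
            f"recipe for {food.food_id!r} has unresolved ingredients: {missing}"
        )
    g = sum(grams / 100.0 * assignments[ing].tfa_g_100g for ing, grams in recipe.ingredients)
    pct = 100.0 * g / food.fat_g_100g if food.fat_g_100g > 0 else 0.0
    return TfaAssignment(food.food_id, g, pct, Step.S4)


# ------------------------------------------------------------ full database


def build_assignments(
    foods: Sequence[FoodItem],
    refs: Sequence[ReferenceRecord],
    foreign: Sequence[ForeignFoodRecord] = (),
    recipes: Sequence[Recipe] = (),
    cfg: CompositionConfig | None = None,
) -> dict[str, TfaAssignment]:
    """Run the full precedence and return one assignment per food.

    Deterministic given inputs and config: foods are processed in food_id
    order and all tie-breaks are by lowest food_id. Raises
    :class:`DatabaseBuildError` if any food is still unresolved after
    Step 4.
    """
    cfg = cfg or CompositionConfig()
    foods_sorted = sorted(foods, key=lambda f: f.food_id)
    foods_by_id = {f.food_id: f for f in foods_sorted}
    if len(foods_by_id) != len(foods_sorted):
        raise ValidationError("duplicate food_id in food table")

    refs_by_food: dict[str, list[ReferenceRecord]] = defaultdict(list)
    for r in refs:
        if r.food_id not in foods_by_id:
            raise ValidationError(f"reference {r.article_id!r} refers to unknown food {r.food_id!r}")
        refs_by_food[r.food_id].append(r)

    assignments: dict[str, TfaAssignment] = {}

    # zero rule
    for f in foods_sorted:
        if zero_rule(f, cfg.fat_threshold):
            assignments[f.food_id] = TfaAssignment(f.food_id, 0.0, 0.0, Step.ZERO)

    # Step 1: analytic pooling
    step1: dict[str, TfaAssignment] = {}
    for f in foods_sorted:
        if f.food_id in assignments or f.food_id not in refs_by_food:
            continue
        pct, step = pool_step1(sorted(refs_by_food[f.food_id], key=lambda r: r.article_id), f)
        g = pct / 100.0 * f.fat_g_100g
        step1[f.food_id] = assignments[f.food_id] = TfaAssignment(f.food_id, g, pct, step)

    # Step 2: similarity transfer
    for f in foods_sorted:
        if f.food_id in assignments:
            continue
        a = assign_step2(f, step1, foods_by_id, cfg)
        if a is not None:
            assignments[f.food_id] = a

    # Step 3: foreign-database match
    for f in foods_sorted:
        if f.food_id in assignments:
            continue
        a = assign_step3(f, foreign, cfg)
        if a is not None:
            assignments[f.food_id] = a

    # Step 4: recipe imputation, nested recipes in dependency order
    recipes_by_food = {r.food_id: r for r in recipes}
    pending = [fid for fid in foods_by_id if fid not in assignments and fid in recipes_by_food]
    ts = TopologicalSorter(
        {
            fid: [ing for ing, _ in recipes_by_food[fid].ingredients if ing in pending]
            for fid in pending
        }
    )
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        raise DatabaseBuildError(f"cyclic recipes: {exc.args[1]}") from exc
    for fid in order:
        assignments[fid] = assign_step4(foods_by_id[fid], recipes_by_food[fid], assignments)

    unresolved = [fid for fid in foods_by_id if fid not in assignments]
    if unresolved:
        raise DatabaseBuildError(
            f"{len(unresolved)} foods unresolved after Step 4: {sorted(unresolved)[:20]}"
        )
    return assignments


def assignments_to_frame(
    assignments: Mapping[str, TfaAssignment]
) -> pd.DataFrame:
    rows = [
        {
            "food_id": a.food_id,
            "tfa_g_100g": a.tfa_g_100g,
            "tfa_pct_fat": a.tfa_pct_fat,
            "step": a.step.value,
            "donor_food_id": a.donor_food_id if a.donor_food_id else "",
        }
        for a in sorted(assignments.values(), key=lambda a: a.food_id)
    ]
    return pd.DataFrame(rows, columns=["food_id", "tfa_g_100g", "tfa_pct_fat", "step", "donor_food_id"])


def provenance_table(
    foods: Sequence[FoodItem], assignments: Mapping[str, TfaAssignment]
) -> pd.DataFrame:
    """Counts of foods per group-label row and per assignment-step column.

    Rows appear in first-seen food order; the grand total of the table
    equals the number of foods.
    """
    labels: list[str] = []
    for f in sorted(foods, key=lambda f: f.food_id):
        if f.group_label not in labels:
            labels.append(f.group_label)
    counts = pd.DataFrame(0, index=labels, columns=list(PROVENANCE_COLUMNS), dtype=int)
    by_id = {f.food_id: f for f in foods}
    for a in assignments.values():
        counts.loc[by_id[a.food_id].group_label, STEP_TO_COLUMN[a.step]] += 1
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    counts.index.name = "group"
    return counts


def build_database(
    foods: Sequence[FoodItem],
    refs: Sequence[ReferenceRecord],
    foreign: Sequence[ForeignFoodRecord] = (),
    recipes: Sequence[Recipe] = (),
    cfg: CompositionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the database; returns (assignments frame, provenance table)."""
    assignments = build_assignments(foods, refs, foreign, recipes, cfg)
    prov = provenance_table(foods, assignments)
    n_zero = int(prov.loc["Total", "ZERO"])
    log.info(
        "database built: %d foods, %d TFA-free by the zero rule, %d assigned",
        len(foods), n_zero, len(foods) - n_zero,
    )
    return assignments_to_frame(assignments), prov
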