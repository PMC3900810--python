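"""CSV schemas, loading/saving, and cross-table validation.

All files are UTF-8, comma-separated, header row mandatory, "." decimal.
An empty ``n_samples`` field means the article did not report its sample
count. Boolean columns are written ``True``/``False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._types import (
    Basis,
    FoodItem,
    ForeignFoodRecord,
    Recipe,
    ReferenceRecord,
    SEASONS,
    VENUES,
)
from .config import PipelineConfig

log = logging.getLogger(__name__)

FOODS_COLUMNS = [
    "food_id", "name", "group", "origin", "category", "species", "part",
    "energy_kcal_100g", "fat_g_100g", "protein_g_100g", "carb_g_100g",
    "contains_hydrogenated_oil", "contains_ruminant",
]
REFERENCES_COLUMNS = [
    "article_id", "food_id", "n_samples", "mean_value", "min_value",
    "max_value", "basis", "ref_fat_g_100g",
]
FOREIGN_COLUMNS = [
    "food_id", "foreign_tfa_g_100g", "energy_kcal_100g", "fat_g_100g",
    "protein_g_100g", "carb_g_100g", "same_manufacturer",
]
RECIPES_COLUMNS = ["food_id", "ingredient_id", "grams_per_100g"]
RECORDS_COLUMNS = ["subject_id", "day_index", "season", "food_id", "grams", "venue"]
SUBJECTS_COLUMNS = ["subject_id", "sex", "age_years", "area", "height_cm", "weight_kg"]


def _read(path, columns, **kw) -> pd.DataFrame:
    # exact float round-trip so write -> read -> write is byte-identical
    df = pd.read_csv(path, float_precision="round_trip", **kw)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[columns]


def read_foods(path) -> pd.DataFrame:
    df = _read(path, FOODS_COLUMNS, dtype={"food_id": str}, keep_default_na=False,
               na_values=[""])
    for col in ("name", "group", "origin", "category", "species", "part"):
        df[col] = df[col].fillna("").astype(str)
    for col in ("contains_hydrogenated_oil", "contains_ruminant"):
        df[col] = df[col].map(
            {"True": True, "False": False, True: True, False: False, "1": True, "0": False}
        )
    for col in ("energy_kcal_100g", "fat_g_100g", "protein_g_100g", "carb_g_100g"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_references(path) -> pd.DataFrame:
    df = _read(path, REFERENCES_COLUMNS, dtype={"article_id": str, "food_id": str})
    df["n_samples"] = df["n_samples"].astype("Int64")
    return df


def read_foreign(path) -> pd.DataFrame:
    df = _read(path, FOREIGN_COLUMNS, dtype={"food_id": str})
    df["same_manufacturer"] = df["same_manufacturer"].map(
        {"True": True, "False": False, True: True, False: False}
    )
    return df


def read_recipes(path) -> pd.DataFrame:
    return _read(path, RECIPES_COLUMNS, dtype={"food_id": str, "ingredient_id": str})


def read_diet_records(path) -> pd.DataFrame:
    return _read(path, RECORDS_COLUMNS, dtype={"subject_id": str, "food_id": str})


def read_subjects(path) -> pd.DataFrame:
    return _read(path, SUBJECTS_COLUMNS, dtype={"subject_id": str})


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"food_id": str, "donor_food_id": str},
                     keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    df["donor_food_id"] = df["donor_food_id"].fillna("")
    for col in ("tfa_g_100g", "tfa_pct_fat"):
        df[col] = pd.to_numeric(df[col])
    return df


def write_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


# ------------------------------------------------- frame <-> domain objects


def foods_from_frame(df: pd.DataFrame) -> list[FoodItem]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            FoodItem(
                food_id=row.food_id, name=row.name, group=row.group,
                origin=row.origin, category=row.category,
                species=row.species or None, part=row.part or None,
                energy_kcal_100g=float(row.energy_kcal_100g),
                fat_g_100g=float(row.fat_g_100g),
                protein_g_100g=float(row.protein_g_100g),
                carb_g_100g=float(row.carb_g_100g),
                contains_hydrogenated_oil=bool(row.contains_hydrogenated_oil),
                contains_ruminant=bool(row.contains_ruminant),
            )
        )
    return out


def references_from_frame(df: pd.DataFrame) -> list[ReferenceRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ReferenceRecord(
                article_id=row.article_id, food_id=row.food_id,
                n_samples=None if pd.isna(row.n_samples) else int(row.n_samples),
                mean_value=float(row.mean_value),
                min_value=None if pd.isna(row.min_value) else float(row.min_value),
                max_value=None if pd.isna(row.max_value) else float(row.max_value),
                basis=Basis(row.basis),
                ref_fat_g_100g=None if pd.isna(row.ref_fat_g_100g) else float(row.ref_fat_g_100g),
            )
        )
    return out


def foreign_from_frame(df: pd.DataFrame) -> list[ForeignFoodRecord]:
    return [
        ForeignFoodRecord(
            food_id=r.food_id, foreign_tfa_g_100g=float(r.foreign_tfa_g_100g),
            energy_kcal_100g=float(r.energy_kcal_100g),
            fat_g_100g=float(r.fat_g_100g), protein_g_100g=float(r.protein_g_100g),
            carb_g_100g=float(r.carb_g_100g),
            same_manufacturer=bool(r.same_manufacturer),
        )
        for r in df.itertuples(index=False)
    ]


def recipes_from_frame(df: pd.DataFrame) -> list[Recipe]:
    return [
        Recipe(
            food_id=fid,
            ingredients=tuple(zip(grp["ingredient_id"], grp["grams_per_100g"].astype(float))),
        )
        for fid, grp in df.groupby("food_id", sort=True)
    ]


def references_to_frame(refs) -> pd.DataFrame:
    rows = [
        {
            "article_id": r.article_id, "food_id": r.food_id,
            "n_samples": r.n_samples if r.n_samples is not None else pd.NA,
            "mean_value": r.mean_value, "min_value": r.min_value,
            "max_value": r.max_value, "basis": r.basis.value,
            "ref_fat_g_100g": r.ref_fat_g_100g,
        }
        for r in refs
    ]
    df = pd.DataFrame(rows, columns=REFERENCES_COLUMNS)
    df["n_samples"] = df["n_samples"].astype("Int64")
    return df


def foreign_to_frame(foreign) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "food_id": r.food_id, "foreign_tfa_g_100g": r.foreign_tfa_g_100g,
                "energy_kcal_100g": r.energy_kcal_100g, "fat_g_100g": r.fat_g_100g,
                "protein_g_100g": r.protein_g_100g, "carb_g_100g": r.carb_g_100g,
                "same_manufacturer": r.same_manufacturer,
            }
            for r in foreign
        ],
        columns=FOREIGN_COLUMNS,
    )


def recipes_to_frame(recipes) -> pd.DataFrame:
    rows = [
        {"food_id": r.food_id, "ingredient_id": ing, "grams_per_100g": g}
        for r in recipes
        for ing, g in r.ingredients
    ]
    return pd.DataFrame(rows, columns=RECIPES_COLUMNS)


# ------------------------------------------------------------- validation


@dataclass
class ValidationReport:
    violations: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, table: str, row: int, message: str) -> None:
        self.violations.append((table, row, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        lines = [f"{t} row {r}: {m}" for t, r, m in self.violations]
        return f"{len(self.violations)} violations:\n" + "\n".join(lines)


def validate_inputs(tables: Mapping[str, pd.DataFrame]) -> ValidationReport:
    """Schema and foreign-key validation; every violation carries its row.

    *tables* maps any of foods / references / foreign / recipes / records /
    subjects to its frame. Row numbers are 0-based frame positions.
    """
    report = ValidationReport()
    foods = tables.get("foods")
    food_ids = set(foods["food_id"]) if foods is not None else None

    if foods is not None:
        for i, row in enumerate(foods.itertuples(index=False)):
            if not row.group or not row.origin:
                report.add("foods", i, f"{row.food_id}: empty group or origin")
            elif row.origin not in ("industrial", "natural"):
                report.add("foods", i, f"{row.food_id}: unknown origin {row.origin!r}")
            for col in ("energy_kcal_100g", "fat_g_100g", "protein_g_100g", "carb_g_100g"):
                v = getattr(row, col)
                if pd.isna(v) or v < 0:
                    report.add("foods", i, f"{row.food_id}: invalid {col} {v!r}")
        dup = foods["food_id"].duplicated()
        for i in foods.index[dup]:
            report.add("foods", int(i), f"duplicate food_id {foods.at[i, 'food_id']}")

    def check_fk(name, df, col):
        if df is None or food_ids is None:
            return
        for i, v in enumerate(df[col]):
            if v not in food_ids:
                report.add(name, i, f"{col} {v!r} not in food table")

    refs = tables.get("references")
    if refs is not None:
        check_fk("references", refs, "food_id")
        for i, row in enumerate(refs.itertuples(index=False)):
            if row.basis not in (b.value for b in Basis):
                report.add("references", i, f"unknown basis {row.basis!r}")
            if pd.isna(row.mean_value):
                report.add("references", i, f"{row.article_id}: missing mean_value")
            if not pd.isna(row.n_samples) and row.n_samples < 1:
                report.add("references", i, f"{row.article_id}: n_samples < 1")

    recipes = tables.get("recipes")
    if recipes is not None:
        check_fk("recipes", recipes, "food_id")
        check_fk("recipes", recipes, "ingredient_id")
        for i, g in enumerate(recipes["grams_per_100g"]):
            if pd.isna(g) or g <= 0:
                report.add("recipes", i, f"grams_per_100g {g!r} must be > 0")

    foreign = tables.get("foreign")
    if foreign is not None:
        check_fk("foreign", foreign, "food_id")

    records = tables.get("records")
    subjects = tables.get("subjects")
    subject_ids = set(subjects["subject_id"]) if subjects is not None else None
    if records is not None:
        check_fk("records", records, "food_id")
        for i, row in enumerate(records.itertuples(index=False)):
            if row.season not in SEASONS:
                report.add("records", i, f"unknown season {row.season!r}")
            if row.venue not in VENUES:
                report.add("records", i, f"unknown venue {row.venue!r}")
            if pd.isna(row.grams) or row.grams <= 0:
                report.add("records", i, f"grams {row.grams!r} must be > 0")
            if subject_ids is not None and row.subject_id not in subject_ids:
                report.add("records", i, f"subject {row.subject_id!r} not in subject table")
    if subjects is not None:
        for i, row in enumerate(subjects.itertuples(index=False)):
            if row.sex not in ("female", "male"):
                report.add("subjects", i, f"unknown sex {row.sex!r}")
            if row.height_cm <= 0 or row.weight_kg <= 0:
                report.add("subjects", i, f"{row.subject_id}: nonpositive height/weight")

    if not report.ok:
        log.warning("input validation failed: %d violations", len(report.violations))
    return report


# ------------------------------------------------------------------ config


def load_config(path=None) -> PipelineConfig:
    """Pipeline configuration from YAML (missing sections use defaults)."""
    if path is None:
        return PipelineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
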