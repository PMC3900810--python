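"""Domain records shared across the pipeline.

Values are carried at full float precision everywhere; rounding to the
0.1 g resolution of printed food-composition tables happens only when a
report table is rendered.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Step(str, enum.Enum):
    """Provenance label: which rule of the assignment hierarchy produced a value.

    ``ZERO``
        the zero rule — no/trace fat and no hydrogenated oil or ruminant source.
    ``S1_SINGLE`` / ``S1_MEAN`` / ``S1_WEIGHTED``
        analytic literature values: a single analysed sample, a single article's
        mean over several samples, or a sample-size-weighted mean over articles.
    ``S2_1A`` / ``S2_1B``
        similarity transfer from an analytically resolved food in the same
        category / same group (non-meat path).
    ``S2_2A`` … ``S2_2E``
        the meat-cut cascade: same part, similar part, similar animal of the
        same species, different species, same meat group.
    ``S3``
        matched foreign-database product of the same manufacturer.
    ``S4``
        recipe / nutrient-composition imputation.
    """

    ZERO = "ZERO"
    S1_SINGLE = "S1_SINGLE"
    S1_MEAN = "S1_MEAN"
    S1_WEIGHTED = "S1_WEIGHTED"
    S2_1A = "S2_1A"
    S2_1B = "S2_1B"
    S2_2A = "S2_2A"
    S2_2B = "S2_2B"
    S2_2C = "S2_2C"
    S2_2D = "S2_2D"
    S2_2E = "S2_2E"
    S3 = "S3"
    S4 = "S4"


STEP1_STEPS = frozenset({Step.S1_SINGLE, Step.S1_MEAN, Step.S1_WEIGHTED})
STEP2_STEPS = frozenset(
    {Step.S2_1A, Step.S2_1B, Step.S2_2A, Step.S2_2B, Step.S2_2C, Step.S2_2D, Step.S2_2E}
)

#: canonical column order of the provenance table (Step 1 sub-steps merged)
PROVENANCE_COLUMNS = (
    "ZERO", "1", "1A", "1B", "2A", "2B", "2C", "2D", "2E", "3", "4",
)

#: maps each provenance step to its printed table column
STEP_TO_COLUMN = {
    Step.ZERO: "ZERO",
    Step.S1_SINGLE: "1",
    Step.S1_MEAN: "1",
    Step.S1_WEIGHTED: "1",
    Step.S2_1A: "1A",
    Step.S2_1B: "1B",
    Step.S2_2A: "2A",
    Step.S2_2B: "2B",
    Step.S2_2C: "2C",
    Step.S2_2D: "2D",
    Step.S2_2E: "2E",
    Step.S3: "3",
    Step.S4: "4",
}


class ValidationError(ValueError):
    """Raised when an input record violates its documented contract."""


@dataclass(frozen=True)
class FoodItem:
    """One composition-table row: identity, classification, macronutrients.

    ``group`` is a base food-group label (e.g. ``"Confectionaries"`` or the
    catch-all ``"no-TFA"``); ``origin`` is ``"industrial"`` or ``"natural"``
    and together with the group forms the printed "(I)"/"(N)" row label.
    ``species``/``part`` are set only for meat cuts and drive the meat cascade.
    """

    food_id: str
    name: str
    group: str
    origin: str
    category: str
    energy_kcal_100g: float
    fat_g_100g: float
    protein_g_100g: float
    carb_g_100g: float
    contains_hydrogenated_oil: bool = False
    contains_ruminant: bool = False
    species: str | None = None
    part: str | None = None

    def __post_init__(self) -> None:
        if not self.group or not self.origin:
            raise ValidationError(f"food {self.food_id!r}: group and origin must be non-empty")
        if self.origin not in ("industrial", "natural"):
            raise ValidationError(f"food {self.food_id!r}: unknown origin {self.origin!r}")
        for label, v in (
            ("energy_kcal_100g", self.energy_kcal_100g),
            ("fat_g_100g", self.fat_g_100g),
            ("protein_g_100g", self.protein_g_100g),
            ("carb_g_100g", self.carb_g_100g),
        ):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValidationError(f"food {self.food_id!r}: missing {label}")
            if v < 0:
                raise ValidationError(f"food {self.food_id!r}: {label} = {v} < 0")
        for label in ("fat_g_100g", "protein_g_100g", "carb_g_100g"):
            if getattr(self, label) > 100:
                raise ValidationError(f"food {self.food_id!r}: {label} > 100 g/100 g")

    @property
    def group_label(self) -> str:
        """Printed row label, e.g. ``"Confectionaries (I)"``."""
        if self.group == "no-TFA":
            return "no-TFA"
        return f"{self.group} ({'I' if self.origin == 'industrial' else 'N'})"


class Basis(str, enum.Enum):
    PERCENT_OF_FAT = "percent_of_fat"
    G_PER_100G_FOOD = "g_per_100g_food"


@dataclass(frozen=True)
class ReferenceRecord:
    """One article's analytic TFA result for one food.

    ``n_samples`` is ``None`` when the article did not state how many samples
    were analysed; such an article is usable as a sole source but is dropped
    from sample-weighted pooling.
    """

    article_id: str
    food_id: str
    mean_value: float
    basis: Basis
    n_samples: int | None = None
    min_value: float | None = None
    max_value: float | None = None
    ref_fat_g_100g: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples is not None and self.n_samples < 1:
            raise ValidationError(
                f"reference {self.article_id!r}/{self.food_id!r}: n_samples must be >= 1"
            )
        lo = self.min_value if self.min_value is not None else self.mean_value
        hi = self.max_value if self.max_value is not None else self.mean_value
        if not (lo <= self.mean_value <= hi):
            raise ValidationError(
                f"reference {self.article_id!r}/{self.food_id!r}: "
                f"min <= mean <= max violated ({lo}, {self.mean_value}, {hi})"
            )


@dataclass(frozen=True)
class TfaAssignment:
    """A food's final TFA value together with the rule that produced it."""

    food_id: str
    tfa_g_100g: float
    tfa_pct_fat: float
    step: Step
    donor_food_id: str | None = None

    def __post_init__(self) -> None:
        if self.tfa_g_100g < 0:
            raise ValidationError(f"assignment {self.food_id!r}: tfa_g_100g < 0")


@dataclass(frozen=True)
class Recipe:
    """Ingredient decomposition of a composed food, grams per 100 g of dish."""

    food_id: str
    ingredients: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for ing, grams in self.ingredients:
            if grams <= 0:
                raise ValidationError(
                    f"recipe {self.food_id!r}: ingredient {ing!r} grams must be > 0"
                )


@dataclass(frozen=True)
class ForeignFoodRecord:
    """A foreign-market product matched to a domestic food by manufacturer."""

    food_id: str
    foreign_tfa_g_100g: float
    energy_kcal_100g: float
    fat_g_100g: float
    protein_g_100g: float
    carb_g_100g: float
    same_manufacturer: bool

    def __post_init__(self) -> None:
        for label in ("foreign_tfa_g_100g", "energy_kcal_100g", "fat_g_100g",
                      "protein_g_100g", "carb_g_100g"):
            if getattr(self, label) < 0:
                raise ValidationError(f"foreign record {self.food_id!r}: {label} < 0")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    sex: str
    age_years: int
    area: str
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"subject {self.subject_id!r}: unknown sex {self.sex!r}")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValidationError(f"subject {self.subject_id!r}: nonpositive height/weight")


SEASONS = ("autumn", "winter", "spring", "summer")
VENUES = ("home", "commercial", "restaurant")


@dataclass(frozen=True)
class DietRecordEntry:
    """One weighed consumption event on one recording day."""

    subject_id: str
    day_index: int
    season: str
    food_id: str
    grams: float
    venue: str

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise ValidationError(
                f"entry {self.subject_id!r} day {self.day_index}: grams must be > 0"
            )
        if self.season not in SEASONS:
            raise ValidationError(f"unknown season {self.season!r}")
        if self.venue not in VENUES:
            raise ValidationError(f"unknown venue {self.venue!r}")


@dataclass(frozen=True)
class SubjectIntake:
    """A subject's mean daily intake over their recorded days.

    TFA is expressed three ways: grams/day, % of total energy (using the
    configured energy conversion factor per gram of fat), and % of total fat.
    """

    subject_id: str
    n_days: int
    energy_kcal_day: float
    fat_g_day: float
    tfa_g_day: float
    tfa_pct_energy: float
    tfa_pct_fat: float
    fat_pct_energy: float
    bmi_kg_m2: float | None = None
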