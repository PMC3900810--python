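"""Synthetic study generator with known ground truth.

Emulates every input the pipeline consumes: a ~2000-food composition
table, an analytic literature corpus, a foreign-database product match
table, recipes, and a stratified 16-day semi-weighed diet-record cohort.
Nothing here reproduces a real food table's contents — foods, nutrient
profiles and consumption are invented — but the *structure* mirrors a
national composition table study: 11 TFA-bearing food groups labelled by
industrial/natural origin, a zero-TFA remainder, per-group step routing
counts, and a cohort design stratified by sex, residential area and
10-year age group.

Routing is exact by construction: each TFA-bearing food is designated a
resolution step and the table is laid out so that the assignment
hierarchy resolves it at exactly that step. Donors sit on a multiplicative
macronutrient grid (adjacent levels differ by a factor 1.7, i.e. a
relative gap of ~0.41, well above the 0.25 similarity threshold), their
designated recipients are jittered within a few percent of them, and
foods destined for Steps 3/4 are placed far from every donor. Each
similarity recipient's true %-of-fat equals its donor's — the transfer
rule's own modelling assumption — so the pipeline recovers the truth
exactly when measurement noise is switched off.

The consumption model is a per-stratum budget model: each subject draws a
daily energy target and a daily TFA target (log-normal around the
configured stratum means, with urban/age multipliers normalised to a
design-weighted mean of one), TFA-bearing foods are scaled to meet the
TFA target, and zero-TFA staples fill the remaining energy budget, so
realized cohort means are unbiased for the targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._types import SEASONS, Basis, FoodItem, ForeignFoodRecord, Recipe, ReferenceRecord
from .config import CompositionConfig

log = logging.getLogger(__name__)

__all__ = [
    "StepCounts",
    "GroupSpec",
    "CohortConfig",
    "GeneratorConfig",
    "FoodUniverse",
    "SyntheticStudy",
    "generate_food_table",
    "generate_literature",
    "generate_cohort",
    "generate_study",
    "default_design",
    "composition_config_for",
]

#: grid ratio between adjacent donor macronutrient levels
_GRID = 1.7


class StepCounts(BaseModel):
    """How many of a group's foods resolve at each step."""

    s1: int = 0
    s1a: int = 0
    s1b: int = 0
    s2a: int = 0
    s2b: int = 0
    s2c: int = 0
    s2d: int = 0
    s2e: int = 0
    s3: int = 0
    s4: int = 0

    @property
    def total(self) -> int:
        return sum(self.model_dump().values())


class GroupSpec(BaseModel):
    group: str
    origin: str
    counts: StepCounts
    #: median true TFA as % of total fat (log-normal across the group's foods)
    tfa_pct_fat_median: float = 4.0
    tfa_pct_fat_sigma: float = 0.35
    #: base (fat, protein, carb) g/100 g of the donor grid
    base_macros: tuple[float, float, float] = (5.0, 4.0, 15.0)


def _default_groups() -> list[GroupSpec]:
    """Study-scale defaults: 526 TFA-bearing foods routed per the published
    database-development summary (11 group rows; column totals
    143/103/78/22/17/38/7/88/14/16)."""
    c = StepCounts
    return [
        GroupSpec(group="Confectionaries", origin="industrial",
                  counts=c(s1=25, s1a=49, s1b=34, s3=2, s4=12),
                  tfa_pct_fat_median=6.0, base_macros=(4.0, 3.0, 12.0)),
        GroupSpec(group="Bakery", origin="industrial",
                  counts=c(s1=6, s1a=12, s1b=9, s3=1),
                  tfa_pct_fat_median=6.0, base_macros=(3.5, 4.0, 18.0)),
        GroupSpec(group="Fats and oils", origin="natural",
                  counts=c(s1=11, s1a=2, s1b=6),
                  tfa_pct_fat_median=4.0, base_macros=(15.0, 2.0, 2.0)),
        GroupSpec(group="Fats and oils", origin="industrial",
                  counts=c(s1=5),
                  tfa_pct_fat_median=10.0, base_macros=(20.0, 2.0, 2.0)),
        GroupSpec(group="Instant and retort foods", origin="industrial",
                  counts=c(s1=17, s1a=26),
                  tfa_pct_fat_median=4.0, base_macros=(5.0, 3.0, 15.0)),
        GroupSpec(group="Milk and dairy products", origin="natural",
                  counts=c(s1=23, s1a=13, s1b=8),
                  tfa_pct_fat_median=4.0, base_macros=(3.0, 3.0, 4.0)),
        GroupSpec(group="Milk and dairy products", origin="industrial",
                  counts=c(s1=7),
                  tfa_pct_fat_median=6.0, base_macros=(4.0, 3.0, 6.0)),
        GroupSpec(group="Meat and meat products", origin="natural",
                  counts=c(s1=41, s1b=21, s2a=22, s2b=17, s2c=38, s2d=7, s2e=88, s4=2),
                  tfa_pct_fat_median=3.5, base_macros=(4.0, 12.0, 2.0)),
        GroupSpec(group="Margarine", origin="industrial",
                  counts=c(s1=3),
                  tfa_pct_fat_median=14.0, base_macros=(25.0, 2.0, 2.0)),
        GroupSpec(group="Fast foods", origin="industrial",
                  counts=c(s1=1, s3=10),
                  tfa_pct_fat_median=6.0, base_macros=(10.0, 6.0, 25.0)),
        GroupSpec(group="Miscellaneous", origin="industrial",
                  counts=c(s1=4, s1a=1, s3=1, s4=2),
                  tfa_pct_fat_median=4.0, base_macros=(8.0, 5.0, 20.0)),
    ]


def default_design() -> pd.DataFrame:
    """Cohort design cells (sex x area x age decade -> n).

    Marginals match the emulated study population: 119 women (urban 57 /
    rural 62; decades 27/29/32/31) and 106 men (urban 51 / rural 55;
    decades 20/29/28/29).
    """
    women = {
        "urban-a": (7, 7, 8, 7),
        "urban-b": (7, 7, 7, 7),
        "rural-a": (7, 8, 8, 8),
        "rural-b": (6, 7, 9, 9),
    }
    men = {
        "urban-a": (5, 7, 7, 7),
        "urban-b": (5, 7, 6, 7),
        "rural-a": (5, 8, 8, 7),
        "rural-b": (5, 7, 7, 8),
    }
    rows = []
    for sex, table in (("female", women), ("male", men)):
        for area, ns in table.items():
            for decade, n in zip((30, 40, 50, 60), ns):
                rows.append({"sex": sex, "area": area, "decade": decade, "n": n})
    return pd.DataFrame(rows)


class CohortConfig(BaseModel):
    """Design and consumption-model parameters of the diet-record cohort."""

    #: list of {sex, area, decade, n} cells; None -> the study-scale design
    design: list[dict] | None = None
    energy_mean: dict[str, float] = Field(
        default_factory=lambda: {"female": 1847.0, "male": 2372.0}
    )
    energy_sd: dict[str, float] = Field(
        default_factory=lambda: {"female": 289.0, "male": 389.0}
    )
    tfa_mean_g: dict[str, float] = Field(
        default_factory=lambda: {"female": 1.7, "male": 1.7}
    )
    tfa_sd_g: dict[str, float] = Field(
        default_factory=lambda: {"female": 0.7, "male": 0.6}
    )
    #: urban/rural and age multipliers on the TFA target (normalised so the
    #: design-weighted mean is 1; ratios mirror the emulated study's gradients)
    urban_factor: float = 1.15
    age_factors: dict[int, float] = Field(
        default_factory=lambda: {30: 1.24, 40: 1.12, 50: 1.0, 60: 0.71}
    )
    urban_areas: tuple[str, ...] = ("urban-a", "urban-b")
    #: within-subject day-to-day variability (log-normal sigma, mean 1)
    day_energy_sigma: float = 0.12
    day_tfa_sigma: float = 0.25
    tfa_foods_per_day: float = 4.0
    staple_foods_per_day: float = 10.0
    amount_median_g: float = 45.0
    amount_sigma: float = 0.6
    #: staples always keep at least this energy share of a day
    min_staple_energy_frac: float = 0.1
    #: Dirichlet concentration of per-subject food-group preference weights
    dirichlet_concentration: float = 12.0
    group_share_base: dict[str, float] = Field(
        default_factory=lambda: {
            "Confectionaries (I)": 0.20,
            "Bakery (I)": 0.18,
            "Fats and oils (I)": 0.16,
            "Meat and meat products (N)": 0.13,
            "Milk and dairy products (N)": 0.11,
            "Instant and retort foods (I)": 0.09,
            "Margarine (I)": 0.05,
            "Fast foods (I)": 0.035,
            "Milk and dairy products (I)": 0.032,
            "Fats and oils (N)": 0.02,
            "Miscellaneous (I)": 0.013,
        }
    )
    restaurant_prob: float = 0.5  # for recipe-bearing foods
    commercial_prob: float = 0.3  # for other TFA foods
    height_weight: dict[str, tuple[float, float, float, float]] = Field(
        default_factory=lambda: {
            "female": (154.6, 6.2, 53.4, 7.1),
            "male": (168.0, 6.4, 67.1, 10.2),
        }
    )


class GeneratorConfig(BaseModel):
    seed: int = 0
    groups: list[GroupSpec] = Field(default_factory=_default_groups)
    n_zero_foods: int = 1469
    #: Step-1 sub-mode allocation (single value / single-article mean /
    #: weighted pooling); rescaled proportionally if the S1 total differs
    s1_single_n: int = 13
    s1_mean_n: int = 71
    s1_weighted_n: int = 59
    #: multiplicative SD of article means around the truth
    noise_sd: float = 0.08
    unknown_n_fraction: float = 0.15
    minmax_spread: float = 0.3
    macro_jitter: float = 0.03
    energy_jitter: float = 0.02
    cohort: CohortConfig = Field(default_factory=CohortConfig)


# ---------------------------------------------------------------- food table


@dataclass
class FoodUniverse:
    """The generated food world and its ground truth."""

    foods: list[FoodItem]
    #: per food: true TFA, designated step, designated donor, added flag
    truth: pd.DataFrame
    recipes: list[Recipe]
    foreign: list[ForeignFoodRecord]
    added_food_ids: list[str]
    composition_cfg: CompositionConfig

    @property
    def foods_frame(self) -> pd.DataFrame:
        rows = [
            {
                "food_id": f.food_id, "name": f.name, "group": f.group,
                "origin": f.origin, "category": f.category,
                "species": f.species or "", "part": f.part or "",
                "energy_kcal_100g": f.energy_kcal_100g,
                "fat_g_100g": f.fat_g_100g,
                "protein_g_100g": f.protein_g_100g,
                "carb_g_100g": f.carb_g_100g,
                "contains_hydrogenated_oil": f.contains_hydrogenated_oil,
                "contains_ruminant": f.contains_ruminant,
            }
            for f in self.foods
        ]
        return pd.DataFrame(rows)


_STAPLE_PROFILES = [
    # (name, fat, protein, carb) g/100 g — zero-TFA staples
    ("rice", 0.3, 2.5, 37.0),
    ("vegetables", 0.1, 1.2, 4.0),
    ("fruit", 0.1, 0.7, 15.0),
    ("white fish", 4.5, 20.0, 0.1),
    ("tofu", 4.2, 6.6, 1.6),
    ("noodles", 0.9, 5.0, 26.0),
    ("egg", 10.0, 12.0, 0.3),
    ("potato", 0.1, 1.8, 17.0),
    ("legumes", 2.0, 9.0, 20.0),
    ("beverage", 0.0, 0.1, 5.0),
]

_MEAT_SPECIES = ("cattle", "pig", "chicken", "sheep")
_MEAT_PARTS = (
    "loin", "shoulder", "thigh", "breast", "rib", "belly",
    "round", "chuck", "shank", "neck", "tenderloin",
)


def _energy(fat: float, protein: float, carb: float, rng, jitter: float) -> float:
    e = 9.0 * fat + 4.0 * protein + 4.0 * carb
    return e * (1.0 + rng.uniform(-jitter, jitter))


def _grid_macros(base: tuple[float, float, float], i: int) -> tuple[float, float, float]:
    """Donor i's macros: a mixed-radix point on the multiplicative grid."""
    f, p, c = base
    return (
        f * _GRID ** (i % 4),
        p * _GRID ** ((i // 4) % 4),
        c * _GRID ** ((i // 16) % 3),
    )


def _far_macros(base: tuple[float, float, float], rng) -> tuple[float, float, float]:
    """Macros guaranteed > grid-gap away from every donor of the group."""
    f, p, c = base
    far_c = c * _GRID ** 4
    if far_c <= 90.0:
        return (f * (1 + rng.uniform(-0.1, 0.1)), p * (1 + rng.uniform(-0.1, 0.1)), far_c)
    far_p = p * _GRID ** 5
    if far_p <= 90.0:
        return (f * (1 + rng.uniform(-0.1, 0.1)), far_p, c * (1 + rng.uniform(-0.1, 0.1)))
    return (min(f * _GRID ** 5, 90.0), p * (1 + rng.uniform(-0.1, 0.1)), c * (1 + rng.uniform(-0.1, 0.1)))


def _near_macros(donor: FoodItem, rng, jitter: float) -> tuple[float, float, float]:
    j = lambda v: v * (1.0 + rng.uniform(-jitter, jitter))
    return (j(donor.fat_g_100g), j(donor.protein_g_100g), j(donor.carb_g_100g))


def generate_food_table(cfg: GeneratorConfig, rng: np.random.Generator) -> FoodUniverse:
    """Generate foods, per-food ground truth, recipes and foreign matches.

    Returns a :class:`FoodUniverse`; its ``composition_cfg`` carries the
    meat part/species adjacency data the cascade needs.
    """
    foods: list[FoodItem] = []
    truth_rows: list[dict] = []
    recipes: list[Recipe] = []
    foreign: list[ForeignFoodRecord] = []
    parts_adj: dict[str, list[str]] = {}
    species_adj: dict[str, list[str]] = {}
    species_fb: dict[str, list[str]] = {}

    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"F{counter[0]:04d}"

    def add_food(food: FoodItem, true_g: float, step: str, donor: str | None) -> None:
        foods.append(food)
        pct = 100.0 * true_g / food.fat_g_100g if food.fat_g_100g > 0 else 0.0
        truth_rows.append(
            {"food_id": food.food_id, "true_tfa_g_100g": true_g,
             "true_tfa_pct_fat": pct, "designated_step": step,
             "designated_donor": donor or ""}
        )

    s4_pool: dict[str, list[str]] = {}  # group label -> S4 food ids (for nesting)
    zero_ids: list[str] = []

    # zero-TFA staples first: they are also the cohort's energy bulk
    for i in range(cfg.n_zero_foods):
        name, f, p, c = _STAPLE_PROFILES[i % len(_STAPLE_PROFILES)]
        jf = lambda v: v * (1.0 + rng.uniform(-0.2, 0.2)) if v > 0 else 0.0
        fat, protein, carb = jf(f), jf(p), jf(c)
        fid = new_id()
        food = FoodItem(
            food_id=fid, name=f"{name} {i}", group="no-TFA", origin="natural",
            category=f"staple-{name}",
            energy_kcal_100g=_energy(fat, protein, carb, rng, cfg.energy_jitter),
            fat_g_100g=fat, protein_g_100g=protein, carb_g_100g=carb,
        )
        add_food(food, 0.0, "ZERO", None)
        zero_ids.append(fid)

    added_ids: list[str] = []

    for spec in cfg.groups:
        slug = f"{spec.group[:4]}{'I' if spec.origin == 'industrial' else 'N'}".replace(" ", "")
        hydro = spec.origin == "industrial"
        rumin = not hydro
        is_meat = spec.group == "Meat and meat products"
        ln_mu = np.log(spec.tfa_pct_fat_median)

        def draw_pct() -> float:
            return float(np.exp(rng.normal(ln_mu, spec.tfa_pct_fat_sigma)))

        def make(fid, name, cat, macros, pct, step, donor=None, species=None, part=None):
            fat, protein, carb = macros
            food = FoodItem(
                food_id=fid, name=name, group=spec.group, origin=spec.origin,
                category=cat, species=species, part=part,
                energy_kcal_100g=_energy(fat, protein, carb, rng, cfg.energy_jitter),
                fat_g_100g=fat, protein_g_100g=protein, carb_g_100g=carb,
                contains_hydrogenated_oil=hydro, contains_ruminant=rumin,
            )
            add_food(food, pct / 100.0 * fat, step, donor)
            return food

        # Step-1 donors on the separated grid
        donors: list[FoodItem] = []
        for i in range(spec.counts.s1):
            fid = new_id()
            sp = pt = None
            if is_meat:
                sp = _MEAT_SPECIES[i % len(_MEAT_SPECIES)]
                pt = _MEAT_PARTS[i // len(_MEAT_SPECIES)]
            donors.append(
                make(fid, f"{slug} donor {i}", f"{slug}-cat{i}",
                     _grid_macros(spec.base_macros, i), draw_pct(), "S1",
                     species=sp, part=pt)
            )

        def donor_for(j: int) -> FoodItem:
            return donors[j % len(donors)]

        truth_pct = {t["food_id"]: t["true_tfa_pct_fat"] for t in truth_rows}

        for j in range(spec.counts.s1a):
            d = donor_for(j)
            make(new_id(), f"{slug} variant {j}", d.category,
                 _near_macros(d, rng, cfg.macro_jitter), truth_pct[d.food_id],
                 "S2_1A", d.food_id)
        for j in range(spec.counts.s1b):
            d = donor_for(j)
            sp = pt = None  # meat-group processed products carry no cut labels
            make(new_id(), f"{slug} related {j}", f"{slug}-cat1b-{j}",
                 _near_macros(d, rng, cfg.macro_jitter), truth_pct[d.food_id],
                 "S2_1B", d.food_id, species=sp, part=pt)

        if is_meat:
            for j in range(spec.counts.s2a):
                d = donor_for(j)
                fat, protein, carb = d.fat_g_100g * 1.4, d.protein_g_100g, d.carb_g_100g
                make(new_id(), f"{slug} cut {j}", f"{slug}-cut2a-{j}",
                     (fat, protein, carb), truth_pct[d.food_id], "S2_2A",
                     d.food_id, species=d.species, part=d.part)
            for j in range(spec.counts.s2b):
                d = donor_for(j)
                adj_part = f"{d.part}-adj{j}"
                parts_adj[adj_part] = [d.part]
                make(new_id(), f"{slug} near cut {j}", f"{slug}-cut2b-{j}",
                     _near_macros(d, rng, cfg.macro_jitter), truth_pct[d.food_id],
                     "S2_2B", d.food_id, species=d.species, part=adj_part)
            for j in range(spec.counts.s2c):
                d = donor_for(j)
                sim_sp = f"{d.species}-sim{j}"
                species_adj[sim_sp] = [d.species]
                make(new_id(), f"{slug} similar animal {j}", f"{slug}-cut2c-{j}",
                     _near_macros(d, rng, cfg.macro_jitter), truth_pct[d.food_id],
                     "S2_2C", d.food_id, species=sim_sp, part="misc")
            for j in range(spec.counts.s2d):
                d = donor_for(j)
                fb_sp = f"exotic{j}"
                species_fb[fb_sp] = [d.species]
                make(new_id(), f"{slug} other animal {j}", f"{slug}-cut2d-{j}",
                     _near_macros(d, rng, cfg.macro_jitter), truth_pct[d.food_id],
                     "S2_2D", d.food_id, species=fb_sp, part="misc")
            for j in range(spec.counts.s2e):
                d = donor_for(j)
                make(new_id(), f"{slug} group mate {j}", d.category,
                     _near_macros(d, rng, 0.1), truth_pct[d.food_id],
                     "S2_2E", d.food_id, species=f"generic{j}", part="misc")

        for j in range(spec.counts.s3):
            fid = new_id()
            pct = draw_pct()
            food = make(fid, f"{slug} import {j}", f"{slug}-cat3-{j}",
                        _far_macros(spec.base_macros, rng), pct, "S3")
            g = pct / 100.0 * food.fat_g_100g
            m = lambda v: v * (1.0 + rng.uniform(-0.02, 0.02))
            foreign.append(
                ForeignFoodRecord(
                    food_id=fid, foreign_tfa_g_100g=g,
                    energy_kcal_100g=m(food.energy_kcal_100g),
                    fat_g_100g=m(food.fat_g_100g),
                    protein_g_100g=m(food.protein_g_100g),
                    carb_g_100g=m(food.carb_g_100g),
                    same_manufacturer=True,
                )
            )

        group_s4: list[str] = []
        for j in range(spec.counts.s4):
            fid = new_id()
            # composed dish: ingredients are staples plus one resolved donor
            staples = [zero_ids[int(rng.integers(len(zero_ids)))] for _ in range(2)]
            d = donor_for(j)
            ing: list[tuple[str, float]] = [(d.food_id, 30.0), (staples[0], 40.0), (staples[1], 30.0)]
            if j == 1 and group_s4:  # one nested recipe per group exercises topo order
                ing[1] = (group_s4[0], 40.0)
            truth_map = {t["food_id"]: t["true_tfa_g_100g"] for t in truth_rows}
            true_g = sum(g / 100.0 * truth_map.get(i, 0.0) for i, g in ing)
            food_macros = _far_macros(spec.base_macros, rng)
            make(fid, f"{slug} dish {j}", f"{slug}-cat4-{j}", food_macros, 0.0, "S4")
            # overwrite the %-derived truth with the recipe-linear truth
            truth_rows[-1]["true_tfa_g_100g"] = true_g
            truth_rows[-1]["true_tfa_pct_fat"] = (
                100.0 * true_g / food_macros[0] if food_macros[0] > 0 else 0.0
            )
            recipes.append(Recipe(food_id=fid, ingredients=tuple(ing)))
            group_s4.append(fid)
        s4_pool[f"{spec.group} ({'I' if hydro else 'N'})"] = group_s4

        # the emulated "added foods": all fast foods, 5 bakery, 3 confectionary
        group_ids = [t["food_id"] for t in truth_rows
                     if foods[int(t["food_id"][1:]) - 1].group == spec.group
                     and foods[int(t["food_id"][1:]) - 1].origin == spec.origin]
        if spec.group == "Fast foods":
            added_ids.extend(group_ids)
        elif spec.group == "Bakery":
            added_ids.extend(group_ids[-5:])
        elif spec.group == "Confectionaries" and spec.origin == "industrial":
            added_ids.extend(group_ids[-3:])

    # a couple of non-matching foreign decoys (never assignable)
    for fid in [r.food_id for r in recipes][:2]:
        foreign.append(
            ForeignFoodRecord(
                food_id=fid, foreign_tfa_g_100g=1.0, energy_kcal_100g=100.0,
                fat_g_100g=5.0, protein_g_100g=5.0, carb_g_100g=5.0,
                same_manufacturer=False,
            )
        )

    comp_cfg = CompositionConfig(
        parts_adjacency=parts_adj,
        species_adjacency=species_adj,
        species_fallback=species_fb,
    )
    truth = pd.DataFrame(truth_rows)
    truth["is_added"] = truth["food_id"].isin(added_ids)
    log.info("generated %d foods (%d TFA-bearing, %d added)",
             len(foods), int((truth["designated_step"] != "ZERO").sum()), len(added_ids))
    return FoodUniverse(foods, truth, recipes, foreign, added_ids, comp_cfg)


def composition_config_for(universe: FoodUniverse) -> CompositionConfig:
    return universe.composition_cfg


# ---------------------------------------------------------------- literature


def generate_literature(
    universe: FoodUniverse, cfg: GeneratorConfig, rng: np.random.Generator
) -> list[ReferenceRecord]:
    """Analytic articles for every Step-1-designated food.

    Sub-modes (single analysed sample / one article's mean over samples /
    several articles pooled by sample size) are allocated in the
    configured proportions; article means are the truth times a
    multiplicative noise term (mean 1, SD ``noise_sd``), so pooled values
    are unbiased for the truth and equal it exactly at zero noise.
    """
    s1_foods = universe.truth[universe.truth["designated_step"] == "S1"]
    n = len(s1_foods)
    alloc = np.array([cfg.s1_single_n, cfg.s1_mean_n, cfg.s1_weighted_n], dtype=float)
    if alloc.sum() != n:
        alloc = np.floor(alloc / alloc.sum() * n)
        alloc[2] = n - alloc[:2].sum()
    n_single, n_mean, _ = alloc.astype(int)
    foods_by_id = {f.food_id: f for f in universe.foods}

    records: list[ReferenceRecord] = []
    art = [0]

    def art_id() -> str:
        art[0] += 1
        return f"A{art[0]:04d}"

    def noisy(pct: float) -> float:
        return max(pct * (1.0 + rng.normal(0.0, cfg.noise_sd)), 0.0)

    def record(fid, pct, n_samples, with_range=True):
        food = foods_by_id[fid]
        if rng.random() < 0.5:
            basis, mean, ref_fat = Basis.PERCENT_OF_FAT, pct, None
        else:
            ref_fat = food.fat_g_100g * (1.0 + rng.uniform(-0.1, 0.1))
            basis, mean = Basis.G_PER_100G_FOOD, pct / 100.0 * ref_fat
        spread = cfg.minmax_spread * rng.random() if with_range else 0.0
        return ReferenceRecord(
            article_id=art_id(), food_id=fid, mean_value=mean, basis=basis,
            n_samples=n_samples,
            min_value=mean * (1 - spread), max_value=mean * (1 + spread),
            ref_fat_g_100g=ref_fat,
        )

    for i, row in enumerate(s1_foods.itertuples(index=False)):
        pct = row.true_tfa_pct_fat
        if i < n_single:
            records.append(record(row.food_id, noisy(pct), 1, with_range=False))
        elif i < n_single + n_mean:
            records.append(record(row.food_id, noisy(pct), 2 + int(rng.poisson(2.0))))
        else:
            for _ in range(int(rng.integers(2, 4))):
                records.append(record(row.food_id, noisy(pct), 1 + int(rng.poisson(2.0))))
            if rng.random() < cfg.unknown_n_fraction:
                records.append(record(row.food_id, noisy(pct), None))
    return records


# ------------------------------------------------------------------- cohort


@dataclass
class SyntheticStudy:
    universe: FoodUniverse
    references: list[ReferenceRecord]
    subjects: pd.DataFrame
    records: pd.DataFrame
    #: per-subject true mean daily intake implied by the generated records
    subject_truth: pd.DataFrame


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _unit_lognormal(rng, sigma: float, size=None):
    """Log-normal with mean exactly 1."""
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size)


def generate_cohort(
    universe: FoodUniverse, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Subjects, 16-day diet records, and per-subject ground-truth intakes.

    Each subject-day meets its energy target exactly (staples fill the
    budget) and its TFA target exactly unless the TFA foods would exceed
    the non-staple energy budget, in which case they are scaled back — a
    rare event under default parameters. Realized stratum means are
    therefore unbiased for the configured targets.
    """
    cc = cfg.cohort
    design = pd.DataFrame(cc.design) if cc.design is not None else default_design()

    # normalise urban/age factors to design-weighted mean 1 per sex
    def raw_factor(row) -> float:
        f = cc.urban_factor if row["area"] in cc.urban_areas else 1.0
        return f * cc.age_factors.get(int(row["decade"]), 1.0)

    design = design[design["n"] > 0].copy()
    design["raw_w"] = design.apply(raw_factor, axis=1)
    norm = design.groupby("sex").apply(
        lambda g: np.average(g["raw_w"], weights=g["n"]), include_groups=False
    )
    design["w"] = design["raw_w"] / design["sex"].map(norm).to_numpy()

    truth = universe.truth.set_index("food_id")
    foods_by_id = {f.food_id: f for f in universe.foods}
    labels = list(cc.group_share_base)
    base_shares = np.array([cc.group_share_base[g] for g in labels])
    base_shares = base_shares / base_shares.sum()
    by_label: dict[str, list[str]] = {lab: [] for lab in labels}
    zero_foods: list[str] = []
    for f in universe.foods:
        if truth.loc[f.food_id, "true_tfa_g_100g"] > 0 or f.group != "no-TFA":
            if f.group_label in by_label:
                by_label[f.group_label].append(f.food_id)
        else:
            zero_foods.append(f.food_id)
    recipe_ids = {r.food_id for r in universe.recipes}

    # per-food constants for speed
    e100 = {fid: foods_by_id[fid].energy_kcal_100g for fid in foods_by_id}
    f100 = {fid: foods_by_id[fid].fat_g_100g for fid in foods_by_id}
    t100 = truth["true_tfa_g_100g"].to_dict()

    subjects_rows, record_rows, truth_rows = [], [], []
    sidx = {"female": 0, "male": 0}
    amount_mu = np.log(cc.amount_median_g)

    for cell in design.itertuples(index=False):
        hmean, hsd, wmean, wsd = cc.height_weight[cell.sex]
        for _ in range(int(cell.n)):
            sidx[cell.sex] += 1
            sid = f"{'W' if cell.sex == 'female' else 'M'}{sidx[cell.sex]:03d}"
            age = int(rng.integers(cell.decade, cell.decade + 10))
            height = float(np.clip(rng.normal(hmean, hsd), hmean - 3 * hsd, hmean + 3 * hsd))
            weight = float(np.clip(rng.normal(wmean, wsd), wmean - 3 * wsd, wmean + 3 * wsd))
            subjects_rows.append(
                {"subject_id": sid, "sex": cell.sex, "age_years": age,
                 "area": cell.area, "height_cm": height, "weight_kg": weight}
            )

            energy_target = float(np.clip(
                rng.normal(cc.energy_mean[cell.sex], cc.energy_sd[cell.sex]), 1000.0, None
            ))
            mu, sig = _lognormal_params(cc.tfa_mean_g[cell.sex] * cell.w,
                                        cc.tfa_sd_g[cell.sex] * cell.w)
            tfa_target = float(rng.lognormal(mu, sig))
            shares = rng.dirichlet(cc.dirichlet_concentration * base_shares)

            tot_e = tot_f = tot_t = 0.0
            for day in range(1, 17):
                season = SEASONS[(day - 1) // 4]
                n_t = max(1, int(rng.poisson(cc.tfa_foods_per_day)))
                n_s = max(3, int(rng.poisson(cc.staple_foods_per_day)))
                gsel = rng.choice(len(labels), size=n_t, p=shares)
                tfa_sel = [
                    by_label[labels[g]][int(rng.integers(len(by_label[labels[g]])))]
                    for g in gsel
                ]
                amts = rng.lognormal(amount_mu, cc.amount_sigma, n_t)
                tpg = np.array([t100[fid] / 100.0 for fid in tfa_sel])
                epg = np.array([e100[fid] / 100.0 for fid in tfa_sel])
                raw_tfa = float(amts @ tpg)
                day_tfa = tfa_target * float(_unit_lognormal(rng, cc.day_tfa_sigma))
                if raw_tfa > 0:
                    amts = amts * (day_tfa / raw_tfa)
                day_energy = energy_target * float(_unit_lognormal(rng, cc.day_energy_sigma))
                e_t = float(amts @ epg)
                budget = (1.0 - cc.min_staple_energy_frac) * day_energy
                if e_t > budget:  # TFA foods scaled back into the energy budget
                    amts = amts * (budget / e_t)
                    e_t = budget
                remainder = day_energy - e_t

                s_sel = [zero_foods[int(rng.integers(len(zero_foods)))] for _ in range(n_s)]
                s_amts = rng.lognormal(amount_mu + 0.7, cc.amount_sigma, n_s)
                s_epg = np.array([e100[fid] / 100.0 for fid in s_sel])
                raw_e = float(s_amts @ s_epg)
                if raw_e > 0:
                    s_amts = s_amts * (remainder / raw_e)

                for fid, g in zip(tfa_sel, amts):
                    if fid in recipe_ids:
                        venue = "restaurant" if rng.random() < cc.restaurant_prob else "home"
                    else:
                        venue = "commercial" if rng.random() < cc.commercial_prob else "home"
                    record_rows.append((sid, day, season, fid, float(g), venue))
                    tot_e += g * e100[fid] / 100.0
                    tot_f += g * f100[fid] / 100.0
                    tot_t += g * t100[fid] / 100.0
                for fid, g in zip(s_sel, s_amts):
                    if g <= 0:
                        continue
                    record_rows.append((sid, day, season, fid, float(g), "home"))
                    tot_e += g * e100[fid] / 100.0
                    tot_f += g * f100[fid] / 100.0

            truth_rows.append(
                {"subject_id": sid, "true_energy_kcal_day": tot_e / 16.0,
                 "true_fat_g_day": tot_f / 16.0, "true_tfa_g_day": tot_t / 16.0}
            )

    subjects = pd.DataFrame(subjects_rows)
    records = pd.DataFrame(
        record_rows,
        columns=["subject_id", "day_index", "season", "food_id", "grams", "venue"],
    )
    log.info("generated cohort: %d subjects, %d record rows", len(subjects), len(records))
    return subjects, records, pd.DataFrame(truth_rows)


def generate_study(cfg: GeneratorConfig | None = None) -> SyntheticStudy:
    """Full synthetic study at ``cfg.seed``; deterministic given the config."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    universe = generate_food_table(cfg, rng)
    references = generate_literature(universe, cfg, rng)
    subjects, records, subject_truth = generate_cohort(universe, cfg, rng)
    return SyntheticStudy(universe, references, subjects, records, subject_truth)
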