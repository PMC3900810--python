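from __future__ import annotations

import numpy as np
import pytest

from tfadb import CompositionConfig, FoodItem
from tfadb.simulate import CohortConfig, GeneratorConfig, GroupSpec, StepCounts


def make_food(
    fid,
    group="Confectionaries",
    origin="industrial",
    category="c0",
    fat=10.0,
    protein=5.0,
    carb=20.0,
    energy=None,
    hydro=True,
    rumin=False,
    species=None,
    part=None,
    name=None,
):
    """Terse FoodItem factory with macro-consistent energy."""
    return FoodItem(
        food_id=fid,
        name=name or fid,
        group=group,
        origin=origin,
        category=category,
        energy_kcal_100g=energy if energy is not None else 9 * fat + 4 * protein + 4 * carb,
        fat_g_100g=fat,
        protein_g_100g=protein,
        carb_g_100g=carb,
        contains_hydrogenated_oil=hydro,
        contains_ruminant=rumin,
        species=species,
        part=part,
    )


@pytest.fixture
def meat_cascade():
    """One Step-1 donor plus one recipient per cascade level.

    The donor is a cattle loin; recipients are constructed so that each
    resolves at exactly one of 2-2A … 2-2E per the part/species adjacency
    data, which the fixture also supplies.
    """
    g = dict(group="Meat and meat products", origin="natural", hydro=False, rumin=True)
    donor = make_food("M00", category="mcat0", species="cattle", part="loin",
                      fat=10, protein=20, carb=1, **g)
    recipients = {
        "S2_2A": make_food("M2A", category="x1", species="cattle", part="loin",
                           fat=18, protein=20, carb=1, **g),
        "S2_2B": make_food("M2B", category="x2", species="cattle", part="loin-adj",
                           fat=10.2, protein=20.4, carb=1, **g),
        "S2_2C": make_food("M2C", category="x3", species="veal", part="misc",
                           fat=9.8, protein=19.6, carb=1, **g),
        "S2_2D": make_food("M2D", category="x4", species="horse", part="misc",
                           fat=30, protein=15, carb=1, **g),
        "S2_2E": make_food("M2E", category="mcat0", species="kangaroo", part="misc",
                           fat=2, protein=25, carb=1, **g),
    }
    cfg = CompositionConfig(
        parts_adjacency={"loin-adj": ["loin"]},
        species_adjacency={"veal": ["cattle"]},
        species_fallback={"horse": ["cattle"]},
    )
    return donor, recipients, cfg


def small_generator_config(seed=0, **overrides) -> GeneratorConfig:
    """A miniature study: 3 food groups, ~40 foods, 24-subject cohort."""
    groups = [
        GroupSpec(group="Confectionaries", origin="industrial",
                  counts=StepCounts(s1=3, s1a=2, s1b=2, s3=1, s4=2),
                  tfa_pct_fat_median=6.0, base_macros=(4.0, 3.0, 12.0)),
        GroupSpec(group="Fats and oils", origin="industrial",
                  counts=StepCounts(s1=2),
                  tfa_pct_fat_median=10.0, base_macros=(20.0, 2.0, 2.0)),
        GroupSpec(group="Meat and meat products", origin="natural",
                  counts=StepCounts(s1=4, s1b=1, s2a=1, s2b=1, s2c=1, s2d=1, s2e=2),
                  tfa_pct_fat_median=3.5, base_macros=(4.0, 12.0, 2.0)),
    ]
    design = [
        {"sex": sex, "area": area, "decade": decade, "n": 3}
        for sex in ("female", "male")
        for area in ("urban-a", "rural-a")
        for decade in (30, 60)
    ]
    cohort = CohortConfig(
        design=design,
        group_share_base={
            "Confectionaries (I)": 0.5,
            "Fats and oils (I)": 0.3,
            "Meat and meat products (N)": 0.2,
        },
    )
    params = dict(seed=seed, groups=groups, n_zero_foods=30, cohort=cohort,
                  s1_single_n=2, s1_mean_n=4, s1_weighted_n=3)
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    from tfadb.simulate import generate_study

    return generate_study(small_generator_config(seed=11))


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """(study, assignments frame, provenance, intakes, group_tfa) bundle."""
    from tfadb.composition import build_database
    from tfadb.intake import estimate_intakes

    study = small_study
    assignments, prov = build_database(
        study.universe.foods, study.references, study.universe.foreign,
        study.universe.recipes, study.universe.composition_cfg,
    )
    recipes = {r.food_id: r for r in study.universe.recipes}
    intakes, group_tfa = estimate_intakes(
        study.records, study.subjects, study.universe.foods_frame,
        assignments, recipes,
    )
    return study, assignments, prov, intakes, group_tfa


@pytest.fixture
def rng():
    return np.random.default_rng(0)
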