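"""Unit and property tests for the 4-step composition-database builder."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfadb import (
    Basis,
    CompositionConfig,
    ReferenceRecord,
    Recipe,
    ForeignFoodRecord,
    Step,
    ValidationError,
)
from tfadb.composition import (
    DatabaseBuildError,
    PoolingError,
    assign_step2,
    assign_step3,
    assign_step4,
    build_assignments,
    build_database,
    convert_reference,
    nutrient_distance,
    pool_step1,
    zero_rule,
)

from conftest import make_food


def ref(fid, mean, n=1, basis=Basis.PERCENT_OF_FAT, ref_fat=None, article="A1",
        lo=None, hi=None):
    return ReferenceRecord(article_id=article, food_id=fid, mean_value=mean,
                           n_samples=n, basis=basis, ref_fat_g_100g=ref_fat,
                           min_value=lo, max_value=hi)


class TestZeroRule:
    def test_no_fat_means_no_tfa(self):
        assert zero_rule(make_food("F1", fat=0.0))

    def test_trace_fat_below_threshold(self):
        assert zero_rule(make_food("F1", fat=0.1), fat_threshold=0.1)
        assert not zero_rule(make_food("F1", fat=0.2), fat_threshold=0.1)

    def test_fatty_food_with_hydrogenated_oil_is_not_zero(self):
        assert not zero_rule(make_food("F1", fat=80.0, hydro=True))

    def test_fatty_food_without_tfa_sources_is_zero(self):
        assert zero_rule(make_food("F1", fat=80.0, hydro=False, rumin=False))


class TestConvertReference:
    def test_percent_of_fat_basis(self):
        food = make_food("F1", fat=80.0)
        assert convert_reference(ref("F1", 10.0), food) == pytest.approx(8.0)

    def test_g_per_100g_with_reference_fat(self):
        food = make_food("F1", fat=20.0)
        r = ref("F1", 2.0, basis=Basis.G_PER_100G_FOOD, ref_fat=40.0)
        assert convert_reference(r, food) == pytest.approx(1.0)

    def test_g_per_100g_without_reference_fat_is_identity(self):
        # the composition table's own fat is used, so the value passes through
        food = make_food("F1", fat=20.0)
        r = ref("F1", 2.0, basis=Basis.G_PER_100G_FOOD)
        assert convert_reference(r, food) == pytest.approx(2.0)

    def test_zero_reference_gives_zero(self):
        assert convert_reference(ref("F1", 0.0), make_food("F1", fat=30.0)) == 0.0

    def test_zero_fat_with_nonzero_reference_is_inconsistent(self):
        food = make_food("F1", fat=0.0)
        with pytest.raises(ValidationError):
            convert_reference(ref("F1", 1.0), food)


class TestPooling:
    def test_sample_weighted_mean_over_articles(self):
        food = make_food("F1")
        records = [ref("F1", 2.0, n=4, article="A1"), ref("F1", 5.0, n=1, article="A2")]
        pct, step = pool_step1(records, food)
        assert pct == pytest.approx(2.6)
        assert step is Step.S1_WEIGHTED

    def test_sole_article_without_sample_count_is_used(self):
        pct, step = pool_step1([ref("F1", 3.0, n=None)], make_food("F1"))
        assert pct == 3.0
        assert step is Step.S1_SINGLE

    def test_unknown_n_article_dropped_from_pooling(self):
        records = [ref("F1", 2.0, n=4, article="A1"), ref("F1", 3.0, n=None, article="A2")]
        pct, _ = pool_step1(records, make_food("F1"))
        assert pct == pytest.approx(2.0)

    def test_single_article_multiple_samples_is_its_mean(self):
        pct, step = pool_step1([ref("F1", 4.2, n=6, lo=3.0, hi=5.5)], make_food("F1"))
        assert pct == pytest.approx(4.2)
        assert step is Step.S1_MEAN

    def test_all_articles_unknown_n_demands_manual_resolution(self):
        records = [ref("F1", 2.0, n=None, article="A1"), ref("F1", 3.0, n=None, article="A2")]
        with pytest.raises(PoolingError):
            pool_step1(records, make_food("F1"))

    def test_weighted_pooling_equals_flat_mean_over_samples(self, rng):
        """When article means are means of per-sample values, the weighted
        pool equals the flat mean over all samples (the pooling oracle)."""
        food = make_food("F1")
        samples = [rng.uniform(1, 8, size=n) for n in (3, 5, 2, 7)]
        records = [
            ref("F1", float(s.mean()), n=len(s), article=f"A{i}")
            for i, s in enumerate(samples)
        ]
        pct, _ = pool_step1(records, food)
        flat = float(np.concatenate(samples).mean())
        assert pct == pytest.approx(flat, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0.1, 50.0), st.integers(1, 20)),
            min_size=2, max_size=6,
        )
    )
    def test_weighted_mean_within_article_mean_bounds(self, articles):
        food = make_food("F1")
        records = [
            ref("F1", m, n=n, article=f"A{i}") for i, (m, n) in enumerate(articles)
        ]
        pct, step = pool_step1(records, food)
        means = [m for m, _ in articles]
        assert min(means) - 1e-12 <= pct <= max(means) + 1e-12
        assert step is Step.S1_WEIGHTED


class TestNutrientDistance:
    def test_identity_is_zero(self):
        v = (200.0, 10.0, 5.0, 20.0)
        assert nutrient_distance(v, v) == 0.0

    def test_single_doubled_component(self):
        assert nutrient_distance((200, 10, 5, 20), (100, 10, 5, 20)) == pytest.approx(1.0)

    def test_floor_caps_near_zero_denominators(self):
        assert nutrient_distance((100, 0.5, 5, 20), (100, 0.0, 5, 20), floor=1.0) == pytest.approx(0.5)

    def test_nearest_neighbour_matches_exhaustive_search(self, rng):
        foods = [
            make_food(f"F{i}", fat=rng.uniform(1, 40), protein=rng.uniform(1, 30),
                      carb=rng.uniform(1, 60))
            for i in range(5)
        ]
        target = make_food("T", fat=12, protein=8, carb=30)
        dists = [nutrient_distance(target, f) for f in foods]
        expected = foods[int(np.argmin(dists))]
        from tfadb.composition import _nearest_donor

        got = _nearest_donor(target, foods, CompositionConfig(), thresholded=False)
        assert got.food_id == expected.food_id


def _brute_force_cascade(food, donor_foods, cfg):
    """Independent enumeration of the meat-rule order from its definition."""
    same = [d for d in donor_foods if d.species == food.species and d.part == food.part]
    if same:
        return "S2_2A"
    thr = cfg.similarity_threshold
    near = lambda d: nutrient_distance(food, d, cfg.similarity_floor) <= thr
    if any(d.species == food.species and d.part in cfg.parts_adjacency.get(food.part, [])
           and near(d) for d in donor_foods):
        return "S2_2B"
    if any(d.species in cfg.species_adjacency.get(food.species, []) and near(d)
           for d in donor_foods):
        return "S2_2C"
    if any(d.species in cfg.species_fallback.get(food.species, []) for d in donor_foods):
        return "S2_2D"
    if any(d.category == food.category for d in donor_foods):
        return "S2_2E"
    return None


class TestStep2:
    def test_same_category_transfer_and_rescale(self):
        donor = make_food("D1", category="C", fat=20.0)
        recipient = make_food("R1", category="C", fat=10.0)
        resolved = {
            "D1": build_assignments([donor], [ref("D1", 3.0)])["D1"],
        }
        a = assign_step2(recipient, resolved, {"D1": donor, "R1": recipient},
                         CompositionConfig(similarity_threshold=10.0))
        assert a.step is Step.S2_1A
        assert a.tfa_pct_fat == pytest.approx(3.0)
        assert a.tfa_g_100g == pytest.approx(0.3)
        assert a.donor_food_id == "D1"

    def test_cascade_falls_back_to_group(self):
        donor = make_food("D1", category="C1", fat=20.0)
        recipient = make_food("R1", category="C2", fat=10.0)
        resolved = {"D1": build_assignments([donor], [ref("D1", 3.0)])["D1"]}
        a = assign_step2(recipient, resolved, {"D1": donor, "R1": recipient},
                         CompositionConfig(similarity_threshold=10.0))
        assert a.step is Step.S2_1B

    def test_meat_cascade_matches_hand_enumeration(self, meat_cascade):
        donor, recipients, cfg = meat_cascade
        resolved = {"M00": build_assignments([donor], [ref("M00", 4.0)], cfg=cfg)["M00"]}
        foods_by_id = {donor.food_id: donor, **{f.food_id: f for f in recipients.values()}}
        for expected_step, food in recipients.items():
            a = assign_step2(food, resolved, foods_by_id, cfg)
            assert a is not None, food.food_id
            assert a.step.value == expected_step
            assert a.step.value == _brute_force_cascade(food, [donor], cfg)

    def test_transfer_consistency(self, meat_cascade):
        # every similarity assignment carries the donor's % of fat exactly
        donor, recipients, cfg = meat_cascade
        resolved = {"M00": build_assignments([donor], [ref("M00", 4.0)], cfg=cfg)["M00"]}
        foods_by_id = {donor.food_id: donor, **{f.food_id: f for f in recipients.values()}}
        for food in recipients.values():
            a = assign_step2(food, resolved, foods_by_id, cfg)
            assert a.tfa_pct_fat == resolved["M00"].tfa_pct_fat
            assert a.tfa_g_100g == pytest.approx(a.tfa_pct_fat * food.fat_g_100g / 100.0)

    def test_zero_fat_recipient_flagged_as_source_gets_zero(self):
        donor = make_food("D1", category="C", fat=20.0)
        recipient = make_food("R1", category="C", fat=0.0, hydro=True)
        resolved = {"D1": build_assignments([donor], [ref("D1", 3.0)])["D1"]}
        a = assign_step2(recipient, resolved, {"D1": donor, "R1": recipient},
                         CompositionConfig(similarity_threshold=10.0))
        assert a.tfa_g_100g == 0.0
        assert a.step is Step.S2_1A


class TestStep3:
    def _foreign(self, fid, food, tfa=1.5, same=True, scale=1.0):
        return ForeignFoodRecord(
            food_id=fid, foreign_tfa_g_100g=tfa,
            energy_kcal_100g=food.energy_kcal_100g * scale,
            fat_g_100g=food.fat_g_100g * scale,
            protein_g_100g=food.protein_g_100g * scale,
            carb_g_100g=food.carb_g_100g * scale,
            same_manufacturer=same,
        )

    def test_identical_composition_assigns_foreign_value(self):
        food = make_food("F1", fat=15.0)
        a = assign_step3(food, [self._foreign("F1", food)], CompositionConfig())
        assert a.step is Step.S3
        assert a.tfa_g_100g == pytest.approx(1.5)

    def test_dissimilar_composition_is_rejected(self):
        food = make_food("F1")
        a = assign_step3(food, [self._foreign("F1", food, scale=2.0)], CompositionConfig())
        assert a is None

    def test_different_manufacturer_never_assigns(self):
        food = make_food("F1")
        a = assign_step3(food, [self._foreign("F1", food, same=False)], CompositionConfig())
        assert a is None


class TestStep4:
    def test_linear_mixing(self):
        food = make_food("F3", fat=10.0)
        recipe = Recipe(food_id="F3", ingredients=(("F1", 50.0), ("F2", 50.0)))
        assignments = {
            "F1": build_assignments([make_food("F1", fat=20)], [ref("F1", 10.0)])["F1"],
            "F2": build_assignments([make_food("F2", fat=0.0, hydro=False)], [])["F2"],
        }
        assert assignments["F1"].tfa_g_100g == pytest.approx(2.0)
        a = assign_step4(food, recipe, assignments)
        assert a.tfa_g_100g == pytest.approx(1.0)
        assert a.step is Step.S4

    def test_all_zero_ingredients_give_zero_with_step_label(self):
        food = make_food("F3")
        recipe = Recipe(food_id="F3", ingredients=(("F2", 100.0),))
        assignments = {"F2": build_assignments([make_food("F2", fat=0.0, hydro=False)], [])["F2"]}
        a = assign_step4(food, recipe, assignments)
        assert a.tfa_g_100g == 0.0
        assert a.step is Step.S4

    def test_unresolved_ingredient_is_an_error(self):
        with pytest.raises(DatabaseBuildError, match="F9"):
            assign_step4(make_food("F3"), Recipe(food_id="F3", ingredients=(("F9", 50.0),)), {})

    def test_nested_recipe_equals_flattened_computation(self):
        """A 3-level nested dish equals the single-level computation over its
        leaf decomposition (independent flattening oracle)."""
        base = make_food("B1", fat=20.0)
        mid = make_food("M1", fat=5.0)
        top = make_food("T1", fat=3.0)
        zero = make_food("Z1", fat=0.0, hydro=False)
        recipes = [
            Recipe(food_id="M1", ingredients=(("B1", 40.0), ("Z1", 60.0))),
            Recipe(food_id="T1", ingredients=(("M1", 50.0), ("Z1", 30.0))),
        ]
        assignments = build_assignments(
            [base, mid, top, zero], [ref("B1", 10.0)], recipes=recipes,
            cfg=CompositionConfig(similarity_threshold=0.0),
        )
        # oracle: flatten by hand — T1 = 0.5 * (0.4 * B1_tfa)
        expected = 0.5 * 0.4 * assignments["B1"].tfa_g_100g
        assert assignments["T1"].tfa_g_100g == pytest.approx(expected, abs=1e-12)

    def test_cyclic_recipes_are_rejected(self):
        a = make_food("A1", fat=5.0)
        b = make_food("B1", fat=5.0)
        recipes = [
            Recipe(food_id="A1", ingredients=(("B1", 50.0),)),
            Recipe(food_id="B1", ingredients=(("A1", 50.0),)),
        ]
        with pytest.raises(DatabaseBuildError, match="cycl"):
            build_assignments([a, b], [], recipes=recipes)

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_recipe_linearity(self, scale):
        food = make_food("F3", fat=10.0)
        recipe = Recipe(food_id="F3", ingredients=(("F1", 30.0), ("F2", 60.0)))
        def mk(pct):
            return {
                "F1": build_assignments([make_food("F1", fat=20)], [ref("F1", pct)])["F1"],
                "F2": build_assignments([make_food("F2", fat=10)], [ref("F2", pct / 2)])["F2"],
            }
        base = assign_step4(food, recipe, mk(4.0)).tfa_g_100g
        scaled = assign_step4(food, recipe, mk(4.0 * scale)).tfa_g_100g
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestBuildDatabase:
    def test_every_food_assigned_and_totals_conserved(self, small_study):
        study = small_study
        _, prov = build_database(
            study.universe.foods, study.references, study.universe.foreign,
            study.universe.recipes, study.universe.composition_cfg,
        )
        assert prov.loc["Total", "Total"] == len(study.universe.foods)

    def test_precedence_analytic_data_wins(self):
        # with references for every food, nothing resolves below Step 1
        foods = [make_food(f"F{i}", category=f"c{i}", fat=10 + i) for i in range(4)]
        refs = [ref(f.food_id, 5.0, article=f"A{i}") for i, f in enumerate(foods)]
        assignments = build_assignments(foods, refs)
        assert all(a.step.value.startswith("S1") for a in assignments.values())

    def test_designated_steps_are_recovered_exactly(self, small_pipeline):
        study, assignments, _, _, _ = small_pipeline
        merged = assignments.merge(study.universe.truth, on="food_id")
        mismatch = merged[
            (merged["designated_step"] != "S1")
            & (merged["designated_step"] != merged["step"])
        ]
        s1 = merged[merged["designated_step"] == "S1"]
        assert mismatch.empty
        assert s1["step"].str.startswith("S1").all()

    def test_input_order_does_not_matter(self, small_study, rng):
        study = small_study
        a1 = build_assignments(study.universe.foods, study.references,
                               study.universe.foreign, study.universe.recipes,
                               study.universe.composition_cfg)
        foods = list(study.universe.foods)
        refs = list(study.references)
        rng.shuffle(foods)
        rng.shuffle(refs)
        a2 = build_assignments(foods, refs, study.universe.foreign,
                               study.universe.recipes, study.universe.composition_cfg)
        assert a1 == a2

    def test_provenance_is_deterministic(self, small_study):
        study = small_study
        _, p1 = build_database(study.universe.foods, study.references,
                               study.universe.foreign, study.universe.recipes,
                               study.universe.composition_cfg)
        _, p2 = build_database(study.universe.foods, study.references,
                               study.universe.foreign, study.universe.recipes,
                               study.universe.composition_cfg)
        assert p1.to_csv() == p2.to_csv()

    def test_unresolvable_food_raises_with_its_id(self):
        # fatty, flagged, no references, no donors, no foreign, no recipe
        lone = make_food("F1", fat=30.0, hydro=True)
        with pytest.raises(DatabaseBuildError, match="F1"):
            build_assignments([lone], [])
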