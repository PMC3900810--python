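"""Configuration models for every pipeline stage.

All thresholds the underlying study left implicit are surfaced here with
documented defaults; nothing numeric is hard-coded in the algorithms.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, field_validator


class CompositionConfig(BaseModel):
    """Parameters of the 4-step database construction.

    fat_threshold
        "trace amount of fat" cut-off, g/100 g. Printed composition tables
        report fat to 0.1 g, so 0.1 is the natural resolution.
    similarity_threshold / similarity_floor
        a donor is "similar" when the max relative macronutrient deviation
        (energy, fat, protein, carbohydrate; each normalised by the donor's
        value floored at ``similarity_floor``) is at most the threshold.
    thresholded_steps
        which similarity-transfer sub-steps require the donor to be within
        the threshold (the rest use pure nearest-neighbour).
    parts_adjacency / species_adjacency / species_fallback
        the meat cascade's "similar part", "similar animal of the same
        species" and "different species" relations, supplied as data because
        they encode expert judgment, not computable structure.
    meat_group
        base group label whose species/part-labelled foods take the cascade.
    """

    fat_threshold: float = 0.1
    similarity_threshold: float = 0.25
    similarity_floor: float = 1.0
    thresholded_steps: tuple[str, ...] = ("S2_1A", "S2_1B", "S2_2B", "S2_2C")
    meat_group: str = "Meat and meat products"
    parts_adjacency: dict[str, list[str]] = Field(default_factory=dict)
    species_adjacency: dict[str, list[str]] = Field(default_factory=dict)
    species_fallback: dict[str, list[str]] = Field(default_factory=dict)

    @field_validator("fat_threshold", "similarity_threshold", "similarity_floor")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v < 0:
            raise ValueError("thresholds must be nonnegative")
        return v


class EstimationConfig(BaseModel):
    """Diet-record intake estimation parameters.

    energy_per_gram_fat
        Atwater factor, kcal per gram of fat, used to express fat-derived
        quantities as % of total energy.
    outlier_k
        SD multiplier of the one-pass, within-sex outlier exclusion applied
        to TFA g/day and TFA %energy.
    """

    energy_per_gram_fat: float = 9.0
    outlier_k: float = 3.0
    expected_days: int = 16


class SummaryConfig(BaseModel):
    """Stratification and report-table parameters."""

    urban_density_threshold: float = 1000.0  # persons/km^2
    #: area label -> population density, persons/km^2
    area_density: dict[str, float] = Field(
        default_factory=lambda: {
            "urban-a": 11743.0,
            "urban-b": 4446.0,
            "rural-a": 786.0,
            "rural-b": 285.0,
        }
    )
    #: interior bin edges of the intake-distribution table
    g_day_edges: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    pct_energy_edges: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    who_threshold_pct_energy: float = 1.0
    age_decades: tuple[int, ...] = (30, 40, 50, 60)


class PipelineConfig(BaseModel):
    """Top-level configuration tying the stages together."""

    composition: CompositionConfig = Field(default_factory=CompositionConfig)
    estimation: EstimationConfig = Field(default_factory=EstimationConfig)
    summaries: SummaryConfig = Field(default_factory=SummaryConfig)
    seed: int = 0
    log_level: str = "INFO"
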