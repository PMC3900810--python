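"""Published reference values from a 16-day diet-record TFA study.

The package's synthetic generator emulates a published study of 225
Japanese adults (119 women, 106 men; four areas, four 10-year age groups)
whose raw records are not available. What *is* available are its printed
summary tables. This module encodes two of them as data so that the
summary operations can be cross-checked against the study's headline
results: the stratified distribution of TFA intake as % of total energy,
and the food-group contribution decomposition.

These are inputs for arithmetic-reproduction checks — they are never used
by the pipeline itself.
"""

from __future__ import annotations

import pandas as pd

#: strata of the distribution table: residential area, then age decade
DISTRIBUTION_STRATA = ("urban", "rural", "30-39", "40-49", "50-59", "60-69")

#: TFA intake distribution (% of total energy), women (n = 119).
#: rows: (bin_lo, bin_hi, counts per stratum in DISTRIBUTION_STRATA order, total)
WOMEN_PCT_ENERGY_DISTRIBUTION = [
    (0.31, 0.49, (3, 11, 0, 0, 3, 11), 14),
    (0.50, 0.74, (16, 27, 6, 12, 10, 15), 43),
    (0.75, 0.99, (18, 15, 12, 6, 11, 4), 33),
    (1.00, 1.24, (11, 4, 5, 4, 6, 0), 15),
    (1.25, 1.49, (6, 4, 2, 5, 2, 1), 10),
    (1.50, 1.95, (3, 1, 2, 2, 0, 0), 4),
]

#: TFA intake distribution (% of total energy), men (n = 106).
MEN_PCT_ENERGY_DISTRIBUTION = [
    (0.20, 0.49, (10, 17, 0, 8, 7, 12), 27),
    (0.50, 0.74, (20, 27, 9, 9, 16, 13), 47),
    (0.75, 0.99, (15, 11, 9, 9, 5, 3), 26),
    (1.00, 1.23, (6, 0, 2, 3, 0, 1), 6),
]

#: food-group contribution (% of total TFA intake): mean and SD per sex
CONTRIBUTION_ROWS = [
    # group label, women mean, women SD, men mean, men SD
    ("Confectionaries (I)", 21.7, 19.7, 15.3, 25.0),
    ("Bakery (I)", 19.1, 13.3, 18.0, 13.7),
    ("Fats and oils (N)", 2.0, 2.0, 2.1, 2.4),
    ("Fats and oils (I)", 14.1, 6.0, 20.0, 7.4),
    ("Instant and retort foods (I)", 7.5, 6.4, 10.0, 8.3),
    ("Milk and dairy products (N)", 12.3, 8.2, 9.7, 7.9),
    ("Milk and dairy products (I)", 3.3, 4.1, 3.1, 5.1),
    ("Meat and meat products (N)", 10.7, 6.6, 15.5, 8.9),
    ("Margarine (I)", 4.8, 6.7, 5.8, 8.9),
    ("Fast foods (I)", 3.5, 7.0, 3.7, 8.8),
    ("Miscellaneous (I)", 1.1, 1.0, 1.0, 0.9),
]


def reference_pct_energy_fixture(sex: str, by: str) -> pd.DataFrame:
    """Per-subject %-energy values reconstructed from the printed counts.

    Each subject is placed at the midpoint of their bin, which preserves
    every count-based statistic (bin membership, threshold frequencies).
    *by* selects the decomposition: ``"area"`` (urban/rural) or ``"age"``
    (the four decades). Returns columns ``tfa_pct_energy`` and ``stratum``.
    """
    table = WOMEN_PCT_ENERGY_DISTRIBUTION if sex == "female" else MEN_PCT_ENERGY_DISTRIBUTION
    strata = DISTRIBUTION_STRATA[:2] if by == "area" else DISTRIBUTION_STRATA[2:]
    offset = 0 if by == "area" else 2
    rows = []
    for lo, hi, counts, _total in table:
        mid = (lo + hi) / 2.0
        for k, stratum in enumerate(strata):
            rows.extend({"tfa_pct_energy": mid, "stratum": stratum} for _ in range(counts[offset + k]))
    return pd.DataFrame(rows)


def reference_contribution_rows(sex: str) -> pd.DataFrame:
    """Contribution table rows for one sex (columns group_label, mean_pct, sd_pct)."""
    i = (1, 2) if sex == "female" else (3, 4)
    return pd.DataFrame(
        [
            {"group_label": r[0], "mean_pct": r[i[0]], "sd_pct": r[i[1]]}
            for r in CONTRIBUTION_ROWS
        ]
    )
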