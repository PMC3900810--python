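"""Descriptive summary surfaces over estimated intakes.

Reproduces, for any cohort, the report tables of a diet-record TFA study:
food-group contribution to total TFA intake, urban/rural and age-decade
comparisons (unpaired t-test; one-way ANOVA with Tukey-Kramer pairwise
comparisons), intake-distribution tables with fixed bin edges, and the
frequency of intake above a recommended %-of-energy ceiling. All
statistics are computed separately by sex by the caller's stratification.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._types import ValidationError
from .config import SummaryConfig

log = logging.getLogger(__name__)

__all__ = [
    "classify_area",
    "add_strata",
    "stratum_summary",
    "contribution_by_group",
    "industrial_share",
    "frequency_above",
    "distribution_table",
    "compare_strata",
    "compare_databases",
]

#: intake expressions summarised throughout
DEFAULT_VARIABLES = (
    "energy_kcal_day",
    "fat_g_day",
    "fat_pct_energy",
    "tfa_g_day",
    "tfa_pct_energy",
    "tfa_pct_fat",
)


def classify_area(density: float, threshold: float = 1000.0) -> str:
    """"urban" iff population density (persons/km^2) >= threshold."""
    if density <= 0:
        raise ValidationError("population density must be positive")
    return "urban" if density >= threshold else "rural"


def add_strata(intakes: pd.DataFrame, cfg: SummaryConfig | None = None) -> pd.DataFrame:
    """Attach urban/rural and age-decade stratum columns."""
    cfg = cfg or SummaryConfig()
    out = intakes.copy()
    density = out["area"].map(cfg.area_density)
    if density.isna().any():
        unknown = sorted(out.loc[density.isna(), "area"].unique())
        raise ValidationError(f"areas without a configured density: {unknown}")
    out["urban_rural"] = [
        classify_area(d, cfg.urban_density_threshold) for d in density
    ]
    decade = (out["age_years"] // 10 * 10).astype(int)
    out["age_group"] = decade.astype(str) + "-" + (decade + 9).astype(str)
    return out


def stratum_summary(
    intakes: pd.DataFrame,
    by: str | list[str] | None = None,
    variables: Sequence[str] = DEFAULT_VARIABLES,
) -> pd.DataFrame:
    """n, mean and SD of each intake expression, per stratum (or overall)."""
    if by is None:
        grp = intakes.assign(_all="all").groupby("_all")
    else:
        grp = intakes.groupby(by)
    parts = {"n": grp.size()}
    for v in variables:
        parts[f"{v}_mean"] = grp[v].mean()
        parts[f"{v}_sd"] = grp[v].std(ddof=1)
    return pd.DataFrame(parts)


# ------------------------------------------------------------ contributions


def contribution_by_group(
    group_tfa: pd.DataFrame,
    group_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean and SD over subjects of each food group's % share of TFA intake.

    Shares are of TFA mass (g/day). Subjects with zero total TFA carry no
    defined shares and are dropped with a warning. Per subject the shares
    sum to 100 across groups by construction.
    """
    totals = group_tfa.groupby("subject_id")["tfa_g_day"].sum()
    zero = totals[totals <= 0].index
    if len(zero):
        warnings.warn(
            f"{len(zero)} subjects with zero total TFA excluded from the "
            "contribution decomposition",
            stacklevel=2,
        )
    g = group_tfa[~group_tfa["subject_id"].isin(zero)].copy()
    g["pct"] = 100.0 * g["tfa_g_day"] / totals.reindex(g["subject_id"]).to_numpy()
    wide = g.pivot_table(index="subject_id", columns="group_label", values="pct", fill_value=0.0)
    if group_labels is not None:
        wide = wide.reindex(columns=list(group_labels), fill_value=0.0)
    out = pd.DataFrame(
        {"mean_pct": wide.mean(axis=0), "sd_pct": wide.std(axis=0, ddof=1)}
    )
    out.index.name = "group_label"
    return out.reset_index()


def industrial_share(contributions: pd.DataFrame) -> float:
    """Sum of mean contributions over industrially sourced "(I)" groups."""
    is_industrial = contributions["group_label"].str.endswith("(I)")
    return float(contributions.loc[is_industrial, "mean_pct"].sum())


# ------------------------------------------------------- threshold frequency


def frequency_above(
    intakes: pd.DataFrame,
    threshold: float = 1.0,
    by: str | None = None,
    value_col: str = "tfa_pct_energy",
) -> pd.DataFrame:
    """Count and percentage of subjects with *value_col* above *threshold*.

    With ``by=None`` a single "all" row is returned. Percentages are exact;
    round at report time (one decimal for cohort totals, integers for
    strata, matching printed-table conventions).
    """
    df = intakes.assign(_stratum=intakes[by] if by else "all")
    grp = df.groupby("_stratum")
    out = pd.DataFrame(
        {
            "n": grp.size(),
            "n_above": grp.apply(
                lambda g: int((g[value_col] > threshold).sum()), include_groups=False
            ),
        }
    )
    out["pct_above"] = np.where(out["n"] > 0, 100.0 * out["n_above"] / out["n"], 0.0)
    out.index.name = "stratum"
    return out.reset_index()


# --------------------------------------------------------------- distribution


def distribution_table(
    intakes: pd.DataFrame,
    edges: Sequence[float],
    value_col: str = "tfa_g_day",
    by: str | None = None,
) -> pd.DataFrame:
    """Counts per half-open intake bin per stratum.

    *edges* are the interior cut points; the first and last bins are
    open-ended and their row labels are truncated at the observed minimum
    and maximum. Bins are [lo, hi). Row sums reproduce each stratum's n.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing")
    values = intakes[value_col]
    lo, hi = float(values.min()), float(values.max())
    full = [-np.inf, *edges, np.inf]
    labels = []
    for a, b in zip(full, full[1:]):
        left = lo if np.isinf(a) else a
        right = hi if np.isinf(b) else b - 0.01
        labels.append(f"{left:.2f}-{right:.2f}")
    binned = pd.cut(values, bins=full, right=False, labels=labels, ordered=False)
    df = intakes.assign(_bin=binned, _stratum=intakes[by] if by else "all")
    table = (
        df.pivot_table(index="_bin", columns="_stratum", values=value_col,
                       aggfunc="count", fill_value=0, observed=False)
        .reindex(labels, fill_value=0)
        .astype(int)
    )
    table["Total"] = table.sum(axis=1)
    table.index.name = "bin"
    return table


# ------------------------------------------------------------- comparisons


def compare_strata(
    intakes: pd.DataFrame,
    area_col: str = "urban_rural",
    age_col: str = "age_group",
    variables: Sequence[str] = DEFAULT_VARIABLES,
) -> dict[str, pd.DataFrame]:
    """Two-group and multi-group mean comparisons per intake expression.

    Urban vs rural: two-sided unpaired Student's t-test. Age decades:
    one-way ANOVA followed by Tukey-Kramer pairwise comparisons (valid
    under unequal group sizes). Degenerate (zero-variance) cases yield
    NaN p-values rather than errors.
    """
    results_t, results_anova, results_tukey = [], [], []

    areas = sorted(intakes[area_col].dropna().unique())
    for v in variables:
        if len(areas) == 2:
            a = intakes.loc[intakes[area_col] == areas[0], v].to_numpy()
            b = intakes.loc[intakes[area_col] == areas[1], v].to_numpy()
            if len(a) >= 2 and len(b) >= 2 and (np.var(a) + np.var(b)) > 0:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            else:
                t, p = np.nan, np.nan
            results_t.append(
                {"variable": v, f"mean_{areas[0]}": a.mean(), f"mean_{areas[1]}": b.mean(),
                 "t": float(t), "p": float(p)}
            )

        groups = [g[v].to_numpy() for _, g in intakes.groupby(age_col)]
        names = [name for name, _ in intakes.groupby(age_col)]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups) and sum(np.var(g) for g in groups) > 0:
            f, p = stats.f_oneway(*groups)
            tukey = stats.tukey_hsd(*groups)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    results_tukey.append(
                        {"variable": v, "group_a": names[i], "group_b": names[j],
                         "p": float(tukey.pvalue[i, j])}
                    )
        else:
            f, p = np.nan, np.nan
        results_anova.append({"variable": v, "F": float(f), "p": float(p)})

    return {
        "ttest": pd.DataFrame(results_t),
        "anova": pd.DataFrame(results_anova),
        "tukey": pd.DataFrame(results_tukey),
    }


def compare_databases(
    intakes_full: pd.DataFrame, intakes_reduced: pd.DataFrame
) -> pd.DataFrame:
    """Per-sex mean TFA intake under the full and base-food-only databases.

    The reduced database assigns zero to foods outside the base list, so
    per subject the reduced estimate never exceeds the full one; the
    difference is the intake attributable to the added foods.
    """
    rows = []
    red = intakes_reduced.set_index("subject_id")
    for sex, grp in intakes_full.groupby("sex"):
        r = red.loc[grp["subject_id"]]
        rows.append(
            {
                "sex": sex,
                "n": len(grp),
                "tfa_g_day_full": grp["tfa_g_day"].mean(),
                "tfa_g_day_reduced": r["tfa_g_day"].mean(),
                "tfa_pct_energy_full": grp["tfa_pct_energy"].mean(),
                "tfa_pct_energy_reduced": r["tfa_pct_energy"].mean(),
            }
        )
    out = pd.DataFrame(rows)
    out["tfa_g_day_added"] = out["tfa_g_day_full"] - out["tfa_g_day_reduced"]
    return out


# ------------------------------------------------------------ report bundle


def report_tables(
    intakes: pd.DataFrame,
    group_tfa: pd.DataFrame | None = None,
    cfg: SummaryConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the study's report tables for an arbitrary cohort.

    Keys: ``characteristics`` (per-sex n/mean/SD of anthropometry and all
    intake expressions), ``contributions`` (food-group % shares, per sex),
    ``by_area`` and ``by_age`` (stratified means with test p-values),
    ``distribution_g_day`` / ``distribution_pct_energy`` (binned counts),
    ``frequency_above`` (share above the recommended %-energy ceiling),
    and ``tests`` (all pairwise Tukey p-values).
    """
    cfg = cfg or SummaryConfig()
    strat = add_strata(intakes, cfg)
    out: dict[str, pd.DataFrame] = {}

    char_vars = ("age_years", "height_cm", "weight_kg", "bmi_kg_m2") + tuple(DEFAULT_VARIABLES)
    out["characteristics"] = stratum_summary(strat, by="sex", variables=char_vars).reset_index()

    if group_tfa is not None:
        parts = []
        for sex, grp in strat.groupby("sex"):
            sub = group_tfa[group_tfa["subject_id"].isin(grp["subject_id"])]
            contrib = contribution_by_group(
                sub[sub["group_label"] != "no-TFA"]
            )
            contrib.insert(0, "sex", sex)
            parts.append(contrib)
        out["contributions"] = pd.concat(parts, ignore_index=True)

    area_rows, age_rows, tukey_rows, freq_rows, dist_g, dist_e = [], [], [], [], [], []
    for sex, grp in strat.groupby("sex"):
        res = compare_strata(grp)
        s_area = stratum_summary(grp, by="urban_rural").reset_index()
        s_area.insert(0, "sex", sex)
        area_rows.append(s_area)
        t = res["ttest"].copy()
        t.insert(0, "sex", sex)
        area_rows.append(t)
        s_age = stratum_summary(grp, by="age_group").reset_index()
        s_age.insert(0, "sex", sex)
        age_rows.append(s_age)
        a = res["anova"].copy()
        a.insert(0, "sex", sex)
        age_rows.append(a)
        tk = res["tukey"].copy()
        tk.insert(0, "sex", sex)
        tukey_rows.append(tk)

        for by in ("urban_rural", "age_group", None):
            f = frequency_above(grp, cfg.who_threshold_pct_energy, by=by)
            f.insert(0, "sex", sex)
            freq_rows.append(f)
        for by in ("urban_rural", "age_group", None):
            g = distribution_table(grp, cfg.g_day_edges, "tfa_g_day", by=by).reset_index()
            g.insert(0, "sex", sex)
            dist_g.append(g)
            e = distribution_table(grp, cfg.pct_energy_edges, "tfa_pct_energy", by=by).reset_index()
            e.insert(0, "sex", sex)
            dist_e.append(e)

    out["by_area"] = pd.concat(area_rows, ignore_index=True)
    out["by_age"] = pd.concat(age_rows, ignore_index=True)
    out["tests"] = pd.concat(tukey_rows, ignore_index=True)
    out["frequency_above"] = pd.concat(freq_rows, ignore_index=True)
    out["distribution_g_day"] = pd.concat(dist_g, ignore_index=True)
    out["distribution_pct_energy"] = pd.concat(dist_e, ignore_index=True)
    return out
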