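"""Grouped-means tables with one-way ANOVA and overall summary statistics.

Each network measure is tabulated by respondent characteristics — age group
(<=64 / 65-74 / >=75), gender, marital status (living with spouse vs not),
education (none / elementary or seodang / middle school and above) and
3-group self-rated health — with the category mean, the category n and
share, a one-way ANOVA p-value across categories, and the overall mean,
sample standard deviation and skewness.

The ANOVA is implemented from the sum-of-squares decomposition (the F upper
tail comes from scipy's F distribution): this module owns the computation
rather than delegating it, so its tests can pin the algebra directly.
Skewness is the adjusted Fisher–Pearson estimator

    G1 = g1 * sqrt(n (n - 1)) / (n - 2),   g1 = m3 / m2^(3/2),

the default of the major statistical packages; the plain moment ratio g1 is
available by switch.  The "overall" mean weights every non-missing
respondent equally (equivalently, categories by their size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey_io import Codebook, PersonRecord

__all__ = [
    "GroupedTable",
    "GROUPINGS",
    "group_categories",
    "anova_oneway",
    "overall_stats",
    "build_table",
    "tables_to_frame",
]

GROUPINGS = ("age_group", "gender", "marital_group", "education", "srh_group")
_NAN = float("nan")


def group_categories(roster: Sequence[PersonRecord], codebook: Codebook) -> pd.DataFrame:
    """Deterministic category labels per respondent for all five groupings.

    Marital status is dichotomised: living_with_spouse vs everyone else
    (separated/divorced/widowed and never married share the non-spouse
    group).
    """
    rows = []
    for p in roster:
        if not p.is_respondent:
            continue
        rows.append(
            {
                "person_id": p.person_id,
                "age_group": codebook.age_group(p.age),
                "gender": p.gender,
                "marital_group": (
                    "living_with_spouse"
                    if p.marital_status == "living_with_spouse"
                    else "separated_divorced_widowed"
                ),
                "education": p.education,
                "srh_group": codebook.srh_3group[p.srh],
            }
        )
    df = pd.DataFrame(
        rows, columns=["person_id", "age_group", "gender", "marital_group",
                       "education", "srh_group"]
    )
    return df.set_index("person_id")


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA from the sum-of-squares decomposition.

    Returns (F, p).  Degenerate cases: fewer than two non-empty groups or no
    residual degrees of freedom -> (nan, nan); zero between- and zero
    within-variance -> (nan, nan); zero within-variance with positive
    between-variance -> (inf, 0); zero between-variance -> (0, 1).
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    samples = [g[~np.isnan(g)] for g in samples]
    samples = [g for g in samples if len(g) > 0]
    k = len(samples)
    n = sum(len(g) for g in samples)
    if k < 2 or n - k < 1:
        return (_NAN, _NAN)
    grand = sum(g.sum() for g in samples) / n
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in samples)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in samples)
    df_between = k - 1
    df_within = n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return (_NAN, _NAN)
        return (float("inf"), 0.0)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return (float(F), p)


def overall_stats(
    values: Sequence[float], skew_estimator: str = "G1"
) -> tuple[float, float, float]:
    """(mean, sample sd, skewness) over non-missing values.

    sd needs n >= 2, skewness n >= 3 and positive variance; otherwise the
    statistic is NaN.  ``skew_estimator`` is "G1" (adjusted Fisher–Pearson,
    default) or "g1" (plain moment ratio).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n == 0:
        return (_NAN, _NAN, _NAN)
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n >= 2 else _NAN
    if n < 3:
        return (mean, sd, _NAN)
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    if m2 == 0.0:
        return (mean, sd, _NAN)
    g1 = m3 / m2**1.5
    if skew_estimator == "g1":
        skew = g1
    elif skew_estimator == "G1":
        skew = g1 * math.sqrt(n * (n - 1)) / (n - 2)
    else:
        raise ValueError(f"unknown skew estimator {skew_estimator!r}")
    return (mean, sd, float(skew))


@dataclass
class GroupedTable:
    """One measure tabulated by one grouping variable."""

    measure: str
    grouping: str
    categories: list[str]
    n: dict[str, int]  # non-missing respondents per category
    proportion: dict[str, float]  # category share of non-missing respondents
    mean: dict[str, float]
    anova_F: float
    anova_p: float
    overall_mean: float
    overall_sd: float
    overall_skewness: float


_CATEGORY_ORDER = {
    "gender": ["male", "female"],
    "marital_group": ["living_with_spouse", "separated_divorced_widowed"],
    "education": ["none", "elementary_or_seodang", "middle_school_plus"],
    "srh_group": ["poor_somewhat_poor", "good", "very_good_excellent"],
}


def _ordered_categories(grouping: str, present: Sequence[str], codebook: Codebook) -> list[str]:
    if grouping == "age_group":
        lo, hi = codebook.age_bin_edges
        order = [f"<={lo}", f"{lo + 1}-{hi - 1}", f">={hi}"]
    else:
        order = _CATEGORY_ORDER.get(grouping, sorted(set(present)))
    return [c for c in order if c in set(present)]


def build_table(
    measures: pd.DataFrame,
    grouping_vars: Sequence[str],
    roster: Sequence[PersonRecord],
    codebook: Codebook,
    skew_estimator: str = "G1",
) -> list[GroupedTable]:
    """Full cross of measures x groupings.

    ``measures`` is a DataFrame indexed by person_id (one column per
    measure, NaN = undefined for that respondent); only roster respondents
    are tabulated.  Category n counts non-missing values, so measures that
    are undefined for small networks (density, bridging) are averaged over
    valid respondents only.
    """
    cats = group_categories(roster, codebook)
    joined = cats.join(measures, how="left")
    tables: list[GroupedTable] = []
    for measure in measures.columns:
        for grouping in grouping_vars:
            sub = joined[[grouping, measure]].dropna(subset=[measure])
            categories = _ordered_categories(grouping, list(sub[grouping]), codebook)
            n = {c: int((sub[grouping] == c).sum()) for c in categories}
            total = sum(n.values())
            proportion = {c: (n[c] / total if total else _NAN) for c in categories}
            mean = {
                c: float(sub.loc[sub[grouping] == c, measure].mean()) for c in categories
            }
            samples = [
                sub.loc[sub[grouping] == c, measure].to_numpy() for c in categories
            ]
            F, p = anova_oneway(samples) if len(categories) >= 2 else (_NAN, _NAN)
            om, osd, osk = overall_stats(
                joined[measure].to_numpy(), skew_estimator=skew_estimator
            )
            tables.append(
                GroupedTable(
                    measure=measure,
                    grouping=grouping,
                    categories=categories,
                    n=n,
                    proportion=proportion,
                    mean=mean,
                    anova_F=F,
                    anova_p=p,
                    overall_mean=om,
                    overall_sd=osd,
                    overall_skewness=osk,
                )
            )
    return tables


def tables_to_frame(tables: Sequence[GroupedTable]) -> pd.DataFrame:
    """Long-form rendering: one row per (measure, grouping, category) plus
    one footer row per (measure, grouping) with the ANOVA and overall stats."""
    rows = []
    for t in tables:
        for c in t.categories:
            rows.append(
                {
                    "measure": t.measure,
                    "grouping": t.grouping,
                    "category": c,
                    "n": t.n[c],
                    "proportion": t.proportion[c],
                    "mean": t.mean[c],
                    "anova_p": _NAN,
                    "overall_mean": _NAN,
                    "overall_sd": _NAN,
                    "overall_skewness": _NAN,
                }
            )
        rows.append(
            {
                "measure": t.measure,
                "grouping": t.grouping,
                "category": "(overall)",
                "n": sum(t.n.values()),
                "proportion": 1.0 if t.n else _NAN,
                "mean": _NAN,
                "anova_p": t.anova_p,
                "overall_mean": t.overall_mean,
                "overall_sd": t.overall_sd,
                "overall_skewness": t.overall_skewness,
            }
        )
    return pd.DataFrame(rows)
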