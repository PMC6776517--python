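"""Cohort aggregation, indirect standardization and SMRs.

Individual screening records (area, age, sex, case flag) are collapsed to a
stratum table with one row per (area, age group, sex); expected counts come
from applying the overall crude rate to each area's denominator (indirect
standardization), and the standardized morbidity ratio is Y_i = O_i / E_i.
Descriptive case percentages with Wald 95% confidence intervals reproduce
the usual cohort-description tables.
"""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import AGE_GROUPS, SEXES, STRATUM_COLUMNS

MARGIN_COLUMNS = ["margin", "participants", "cases", "percent", "ci_low", "ci_high"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13), as printed tables use."""
    if not np.isfinite(x):
        return float("nan")
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _age_group_from_years(age: float) -> str:
    # "<=60" read inclusively: exactly 60 goes to le60
    return "le60" if age <= 60 else "gt60"


def aggregate(records) -> pd.DataFrame:
    """Collapse individual records to a stratum table.

    ``records`` is a DataFrame (or convertible) with columns ``area_id``,
    ``sex``, ``is_case`` and either ``age_years`` or ``age_group``.  Every
    (area, age, sex) cell of areas present in the records appears in the
    output, zero-filled; the expected column is initialised to 0 and filled
    by :func:`expected_counts`.
    """
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=STRATUM_COLUMNS).astype(
            {"participants": int, "cases": int, "expected": float}
        )
    df = df.reset_index(drop=True)
    if "age_group" in df.columns and "age_years" in df.columns:
        raise ValueError("records must carry age_years or age_group, not both")
    if "age_years" in df.columns:
        if (pd.to_numeric(df["age_years"]) < 0).any():
            bad = df.index[pd.to_numeric(df["age_years"]) < 0].tolist()
            raise ValueError(f"negative age at rows {bad}")
        df["age_group"] = pd.to_numeric(df["age_years"]).map(_age_group_from_years)
    elif "age_group" not in df.columns:
        raise ValueError("records need an age_years or age_group column")

    bad_age = ~df["age_group"].isin(AGE_GROUPS)
    if bad_age.any():
        raise ValueError(f"unknown age_group token at rows {df.index[bad_age].tolist()}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"unknown sex token at rows {df.index[bad_sex].tolist()}")
    if df["area_id"].isna().any() or (df["area_id"].astype(str) == "").any():
        raise ValueError("empty area_id in records")

    df["is_case"] = df["is_case"].astype(bool)
    g = (
        df.groupby(["area_id", "age_group", "sex"], sort=False)
        .agg(participants=("is_case", "size"), cases=("is_case", "sum"))
        .reset_index()
    )
    # complete the area x age x sex cross with zero cells
    areas = pd.unique(df["area_id"])
    full = pd.MultiIndex.from_product(
        [areas, AGE_GROUPS, SEXES], names=["area_id", "age_group", "sex"]
    ).to_frame(index=False)
    out = full.merge(g, on=["area_id", "age_group", "sex"], how="left").fillna(
        {"participants": 0, "cases": 0}
    )
    out["participants"] = out["participants"].astype(int)
    out["cases"] = out["cases"].astype(int)
    out["expected"] = 0.0
    return out[STRATUM_COLUMNS]


def expand_to_records(table: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Inverse of :func:`aggregate` up to row order: one record per participant."""
    rows = {"area_id": [], "age_group": [], "sex": [], "is_case": []}
    for _, r in table.iterrows():
        n, o = int(r["participants"]), int(r["cases"])
        rows["area_id"].extend([r["area_id"]] * n)
        rows["age_group"].extend([r["age_group"]] * n)
        rows["sex"].extend([r["sex"]] * n)
        rows["is_case"].extend([True] * o + [False] * (n - o))
    df = pd.DataFrame(rows)
    if rng is not None:
        df = df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    return df.reset_index(drop=True)


def _margin_row(label: str, n: int, o: int) -> dict:
    if n == 0:
        return {
            "margin": label, "participants": 0, "cases": int(o),
            "percent": float("nan"), "ci_low": float("nan"), "ci_high": float("nan"),
        }
    p = o / n
    z = stats.norm.ppf(0.975)
    half = z * np.sqrt(p * (1 - p) / n)
    return {
        "margin": label,
        "participants": int(n),
        "cases": int(o),
        "percent": round_half_up(100 * p),
        "ci_low": round_half_up(100 * max(p - half, 0.0)),
        "ci_high": round_half_up(100 * min(p + half, 1.0)),
    }


def percentage_table(table: pd.DataFrame) -> pd.DataFrame:
    """Case percentages (100*O/N, half-up to 2 dp) with Wald 95% CIs for the
    overall cohort, each sex, each age group, each sex x age cell, and the
    share of participants per sex and per age group."""
    if table.empty:
        raise ValueError("empty stratum table")
    rows = [_margin_row("overall", table["participants"].sum(), table["cases"].sum())]
    for sex in SEXES:
        sub = table[table["sex"] == sex]
        rows.append(_margin_row(f"sex:{sex}", sub["participants"].sum(), sub["cases"].sum()))
    for age in AGE_GROUPS:
        sub = table[table["age_group"] == age]
        rows.append(_margin_row(f"age:{age}", sub["participants"].sum(), sub["cases"].sum()))
    for sex in SEXES:
        for age in AGE_GROUPS:
            sub = table[(table["sex"] == sex) & (table["age_group"] == age)]
            rows.append(
                _margin_row(f"sex_age:{sex}_{age}", sub["participants"].sum(), sub["cases"].sum())
            )
    total = table["participants"].sum()
    for sex in SEXES:
        n_sex = table.loc[table["sex"] == sex, "participants"].sum()
        rows.append(_margin_row(f"share:{sex}", total, n_sex))
    for age in AGE_GROUPS:
        n_age = table.loc[table["age_group"] == age, "participants"].sum()
        rows.append(_margin_row(f"share:{age}", total, n_age))
    return pd.DataFrame(rows, columns=MARGIN_COLUMNS)


def crude_rate(table: pd.DataFrame, population: pd.Series, per: float = 100_000.0) -> float:
    """Total cases over total population, scaled to `per` persons."""
    if (population <= 0).any():
        raise ValueError("populations must be positive")
    total_pop = float(population.sum())
    if total_pop == 0:
        raise ValueError("zero total population")
    return float(table["cases"].sum()) / total_pop * per


def expected_counts(
    table: pd.DataFrame,
    population: pd.Series | None = None,
    convention: str = "cohort",
) -> pd.DataFrame:
    """Fill the expected column by indirect standardization.

    cohort: E_ikl = N_ikl * (sum O / sum N) — the screened cohort is its own
    reference population (the offset used in the regression models).
    population: E_i = pop_i * (sum O / sum pop) from an external per-area
    population series (indexed by area_id), apportioned to strata by each
    stratum's share of the area's participants.

    Either way the standardization identity sum(E) = sum(O) holds exactly.
    """
    out = table.copy()
    total_cases = out["cases"].sum()
    if convention == "cohort":
        total_n = out["participants"].sum()
        if total_n == 0:
            raise ValueError("no participants; cannot standardize")
        out["expected"] = out["participants"] * (total_cases / total_n)
    elif convention == "population":
        if population is None:
            raise ValueError("population convention requires a per-area population series")
        areas = pd.unique(out["area_id"])
        missing = [a for a in areas if a not in population.index]
        if missing:
            raise ValueError(f"missing population for areas: {missing}")
        rate = total_cases / float(population.loc[areas].sum())
        area_n = out.groupby("area_id")["participants"].transform("sum")
        e_area = out["area_id"].map(population) * rate
        share = np.where(area_n > 0, out["participants"] / area_n.replace(0, 1), 0.25)
        out["expected"] = e_area * share
    else:
        raise ValueError(f"unknown offset convention {convention!r}")
    return out


def smr(table: pd.DataFrame) -> pd.DataFrame:
    """Per-area standardized morbidity ratio Y_i = O_i / E_i.

    E_i = 0 with O_i = 0 yields NaN (undefined); E_i = 0 with O_i > 0 yields
    +inf and a flag.
    """
    g = table.groupby("area_id", sort=False).agg(
        observed=("cases", "sum"), expected=("expected", "sum")
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        y = g["observed"] / g["expected"]
    y = y.where(~((g["expected"] == 0) & (g["observed"] == 0)), np.nan)
    y = y.where(~((g["expected"] == 0) & (g["observed"] > 0)), np.inf)
    g["smr"] = y
    g["flag_infinite"] = np.isinf(g["smr"])
    return g
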