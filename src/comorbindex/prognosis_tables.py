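"""Actual-prognosis outputs under competing risks.

"Actual prognosis" reports, for a patient stratum, the absolute
probabilities of the three mutually exclusive outcomes at 1, 2 and 5
years after diagnosis: died of the index cancer, died of other causes,
still alive. Probabilities come from the Aalen–Johansen
cumulative-incidence estimator, so the three numbers sum to one at every
horizon — unlike net (cancer-only) survival. Strata are site × sex ×
age band × stage × comorbidity level, with optional histology and
diagnosis-period stratifiers for site-specific analyses.

Small strata carry the registry disclosure flags: fewer than 100 or 50
patients are marked, and cells under 5 are suppressed outright.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .survival_core import cuminc

logger = logging.getLogger(__name__)

__all__ = [
    "prognosis_grid",
    "stage_age_level_table",
    "survivor_prevalence",
    "HORIZON_DAYS",
    "ELDERLY_AGE_BANDS",
    "WIDE_AGE_BANDS",
]

# fixed integer day grid for the year horizons
HORIZON_DAYS = {1: 365, 2: 730, 5: 1826}

ELDERLY_AGE_BANDS = {"65-74": (65, 74), "75-84": (75, 84), "85-94": (85, 94)}
WIDE_AGE_BANDS = {"15-64": (15, 64), "65-74": (65, 74), "75-84": (75, 84), "85-94": (85, 94)}
DISTANT_LUNG_BANDS = {"30-94": (30, 94)}


def _age_at_diagnosis(registry: pd.DataFrame) -> pd.Series:
    diag = pd.to_datetime(registry["diagnosis_date"])
    birth = pd.to_datetime(registry["birth_date"])
    return ((diag - birth).dt.days / 365.25).rename("age")


def _band_of(age: pd.Series, bands: dict[str, tuple[int, int]]) -> pd.Series:
    out = pd.Series(pd.NA, index=age.index, dtype="object")
    for name, (lo, hi) in bands.items():
        out[(age >= lo) & (age < hi + 1)] = name
    return out


def prognosis_grid(
    outcomes: pd.DataFrame,
    levels: pd.DataFrame,
    registry: pd.DataFrame,
    horizons=(1, 2, 5),
    age_bands: dict[str, tuple[int, int]] | None = None,
    strata: tuple[str, ...] = ("site", "sex", "age_band", "stage", "level"),
    extra_columns: dict[str, pd.Series] | None = None,
    suppress_below: int = 5,
) -> pd.DataFrame:
    """Cumulative-incidence prognosis cells for every nonempty stratum.

    Parameters
    ----------
    outcomes
        ``patient_id, time_days, event`` rows from
        :func:`~comorbindex.endpoints.build_outcomes`.
    levels
        ``tcci, level`` per patient (index = patient id).
    registry
        Registry table supplying site, sex, stage, and dates.
    age_bands
        Band name → (lo, hi) inclusive years; default 65-74/75-84/85-94.
        Patients outside every band are excluded.
    strata
        Which keys define a stratum; subsets of
        ``site, sex, age_band, stage, level`` plus any key of
        ``extra_columns`` (e.g. histology, diagnosis period).

    Returns
    -------
    One row per stratum × horizon with ``n``, the three probabilities
    (summing to one), and flags ``small_100``, ``small_50``,
    ``suppressed`` (probabilities masked when ``n < suppress_below``).
    """
    age_bands = age_bands or ELDERLY_AGE_BANDS
    reg = registry.set_index("patient_id")
    df = outcomes.set_index("patient_id").join(levels, how="inner")
    df["site"] = reg["site"]
    df["sex"] = reg["sex"]
    df["stage"] = reg["stage"]
    df["age_band"] = _band_of(_age_at_diagnosis(reg), age_bands)
    if extra_columns:
        for name, series in extra_columns.items():
            df[name] = series
    df = df.dropna(subset=[s for s in strata if s in df.columns])

    rows = []
    for key, grp in df.groupby(list(strata), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        est = cuminc(
            grp["time_days"],
            grp["event"].where(grp["event"] != "censored", "censored"),
            causes=["cancer_death", "noncancer_death"],
        )
        n = len(grp)
        for h in horizons:
            t = HORIZON_DAYS[h]
            at = est.at(t)
            rec = dict(zip(strata, key))
            rec.update(
                horizon_years=h,
                n=n,
                p_cancer_death=at["cancer_death"],
                p_other_death=at["noncancer_death"],
                p_survival=at["survival"],
                small_100=n < 100,
                small_50=n < 50,
                suppressed=n < suppress_below,
            )
            rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        mask = out["suppressed"]
        out.loc[mask, ["p_cancer_death", "p_other_death", "p_survival"]] = np.nan
    return out


def stage_age_level_table(
    registry: pd.DataFrame,
    levels: pd.DataFrame,
    age_bands: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Counts and percentages of patients by site × age band × comorbidity
    level × stage; percentages are within each site × age × level column
    (across stages), rounded to one decimal."""
    age_bands = age_bands or WIDE_AGE_BANDS
    reg = registry.set_index("patient_id")
    df = pd.DataFrame(
        {
            "site": reg["site"],
            "stage": reg["stage"],
            "age_band": _band_of(_age_at_diagnosis(reg), age_bands),
        }
    ).join(levels["level"], how="inner")
    df = df.dropna(subset=["age_band"])
    counts = (
        df.groupby(["site", "age_band", "level", "stage"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    col_totals = counts.groupby(["site", "age_band", "level"], observed=True)["count"].transform("sum")
    counts["pct"] = (100.0 * counts["count"] / col_totals).round(1)
    return counts


def survivor_prevalence(
    registry: pd.DataFrame,
    deaths: pd.DataFrame,
    enrollment: pd.DataFrame,
    as_of_years,
) -> pd.DataFrame:
    """Cancer-survivor counts at each year end, by years since diagnosis.

    A patient counts as a survivor at the end of year ``Y`` when diagnosed
    in or before ``Y``, with no death recorded by the end of ``Y``, and
    with enrollment coverage through the end of ``Y``. Survival-time bands
    use whole calendar-year differences: 0-5, 6-10, 11-15, and >15.
    """
    diag_year = pd.to_datetime(registry["diagnosis_date"]).dt.year
    pid = registry["patient_id"]
    death_year = pd.to_datetime(deaths.set_index("patient_id")["death_date"]).dt.year
    death_year = pid.map(death_year)
    last_seen = pd.to_datetime(enrollment.set_index("patient_id")["last_seen"])
    last_seen = pid.map(last_seen)

    rows = []
    for y in as_of_years:
        year_end = pd.Timestamp(year=int(y), month=12, day=31)
        alive = death_year.isna() | (death_year > y)
        covered = last_seen.notna() & (last_seen >= year_end)
        in_scope = diag_year <= y
        t = (y - diag_year)[alive & covered & in_scope]
        band = pd.cut(
            t,
            bins=[-0.5, 5.5, 10.5, 15.5, np.inf],
            labels=["0-5", "6-10", "11-15", ">15"],
        )
        vc = band.value_counts()
        for b in ["0-5", "6-10", "11-15", ">15"]:
            rows.append({"year": int(y), "band": b, "count": int(vc.get(b, 0))})
        rows.append({"year": int(y), "band": "total", "count": int(len(t))})
    return pd.DataFrame(rows)


def plot_prognosis(cells: pd.DataFrame, path, horizon_years: int = 5) -> None:
    """Stacked probability bars (cancer death / other death / survival)
    for one horizon; optional, requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = cells[(cells["horizon_years"] == horizon_years) & ~cells["suppressed"]].copy()
    labels = sub.apply(
        lambda r: "/".join(str(r[c]) for c in sub.columns[: list(sub.columns).index("horizon_years")]),
        axis=1,
    )
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(sub)), 4))
    x = np.arange(len(sub))
    ax.bar(x, sub["p_cancer_death"], label="cancer death")
    ax.bar(x, sub["p_other_death"], bottom=sub["p_cancer_death"], label="other-cause death")
    ax.bar(
        x,
        sub["p_survival"],
        bottom=sub["p_cancer_death"] + sub["p_other_death"],
        label="survival",
    )
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel(f"probability at {horizon_years}y")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
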