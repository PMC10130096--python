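"""Claims-based ascertainment of the 18 comorbid conditions.

A condition counts as present before a cancer diagnosis when the claims
history, restricted to a qualifying window before diagnosis, contains

* at least one inpatient diagnosis of the condition, or
* at least two outpatient diagnoses with service dates more than 30 days
  apart.

The qualifying window is ``[diagnosis - window_months, diagnosis - 6
months)`` in calendar months (half-open): the 6 months immediately before
diagnosis are a washout, excluded so that diagnoses triggered by the
not-yet-registered cancer itself do not count as pre-existing comorbidity.
Supported windows are 30, 54 and 78 months (i.e. 24, 48 or 72 qualifying
months); 30 is the default.

Diagnosis codes are matched by prefix against a configurable condition
catalog. The default catalog carries Deyo-style ICD-9 prefixes with mild
liver disease extended by viral hepatitis B/C and hypertension split into
uncomplicated vs complicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._reference_tables import CONDITIONS, SEVERE_CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionCatalog",
    "AscertainmentPolicy",
    "ascertain_condition",
    "build_profiles",
    "prevalence_table",
    "n_condition_band",
    "BANDS",
]

BANDS: tuple[str, ...] = ("0", "1", "2", "3", "4+")

# Deyo-style ICD-9 prefixes (dots stripped), per condition. Mild LD adds
# viral hepatitis B (0702/0703) and C (07041/07044/07051/07054/0707);
# hypertension is split: 401 uncomplicated vs 402-405 complicated.
_DEFAULT_CODE_MAP: dict[str, tuple[str, ...]] = {
    "AMI": ("410",),
    "Old MI": ("412",),
    "CHF": ("428",),
    "PVD": ("441", "4439", "7854", "V434"),
    "CVD": ("430", "431", "432", "433", "434", "435", "436", "437", "438"),
    "COPD": ("490", "491", "492", "493", "494", "495", "496",
             "500", "501", "502", "503", "504", "505", "5064"),
    "Dementia": ("290",),
    "Paralysis": ("342", "3441"),
    "DM W/O CC": ("2500", "2501", "2502", "2503", "2507"),
    "DM W CC": ("2504", "2505", "2506"),
    "CRF": ("585", "586", "V420", "V451", "V56"),
    "Mild LD": ("5712", "5714", "5715", "5716",
                "0702", "0703", "07041", "07044", "07051", "07054", "0707"),
    "MS LD": ("5722", "5723", "5724", "5725", "5726", "5727", "5728",
              "4560", "4561", "4562"),
    "RD": ("7100", "7101", "7104", "7140", "7141", "7142", "71481", "725"),
    "AIDS": ("042", "043", "044"),
    "Ulcer": ("531", "532", "533", "534"),
    "HT UC": ("401",),
    "HT C": ("402", "403", "404", "405"),
}


def _normalize_code(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class ConditionCatalog:
    """The ordered list of the 18 conditions, their code prefixes, and the
    severe-illness subset used by the comorbidity-level override."""

    conditions: tuple[str, ...] = CONDITIONS
    code_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CODE_MAP)
    )
    severe_set: frozenset[str] = SEVERE_CONDITIONS

    def __post_init__(self):
        if len(self.conditions) != 18:
            raise ValueError(f"catalog must define exactly 18 conditions, got {len(self.conditions)}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition names must be unique")
        missing = set(self.conditions) - set(self.code_map)
        if missing:
            raise ValueError(f"conditions missing from code_map: {sorted(missing)}")
        stray = self.severe_set - set(self.conditions)
        if stray:
            raise ValueError(f"severe_set members not in catalog: {sorted(stray)}")
        object.__setattr__(
            self,
            "code_map",
            {c: tuple(_normalize_code(p) for p in self.code_map[c]) for c in self.conditions},
        )

    def _prefix_index(self) -> dict[str, tuple[str, ...]]:
        idx: dict[str, list[str]] = {}
        for cond, prefixes in self.code_map.items():
            for p in prefixes:
                idx.setdefault(p, []).append(cond)
        return {p: tuple(cs) for p, cs in idx.items()}

    def conditions_for_code(self, code: str) -> tuple[str, ...]:
        """All conditions whose prefix list matches ``code``."""
        idx = self._cached_index()
        code = _normalize_code(code)
        out: list[str] = []
        for k in range(1, len(code) + 1):
            out.extend(idx.get(code[:k], ()))
        return tuple(dict.fromkeys(out))

    def _cached_index(self):
        # frozen dataclass: stash the index on first use
        if not hasattr(self, "_idx"):
            object.__setattr__(self, "_idx", self._prefix_index())
        return self._idx

    @classmethod
    def from_yaml(cls, path) -> "ConditionCatalog":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            conditions=tuple(raw["conditions"]),
            code_map={k: tuple(v) for k, v in raw["code_map"].items()},
            severe_set=frozenset(raw["severe_set"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "conditions": list(self.conditions),
                    "code_map": {k: list(v) for k, v in self.code_map.items()},
                    "severe_set": sorted(self.severe_set),
                },
                fh,
                sort_keys=False,
            )


@dataclass(frozen=True)
class AscertainmentPolicy:
    """Window/washout/setting rules for claims-based ascertainment.

    ``window_months`` is the total lookback (one of 30, 54, 78);
    subtracting the fixed 6-month washout leaves 24, 48 or 72 qualifying
    months. Outpatient ascertainment requires two claims more than 30 days
    apart; one inpatient claim suffices.
    """

    window_months: int = 30
    washout_months: int = 6
    outpatient_min_claims: int = 2
    outpatient_min_gap_days: int = 30  # gap must be strictly greater
    inpatient_min_claims: int = 1

    def __post_init__(self):
        if self.window_months not in (30, 54, 78):
            raise ValueError("window_months must be one of 30, 54, 78")
        if self.washout_months != 6:
            raise ValueError("washout is fixed at 6 months")

    @property
    def qualifying_months(self) -> int:
        return self.window_months - self.washout_months

    def window_bounds(self, diagnosis_date) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Half-open qualifying interval ``[start, end)`` in calendar months.

        Month arithmetic clamps the day of month for short months
        (e.g. July 31 minus 30 months -> January 31; minus 6 -> January 31;
        March 31 minus 6 months -> September 30).
        """
        diag = pd.Timestamp(diagnosis_date)
        start = diag - pd.DateOffset(months=self.window_months)
        end = diag - pd.DateOffset(months=self.washout_months)
        return start, end


def ascertain_condition(
    claims: pd.DataFrame,
    condition: str,
    diagnosis_date,
    policy: AscertainmentPolicy,
    catalog: ConditionCatalog,
) -> bool:
    """Decide presence of one condition for one patient.

    ``claims`` must have columns ``setting`` (``inpatient``/``outpatient``),
    ``service_date`` and ``code``, all belonging to the same patient.
    Claims on or after the diagnosis date are ignored (logged).
    """
    if condition not in catalog.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    if claims.empty:
        return False
    dates = pd.to_datetime(claims["service_date"])
    diag = pd.Timestamp(diagnosis_date)
    late = dates >= diag
    if late.any():
        logger.warning(
            "%d claim(s) dated on/after diagnosis %s excluded from ascertainment",
            int(late.sum()), diag.date(),
        )
    prefixes = catalog.code_map[condition]
    codes = claims["code"].map(_normalize_code)
    matches = codes.map(lambda c: any(c.startswith(p) for p in prefixes))
    start, end = policy.window_bounds(diag)
    in_window = (dates >= start) & (dates < end) & ~late
    hits = claims[matches & in_window]
    inpat = hits["setting"] == "inpatient"
    if inpat.sum() >= policy.inpatient_min_claims:
        return True
    out_dates = pd.to_datetime(hits.loc[~inpat, "service_date"])
    if len(out_dates) >= policy.outpatient_min_claims:
        span = (out_dates.max() - out_dates.min()).days
        if span > policy.outpatient_min_gap_days:
            return True
    return False


def build_profiles(
    dataset,
    policy: AscertainmentPolicy | None = None,
    catalog: ConditionCatalog | None = None,
) -> pd.DataFrame:
    """Ascertain all conditions for every registry patient.

    Parameters
    ----------
    dataset
        A :class:`~comorbindex.synthetic_cohort.LinkedDataset`, or any
        object with ``registry`` (``patient_id``, ``diagnosis_date``) and
        ``claims`` (``patient_id``, ``setting``, ``service_date``, ``code``)
        DataFrames.

    Returns
    -------
    DataFrame indexed by ``patient_id`` with one 0/1 column per catalog
    condition plus ``n_conditions``. Deterministic and invariant to claims
    row order.
    """
    policy = policy or AscertainmentPolicy()
    catalog = catalog or ConditionCatalog()
    registry = dataset.registry
    claims = dataset.claims

    pids = pd.Index(registry["patient_id"], name="patient_id")
    profiles = pd.DataFrame(0, index=pids, columns=list(catalog.conditions), dtype=np.int8)

    if len(claims):
        diag = registry.set_index("patient_id")["diagnosis_date"]
        diag = pd.to_datetime(diag)
        cl = claims[["patient_id", "setting", "service_date", "code"]].copy()
        cl["service_date"] = pd.to_datetime(cl["service_date"])
        cl["diag"] = cl["patient_id"].map(diag)

        late = cl["service_date"] >= cl["diag"]
        if late.any():
            logger.warning("excluding %d claim(s) dated on/after diagnosis", int(late.sum()))
            cl = cl[~late]

        # calendar-month window bounds, computed once per distinct diagnosis date
        uniq_diag = pd.Series(cl["diag"].unique())
        starts = uniq_diag - pd.DateOffset(months=policy.window_months)
        ends = uniq_diag - pd.DateOffset(months=policy.washout_months)
        start_map = pd.Series(starts.values, index=uniq_diag.values)
        end_map = pd.Series(ends.values, index=uniq_diag.values)
        cl["win_start"] = cl["diag"].map(start_map)
        cl["win_end"] = cl["diag"].map(end_map)
        cl = cl[(cl["service_date"] >= cl["win_start"]) & (cl["service_date"] < cl["win_end"])]

        if len(cl):
            # map codes to conditions on unique codes only, then explode
            code_conds = {c: catalog.conditions_for_code(c) for c in cl["code"].unique()}
            cl["conds"] = cl["code"].map(code_conds)
            cl = cl[cl["conds"].map(len) > 0]
            cl = cl.explode("conds").rename(columns={"conds": "condition"})

            inpat = cl[cl["setting"] == "inpatient"]
            got_in = inpat.groupby(["patient_id", "condition"]).size()
            got_in = got_in[got_in >= policy.inpatient_min_claims]

            outp = cl[cl["setting"] == "outpatient"]
            g = outp.groupby(["patient_id", "condition"])["service_date"]
            agg = g.agg(["count", "min", "max"])
            span_days = (agg["max"] - agg["min"]).dt.days
            got_out = agg[
                (agg["count"] >= policy.outpatient_min_claims)
                & (span_days > policy.outpatient_min_gap_days)
            ]

            present = got_in.index.union(got_out.index)
            if len(present):
                rows = present.get_level_values(0)
                cols = present.get_level_values(1)
                keep = rows.isin(profiles.index)
                arr = profiles.to_numpy()
                ri = profiles.index.get_indexer(rows[keep])
                ci = profiles.columns.get_indexer(cols[keep])
                arr[ri, ci] = 1
                profiles.iloc[:, :] = arr

    profiles["n_conditions"] = profiles[list(catalog.conditions)].sum(axis=1).astype(int)
    return profiles


def n_condition_band(n: int) -> str:
    """Band label for a count of comorbid conditions (0/1/2/3/4+)."""
    return str(n) if n < 4 else "4+"


def prevalence_table(
    profiles: pd.DataFrame,
    grouping: pd.Series | None = None,
    suppress_below: int = 5,
) -> pd.DataFrame:
    """Per-cohort condition prevalence and condition-count bands.

    Parameters
    ----------
    profiles
        Output of :func:`build_profiles`.
    grouping
        Cohort label per patient (aligned with ``profiles.index``); omitted
        means a single pooled cohort.
    suppress_below
        Cells with ``0 < count < suppress_below`` are masked (count and
        percentage set to missing, ``suppressed`` flag raised), mirroring
        the small-cell disclosure rule of registry reporting.

    Returns
    -------
    Tidy DataFrame with columns ``cohort, row, count, pct, suppressed``;
    rows are the 18 conditions and the bands ``0/1/2/3/4+``. Percentages
    are rounded to one decimal.
    """
    if profiles.empty:
        logger.warning("empty profile set: returning empty prevalence table")
        return pd.DataFrame(columns=["cohort", "row", "count", "pct", "suppressed"])
    if grouping is None:
        grouping = pd.Series("all", index=profiles.index)
    grouping = grouping.reindex(profiles.index)
    conds = [c for c in profiles.columns if c != "n_conditions"]

    records = []
    for label, idx in profiles.groupby(grouping).groups.items():
        sub = profiles.loc[idx]
        n = len(sub)
        bands = sub["n_conditions"].map(n_condition_band).value_counts()
        for band in BANDS:
            records.append((label, f"n_conditions={band}", int(bands.get(band, 0)), n))
        for cond in conds:
            records.append((label, cond, int(sub[cond].sum()), n))

    out = pd.DataFrame(records, columns=["cohort", "row", "count", "n"])
    out["pct"] = (100.0 * out["count"] / out["n"]).round(1)
    out["suppressed"] = (out["count"] > 0) & (out["count"] < suppress_below)
    out.loc[out["suppressed"], ["count", "pct"]] = pd.NA
    return out.drop(columns="n")
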