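"""Cause-of-death classification and outcome construction.

Deaths are classified as death from the index cancer vs death from other
causes with a simplified SEER-style rule: the underlying-cause code is
matched by prefix against the index site's own code family (plus a small
set of ill-defined codes attributable to any index cancer). Everything
else is a noncancer death.

Two outcome representations are derived from the classification:

* cause-specific survival data for index training — noncancer death is
  the event; cancer death and loss to follow-up are censoring; and
* competing-risks data for prognosis — both death causes are events.

Patients without a death record inside the death-data horizon are
considered alive and censored at their enrollment last-seen date (capped
at the death horizon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["CauseMap", "classify_death", "build_outcomes", "EVENT_LABELS"]

EVENT_LABELS = ("noncancer_death", "cancer_death", "censored")

# sentinel prefix: synthetic "index-cancer" cause codes are attributable to
# every site, so generated data can exercise the classifier directly
_SENTINEL_INDEX_CANCER = "ZC"

_DEFAULT_SITE_CODES: dict[str, tuple[str, ...]] = {
    "breast": ("174", "175"),
    "colorectal": ("153", "154"),
    "liver": ("155",),
    "lung": ("162",),
    "oral": ("140", "141", "142", "143", "144", "145", "146", "147", "148", "149"),
}

# ill-defined / unknown-primary codes attributed to the index cancer
_DEFAULT_SHARED_CODES: tuple[str, ...] = ("199", "1991", _SENTINEL_INDEX_CANCER)


@dataclass(frozen=True)
class CauseMap:
    """Site → underlying-cause code prefixes counted as index-cancer death."""

    site_codes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_SITE_CODES.items()}
    )
    shared_codes: tuple[str, ...] = _DEFAULT_SHARED_CODES

    def prefixes_for(self, site: str) -> tuple[str, ...]:
        if site not in self.site_codes:
            raise KeyError(f"no cause-of-death entry for site {site!r}")
        return self.site_codes[site] + self.shared_codes

    @classmethod
    def from_yaml(cls, path) -> "CauseMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            site_codes={k: tuple(v) for k, v in raw["site_codes"].items()},
            shared_codes=tuple(raw.get("shared_codes", _DEFAULT_SHARED_CODES)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "site_codes": {k: list(v) for k, v in self.site_codes.items()},
                    "shared_codes": list(self.shared_codes),
                },
                fh,
                sort_keys=False,
            )


def classify_death(cause_code: str, site: str, cause_map: CauseMap | None = None) -> str:
    """Classify one death: ``"cancer_death"`` iff the underlying cause
    matches the index site's entry (or a shared attributable code)."""
    cause_map = cause_map or CauseMap()
    code = str(cause_code).replace(".", "").strip().upper()
    prefixes = cause_map.prefixes_for(site)
    if any(code.startswith(p) for p in prefixes):
        return "cancer_death"
    return "noncancer_death"


def build_outcomes(
    dataset,
    cause_map: CauseMap | None = None,
    death_horizon=None,
    enrollment_horizon=None,
) -> pd.DataFrame:
    """Build one survival outcome per registry patient.

    Parameters
    ----------
    dataset
        Object with ``registry`` (``patient_id, site, diagnosis_date``),
        ``deaths`` (``patient_id, death_date, cause_code``) and
        ``enrollment`` (``patient_id, last_seen``) DataFrames.
    death_horizon, enrollment_horizon
        Calendar ends of the death data and of enrollment coverage; default
        to the maxima observed in the respective tables.

    Returns
    -------
    DataFrame ``patient_id, time_days, event, censor_source`` — exactly one
    row per registry patient. ``event`` is ``noncancer_death``,
    ``cancer_death`` or ``censored``; censored patients carry
    ``censor_source`` ``admin_end`` or ``lost_to_followup``. Deaths dated
    before diagnosis are rejected (logged) and the patient censored at
    0 days with source ``lost_to_followup``.
    """
    cause_map = cause_map or CauseMap()
    reg = dataset.registry[["patient_id", "site", "diagnosis_date"]].copy()
    reg["diagnosis_date"] = pd.to_datetime(reg["diagnosis_date"])

    deaths = dataset.deaths.copy()
    deaths["death_date"] = pd.to_datetime(deaths["death_date"])
    if death_horizon is None:
        death_horizon = deaths["death_date"].max() if len(deaths) else reg["diagnosis_date"].max()
    death_horizon = pd.Timestamp(death_horizon)
    deaths = deaths[deaths["death_date"] <= death_horizon]

    enr = dataset.enrollment.copy()
    enr["last_seen"] = pd.to_datetime(enr["last_seen"])
    if enrollment_horizon is None:
        enrollment_horizon = enr["last_seen"].max() if len(enr) else death_horizon
    enrollment_horizon = pd.Timestamp(enrollment_horizon)

    df = reg.merge(deaths, on="patient_id", how="left").merge(enr, on="patient_id", how="left")

    missing_enroll = df["last_seen"].isna() & df["death_date"].isna()
    if missing_enroll.any():
        logger.warning(
            "%d patient(s) absent from both death and enrollment data; "
            "censored at diagnosis + 0 days (linkage gap)",
            int(missing_enroll.sum()),
        )

    dead = df["death_date"].notna()
    pre_diag = dead & (df["death_date"] < df["diagnosis_date"])
    if pre_diag.any():
        for pid in df.loc[pre_diag, "patient_id"]:
            logger.error("death before diagnosis for %s: record rejected", pid)
        dead &= ~pre_diag

    event = pd.Series("censored", index=df.index)
    if dead.any():
        event.loc[dead] = [
            classify_death(c, s, cause_map)
            for c, s in zip(df.loc[dead, "cause_code"], df.loc[dead, "site"])
        ]

    censor_date = df["last_seen"].fillna(df["diagnosis_date"]).clip(upper=death_horizon)
    end = df["death_date"].where(dead, censor_date)
    time_days = (end - df["diagnosis_date"]).dt.days.clip(lower=0)

    censor_source = pd.Series(pd.NA, index=df.index, dtype="object")
    admin_cut = min(enrollment_horizon, death_horizon)
    censor_source.loc[~dead] = "lost_to_followup"
    censor_source.loc[(~dead) & (censor_date >= admin_cut)] = "admin_end"

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "time_days": time_days.astype(int),
            "event": event,
            "censor_source": censor_source,
        }
    )
    assert len(out) == len(reg)
    return out
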