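"""Synthetic linked registry / claims / death data with known ground truth.

Real construction of a cancer-comorbidity index runs on the linkage of a
cancer registry, an insurance-claims database, and a cause-of-death
registry — data that live behind restricted research enclaves. This module
generates a statistically analogous linkage with *known* comorbidity truth
and known cause-specific hazards, so every downstream stage (claims
ascertainment, endpoint classification, index fitting, prognosis tables)
can be tested for parameter recovery without any external data.

Generative model
----------------
* Comorbidity presence: a latent-threshold (Gaussian copula) draw with a
  single exchangeable correlation knob; marginal prevalences are exact.
* Claims: for each present condition, a homogeneous Poisson stream of
  inpatient and outpatient claims over a configurable pre-diagnosis
  horizon, ending at the 6-month washout; with probability
  ``washout_leak_rate`` a condition instead emits claims *only inside*
  the washout (a recent-onset condition invisible to a compliant
  ascertainment rule). Unmapped background claims add realistic noise.
* Death: two competing exponential cause-specific hazards. The noncancer
  hazard is ``baseline × exp(age·w_age + male·w_sex + Σ true_weights)``
  over present conditions; the cancer hazard depends on site and stage.
  Deaths past the death-data horizon are unobserved (patient "alive");
  the living are administratively censored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._reference_tables import CONDITIONS, pooled_cancer_prevalence
from ._reference_tables import PUBLISHED_MAIN_EFFECTS
from .claims_comorbidity import ConditionCatalog

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "LinkedDataset", "generate_cohort", "generate_noncancer_arm"]

SITES: tuple[str, ...] = ("breast", "colorectal", "liver", "lung", "oral")
STAGES: tuple[str, ...] = ("localized", "regional", "distant", "others")
AGE_BANDS: dict[str, tuple[int, int]] = {
    "15-64": (15, 64),
    "65-74": (65, 74),
    "75-84": (75, 84),
    "85-94": (85, 94),
}

_DEFAULT_SITE_MIX = {
    "breast": 16_734, "colorectal": 65_771, "liver": 57_201, "lung": 64_196, "oral": 14_351,
}
_tot = sum(_DEFAULT_SITE_MIX.values())
_DEFAULT_SITE_MIX = {k: v / _tot for k, v in _DEFAULT_SITE_MIX.items()}

# per-site, per-stage annual cancer-death hazards, tuned so long-run
# cause-of-death fractions resemble the published cohorts (liver and lung
# dominated by cancer death, breast mostly surviving)
_DEFAULT_CANCER_HAZARD: dict[str, dict[str, float]] = {
    "breast": {"localized": 0.01, "regional": 0.03, "distant": 0.25, "others": 0.04},
    "colorectal": {"localized": 0.03, "regional": 0.08, "distant": 0.50, "others": 0.10},
    "liver": {"localized": 0.15, "regional": 0.40, "distant": 1.20, "others": 0.30},
    "lung": {"localized": 0.12, "regional": 0.35, "distant": 1.00, "others": 0.35},
    "oral": {"localized": 0.05, "regional": 0.12, "distant": 0.60, "others": 0.12},
}

# underlying-cause codes emitted on death: the index cancer's own ICD-9
# family, or a rotating set of common noncancer causes
_SITE_DEATH_CODE: dict[str, str] = {
    "breast": "1749", "colorectal": "1539", "liver": "1550", "lung": "1629", "oral": "1459",
}
_NONCANCER_DEATH_CODES: tuple[str, ...] = ("4280", "4349", "486", "5859", "2500")


def _default_true_weights() -> dict[str, float]:
    """Published index weights as generative truth; deleted conditions get 0."""
    w = {c: 0.0 for c in CONDITIONS}
    w.update({c: coef for c, (coef, _) in PUBLISHED_MAIN_EFFECTS.items()})
    return w


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study scenario.

    Defaults reproduce the published study conditions where those are
    stated: site mix from the five cohort sizes, comorbidity prevalences
    pooled over the five cancer cohorts (ages 65-94), true log-hazard
    weights equal to the published index coefficients, and the study
    calendar (diagnoses 2004-2014, enrollment through 2015, death data
    through 2016). Rates without a published value (claims intensities,
    correlation, leak rate) are fixed at values typical of chronic-disease
    claims under universal single-payer insurance; see the methods note.
    """

    n_patients: int = 10_000
    site_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SITE_MIX))
    sex_mix: dict[str, float] = field(default_factory=lambda: {"female": 0.5, "male": 0.5})
    age_distribution: dict[str, float] = field(
        default_factory=lambda: {"15-64": 0.55, "65-74": 0.25, "75-84": 0.15, "85-94": 0.05}
    )
    stage_mix: dict[str, float] = field(
        default_factory=lambda: {"localized": 0.35, "regional": 0.30, "distant": 0.20, "others": 0.15}
    )
    comorbidity_prevalence: dict[str, float] = field(default_factory=pooled_cancer_prevalence)
    comorbidity_correlation: float = 0.2
    claims_rate: dict[str, float] = field(
        default_factory=lambda: {"inpatient": 0.3, "outpatient": 4.0}
    )  # expected claims per present condition per year, by setting
    claims_horizon_months: int = 84  # pre-diagnosis span over which claims are emitted
    washout_leak_rate: float = 0.05
    background_claims_rate: float = 0.5  # unmapped outpatient claims per patient-year
    true_weights: dict[str, float] = field(default_factory=_default_true_weights)
    age_weight: float = 0.06  # per year, centred at 65
    sex_weight: float = 0.49  # male indicator
    noncancer_baseline: float = 0.015  # annual hazard at reference covariates
    cancer_hazard: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in _DEFAULT_CANCER_HAZARD.items()}
    )
    study_start: str = "2004-01-01"
    study_end: str = "2014-12-31"
    admin_end: str = "2015-12-31"  # enrollment (beneficiary registry) horizon
    death_horizon: str = "2016-12-31"  # cause-of-death data horizon
    lost_followup_rate: float = 0.0  # fraction of patients leaving enrollment early
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, mix in (
            ("site_mix", self.site_mix),
            ("sex_mix", self.sex_mix),
            ("age_distribution", self.age_distribution),
            ("stage_mix", self.stage_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, not 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative proportions")
        unknown = set(self.true_weights) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition name(s) in true_weights: {sorted(unknown)}")
        unknown = set(self.comorbidity_prevalence) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition name(s) in comorbidity_prevalence: {sorted(unknown)}")
        for c, p in self.comorbidity_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {c} outside [0, 1]: {p}")
        if not 0.0 <= self.comorbidity_correlation < 1.0:
            raise ValueError("comorbidity_correlation must be in [0, 1)")
        for k, v in self.claims_rate.items():
            if v < 0:
                raise ValueError(f"negative claims rate for {k}")
        if self.noncancer_baseline < 0:
            raise ValueError("noncancer_baseline must be nonnegative")

    def with_(self, **kw) -> "ScenarioConfig":
        """Copy with replaced fields."""
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


REGISTRY_COLUMNS = ["patient_id", "sex", "birth_date", "site", "diagnosis_date", "stage", "histology"]
CLAIMS_COLUMNS = ["patient_id", "setting", "service_date", "code"]
DEATHS_COLUMNS = ["patient_id", "death_date", "cause_code"]
ENROLLMENT_COLUMNS = ["patient_id", "last_seen"]


@dataclass
class LinkedDataset:
    """The three-way linkage plus enrollment and the generator's truth table."""

    registry: pd.DataFrame
    claims: pd.DataFrame
    deaths: pd.DataFrame
    enrollment: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> "LinkedDataset":
        ids = set(self.registry["patient_id"])
        for name, df, col in (
            ("claims", self.claims, "patient_id"),
            ("deaths", self.deaths, "patient_id"),
            ("enrollment", self.enrollment, "patient_id"),
        ):
            stray = set(df[col]) - ids
            if stray:
                raise ValueError(f"{name} references unknown patient ids, e.g. {sorted(stray)[:3]}")
        if self.deaths["patient_id"].duplicated().any():
            raise ValueError("multiple death records for one patient")
        if self.truth is not None and set(self.truth["patient_id"]) != ids:
            raise ValueError("truth table does not cover the registry exactly")
        merged = self.deaths.merge(
            self.registry[["patient_id", "diagnosis_date"]], on="patient_id"
        )
        if len(merged):
            bad = pd.to_datetime(merged["death_date"]) < pd.to_datetime(merged["diagnosis_date"])
            if bad.any():
                raise ValueError(f"{int(bad.sum())} death(s) precede diagnosis")
        return self

    def write_csv(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "registry.csv": self.registry,
            "claims.csv": self.claims,
            "deaths.csv": self.deaths,
            "enrollment.csv": self.enrollment,
        }
        if self.truth is not None:
            tables["truth.csv"] = self.truth
        for name, df in tables.items():
            p = outdir / name
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def read_csv(cls, indir) -> "LinkedDataset":
        indir = Path(indir)
        expected = {
            "registry.csv": REGISTRY_COLUMNS,
            "claims.csv": CLAIMS_COLUMNS,
            "deaths.csv": DEATHS_COLUMNS,
            "enrollment.csv": ENROLLMENT_COLUMNS,
        }
        frames = {}
        for name, cols in expected.items():
            df = pd.read_csv(indir / name, dtype={"code": str, "cause_code": str})
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{name} missing column(s): {sorted(missing)}")
            frames[name.removesuffix(".csv")] = df
        truth_path = indir / "truth.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else None
        return cls(
            registry=frames["registry"],
            claims=frames["claims"],
            deaths=frames["deaths"],
            enrollment=frames["enrollment"],
            truth=truth,
        ).validate()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def sample_true_profiles(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent-threshold comorbidity draw: ``(n, 18)`` 0/1 array.

    ``Z_j = √ρ·G + √(1−ρ)·E_j`` with shared ``G`` induces exchangeable
    positive association while keeping each marginal prevalence exact:
    condition ``j`` is present iff ``Z_j`` exceeds its normal quantile.
    """
    from scipy.stats import norm

    n = config.n_patients
    rho = config.comorbidity_correlation
    g = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(CONDITIONS)))
    z = np.sqrt(rho) * g[:, None] + np.sqrt(1.0 - rho) * eps
    p = np.array([config.comorbidity_prevalence.get(c, 0.0) for c in CONDITIONS])
    with np.errstate(divide="ignore"):
        thresh = norm.ppf(1.0 - p)  # +inf where p == 0
    return (z > thresh[None, :]).astype(np.int8)


def _draw_categorical(rng, mix: dict[str, float], n: int) -> np.ndarray:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return np.array(keys)[rng.choice(len(keys), size=n, p=probs)]


def _emit_condition_claims(
    config: ScenarioConfig,
    rng: np.random.Generator,
    pids: np.ndarray,
    diag: pd.Series,
    profiles: np.ndarray,
    catalog: ConditionCatalog,
) -> pd.DataFrame:
    """Poisson claims per (patient, present condition), split by setting."""
    diag_dt = pd.to_datetime(diag)
    washout_start = (diag_dt - pd.DateOffset(months=6)).to_numpy()
    horizon_start = (diag_dt - pd.DateOffset(months=config.claims_horizon_months)).to_numpy()
    diag_np = diag_dt.to_numpy()

    pat_idx, cond_idx = np.nonzero(profiles)
    n_pairs = len(pat_idx)
    if n_pairs == 0:
        return pd.DataFrame(columns=CLAIMS_COLUMNS)

    leak = rng.random(n_pairs) < config.washout_leak_rate
    # interval per pair: [horizon_start, washout_start) normally,
    # [washout_start, diagnosis) for washout-leaking conditions
    lo = np.where(leak, washout_start[pat_idx], horizon_start[pat_idx])
    hi = np.where(leak, diag_np[pat_idx], washout_start[pat_idx])
    span_days = (hi - lo) / np.timedelta64(1, "D")
    span_years = span_days / 365.25

    frames = []
    for setting, rate in config.claims_rate.items():
        counts = rng.poisson(rate * span_years)
        total = int(counts.sum())
        if total == 0:
            continue
        rep = np.repeat(np.arange(n_pairs), counts)
        offs = np.floor(rng.random(total) * span_days[rep]).astype("timedelta64[D]")
        dates = lo[rep] + offs
        # one representative code per claim, drawn from the condition's prefixes
        prefix_lists = [catalog.code_map[c] for c in CONDITIONS]
        max_len = max(len(p) for p in prefix_lists)
        pad = np.empty((len(CONDITIONS), max_len), dtype=object)
        lens = np.empty(len(CONDITIONS), dtype=int)
        for i, plist in enumerate(prefix_lists):
            lens[i] = len(plist)
            pad[i, : len(plist)] = plist
            pad[i, len(plist):] = plist[0]
        ci = cond_idx[rep]
        pick = np.floor(rng.random(total) * lens[ci]).astype(int)
        codes = pad[ci, pick]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids[pat_idx[rep]],
                    "setting": setting,
                    "service_date": dates,
                    "code": codes,
                }
            )
        )
    if config.background_claims_rate > 0:
        years = config.claims_horizon_months / 12.0
        counts = rng.poisson(config.background_claims_rate * years, size=len(pids))
        total = int(counts.sum())
        if total:
            rep = np.repeat(np.arange(len(pids)), counts)
            span = (diag_np - horizon_start) / np.timedelta64(1, "D")
            offs = np.floor(rng.random(total) * span[rep]).astype("timedelta64[D]")
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pids[rep],
                        "setting": "outpatient",
                        "service_date": horizon_start[rep] + offs,
                        "code": "7999",  # ill-defined, unmapped
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=CLAIMS_COLUMNS)
    claims = pd.concat(frames, ignore_index=True)
    claims["service_date"] = pd.to_datetime(claims["service_date"]).dt.strftime("%Y-%m-%d")
    return claims.sort_values(["patient_id", "service_date", "code"], kind="stable").reset_index(
        drop=True
    )[CLAIMS_COLUMNS]


def generate_cohort(
    config: ScenarioConfig, catalog: ConditionCatalog | None = None
) -> LinkedDataset:
    """Generate a linked cancer cohort under ``config``.

    Deterministic: the same config (including its ``seed``) yields
    byte-identical tables.
    """
    catalog = catalog or ConditionCatalog()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = np.array([f"P{i:07d}" for i in range(1, n + 1)])

    site = _draw_categorical(rng, config.site_mix, n)
    sex = _draw_categorical(rng, config.sex_mix, n)
    band = _draw_categorical(rng, config.age_distribution, n)
    lo = np.array([AGE_BANDS[b][0] for b in band])
    hi = np.array([AGE_BANDS[b][1] for b in band])
    age = rng.integers(lo, hi + 1)
    stage = _draw_categorical(rng, config.stage_mix, n)

    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    diag_days = rng.integers(0, (end - start).days + 1, size=n)
    diag = pd.Series(start + pd.to_timedelta(diag_days, unit="D"))

    histology = np.where(
        site == "lung",
        np.array(["ADC", "SCC", "SCLC", "other"])[rng.choice(4, size=n, p=[0.5, 0.2, 0.1, 0.2])],
        "NOS",
    )

    profiles = sample_true_profiles(config, rng)

    # competing exponential event times (years since diagnosis)
    weights = np.array([config.true_weights.get(c, 0.0) for c in CONDITIONS])
    lin = (
        profiles @ weights
        + config.age_weight * (age - 65)
        + config.sex_weight * (sex == "male")
    )
    h_nc = config.noncancer_baseline * np.exp(lin)
    h_c = np.array([config.cancer_hazard[s][st] for s, st in zip(site, stage)])

    def _exp_draw(h):
        with np.errstate(divide="ignore"):
            scale = np.where(h > 0, 1.0 / np.where(h > 0, h, 1.0), np.inf)
        u = rng.random(len(h))
        return np.where(np.isinf(scale), np.inf, -np.log1p(-u) * scale)

    t_nc = _exp_draw(h_nc)
    t_c = _exp_draw(h_c)
    true_time = np.minimum(t_nc, t_c)
    true_cause = np.where(t_c <= t_nc, "cancer", "noncancer")
    true_days = np.where(np.isinf(true_time), np.inf, np.ceil(true_time * 365.25))

    death_horizon = pd.Timestamp(config.death_horizon)
    # cap date arithmetic at 100 years: anything beyond the death horizon is
    # unobserved anyway, and huge exponential draws overflow datetime64
    capped_days = np.where(np.isinf(true_days), 36525, np.minimum(true_days, 36525))
    death_date = diag + pd.to_timedelta(capped_days, unit="D")
    observed_death = (~np.isinf(true_days)) & (death_date <= death_horizon)

    cause_code = np.where(
        true_cause == "cancer",
        pd.Series(site).map(_SITE_DEATH_CODE).to_numpy(),
        _NONCANCER_DEATH_CODES[0],
    )
    # rotate noncancer causes for realism
    nc_mask = (true_cause == "noncancer") & observed_death
    cause_code = cause_code.astype(object)
    if nc_mask.any():
        cause_code[nc_mask] = rng.choice(_NONCANCER_DEATH_CODES, size=int(nc_mask.sum()))

    admin_end = pd.Timestamp(config.admin_end)
    last_seen = pd.Series(admin_end, index=range(n))
    if config.lost_followup_rate > 0:
        lost = rng.random(n) < config.lost_followup_rate
        frac = rng.random(n)
        span = (admin_end - diag).dt.days.to_numpy()
        early = diag + pd.to_timedelta(np.floor(frac * span), unit="D")
        last_seen = last_seen.where(~lost, early)

    registry = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": sex,
            # ceil keeps the recomputed fractional age on/above the drawn
            # integer age, so band edges round-trip exactly
            "birth_date": (diag - pd.to_timedelta(np.ceil(age * 365.25), unit="D")).dt.strftime("%Y-%m-%d"),
            "site": site,
            "diagnosis_date": diag.dt.strftime("%Y-%m-%d"),
            "stage": stage,
            "histology": histology,
        }
    )
    deaths = pd.DataFrame(
        {
            "patient_id": pids[observed_death],
            "death_date": death_date[observed_death].dt.strftime("%Y-%m-%d"),
            "cause_code": cause_code[observed_death],
        }
    ).reset_index(drop=True)
    enrollment = pd.DataFrame(
        {"patient_id": pids, "last_seen": last_seen.dt.strftime("%Y-%m-%d")}
    )
    claims = _emit_condition_claims(config, rng, pids, diag, profiles, catalog)

    truth = pd.DataFrame(profiles, columns=list(CONDITIONS))
    truth.insert(0, "patient_id", pids)
    truth["true_event_days"] = np.where(np.isinf(true_days), -1, true_days).astype(int)
    truth["true_cause"] = true_cause
    truth["observed_death"] = observed_death.astype(int)

    ds = LinkedDataset(
        registry=registry, claims=claims, deaths=deaths, enrollment=enrollment, truth=truth
    )
    return ds.validate()


def recovery_scenario(n_patients: int = 50_000, seed: int = 0) -> ScenarioConfig:
    """Parameter-recovery study design.

    Nonzero log-hazard weights sit on eight conditions kept common enough
    (prevalence >= 0.12) that the training fold carries the information to
    pin each weight down, including one protective condition (Ulcer,
    -0.30) that the negative-deletion loop must remove. The noncancer
    baseline is raised and the cancer hazards halved relative to the
    cohort-emulation defaults so noncancer deaths — the training events —
    are plentiful; rare conditions keep weight zero because no estimator
    can localise a coefficient observed in a handful of subjects.
    """
    prevalence = pooled_cancer_prevalence()
    prevalence.update(
        {
            "CHF": 0.15, "CVD": 0.15, "COPD": 0.20, "Dementia": 0.12,
            "DM W/O CC": 0.25, "DM W CC": 0.12, "CRF": 0.12, "Ulcer": 0.20,
        }
    )
    weights = {c: 0.0 for c in CONDITIONS}
    weights.update(
        {
            "CHF": 0.75, "CVD": 0.37, "COPD": 0.26, "Dementia": 0.66,
            "DM W/O CC": 0.28, "DM W CC": 0.38, "CRF": 0.80, "Ulcer": -0.30,
        }
    )
    hazards = {s: {st: 0.5 * v for st, v in d.items()} for s, d in _DEFAULT_CANCER_HAZARD.items()}
    return ScenarioConfig(
        n_patients=n_patients,
        comorbidity_prevalence=prevalence,
        comorbidity_correlation=0.1,
        true_weights=weights,
        washout_leak_rate=0.02,
        noncancer_baseline=0.04,
        cancer_hazard=hazards,
        seed=seed,
    )


def generate_noncancer_arm(
    config: ScenarioConfig, catalog: ConditionCatalog | None = None
) -> LinkedDataset:
    """Generate a cancer-free comparison arm.

    The same claims machinery runs, but there is no cancer: each subject
    gets an *index date* sampled uniformly over the study window (the
    ascertainment window anchor), the cancer hazard is zero, and the
    registry-like table carries ``site == "noncancer"`` with no stage.
    """
    cfg = config.with_(
        cancer_hazard={s: {st: 0.0 for st in STAGES} for s in SITES},
        site_mix={"breast": 1.0, "colorectal": 0.0, "liver": 0.0, "lung": 0.0, "oral": 0.0},
    )
    ds = generate_cohort(cfg, catalog=catalog)
    ds.registry["site"] = "noncancer"
    ds.registry["stage"] = "none"
    ds.registry["histology"] = "none"
    if len(ds.deaths):
        assert (ds.truth.set_index("patient_id").loc[ds.deaths["patient_id"], "true_cause"] == "noncancer").all()
    return ds
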