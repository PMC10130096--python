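"""Construction of the cancer comorbidity index (TCCI).

The index is built from a Cox model for time from cancer diagnosis to
*noncancer* death whose covariates are age, sex, all 18 comorbid
conditions, and every pairwise interaction among the 11 most common
conditions ("Main18&11", 55 pairs). The fitted model is then pruned by
*negative deletion*: any condition whose main-effect coefficient is
negative is removed outright — together with every interaction involving
it — and the model refitted, iterating until all retained main effects
are nonnegative. A patient's TCCI is the sum of the retained coefficients
over their present conditions and condition pairs (age and sex are
reported but never scored).

Comorbidity levels then code each patient 0 (none of the 18 conditions),
2 (TCCI > 0.66, or any severe illness — CHF, COPD, dementia, CRF,
moderate/severe liver disease — present), or 1 otherwise.

Train/validation/test folds (1/2, 1/4, 1/4) are assigned by a pure hash
of patient id and seed, which makes fold membership automatically
consistent across any system of nested cohort subsets: restricting a
cohort restricts its folds.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._reference_tables import (
    CONDITIONS,
    PUBLISHED_AGE_SEX,
    PUBLISHED_DELETED,
    PUBLISHED_INTERACTIONS,
    PUBLISHED_MAIN_EFFECTS,
)
from .claims_comorbidity import ConditionCatalog
from .survival_core import FittedCox, auc_se, fit_cox, td_auc

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "IndexModel",
    "select_top11",
    "build_design",
    "negative_deletion_fit",
    "tcci_score",
    "score_profiles",
    "assign_level",
    "assign_levels",
    "nested_split",
    "validate_index",
    "published_model",
]

FOLDS = ("train", "validation", "test")
DAYS_PER_YEAR = 365.25


def _pair_name(a: str, b: str) -> str:
    return f"{a}*{b}"


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the index model before deletion."""

    main_conditions: tuple[str, ...] = CONDITIONS
    interaction_pairs: tuple[tuple[str, str], ...] = ()
    include_age_sex: bool = True

    @classmethod
    def main18_and_11(cls, top11: list[str] | tuple[str, ...]) -> "ModelSpec":
        """All 18 main effects + the 55 pairs among the 11 most common."""
        if len(top11) != 11:
            raise ValueError(f"expected 11 common conditions, got {len(top11)}")
        pairs = tuple(combinations(tuple(top11), 2))
        return cls(main_conditions=CONDITIONS, interaction_pairs=pairs)

    @classmethod
    def main11(cls, top11) -> "ModelSpec":
        return cls(main_conditions=tuple(top11), interaction_pairs=())

    @classmethod
    def main18(cls) -> "ModelSpec":
        return cls(main_conditions=CONDITIONS, interaction_pairs=())


@dataclass
class DesignMatrix:
    """Design for index fitting: named columns + the training outcome."""

    X: pd.DataFrame
    time: np.ndarray
    event: np.ndarray  # 1 = noncancer death
    condition_terms: list[str]
    interaction_terms: list[tuple[str, str]]
    dropped_terms: list[str] = field(default_factory=list)


def select_top11(profiles: pd.DataFrame, n_top: int = 11) -> list[str]:
    """The most common conditions by pooled count, descending.

    Ties are broken alphabetically (logged when they occur). Raises if
    fewer than ``n_top`` conditions are ever present.
    """
    conds = [c for c in profiles.columns if c in CONDITIONS]
    counts = profiles[conds].sum()
    nonzero = counts[counts > 0]
    if len(nonzero) < n_top:
        raise ValueError(
            f"only {len(nonzero)} conditions ever present; cannot select top {n_top}"
        )
    ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
    top = ordered.iloc[:n_top]
    if len(ordered) > n_top and top.iloc[-1] == ordered.iloc[n_top]:
        logger.warning("tie at the top-%d boundary broken alphabetically", n_top)
    return list(top.index)


def build_design(
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    registry: pd.DataFrame,
    spec: ModelSpec,
) -> DesignMatrix:
    """Assemble the named design matrix for a set of patients.

    Age (years at diagnosis) and a male indicator come from the registry;
    condition indicators from the profiles; interaction columns are the
    elementwise products of their parent indicators. Columns that are
    constant in this sample (typically rare pairs that never co-occur)
    are dropped and recorded in ``dropped_terms``.
    """
    reg = registry.set_index("patient_id")
    out = outcomes.set_index("patient_id").loc[profiles.index]
    cols: dict[str, np.ndarray] = {}
    if spec.include_age_sex:
        diag = pd.to_datetime(reg.loc[profiles.index, "diagnosis_date"])
        birth = pd.to_datetime(reg.loc[profiles.index, "birth_date"])
        cols["age"] = ((diag - birth).dt.days / DAYS_PER_YEAR).to_numpy()
        cols["sex"] = (reg.loc[profiles.index, "sex"] == "male").to_numpy(dtype=float)
    for c in spec.main_conditions:
        cols[c] = profiles[c].to_numpy(dtype=float)
    for a, b in spec.interaction_pairs:
        cols[_pair_name(a, b)] = cols[a] * cols[b]

    X = pd.DataFrame(cols, index=profiles.index)
    constant = X.columns[(X.max() - X.min()) == 0].tolist()
    if constant:
        logger.warning("dropping constant design column(s): %s", constant)
        X = X.drop(columns=constant)

    cond_terms = [c for c in spec.main_conditions if c in X.columns]
    pair_terms = [(a, b) for a, b in spec.interaction_pairs if _pair_name(a, b) in X.columns]
    return DesignMatrix(
        X=X,
        time=out["time_days"].to_numpy(dtype=float),
        event=(out["event"] == "noncancer_death").to_numpy(),
        condition_terms=cond_terms,
        interaction_terms=pair_terms,
        dropped_terms=constant,
    )


@dataclass
class IndexModel:
    """A fitted (or published) comorbidity index.

    Scoring uses only ``condition_coefs`` and ``interaction_coefs``;
    ``age_coef``/``sex_coef`` are reported for the underlying survival
    model and used in validation markers, never in the TCCI itself.
    Conditions deleted by the negative-deletion loop contribute zero.
    """

    condition_coefs: dict[str, float]
    interaction_coefs: dict[tuple[str, str], float]
    age_coef: float
    sex_coef: float
    deleted_conditions: tuple[str, ...] = ()
    deletion_history: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)
    fit: FittedCox | None = None

    def __post_init__(self):
        neg = [c for c, v in self.condition_coefs.items() if v < 0]
        if neg:
            raise ValueError(f"retained negative main effect(s): {neg}")
        orphans = [
            (a, b)
            for a, b in self.interaction_coefs
            if a in self.deleted_conditions or b in self.deleted_conditions
        ]
        if orphans:
            raise ValueError(f"interactions outlived a deleted parent: {orphans}")

    # -- plain-text round trip ------------------------------------------------
    def to_text(self, path) -> None:
        lines = [f"age\t{self.age_coef!r}", f"sex\t{self.sex_coef!r}"]
        for c, v in self.condition_coefs.items():
            lines.append(f"{c}\t{v!r}")
        for (a, b), v in self.interaction_coefs.items():
            lines.append(f"{_pair_name(a, b)}\t{v!r}")
        for c in self.deleted_conditions:
            lines.append(f"#deleted\t{c}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "IndexModel":
        cond, inter, deleted = {}, {}, []
        age = sex = 0.0
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, val = line.split("\t")
            if key == "#deleted":
                deleted.append(val)
            elif key == "age":
                age = float(val)
            elif key == "sex":
                sex = float(val)
            elif "*" in key:
                a, b = key.split("*")
                inter[(a, b)] = float(val)
            else:
                cond[key] = float(val)
        return cls(
            condition_coefs=cond,
            interaction_coefs=inter,
            age_coef=age,
            sex_coef=sex,
            deleted_conditions=tuple(deleted),
        )


def published_model() -> IndexModel:
    """The published TCCI weights shipped with the package."""
    return IndexModel(
        condition_coefs={c: v for c, (v, _) in PUBLISHED_MAIN_EFFECTS.items()},
        interaction_coefs={k: v for k, (v, _) in PUBLISHED_INTERACTIONS.items()},
        age_coef=PUBLISHED_AGE_SEX["age"][0],
        sex_coef=PUBLISHED_AGE_SEX["sex"][0],
        deleted_conditions=PUBLISHED_DELETED,
    )


def negative_deletion_fit(design: DesignMatrix, ties: str = "efron") -> IndexModel:
    """Iteratively delete negative-main-effect conditions and refit.

    Each iteration fits the Cox model, finds *all* conditions whose
    main-effect coefficient is negative (exact zeros are kept), deletes
    them and every interaction involving them, and refits; the loop stops
    when no main effect is negative. Age and sex are never deleted.
    Terminates in at most 18 iterations since the deleted set grows
    strictly. Raises if deletion empties the condition set.
    """
    X = design.X.copy()
    cond_terms = list(design.condition_terms)
    pair_terms = list(design.interaction_terms)
    deleted: list[str] = []
    history: list[tuple[int, tuple[str, ...]]] = []

    fitted = None
    for iteration in range(1, len(CONDITIONS) + 2):
        if not cond_terms:
            raise RuntimeError("model degenerate: every condition was deleted")
        fitted = fit_cox(X, design.time, design.event, ties=ties)
        coefs = fitted.coef_series()
        negative = [c for c in cond_terms if coefs[c] < 0]
        if not negative:
            break
        history.append((iteration, tuple(negative)))
        deleted.extend(negative)
        logger.info("iteration %d: deleting %s", iteration, negative)
        cond_terms = [c for c in cond_terms if c not in negative]
        drop_pairs = [(a, b) for a, b in pair_terms if a in negative or b in negative]
        pair_terms = [p for p in pair_terms if p not in drop_pairs]
        drop_cols = negative + [_pair_name(a, b) for a, b in drop_pairs]
        X = X.drop(columns=[c for c in drop_cols if c in X.columns])
    else:
        raise RuntimeError("negative-deletion loop failed to terminate")

    coefs = fitted.coef_series()
    return IndexModel(
        condition_coefs={c: float(coefs[c]) for c in cond_terms},
        interaction_coefs={(a, b): float(coefs[_pair_name(a, b)]) for a, b in pair_terms},
        age_coef=float(coefs.get("age", 0.0)),
        sex_coef=float(coefs.get("sex", 0.0)),
        deleted_conditions=tuple(deleted),
        deletion_history=history,
        fit=fitted,
    )


# ---------------------------------------------------------------------------
# scoring and levels
# ---------------------------------------------------------------------------


def _present_set(profile) -> set[str]:
    if isinstance(profile, (set, frozenset, list, tuple)):
        return set(profile)
    if isinstance(profile, pd.Series):
        return {c for c in CONDITIONS if c in profile.index and profile[c] == 1}
    if isinstance(profile, dict):
        return {c for c, v in profile.items() if v}
    raise TypeError(f"cannot interpret profile of type {type(profile)}")


def tcci_score(profile, model: IndexModel) -> float:
    """TCCI of one patient: sum of retained coefficients over present
    conditions and present condition pairs. Deleted conditions (and age
    and sex) contribute nothing."""
    present = _present_set(profile)
    unknown = present - set(CONDITIONS)
    if unknown:
        raise KeyError(f"unknown condition(s): {sorted(unknown)}")
    score = sum(model.condition_coefs.get(c, 0.0) for c in present)
    score += sum(
        v for (a, b), v in model.interaction_coefs.items() if a in present and b in present
    )
    return float(score)


def score_profiles(profiles: pd.DataFrame, model: IndexModel) -> pd.Series:
    """Vectorised :func:`tcci_score` over a profile table."""
    score = pd.Series(0.0, index=profiles.index)
    for c, v in model.condition_coefs.items():
        if c in profiles.columns:
            score += v * profiles[c]
    for (a, b), v in model.interaction_coefs.items():
        if a in profiles.columns and b in profiles.columns:
            score += v * (profiles[a] * profiles[b])
    return score.rename("tcci")


def assign_level(profile, tcci: float, severe_set=None) -> int:
    """Comorbidity level: 0 none of the 18 conditions; 2 if TCCI > 0.66 or
    a severe illness is present; else 1."""
    severe_set = severe_set if severe_set is not None else ConditionCatalog().severe_set
    present = _present_set(profile)
    if not present:
        return 0
    if tcci > 0.66 or present & set(severe_set):
        return 2
    return 1


def assign_levels(
    profiles: pd.DataFrame, scores: pd.Series, catalog: ConditionCatalog | None = None
) -> pd.DataFrame:
    """Vectorised level assignment; returns ``tcci`` and ``level`` per patient."""
    catalog = catalog or ConditionCatalog()
    conds = [c for c in catalog.conditions if c in profiles.columns]
    any_cond = profiles[conds].sum(axis=1) > 0
    severe = profiles[[c for c in catalog.severe_set if c in profiles.columns]].sum(axis=1) > 0
    level = np.where(~any_cond, 0, np.where((scores > 0.66) | severe, 2, 1))
    return pd.DataFrame({"tcci": scores, "level": level.astype(int)}, index=profiles.index)


# ---------------------------------------------------------------------------
# nested splits
# ---------------------------------------------------------------------------


def _fold_uniform(patient_id: str, seed: int) -> float:
    h = hashlib.blake2b(f"{seed}:{patient_id}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") / 2**64


def nested_split(patient_ids, seed: int) -> pd.Series:
    """Assign each patient to train (1/2), validation (1/4) or test (1/4).

    The assignment is a pure function of (patient id, seed), so for *any*
    subset of patients the subset's folds are the restriction of the
    global assignment — the compatibility the nested cohort-subset design
    requires holds by construction.
    """
    ids = pd.Index(patient_ids)
    if ids.has_duplicates:
        raise ValueError("patient ids must be unique")
    u = np.array([_fold_uniform(str(p), seed) for p in ids])
    fold = np.where(u < 0.5, "train", np.where(u < 0.75, "validation", "test"))
    return pd.Series(fold, index=ids, name="fold")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_index(
    model: IndexModel,
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    registry: pd.DataFrame,
    folds: pd.Series,
    horizons_years=(1, 2, 5),
    train_ids=None,
    mode: str = "integrated_to",
) -> pd.DataFrame:
    """Time-dependent AUC of the index model's linear predictor on the
    validation fold, per site × sex cohort.

    The marker is ``age·β_age + male·β_sex + TCCI``. If ``train_ids`` is
    given, disjointness from the validation fold is asserted (leakage
    guard). Cohorts without usable events at a horizon are skipped with a
    warning. Returns tidy rows ``site, sex, horizon_years, auc, se, n,
    n_events``.
    """
    val_ids = folds.index[folds == "validation"]
    if train_ids is not None:
        overlap = set(val_ids) & set(train_ids)
        assert not overlap, f"training/validation leakage: {len(overlap)} shared ids"

    prof = profiles.loc[profiles.index.intersection(val_ids)]
    reg = registry.set_index("patient_id").loc[prof.index]
    out = outcomes.set_index("patient_id").loc[prof.index]

    diag = pd.to_datetime(reg["diagnosis_date"])
    birth = pd.to_datetime(reg["birth_date"])
    age = (diag - birth).dt.days / DAYS_PER_YEAR
    male = (reg["sex"] == "male").astype(float)
    marker = model.age_coef * age + model.sex_coef * male + score_profiles(prof, model)

    time = out["time_days"].to_numpy(dtype=float)
    event = (out["event"] == "noncancer_death").to_numpy()

    rows = []
    groups = [("all", "all", np.ones(len(prof), dtype=bool))]
    for site in sorted(reg["site"].unique()):
        for sex in sorted(reg["sex"].unique()):
            mask = ((reg["site"] == site) & (reg["sex"] == sex)).to_numpy()
            if mask.any():
                groups.append((site, sex, mask))
    for site, sex, mask in groups:
        for h in horizons_years:
            horizon = h * DAYS_PER_YEAR
            ev_mask = event[mask] & (time[mask] <= horizon)
            n_ev = int(ev_mask.sum())
            if n_ev == 0:
                logger.warning("no events before %sy for %s/%s: skipped", h, site, sex)
                continue
            auc = td_auc(marker.to_numpy()[mask], time[mask], event[mask], horizon, mode=mode)
            n_controls = int((time[mask] > horizon).sum())
            rows.append(
                {
                    "site": site,
                    "sex": sex,
                    "horizon_years": h,
                    "auc": auc,
                    "se": auc_se(auc, n_ev, max(n_controls, 1)),
                    "n": int(mask.sum()),
                    "n_events": n_ev,
                }
            )
    return pd.DataFrame(rows)
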