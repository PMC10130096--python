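"""Index-construction tests: top-11 selection, negative deletion,
TCCI scoring, level assignment, nested splits, and validation guards."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from comorbindex._reference_tables import (
    CONDITIONS,
    PUBLISHED_INTERACTIONS,
    SEVERE_CONDITIONS,
    TOP11_POOLED_COUNTS,
)
from comorbindex import build_outcomes, build_profiles, generate_cohort
from comorbindex.index_builder import (
    IndexModel,
    ModelSpec,
    assign_level,
    assign_levels,
    build_design,
    negative_deletion_fit,
    nested_split,
    published_model,
    score_profiles,
    select_top11,
    tcci_score,
    validate_index,
)
from comorbindex.synthetic_cohort import ScenarioConfig


def profiles_with_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Profile table whose column sums equal the requested counts."""
    n = max(counts.values()) + 1
    data = {c: np.zeros(n, dtype=int) for c in CONDITIONS}
    for c, k in counts.items():
        data[c][:k] = 1
    df = pd.DataFrame(data, index=pd.Index([f"p{i}" for i in range(n)], name="patient_id"))
    df["n_conditions"] = df[list(CONDITIONS)].sum(axis=1)
    return df


class TestTop11:
    def test_published_counts_give_published_order(self):
        # scale the published pooled counts down 10x (order preserved)
        counts = {c: v // 10 for c, v in TOP11_POOLED_COUNTS.items()}
        counts.update({c: 5 for c in CONDITIONS if c not in counts})
        prof = profiles_with_counts(counts)
        assert select_top11(prof) == list(TOP11_POOLED_COUNTS)

    def test_all_equal_counts_alphabetical(self):
        prof = profiles_with_counts({c: 7 for c in CONDITIONS})
        assert select_top11(prof) == sorted(CONDITIONS)[:11]

    def test_permutation_invariant(self):
        counts = {c: v // 10 for c, v in TOP11_POOLED_COUNTS.items()}
        counts.update({c: 5 for c in CONDITIONS if c not in counts})
        prof = profiles_with_counts(counts)
        shuffled = prof.sample(frac=1.0, random_state=0)
        assert select_top11(shuffled) == select_top11(prof)

    def test_too_few_conditions_errors(self):
        prof = profiles_with_counts({"CRF": 5, "CHF": 3})
        with pytest.raises(ValueError, match="cannot select"):
            select_top11(prof)


class TestModelSpec:
    def test_main18_and_11_counts(self):
        spec = ModelSpec.main18_and_11(list(TOP11_POOLED_COUNTS))
        assert len(spec.main_conditions) == 18
        assert len(spec.interaction_pairs) == 55

    def test_wrong_top11_length(self):
        with pytest.raises(ValueError):
            ModelSpec.main18_and_11(["CHF", "CRF"])

    def test_deletion_contract_reproduces_published_pairs(self):
        """Deleting the three dropped commons leaves exactly the 28
        published interaction pairs among the 8 survivors."""
        spec = ModelSpec.main18_and_11(list(TOP11_POOLED_COUNTS))
        deleted = {"Mild LD", "Ulcer", "HT C"}
        survivors = [p for p in spec.interaction_pairs if not (set(p) & deleted)]
        assert len(survivors) == 28
        assert {frozenset(p) for p in survivors} == {
            frozenset(p) for p in PUBLISHED_INTERACTIONS
        }
        commons_left = [c for c in TOP11_POOLED_COUNTS if c not in deleted]
        assert len(list(combinations(commons_left, 2))) == 28


@pytest.fixture(scope="module")
def fitted():
    """Small simulation with one protective and two harmful conditions."""
    prev = {c: 0.0 for c in CONDITIONS}
    prev.update({"CRF": 0.3, "CHF": 0.25, "Ulcer": 0.3, "HT UC": 0.4})
    w = {c: 0.0 for c in CONDITIONS}
    w.update({"CRF": 0.8, "CHF": 0.7, "Ulcer": -0.5, "HT UC": 0.3})
    cfg = ScenarioConfig(
        n_patients=8000, seed=21, comorbidity_prevalence=prev, true_weights=w,
        noncancer_baseline=0.05, washout_leak_rate=0.0,
    )
    ds = generate_cohort(cfg)
    prof = build_profiles(ds)
    out = build_outcomes(ds)
    spec = ModelSpec(
        main_conditions=("CRF", "CHF", "Ulcer", "HT UC"),
        interaction_pairs=(("CRF", "CHF"), ("CRF", "Ulcer"), ("CHF", "Ulcer")),
    )
    design = build_design(prof, out, ds.registry, spec)
    return negative_deletion_fit(design)


class TestNegativeDeletion:
    def test_protective_condition_deleted_with_interactions(self, fitted):
        assert "Ulcer" in fitted.deleted_conditions
        assert "Ulcer" not in fitted.condition_coefs
        assert all("Ulcer" not in pair for pair in fitted.interaction_coefs)

    def test_retained_main_effects_nonnegative(self, fitted):
        assert all(v >= 0 for v in fitted.condition_coefs.values())
        assert fitted.deletion_history  # at least one deletion iteration

    def test_harmful_conditions_recovered(self, fitted):
        assert fitted.condition_coefs["CRF"] == pytest.approx(0.8, abs=0.2)
        assert fitted.condition_coefs["CHF"] == pytest.approx(0.7, abs=0.2)

    def test_all_positive_weights_no_deletions(self):
        prev = {c: 0.0 for c in CONDITIONS}
        prev.update({"CRF": 0.35, "CHF": 0.35})
        w = {c: 0.0 for c in CONDITIONS}
        w.update({"CRF": 0.9, "CHF": 0.8})
        cfg = ScenarioConfig(
            n_patients=6000, seed=22, comorbidity_prevalence=prev, true_weights=w,
            noncancer_baseline=0.05, washout_leak_rate=0.0,
        )
        ds = generate_cohort(cfg)
        design = build_design(
            build_profiles(ds), build_outcomes(ds), ds.registry,
            ModelSpec(main_conditions=("CRF", "CHF"), interaction_pairs=(("CRF", "CHF"),)),
        )
        model = negative_deletion_fit(design)
        assert model.deletion_history == []
        assert model.deleted_conditions == ()


class TestIndexModelInvariants:
    def test_negative_retained_main_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            IndexModel({"CRF": -0.1}, {}, 0.0, 0.0)

    def test_orphan_interaction_rejected(self):
        with pytest.raises(ValueError, match="outlived"):
            IndexModel({"CHF": 0.5}, {("CHF", "CVD"): 0.1}, 0.0, 0.0,
                       deleted_conditions=("CVD",))

    def test_text_round_trip_bit_exact(self, tmp_path):
        model = published_model()
        model.condition_coefs["CRF"] = 0.1 + 0.2  # not exactly representable
        model.to_text(tmp_path / "w.txt")
        back = IndexModel.from_text(tmp_path / "w.txt")
        assert back.condition_coefs == model.condition_coefs
        assert back.interaction_coefs == model.interaction_coefs
        assert back.deleted_conditions == model.deleted_conditions


class TestScoring:
    MODEL = published_model()

    @pytest.mark.parametrize(
        "present,expected",
        [
            (set(), 0.0),
            ({"CRF"}, 0.80),
            ({"CHF", "CVD"}, 0.75 + 0.37 - 0.12),  # pair term included
            ({"Ulcer"}, 0.0),  # deleted condition contributes nothing
        ],
    )
    def test_worked_examples(self, present, expected):
        assert tcci_score(present, self.MODEL) == pytest.approx(expected)

    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError):
            tcci_score({"Gout"}, self.MODEL)

    def test_additivity_over_all_subsets_of_retained_commons(self):
        """score(S) = Σ mains + Σ pair terms, enumerated over all 2^8 subsets."""
        commons = sorted({c for pair in PUBLISHED_INTERACTIONS for c in pair})
        assert len(commons) == 8
        for bits in range(2 ** len(commons)):
            present = {c for i, c in enumerate(commons) if bits >> i & 1}
            expected = sum(self.MODEL.condition_coefs[c] for c in present)
            expected += sum(
                v for (a, b), v in self.MODEL.interaction_coefs.items()
                if a in present and b in present
            )
            assert tcci_score(present, self.MODEL) == pytest.approx(expected, abs=1e-12)

    def test_vectorised_scoring_agrees(self, profiles):
        scores = score_profiles(profiles, self.MODEL)
        sample = profiles.sample(30, random_state=2)
        for pid, row in sample.iterrows():
            present = {c for c in CONDITIONS if row[c] == 1}
            assert scores[pid] == pytest.approx(tcci_score(present, self.MODEL))

    def test_deleting_absent_condition_leaves_score_unchanged(self, profiles):
        pruned = IndexModel(
            condition_coefs={c: v for c, v in self.MODEL.condition_coefs.items() if c != "CRF"},
            interaction_coefs={
                p: v for p, v in self.MODEL.interaction_coefs.items() if "CRF" not in p
            },
            age_coef=self.MODEL.age_coef,
            sex_coef=self.MODEL.sex_coef,
            deleted_conditions=self.MODEL.deleted_conditions + ("CRF",),
        )
        no_crf = profiles[profiles["CRF"] == 0]
        a = score_profiles(no_crf, self.MODEL)
        b = score_profiles(no_crf, pruned)
        pd.testing.assert_series_equal(a, b)


class TestLevels:
    MODEL = published_model()

    def test_spec_examples(self):
        assert assign_level(set(), 0.0) == 0
        assert assign_level({"COPD"}, tcci_score({"COPD"}, self.MODEL)) == 2  # severe override
        assert assign_level({"AMI"}, tcci_score({"AMI"}, self.MODEL)) == 1
        assert assign_level({"CRF"}, tcci_score({"CRF"}, self.MODEL)) == 2  # 0.80 > 0.66
        # deleted-only profile: TCCI 0 but conditions present -> level 1
        assert assign_level({"Ulcer"}, 0.0) == 1

    def test_vectorised_levels_agree(self, profiles, levels):
        sample = profiles.sample(50, random_state=3)
        for pid, row in sample.iterrows():
            present = {c for c in CONDITIONS if row[c] == 1}
            expected = assign_level(present, levels.loc[pid, "tcci"])
            assert levels.loc[pid, "level"] == expected

    def test_level0_iff_no_conditions(self, profiles, levels):
        zero = profiles["n_conditions"] == 0
        assert ((levels["level"] == 0) == zero).all()


class TestNestedSplit:
    def test_deterministic_and_valid(self):
        ids = [f"p{i}" for i in range(1000)]
        a = nested_split(ids, seed=3)
        b = nested_split(ids, seed=3)
        pd.testing.assert_series_equal(a, b)
        assert set(a.unique()) <= {"train", "validation", "test"}

    def test_restriction_property(self):
        ids = [f"p{i}" for i in range(5000)]
        full = nested_split(ids, seed=9)
        rng = np.random.default_rng(0)
        for _ in range(5):
            subset = rng.choice(ids, size=500, replace=False)
            sub = nested_split(subset, seed=9)
            pd.testing.assert_series_equal(sub, full.loc[sub.index], check_names=False)

    def test_fold_proportions(self):
        folds = nested_split([f"p{i}" for i in range(10_000)], seed=1)
        freq = folds.value_counts(normalize=True)
        assert freq["train"] == pytest.approx(0.50, abs=0.02)
        assert freq["validation"] == pytest.approx(0.25, abs=0.02)
        assert freq["test"] == pytest.approx(0.25, abs=0.02)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            nested_split(["a", "a", "b"], seed=0)


class TestValidateIndex:
    def test_leakage_guard(self, cohort, profiles, outcomes):
        folds = nested_split(cohort.registry["patient_id"], seed=2)
        val_ids = folds.index[folds == "validation"]
        with pytest.raises(AssertionError, match="leakage"):
            validate_index(
                published_model(), profiles, outcomes, cohort.registry, folds,
                train_ids=list(val_ids[:5]),
            )

    def test_informative_marker_beats_chance(self, cohort, profiles, outcomes):
        """The generator's weights are the published weights, so the published
        index should discriminate noncancer death on the validation fold."""
        folds = nested_split(cohort.registry["patient_id"], seed=2)
        auc = validate_index(
            published_model(), profiles, outcomes, cohort.registry, folds,
            horizons_years=(5,),
        )
        pooled = auc[(auc["site"] == "all")].iloc[0]
        assert pooled["auc"] - 0.5 > 3 * pooled["se"]
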