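"""Published reference numbers shipped with the package.

Two blocks of constants:

* the published prevalence table of the 18 comorbid conditions among
  Taiwanese patients aged 65-94 with the five most common cancers
  (breast, colorectal, liver, lung, oral) and a matched noncancer cohort,
  used for default simulation margins and for arithmetic self-checks; and
* the published TCCI weights -- the negative-deletion Cox model
  (``Main18&11.ND``) coefficients from which the index is scored.

Counts are stored as printed; percentages are stored as printed (one
decimal, ``None`` where the source suppressed the cell).
"""

from __future__ import annotations

CONDITIONS: tuple[str, ...] = (
    "AMI",
    "Old MI",
    "CHF",
    "PVD",
    "CVD",
    "COPD",
    "Dementia",
    "Paralysis",
    "DM W/O CC",
    "DM W CC",
    "CRF",
    "Mild LD",
    "MS LD",
    "RD",
    "AIDS",
    "Ulcer",
    "HT UC",
    "HT C",
)

SEVERE_CONDITIONS: frozenset[str] = frozenset({"CHF", "COPD", "Dementia", "CRF", "MS LD"})

COHORTS: tuple[str, ...] = ("breast", "colorectal", "liver", "lung", "oral", "noncancer")

COHORT_SIZES: dict[str, int] = {
    "breast": 16_734,
    "colorectal": 65_771,
    "liver": 57_201,
    "lung": 64_196,
    "oral": 14_351,
    "noncancer": 268_379,
}

# condition -> cohort -> (count, printed percentage or None)
PREVALENCE: dict[str, dict[str, tuple[int, float | None]]] = {
    "HT UC": {
        "breast": (7993, 47.8), "colorectal": (29984, 45.6), "liver": (26850, 46.9),
        "lung": (27797, 43.3), "oral": (5835, 40.7), "noncancer": (112034, 41.7),
    },
    "DM W/O CC": {
        "breast": (4211, 25.2), "colorectal": (15080, 22.9), "liver": (16482, 28.8),
        "lung": (11851, 18.5), "oral": (2993, 20.9), "noncancer": (52033, 19.4),
    },
    "HT C": {
        "breast": (3619, 21.6), "colorectal": (13783, 21.0), "liver": (11555, 20.2),
        "lung": (12387, 19.3), "oral": (2379, 16.6), "noncancer": (49735, 18.5),
    },
    "Ulcer": {
        "breast": (2384, 14.3), "colorectal": (10565, 16.1), "liver": (13707, 24.0),
        "lung": (10632, 16.6), "oral": (2024, 14.1), "noncancer": (38874, 14.5),
    },
    "COPD": {
        "breast": (1758, 10.5), "colorectal": (10554, 16.0), "liver": (9651, 16.9),
        "lung": (16045, 25.0), "oral": (2500, 17.4), "noncancer": (38696, 14.4),
    },
    "CVD": {
        "breast": (1909, 11.4), "colorectal": (9360, 14.2), "liver": (7341, 12.8),
        "lung": (9159, 14.3), "oral": (1865, 13.0), "noncancer": (35611, 13.3),
    },
    "DM W CC": {
        "breast": (1399, 8.4), "colorectal": (5045, 7.7), "liver": (5734, 10.0),
        "lung": (3901, 6.1), "oral": (955, 6.7), "noncancer": (17267, 6.4),
    },
    "Mild LD": {
        "breast": (1194, 7.1), "colorectal": (4021, 6.1), "liver": (23934, 41.8),
        "lung": (3767, 5.9), "oral": (1084, 7.6), "noncancer": (16412, 6.1),
    },
    "CHF": {
        "breast": (689, 4.1), "colorectal": (3780, 5.7), "liver": (3358, 5.9),
        "lung": (3682, 5.7), "oral": (607, 4.2), "noncancer": (13666, 5.1),
    },
    "CRF": {
        "breast": (679, 4.1), "colorectal": (3847, 5.8), "liver": (4146, 7.2),
        "lung": (3206, 5.0), "oral": (691, 4.8), "noncancer": (12902, 4.8),
    },
    "Dementia": {
        "breast": (558, 3.3), "colorectal": (2533, 3.9), "liver": (1865, 3.3),
        "lung": (2206, 3.4), "oral": (364, 2.5), "noncancer": (10563, 3.9),
    },
    "PVD": {
        "breast": (213, 1.3), "colorectal": (962, 1.5), "liver": (873, 1.5),
        "lung": (1053, 1.6), "oral": (208, 1.4), "noncancer": (3799, 1.4),
    },
    "RD": {
        "breast": (191, 1.1), "colorectal": (551, 0.8), "liver": (587, 1.0),
        "lung": (600, 0.9), "oral": (126, 0.9), "noncancer": (2653, 1.0),
    },
    "Paralysis": {
        "breast": (116, 0.7), "colorectal": (603, 0.9), "liver": (440, 0.8),
        "lung": (546, 0.9), "oral": (146, 1.0), "noncancer": (2456, 0.9),
    },
    "AMI": {
        "breast": (58, 0.4), "colorectal": (567, 0.9), "liver": (389, 0.7),
        "lung": (578, 0.9), "oral": (98, 0.7), "noncancer": (2199, 0.8),
    },
    "Old MI": {
        "breast": (48, 0.3), "colorectal": (483, 0.7), "liver": (374, 0.7),
        "lung": (611, 1.0), "oral": (109, 0.8), "noncancer": (1793, 0.7),
    },
    "MS LD": {
        "breast": (32, 0.2), "colorectal": (142, 0.2), "liver": (2564, 4.5),
        "lung": (85, 0.1), "oral": (65, 0.5), "noncancer": (584, 0.2),
    },
    "AIDS": {
        "breast": (0, None), "colorectal": (0, None), "liver": (13, 0.0),
        "lung": (5, 0.0), "oral": (0, None), "noncancer": (22, 0.0),
    },
}

# cohort -> band -> (count, printed percentage); bands count comorbid conditions
CONDITION_COUNT_BANDS: dict[str, dict[str, tuple[int, float]]] = {
    "breast": {"0": (4466, 26.7), "1": (4405, 26.3), "2": (3902, 23.3), "3": (2177, 13.0), "4+": (1784, 10.7)},
    "colorectal": {"0": (17696, 26.9), "1": (16241, 24.7), "2": (14554, 22.1), "3": (8805, 13.4), "4+": (8475, 12.9)},
    "liver": {"0": (9848, 17.2), "1": (11088, 19.4), "2": (13227, 23.1), "3": (10505, 18.4), "4+": (12533, 21.9)},
    "lung": {"0": (17633, 27.5), "1": (15767, 24.6), "2": (14092, 22.0), "3": (8539, 13.3), "4+": (8165, 12.7)},
    "oral": {"0": (4664, 32.5), "1": (3410, 23.8), "2": (2907, 20.3), "3": (1770, 12.3), "4+": (1600, 11.1)},
    "noncancer": {"0": (90435, 33.7), "1": (62370, 23.2), "2": (52817, 19.7), "3": (31694, 11.8), "4+": (31063, 11.6)},
}

# cohort -> status -> (count, printed percentage); follow-up through the death horizon
VITAL_STATUS: dict[str, dict[str, tuple[int, float]]] = {
    "breast": {"alive": (11231, 67.1), "cancer_death": (3454, 20.6), "other_death": (2049, 12.2)},
    "colorectal": {"alive": (27239, 41.4), "cancer_death": (28723, 43.7), "other_death": (9809, 14.9)},
    "liver": {"alive": (9416, 16.5), "cancer_death": (43164, 75.5), "other_death": (4621, 8.1)},
    "lung": {"alive": (6759, 10.5), "cancer_death": (53193, 82.9), "other_death": (4244, 6.6)},
    "oral": {"alive": (5022, 35.0), "cancer_death": (7043, 49.1), "other_death": (2286, 15.9)},
}

# The 11 most common conditions pooled across the five cancer cohorts, in the
# published order, with the published pooled counts.
TOP11_POOLED_COUNTS: dict[str, int] = {
    "HT UC": 98_458,
    "DM W/O CC": 50_617,
    "HT C": 43_723,
    "COPD": 40_508,
    "Ulcer": 39_312,
    "Mild LD": 34_000,
    "CVD": 29_634,
    "DM W CC": 17_034,
    "CRF": 12_569,
    "CHF": 12_116,
    "Dementia": 7_526,
}

# ---------------------------------------------------------------------------
# Published TCCI weights (negative-deletion model): term -> (coef, printed HR).
# Age is per year; sex is an indicator for male. Conditions absent from the
# main-effect table were deleted by the negative-deletion procedure and
# contribute zero to the index.
# ---------------------------------------------------------------------------

PUBLISHED_AGE_SEX: dict[str, tuple[float, float]] = {
    "age": (0.06, 1.07),
    "sex": (0.49, 1.63),
}

PUBLISHED_MAIN_EFFECTS: dict[str, tuple[float, float]] = {
    "AMI": (0.27, 1.30),
    "Old MI": (0.08, 1.08),
    "CHF": (0.75, 2.11),
    "PVD": (0.24, 1.27),
    "CVD": (0.37, 1.45),
    "COPD": (0.26, 1.30),
    "Dementia": (0.66, 1.94),
    "Paralysis": (0.34, 1.40),
    "DM W/O CC": (0.28, 1.32),
    "DM W CC": (0.38, 1.46),
    "CRF": (0.80, 2.23),
    "MS LD": (0.81, 2.24),
    "RD": (0.29, 1.33),
    "AIDS": (1.65, 5.22),
    "HT UC": (0.02, 1.02),
}

PUBLISHED_DELETED: tuple[str, ...] = ("Mild LD", "Ulcer", "HT C")

PUBLISHED_INTERACTIONS: dict[tuple[str, str], tuple[float, float]] = {
    ("CHF", "CVD"): (-0.12, 0.88),
    ("CHF", "COPD"): (-0.11, 0.90),
    ("CHF", "Dementia"): (-0.31, 0.74),
    ("CHF", "DM W/O CC"): (0.02, 1.02),
    ("CHF", "DM W CC"): (-0.08, 0.93),
    ("CHF", "CRF"): (0.03, 1.03),
    ("CHF", "HT UC"): (-0.17, 0.85),
    ("CVD", "COPD"): (0.01, 1.01),
    ("CVD", "Dementia"): (-0.07, 0.93),
    ("CVD", "DM W/O CC"): (0.12, 1.13),
    ("CVD", "DM W CC"): (-0.08, 0.92),
    ("CVD", "CRF"): (-0.16, 0.85),
    ("CVD", "HT UC"): (0.06, 1.06),
    ("COPD", "Dementia"): (0.05, 1.05),
    ("COPD", "DM W/O CC"): (-0.10, 0.90),
    ("COPD", "DM W CC"): (-0.02, 0.98),
    ("COPD", "CRF"): (-0.17, 0.84),
    ("COPD", "HT UC"): (0.01, 1.01),
    ("Dementia", "DM W/O CC"): (-0.02, 0.98),
    ("Dementia", "DM W CC"): (-0.05, 0.95),
    ("Dementia", "CRF"): (-0.35, 0.71),
    ("Dementia", "HT UC"): (-0.04, 0.96),
    ("DM W/O CC", "DM W CC"): (-0.11, 0.89),
    ("DM W/O CC", "CRF"): (0.07, 1.07),
    ("DM W/O CC", "HT UC"): (0.05, 1.05),
    ("DM W CC", "CRF"): (0.11, 1.12),
    ("DM W CC", "HT UC"): (0.00, 1.00),
    ("CRF", "HT UC"): (-0.05, 0.95),
}


def pooled_cancer_prevalence() -> dict[str, float]:
    """Prevalence of each condition pooled over the five cancer cohorts."""
    n = sum(COHORT_SIZES[c] for c in COHORTS if c != "noncancer")
    out = {}
    for cond in CONDITIONS:
        count = sum(PREVALENCE[cond][c][0] for c in COHORTS if c != "noncancer")
        out[cond] = count / n
    return out


def noncancer_prevalence() -> dict[str, float]:
    """Prevalence of each condition in the published noncancer cohort."""
    n = COHORT_SIZES["noncancer"]
    return {cond: PREVALENCE[cond]["noncancer"][0] / n for cond in CONDITIONS}


def hr_consistent(coef: float, hr: float, dp: int = 2) -> bool:
    """Is a printed hazard ratio consistent with a printed coefficient?

    Both numbers are rounded to ``dp`` decimals of an unknown unrounded
    coefficient, so the printed HR must fall within the image of the
    coefficient's rounding interval, widened by the HR's own half-ulp.
    """
    import math

    half = 0.5 * 10 ** (-dp)
    lo = math.exp(coef - half) - half
    hi = math.exp(coef + half) + half
    return lo <= hr <= hi
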