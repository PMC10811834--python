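"""Published summary counts from a cross-sectional survey of 1741 Tibetan
adults (Qinghai, China) and its nested 1:1 matched obesity case-control
sample (319 pairs).

These aggregate counts are the package's reference inputs: the prevalence,
contingency-test and genetics modules reproduce the survey's printed
percentages and p-values from them, and the synthetic-data generator takes
its default marginal distributions and allele frequencies from them.
Cell counts only — no individual-level data.
"""

from __future__ import annotations

import pandas as pd

from .genetics import GenotypeCounts

#: Survey totals.
N_TOTAL = 1741
N_OBESE = 339
N_OVERWEIGHT = 586
N_NORMAL = 816
N_MALE = 870
N_FEMALE = 871

#: Obesity and overweight counts within each sex.
OBESE_BY_SEX = {"male": 192, "female": 147}
OVERWEIGHT_BY_SEX = {"male": 322, "female": 264}

#: Survey marginal counts per covariate (category -> count over the whole
#: sample of 1741).  Category order matches the level order of the enums.
SURVEY_MARGINALS: dict[str, dict[str, int]] = {
    "sex": {"male": 870, "female": 871},
    "age_band": {"20-29": 258, "30-39": 386, "40-49": 517, "50-59": 366, "60-80": 214},
    "residence": {"urban": 843, "rural": 898},
    "income": {"low": 853, "high": 888},
    "education": {
        "primary_or_below": 1007,
        "junior_or_senior_high": 331,
        "college_or_above": 403,
    },
    "smoking": {"never": 1260, "former": 179, "current": 302},
    "drinking": {"never": 1185, "former": 196, "current": 360},
    "occupational_pa": {"light": 1241, "moderate": 186, "heavy": 313},
    "leisure_exercise": {"light": 705, "moderate": 448, "heavy": 583},
}

#: Case-control sample (319 obesity cases vs 319 normal-weight controls):
#: covariate counts as (case, control) per category.
CASE_CONTROL_COVARIATES: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {"male": (180, 180), "female": (139, 139)},
    "age_band": {
        "20-29": (13, 13),
        "30-39": (56, 53),
        "40-49": (113, 99),
        "50-59": (85, 87),
        "60-80": (52, 67),
    },
    "residence": {"urban": (134, 125), "rural": (185, 194)},
    "income": {"low": (185, 178), "high": (134, 141)},
    "education": {
        "primary_or_below": (209, 221),
        "junior_or_senior_high": (52, 48),
        "college_or_above": (58, 50),
    },
    "smoking": {"never": (236, 190), "former": (44, 43), "current": (39, 86)},
    "drinking": {"never": (221, 193), "former": (38, 48), "current": (60, 78)},
    "occupational_pa": {"light": (230, 209), "moderate": (36, 42), "heavy": (53, 68)},
    "leisure_exercise": {"light": (101, 149), "moderate": (90, 69), "heavy": (128, 101)},
}

#: Genotype counts (hom-ref, het, hom-effect) in cases and controls for the
#: four-SNP panel; effect allele = control minor allele.
CASE_GENOTYPES: dict[str, GenotypeCounts] = {
    "rs17782313": GenotypeCounts("rs17782313", 165, 133, 21),
    "rs12970134": GenotypeCounts("rs12970134", 182, 122, 15),
    "rs1121980": GenotypeCounts("rs1121980", 187, 107, 25),
    "rs17817449": GenotypeCounts("rs17817449", 194, 103, 22),
}

CONTROL_GENOTYPES: dict[str, GenotypeCounts] = {
    "rs17782313": GenotypeCounts("rs17782313", 187, 114, 18),
    "rs12970134": GenotypeCounts("rs12970134", 202, 105, 12),
    "rs1121980": GenotypeCounts("rs1121980", 194, 105, 20),
    "rs17817449": GenotypeCounts("rs17817449", 199, 103, 17),
}


def case_control_table(covariate: str) -> pd.DataFrame:
    """Case/control contingency table (categories x {case, control}) for one
    covariate of the matched sample."""
    counts = CASE_CONTROL_COVARIATES[covariate]
    return pd.DataFrame(
        {"case": [c for c, _ in counts.values()], "control": [k for _, k in counts.values()]},
        index=list(counts.keys()),
    )


def sex_by_obesity_table() -> pd.DataFrame:
    """2x2 table of obesity status by sex over the full survey."""
    return pd.DataFrame(
        {
            "obese": [OBESE_BY_SEX["male"], OBESE_BY_SEX["female"]],
            "not_obese": [
                N_MALE - OBESE_BY_SEX["male"],
                N_FEMALE - OBESE_BY_SEX["female"],
            ],
        },
        index=["male", "female"],
    )


def sex_by_overweight_table() -> pd.DataFrame:
    """2x2 table of overweight status by sex over the full survey."""
    return pd.DataFrame(
        {
            "overweight": [OVERWEIGHT_BY_SEX["male"], OVERWEIGHT_BY_SEX["female"]],
            "not_overweight": [
                N_MALE - OVERWEIGHT_BY_SEX["male"],
                N_FEMALE - OVERWEIGHT_BY_SEX["female"],
            ],
        },
        index=["male", "female"],
    )
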