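"""Seeded synthetic cardiovascular cohort.

The real study population (218 records from a specialist hospital, 76.6%
male, all patients over 30) is restricted, so this module emits a synthetic
cohort reproducing its *schema* and qualitative distributional character:
13 continuous features — baseline/follow-up HbA1c, diastolic blood
pressure, LDL and total cholesterol, a coronary artery calcium score,
age, weight, height and BMI — and 11 categorical features (kidney function
class plus imbalanced binary diagnoses). Continuous marginals are
multimodal or heavy-tailed on purpose: HbA1c is bimodal (non-diabetic vs
diabetic component), the calcium score is zero-inflated log-normal, and
follow-up measurements are correlated with baseline (target r ~ 0.6).
BMI is computed from weight and height, never drawn.

All parameters are invented and recorded in :class:`CohortGroundTruth`, so
tests assert against the truth actually used. Nothing here should be read
as clinically equivalent to the restricted hospital data.

Units: Age years, WT kg, HT cm, DBP mmHg, LDL / T.C. mmol/L, hA1c %,
CACS Agatston-like score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import ColumnKind, ColumnSpec, DataTable, TableSchema

__all__ = [
    "CONTINUOUS_COLUMNS",
    "CATEGORICAL_COLUMNS",
    "UNITS",
    "CohortGroundTruth",
    "cohort_schema",
    "generate_reference_cohort",
]

CONTINUOUS_COLUMNS = [
    "hA1c.#1", "DBP.#1", "LDL.#1", "T.C.#1", "CACS#2.scor",
    "hA1c.#2", "DBP.#2", "LDL.#2", "T.C.#2", "Age", "WT", "HT", "BMI",
]
CATEGORICAL_COLUMNS = [
    "eGFR", "P.STRK", "P.MI", "A.F", "Gender", "CAD.prior",
    "RA", "CKD", "DLP", "DM", "HTN",
]

UNITS = {
    "hA1c.#1": "%", "hA1c.#2": "%",
    "DBP.#1": "mmHg", "DBP.#2": "mmHg",
    "LDL.#1": "mmol/L", "LDL.#2": "mmol/L",
    "T.C.#1": "mmol/L", "T.C.#2": "mmol/L",
    "CACS#2.scor": "score", "Age": "years",
    "WT": "kg", "HT": "cm", "BMI": "kg/m^2",
}

MALE_FRACTION = 0.766
AGE_MIN = 30.0

# categorical class probabilities (binaries imbalanced on purpose;
# Gender is assigned by exact count, its entry is the target fraction)
CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "eGFR": {">=90": 0.40, "60-89": 0.42, "<60": 0.18},
    "P.STRK": {"no": 0.92, "yes": 0.08},
    "P.MI": {"no": 0.85, "yes": 0.15},
    "A.F": {"no": 0.88, "yes": 0.12},
    "Gender": {"male": MALE_FRACTION, "female": 1 - MALE_FRACTION},
    "CAD.prior": {"no": 0.65, "yes": 0.35},
    "RA": {"no": 0.93, "yes": 0.07},
    "CKD": {"no": 0.82, "yes": 0.18},
    "DLP": {"no": 0.42, "yes": 0.58},
    "DM": {"no": 0.52, "yes": 0.48},
    "HTN": {"no": 0.28, "yes": 0.72},
}

# two-component age mixture, truncated strictly above AGE_MIN
AGE_MIX = {"weights": (0.45, 0.55), "means": (45.0, 63.0), "stds": (6.0, 8.0)}
# bimodal HbA1c: non-diabetic and diabetic components
HA1C_MIX = {"weights": (0.55, 0.45), "means": (5.6, 8.6), "stds": (0.35, 1.2)}
DBP_PARAMS = {"mean": 82.0, "std": 10.0}
LDL_LOGNORM = {"mu": np.log(2.8), "sigma": 0.35}
TC_OFFSET = {"mean": 2.1, "std": 0.4}  # T.C. = LDL + non-LDL cholesterol
CACS_ZIL = {"p_zero": 0.40, "mu": 4.0, "sigma": 1.5}
HT_BY_SEX = {"male": (172.0, 6.0), "female": (159.0, 6.0)}
WT_RULE = {"base": 75.0, "slope": 0.5, "ht_ref": 168.0, "resid_sd": 12.0}
FOLLOWUP_RHO = 0.6
FOLLOWUP_SHIFT = {"hA1c": -0.3, "DBP": -2.0, "LDL": -0.4, "T.C.": -0.4}


@dataclass
class CohortGroundTruth:
    """The parameters the synthetic cohort was actually drawn from."""

    n: int
    male_count: int
    continuous: dict[str, dict] = field(default_factory=dict)
    categorical: dict[str, dict[str, float]] = field(default_factory=dict)

    def expected_mean(self, column: str) -> float | None:
        """Analytic marginal mean, or None for nonlinearly derived columns."""
        return self.continuous[column].get("expected_mean")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n": self.n,
                    "male_count": self.male_count,
                    "continuous": self.continuous,
                    "categorical": self.categorical,
                },
                fh,
                indent=1,
            )


def cohort_schema() -> TableSchema:
    cols = [ColumnSpec(n, ColumnKind.CONTINUOUS) for n in CONTINUOUS_COLUMNS]
    cols += [
        ColumnSpec(n, ColumnKind.CATEGORICAL, tuple(sorted(CATEGORY_PROBS[n])))
        for n in CATEGORICAL_COLUMNS
    ]
    return TableSchema(tuple(cols))


def _truncated_mixture_age(n: int, rng: np.random.Generator) -> np.ndarray:
    w = np.asarray(AGE_MIX["weights"])
    comp = rng.choice(2, size=n, p=w)
    mu = np.asarray(AGE_MIX["means"])[comp]
    sd = np.asarray(AGE_MIX["stds"])[comp]
    age = rng.normal(mu, sd)
    while np.any(age <= AGE_MIN):  # resample below the truncation point
        bad = age <= AGE_MIN
        age[bad] = rng.normal(mu[bad], sd[bad])
    return age


def _age_expected_mean() -> float:
    total = 0.0
    for w, mu, sd in zip(*AGE_MIX.values()):
        a = (AGE_MIN - mu) / sd
        total += w * stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)
    return float(total)


def _followup(x1: np.ndarray, shift: float, rng: np.random.Generator) -> np.ndarray:
    """Follow-up = shifted baseline deviation scaled for corr ~ FOLLOWUP_RHO."""
    s1 = x1.std()
    target_sd = s1  # keep the follow-up spread comparable to baseline
    noise_sd = target_sd * np.sqrt(1 - FOLLOWUP_RHO**2)
    return (
        x1.mean() + shift
        + FOLLOWUP_RHO * (x1 - x1.mean())
        + rng.normal(0, noise_sd, size=x1.size)
    )


def generate_reference_cohort(
    n: int = 218, seed: int = 42
) -> tuple[DataTable, CohortGroundTruth]:
    """Draw a reproducible synthetic cohort of ``n`` patients.

    The male count is exact — ``round(0.766 n)`` records — and every age is
    strictly above 30; all other marginals follow the module-level
    parameters, which are returned in the ground-truth object.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    schema = cohort_schema()

    male_count = int(round(MALE_FRACTION * n))
    gender = np.array(["male"] * male_count + ["female"] * (n - male_count))
    rng.shuffle(gender)

    age = _truncated_mixture_age(n, rng)

    ht = np.where(
        gender == "male",
        rng.normal(*HT_BY_SEX["male"], size=n),
        rng.normal(*HT_BY_SEX["female"], size=n),
    )
    wt = (
        WT_RULE["base"]
        + WT_RULE["slope"] * (ht - WT_RULE["ht_ref"])
        + rng.normal(0, WT_RULE["resid_sd"], size=n)
    )
    bmi = wt / (ht / 100.0) ** 2

    comp = rng.choice(2, size=n, p=HA1C_MIX["weights"])
    ha1c1 = rng.normal(
        np.asarray(HA1C_MIX["means"])[comp], np.asarray(HA1C_MIX["stds"])[comp]
    )
    dbp1 = rng.normal(DBP_PARAMS["mean"], DBP_PARAMS["std"], size=n)
    ldl1 = rng.lognormal(LDL_LOGNORM["mu"], LDL_LOGNORM["sigma"], size=n)
    tc1 = ldl1 + rng.normal(TC_OFFSET["mean"], TC_OFFSET["std"], size=n)

    ha1c2 = _followup(ha1c1, FOLLOWUP_SHIFT["hA1c"], rng)
    dbp2 = _followup(dbp1, FOLLOWUP_SHIFT["DBP"], rng)
    ldl2 = np.maximum(_followup(ldl1, FOLLOWUP_SHIFT["LDL"], rng), 0.3)
    tc2 = np.maximum(_followup(tc1, FOLLOWUP_SHIFT["T.C."], rng), 1.0)

    zero = rng.random(n) < CACS_ZIL["p_zero"]
    cacs = np.where(
        zero, 0.0, rng.lognormal(CACS_ZIL["mu"], CACS_ZIL["sigma"], size=n)
    )

    data = {
        "hA1c.#1": ha1c1, "DBP.#1": dbp1, "LDL.#1": ldl1, "T.C.#1": tc1,
        "CACS#2.scor": cacs, "hA1c.#2": ha1c2, "DBP.#2": dbp2,
        "LDL.#2": ldl2, "T.C.#2": tc2, "Age": age, "WT": wt, "HT": ht,
        "BMI": bmi,
    }
    for name in CATEGORICAL_COLUMNS:
        if name == "Gender":
            data[name] = gender
            continue
        probs = CATEGORY_PROBS[name]
        labels = list(probs)
        data[name] = rng.choice(labels, size=n, p=[probs[k] for k in labels])

    table = DataTable(schema=schema, frame=pd.DataFrame(data))

    ldl_mean = float(np.exp(LDL_LOGNORM["mu"] + LDL_LOGNORM["sigma"] ** 2 / 2))
    cacs_mean = float(
        (1 - CACS_ZIL["p_zero"])
        * np.exp(CACS_ZIL["mu"] + CACS_ZIL["sigma"] ** 2 / 2)
    )
    ht_mean = (
        MALE_FRACTION * HT_BY_SEX["male"][0]
        + (1 - MALE_FRACTION) * HT_BY_SEX["female"][0]
    )
    truth = CohortGroundTruth(n=n, male_count=male_count)
    truth.categorical = {k: dict(v) for k, v in CATEGORY_PROBS.items()}
    truth.continuous = {
        "hA1c.#1": {
            "kind": "gaussian_mixture", **{k: list(v) for k, v in HA1C_MIX.items()},
            "expected_mean": float(np.dot(HA1C_MIX["weights"], HA1C_MIX["means"])),
        },
        "DBP.#1": {"kind": "normal", **DBP_PARAMS,
                   "expected_mean": DBP_PARAMS["mean"]},
        "LDL.#1": {"kind": "lognormal", **LDL_LOGNORM, "expected_mean": ldl_mean},
        "T.C.#1": {"kind": "ldl_plus_offset", **TC_OFFSET,
                   "expected_mean": ldl_mean + TC_OFFSET["mean"]},
        "CACS#2.scor": {"kind": "zero_inflated_lognormal", **CACS_ZIL,
                        "expected_mean": cacs_mean},
        "hA1c.#2": {"kind": "followup", "rho": FOLLOWUP_RHO,
                    "shift": FOLLOWUP_SHIFT["hA1c"], "expected_mean": None},
        "DBP.#2": {"kind": "followup", "rho": FOLLOWUP_RHO,
                   "shift": FOLLOWUP_SHIFT["DBP"], "expected_mean": None},
        "LDL.#2": {"kind": "followup_floored", "rho": FOLLOWUP_RHO,
                   "shift": FOLLOWUP_SHIFT["LDL"], "expected_mean": None},
        "T.C.#2": {"kind": "followup_floored", "rho": FOLLOWUP_RHO,
                   "shift": FOLLOWUP_SHIFT["T.C."], "expected_mean": None},
        "Age": {
            "kind": "truncated_gaussian_mixture",
            **{k: list(v) for k, v in AGE_MIX.items()},
            "truncate_above": AGE_MIN, "expected_mean": _age_expected_mean(),
        },
        "WT": {"kind": "linear_in_ht", **WT_RULE,
               "expected_mean": WT_RULE["base"]
               + WT_RULE["slope"] * (ht_mean - WT_RULE["ht_ref"])},
        "HT": {"kind": "normal_by_sex",
               "male": list(HT_BY_SEX["male"]), "female": list(HT_BY_SEX["female"]),
               "expected_mean": float(ht_mean)},
        "BMI": {"kind": "derived", "rule": "WT / (HT/100)^2", "expected_mean": None},
    }
    return table, truth
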