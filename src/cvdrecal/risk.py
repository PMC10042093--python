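"""Non-laboratory 10-year cardiovascular risk scoring.

A risk model holds four Cox-chart-style submodels (two sexes x two event
subtypes: coronary artery disease and stroke).  Each submodel is a linear
predictor over centred covariates (age, current smoking, systolic blood
pressure, body mass index, optional age interactions) plus a reference
10-year risk at the centring point; the risk transform is on the survival
scale,

    risk = 1 - (1 - reference_risk) ** exp(lp),

so that lp = 0 returns the reference risk exactly and recalibration is
exact on the cumulative-hazard scale.  Subtype risks combine into total
cardiovascular risk as a complement product (independent-subtype
survival) by default.

Coefficients are data, not code: models are read from JSON files.  The
default model shipped here is illustrative only — plausible magnitudes
for an East-Asian non-laboratory chart — and no number in it is a test
oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CORONARY, FEMALE, MALE, SEXES, STROKE, SUBTYPES

__all__ = [
    "KNOWN_TERMS",
    "Submodel",
    "RiskModel",
    "linear_predictor",
    "ten_year_risk",
    "combine_subtype_risks",
    "score_cohort",
    "default_model",
]

logger = logging.getLogger(__name__)

KNOWN_TERMS = ("age", "smoker", "sbp", "bmi", "age_x_smoker", "age_x_sbp", "age_x_bmi")

_BOUNDS = {"sbp": (60.0, 300.0), "bmi": (10.0, 60.0)}


@dataclass
class Submodel:
    """One sex-by-subtype component of the risk model."""

    sex: str
    subtype: str
    coefficients: dict[str, float]
    reference_risk: float
    centring: dict[str, float] = field(
        default_factory=lambda: {"age": 60.0, "sbp": 120.0, "bmi": 25.0}
    )

    def validate(self) -> None:
        if not 0.0 < self.reference_risk < 1.0:
            raise ValueError(
                f"submodel ({self.sex}, {self.subtype}): reference_risk must be in (0, 1)"
            )
        if not self.coefficients:
            raise ValueError(f"submodel ({self.sex}, {self.subtype}): no coefficients")
        unknown = set(self.coefficients) - set(KNOWN_TERMS)
        if unknown:
            raise ValueError(
                f"submodel ({self.sex}, {self.subtype}): unknown terms {sorted(unknown)}"
            )
        if not all(np.isfinite(v) for v in self.centring.values()):
            raise ValueError(f"submodel ({self.sex}, {self.subtype}): non-finite centring")


def _term_values(profile: pd.DataFrame, centring: dict[str, float]) -> dict[str, np.ndarray]:
    age = profile["age"].to_numpy(dtype=float) - centring["age"]
    smoker = profile["smoker"].to_numpy(dtype=float)
    sbp = profile["sbp"].to_numpy(dtype=float) - centring["sbp"]
    bmi = profile["bmi"].to_numpy(dtype=float) - centring["bmi"]
    return {
        "age": age,
        "smoker": smoker,
        "sbp": sbp,
        "bmi": bmi,
        "age_x_smoker": age * smoker,
        "age_x_sbp": age * sbp,
        "age_x_bmi": age * bmi,
    }


def linear_predictor(profile, submodel: Submodel) -> np.ndarray | float:
    """Sum of coefficients times centred covariate terms.

    ``profile`` is a mapping (single participant) or DataFrame with
    columns age, smoker, sbp, bmi.  Covariates outside physiological
    bounds are scored but logged as warnings.
    """
    scalar = not isinstance(profile, pd.DataFrame)
    df = pd.DataFrame([profile]) if scalar else profile
    missing = {"age", "smoker", "sbp", "bmi"} - set(df.columns)
    if missing:
        raise KeyError(f"profile missing covariates: {sorted(missing)}")
    for covar, (lo, hi) in _BOUNDS.items():
        vals = df[covar].to_numpy(dtype=float)
        bad = int(((vals < lo) | (vals > hi)).sum())
        if bad:
            logger.warning(
                "%d value(s) of %s outside physiological bounds [%g, %g]",
                bad, covar, lo, hi,
            )
    terms = _term_values(df, submodel.centring)
    lp = np.zeros(len(df))
    for name, beta in submodel.coefficients.items():
        lp += beta * terms[name]
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    return float(lp[0]) if scalar else lp


def ten_year_risk(lp, submodel: Submodel):
    """Survival-scale risk transform: 1 - (1 - reference_risk)^exp(lp)."""
    if not 0.0 < submodel.reference_risk < 1.0:
        raise ValueError("reference_risk must be in (0, 1)")
    base_surv = 1.0 - submodel.reference_risk
    return 1.0 - np.power(base_surv, np.exp(lp))


def combine_subtype_risks(p_coronary, p_stroke, rule: str = "complement_product"):
    """Total cardiovascular risk from the two subtype risks."""
    pc = np.asarray(p_coronary, dtype=float)
    ps = np.asarray(p_stroke, dtype=float)
    if np.any((pc < 0) | (pc > 1)) or np.any((ps < 0) | (ps > 1)):
        raise ValueError("subtype risks must lie in [0, 1]")
    if rule == "complement_product":
        total = 1.0 - (1.0 - pc) * (1.0 - ps)
    elif rule == "capped_sum":
        total = np.minimum(pc + ps, 1.0)
    else:
        raise ValueError(f"unknown combination rule: {rule!r}")
    return total if total.ndim else float(total)


@dataclass
class RiskModel:
    """Four submodels (sex x subtype) plus metadata."""

    submodels: dict[tuple[str, str], Submodel]
    name: str = "unnamed"
    vintage: str = "2017"

    def validate(self) -> None:
        expected = {(s, st) for s in SEXES for st in SUBTYPES}
        if set(self.submodels) != expected:
            raise ValueError(
                f"model {self.name!r}: need exactly one submodel per (sex, subtype); "
                f"got {sorted(self.submodels)}"
            )
        for sm in self.submodels.values():
            sm.validate()

    def submodel(self, sex: str, subtype: str) -> Submodel:
        try:
            return self.submodels[(sex, subtype)]
        except KeyError:
            raise KeyError(f"no submodel for sex={sex!r}, subtype={subtype!r}") from None

    # -- file round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {"metadata": {"name": self.name, "vintage": self.vintage}, "submodels": {}}
        for (sex, st), sm in self.submodels.items():
            out["submodels"].setdefault(sex, {})[st] = {
                "coefficients": sm.coefficients,
                "centring": sm.centring,
                "reference_risk": sm.reference_risk,
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        meta = d.get("metadata", {})
        submodels = {}
        for sex, per_subtype in d["submodels"].items():
            for st, body in per_subtype.items():
                submodels[(sex, st)] = Submodel(
                    sex=sex,
                    subtype=st,
                    coefficients=dict(body["coefficients"]),
                    reference_risk=float(body["reference_risk"]),
                    centring=dict(body.get("centring", {"age": 60.0, "sbp": 120.0, "bmi": 25.0})),
                )
        model = cls(
            submodels=submodels,
            name=meta.get("name", "unnamed"),
            vintage=str(meta.get("vintage", "2017")),
        )
        model.validate()
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def score_cohort(
    cohort: pd.DataFrame, model: RiskModel, combine_rule: str = "complement_product"
) -> pd.DataFrame:
    """Per-participant linear predictors and uncalibrated 10-year risks.

    Each row is routed to the submodels of its sex; the result index is
    aligned with the cohort.
    """
    model.validate()
    bad_sex = set(cohort["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"no submodels for sex value(s): {sorted(bad_sex)}")

    n = len(cohort)
    lp = {st: np.zeros(n) for st in SUBTYPES}
    p = {st: np.zeros(n) for st in SUBTYPES}
    for sex in SEXES:
        mask = (cohort["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        sub = cohort.loc[mask, ["age", "smoker", "sbp", "bmi"]]
        for st in SUBTYPES:
            sm = model.submodel(sex, st)
            lp_s = linear_predictor(sub, sm)
            lp[st][mask] = lp_s
            p[st][mask] = ten_year_risk(lp_s, sm)

    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "lp_coronary": lp[CORONARY],
            "lp_stroke": lp[STROKE],
            "p_coronary": p[CORONARY],
            "p_stroke": p[STROKE],
            "p_total": combine_subtype_risks(p[CORONARY], p[STROKE], combine_rule),
            "stage": "uncalibrated",
        },
        index=cohort.index,
    )


def model_from_truth(truth, horizon: float = 10.0) -> RiskModel:
    """Risk model whose submodels mirror a data-generating truth.

    Coefficients are copied from the truth's log-hazard ratios and each
    reference risk is the closed-form ``horizon``-year risk at the centring
    point (exponential baseline), so the model is exactly calibrated for a
    population with region hazard multipliers of 1.  Useful for controlled
    miscalibration experiments where regions deviate from the reference.
    """
    submodels = {}
    for sex in SEXES:
        sex_mult = truth.male_multiplier if sex == MALE else 1.0
        for st in SUBTYPES:
            rate = truth.baseline_rate[st] * sex_mult
            submodels[(sex, st)] = Submodel(
                sex=sex,
                subtype=st,
                coefficients=dict(truth.log_hr[sex][st]),
                reference_risk=float(-np.expm1(-rate * horizon)),
                centring=dict(truth.centring),
            )
    return RiskModel(submodels=submodels, name="matched-to-truth", vintage="synthetic")


def default_model() -> RiskModel:
    """Illustrative non-laboratory chart for East Asia (synthetic).

    Coefficient magnitudes are plausible for a Cox-chart model on these
    covariates; reference risks are deliberately on the low side relative
    to a high-incidence target population, so the uncalibrated model
    underestimates and the recalibration machinery has real work to do.
    Not derived from any published coefficient table.
    """
    coeffs = {
        (FEMALE, CORONARY): {"age": 0.065, "smoker": 0.55, "sbp": 0.015, "bmi": 0.022},
        (FEMALE, STROKE): {"age": 0.070, "smoker": 0.30, "sbp": 0.020, "bmi": 0.012},
        (MALE, CORONARY): {"age": 0.062, "smoker": 0.50, "sbp": 0.014, "bmi": 0.020},
        (MALE, STROKE): {"age": 0.068, "smoker": 0.32, "sbp": 0.019, "bmi": 0.011},
    }
    ref = {
        (FEMALE, CORONARY): 0.015,
        (FEMALE, STROKE): 0.020,
        (MALE, CORONARY): 0.022,
        (MALE, STROKE): 0.030,
    }
    submodels = {
        key: Submodel(sex=key[0], subtype=key[1], coefficients=dict(c), reference_risk=ref[key])
        for key, c in coeffs.items()
    }
    return RiskModel(submodels=submodels, name="illustrative-east-asia", vintage="2017")
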