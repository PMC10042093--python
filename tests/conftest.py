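"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cvdrecal.cohort import (
    CORONARY,
    FEMALE,
    MALE,
    STROKE,
    RegionSpec,
    SexCovariates,
    TrueHazardSpec,
    generate_cohort,
)
from cvdrecal.risk import RiskModel, Submodel


def brute_force_c(time, event, risk):
    """All-pairs Harrell's C by direct enumeration (independent oracle).

    A pair is comparable when one member has an event strictly before the
    other's time, or at the same time as the other's censoring; both-event
    time ties are not comparable.  Risk ties score 1/2.
    """
    t = list(map(float, time))
    e = list(map(bool, event))
    p = list(map(float, risk))
    n = len(t)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] < t[j] and e[i]:
                first, second = i, j
            elif t[j] < t[i] and e[j]:
                first, second = j, i
            elif t[i] == t[j] and e[i] != e[j]:
                first, second = (i, j) if e[i] else (j, i)
            else:
                continue
            den += 1
            if p[first] > p[second]:
                num += 1.0
            elif p[first] == p[second]:
                num += 0.5
    return (num, den)


def random_survival_sample(rng, n, *, censor_frac=0.3, tie_frac=0.2):
    """Random censored sample with time and risk ties for oracle tests."""
    time = rng.exponential(5.0, n)
    if tie_frac:
        # force ties by rounding a subset to a coarse grid
        tied = rng.random(n) < tie_frac
        time[tied] = np.ceil(time[tied])
    time = np.maximum(time, 0.01)
    event = rng.random(n) > censor_frac
    risk = rng.random(n)
    tied = rng.random(n) < tie_frac
    risk[tied] = np.round(risk[tied], 1)
    return time, event, risk


def two_region_specs(mult_a=1.0, mult_b=1.0, *, smoking=0.3, mult_cor=1.0):
    def cov():
        return {
            FEMALE: SexCovariates(smoking, 130.0, 15.0, 24.0, 3.0),
            MALE: SexCovariates(smoking, 132.0, 15.0, 23.5, 3.0),
        }

    return [
        RegionSpec("reg_a", False, cov(), {CORONARY: mult_cor, STROKE: mult_a}),
        RegionSpec("reg_b", True, cov(), {CORONARY: mult_cor, STROKE: mult_b}),
    ]


@pytest.fixture
def clean_truth():
    """Truth with no ineligible-row injection and no loss to follow-up."""
    return TrueHazardSpec(
        loss_to_followup_prob=0.0,
        prior_cvd_frac=0.0,
        underage_frac=0.0,
        missing_bmi_frac=0.0,
    )


@pytest.fixture
def small_cohort(clean_truth):
    return generate_cohort(two_region_specs(2.0, 1.0), clean_truth, 400, seed=42)


def toy_model(reference_risk=0.05, beta_age=0.05, beta_smoker=0.4,
              beta_sbp=0.01, beta_bmi=0.02):
    """Hand-set four-submodel risk model for exact composition tests."""
    submodels = {}
    for sex in (FEMALE, MALE):
        for st, scale in ((CORONARY, 1.0), (STROKE, 0.8)):
            submodels[(sex, st)] = Submodel(
                sex=sex,
                subtype=st,
                coefficients={
                    "age": beta_age * scale,
                    "smoker": beta_smoker * scale,
                    "sbp": beta_sbp * scale,
                    "bmi": beta_bmi * scale,
                },
                reference_risk=reference_risk,
            )
    return RiskModel(submodels=submodels, name="toy", vintage="test")


@pytest.fixture
def hand_model():
    return toy_model()
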