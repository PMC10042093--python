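"""Stratum-level recalibration of predicted 10-year risks.

Recalibration rescales the risks of a universal model so that, within
each stratum (region x sex x age band), the mean prediction matches the
target population's expected 10-year risk — without refitting any
coefficient.  For a stratum s with expected risk p̄_s and mean relative
risk r̄_s (arithmetic mean of exp(lp) over stratum members), each
participant gets the cumulative-hazard-scaled risk

    w_i = exp(lp_i) / r̄_s
    p'_i = 1 - (1 - p̄_s) ** w_i

which is monotone in lp within the stratum (rank-preserving) and exact on
the cumulative-hazard scale.  The same machinery expresses both a
super-region external table (one stratum scheme covering every region)
and separate per-region empirical recalibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CORONARY, SEXES, STROKE, SUBTYPES, first_event_outcome
from .metrics import km_risk
from .risk import combine_subtype_risks

__all__ = [
    "DEFAULT_AGE_BANDS",
    "TABLE_COLUMNS",
    "StratumScheme",
    "expected_risk_from_rates",
    "rate_from_expected_risk",
    "estimate_recalibration_table",
    "recalibrate",
    "load_recalibration_table",
    "save_recalibration_table",
    "validate_recalibration_table",
]

DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (40.0, 50.0),
    (50.0, 60.0),
    (60.0, 70.0),
    (70.0, 80.0),
)

TABLE_COLUMNS = [
    "region", "sex", "age_lo", "age_hi", "subtype",
    "expected_risk", "mean_rr", "provenance",
]


@dataclass(frozen=True)
class StratumScheme:
    """How participants map to recalibration strata.

    With ``by_region`` the region label is the cohort's own region; with a
    ``super_region`` label every participant falls into one pooled region
    (the "model for East Asia" style of recalibration).  Age bands must
    partition [40, 80) without overlap.
    """

    age_bands: tuple[tuple[float, float], ...] = DEFAULT_AGE_BANDS
    by_region: bool = True
    super_region: str | None = None

    def __post_init__(self):
        bands = sorted(self.age_bands)
        if not bands or bands[0][0] != 40.0 or bands[-1][1] != 80.0:
            raise ValueError("age bands must span [40, 80)")
        for (lo, hi), (lo2, _) in zip(bands, bands[1:]):
            if hi != lo2:
                raise ValueError("age bands must partition [40, 80) without gaps or overlap")
        if any(lo >= hi for lo, hi in bands):
            raise ValueError("each age band needs lo < hi")
        if self.by_region == (self.super_region is not None):
            raise ValueError("choose exactly one of by_region or super_region")

    def assign(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Per-row stratum labels: region, sex, age_lo, age_hi."""
        age = cohort["age"].to_numpy(dtype=float)
        edges = np.array([lo for lo, _ in sorted(self.age_bands)] + [80.0])
        idx = np.searchsorted(edges, age, side="right") - 1
        if np.any((idx < 0) | (idx >= len(self.age_bands))):
            raise ValueError("participant age outside [40, 80): run eligibility filters first")
        bands = np.array(sorted(self.age_bands))
        region = (
            cohort["region_id"].to_numpy()
            if self.by_region
            else np.full(len(cohort), self.super_region)
        )
        return pd.DataFrame(
            {
                "region": region,
                "sex": cohort["sex"].to_numpy(),
                "age_lo": bands[idx, 0],
                "age_hi": bands[idx, 1],
            },
            index=cohort.index,
        )


def expected_risk_from_rates(rate: float, horizon: float = 10.0) -> float:
    """Expected risk over ``horizon`` years from a constant annual incidence rate."""
    if rate < 0:
        raise ValueError("incidence rate must be non-negative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return float(-np.expm1(-rate * horizon))


def rate_from_expected_risk(risk: float, horizon: float = 10.0) -> float:
    """Inverse of :func:`expected_risk_from_rates`."""
    if not 0.0 <= risk < 1.0:
        raise ValueError("risk must lie in [0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return float(-np.log1p(-risk) / horizon)


def estimate_recalibration_table(
    cohort: pd.DataFrame,
    predictions: pd.DataFrame,
    scheme: StratumScheme,
    t0: float = 10.0,
    provenance: str = "empirical",
    mean_rr: str = "arithmetic",
    subtype_weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Empirical recalibration parameters from a target cohort.

    Per stratum and subtype, r̄_s is the arithmetic mean of exp(lp) (a
    geometric-mean option exists) and p̄_s is the Kaplan-Meier ``t0``-year
    risk of that subtype within the stratum; strata with zero events get
    the small-sample floor p̄_s = 0.5 / n with a warning.
    ``subtype_weights`` thins subtype events so the parameters target a
    narrower outcome-definition variant.
    """
    if (predictions["stage"] != "uncalibrated").any():
        raise ValueError("recalibration parameters are estimated from uncalibrated predictions")
    if len(cohort) != len(predictions):
        raise ValueError("cohort and predictions are not aligned")
    strata = scheme.assign(cohort)
    rows = []
    grouped = strata.groupby(["region", "sex", "age_lo", "age_hi"], sort=True)
    for key, idx in grouped.indices.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty
            raise ValueError(f"empty stratum: {key}")
        members = cohort.iloc[idx]
        preds = predictions.iloc[idx]
        for st in SUBTYPES:
            lp = preds[f"lp_{st}"].to_numpy(dtype=float)
            rr = np.exp(lp)
            rbar = float(rr.mean()) if mean_rr == "arithmetic" else float(np.exp(lp.mean()))
            outcome = first_event_outcome(members, f"{st}_only", subtype_weights)
            if outcome["event"].any():
                pbar, _ = km_risk(outcome["time"], outcome["event"], t0)
                if pbar <= 0.0:
                    # events exist but all after t0
                    pbar = 0.5 / len(idx)
                    warnings.warn(f"stratum {key} ({st}): no events by t0; applying floor")
            else:
                pbar = 0.5 / len(idx)
                warnings.warn(f"stratum {key} ({st}): zero events; applying small-sample floor")
            rows.append(
                dict(
                    region=key[0], sex=key[1], age_lo=key[2], age_hi=key[3],
                    subtype=st, expected_risk=pbar, mean_rr=rbar, provenance=provenance,
                )
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    validate_recalibration_table(table)
    return table


def _scheme_from_table(table: pd.DataFrame, cohort: pd.DataFrame) -> StratumScheme:
    bands = tuple(
        sorted({(float(lo), float(hi)) for lo, hi in zip(table["age_lo"], table["age_hi"])})
    )
    table_regions = set(table["region"].unique())
    cohort_regions = set(cohort["region_id"].unique())
    if table_regions & cohort_regions:
        return StratumScheme(age_bands=bands, by_region=True)
    if len(table_regions) == 1:
        # super-region table: one label applied to every participant
        return StratumScheme(age_bands=bands, by_region=False,
                             super_region=next(iter(table_regions)))
    raise ValueError(
        f"recalibration table regions {sorted(table_regions)} match no cohort region"
    )


def recalibrate(
    predictions: pd.DataFrame,
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    combine_rule: str = "complement_product",
) -> pd.DataFrame:
    """Apply stratum recalibration parameters to predicted risks.

    Every participant must map to exactly one stratum per subtype; the
    output has stage ``recalibrated`` and total risk recombined from the
    recalibrated subtype risks.
    """
    validate_recalibration_table(table)
    if len(cohort) != len(predictions):
        raise ValueError("cohort and predictions are not aligned")
    scheme = _scheme_from_table(table, cohort)
    strata = scheme.assign(cohort)

    out = predictions.copy()
    new_p = {}
    for st in SUBTYPES:
        sub = table[table["subtype"] == st].set_index(["region", "sex", "age_lo", "age_hi"])
        if sub.index.has_duplicates:
            dups = sub.index[sub.index.duplicated()].tolist()
            raise ValueError(f"duplicate strata in table for {st}: {dups}")
        key = pd.MultiIndex.from_frame(strata[["region", "sex", "age_lo", "age_hi"]])
        matched = sub.reindex(key)
        missing = matched["expected_risk"].isna()
        if missing.any():
            bad = sorted(set(key[np.asarray(missing)]))
            raise KeyError(f"no recalibration stratum for participants in: {bad[:5]}")
        pbar = matched["expected_risk"].to_numpy(dtype=float)
        rbar = matched["mean_rr"].to_numpy(dtype=float)
        w = np.exp(predictions[f"lp_{st}"].to_numpy(dtype=float)) / rbar
        new_p[st] = 1.0 - np.power(1.0 - pbar, w)
        out[f"p_{st}"] = new_p[st]
    out["p_total"] = combine_subtype_risks(new_p[CORONARY], new_p[STROKE], combine_rule)
    out["stage"] = "recalibrated"
    return out


def validate_recalibration_table(table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"recalibration table missing columns: {missing}")
    for _, row in table.iterrows():
        stratum = (row["region"], row["sex"], row["age_lo"], row["age_hi"], row["subtype"])
        if row["subtype"] not in SUBTYPES:
            raise ValueError(f"stratum {stratum}: unknown subtype")
        if row["sex"] not in SEXES:
            raise ValueError(f"stratum {stratum}: unknown sex")
        if not 0.0 < row["expected_risk"] < 1.0:
            raise ValueError(f"stratum {stratum}: expected_risk outside (0, 1)")
        if not row["mean_rr"] > 0:
            raise ValueError(f"stratum {stratum}: mean_rr must be positive")


def save_recalibration_table(table: pd.DataFrame, path) -> None:
    validate_recalibration_table(table)
    table[TABLE_COLUMNS].to_csv(path, index=False)


def load_recalibration_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, dtype={"region": str, "sex": str, "subtype": str, "provenance": str}
    )
    validate_recalibration_table(table)
    return table
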