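"""Tests for stratum-wise recalibration of predicted risks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import toy_model, two_region_specs
from cvdrecal.cohort import (
    CORONARY,
    FEMALE,
    MALE,
    STROKE,
    TrueHazardSpec,
    first_event_outcome,
    generate_cohort,
)
from cvdrecal.metrics import harrell_c, km_risk, po_ratio
from cvdrecal.recalibration import (
    StratumScheme,
    estimate_recalibration_table,
    expected_risk_from_rates,
    load_recalibration_table,
    rate_from_expected_risk,
    recalibrate,
    save_recalibration_table,
)
from cvdrecal.risk import score_cohort


class TestExpectedRiskFromRates:
    def test_zero_rate(self):
        assert expected_risk_from_rates(0.0, 10.0) == 0.0

    def test_closed_form(self):
        assert expected_risk_from_rates(0.01, 10.0) == pytest.approx(
            1 - np.exp(-0.1), abs=1e-12
        )

    def test_round_trip_bijection(self):
        for risk in (0.001, 0.05, 0.3, 0.9):
            back = expected_risk_from_rates(rate_from_expected_risk(risk, 10.0), 10.0)
            assert back == pytest.approx(risk, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            expected_risk_from_rates(-0.01, 10.0)


class TestStratumScheme:
    def test_bands_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            StratumScheme(age_bands=((40.0, 55.0), (60.0, 80.0)))
        with pytest.raises(ValueError, match="span"):
            StratumScheme(age_bands=((40.0, 60.0),))

    def test_exactly_one_region_mode(self):
        with pytest.raises(ValueError, match="exactly one"):
            StratumScheme(by_region=True, super_region="east_asia")

    def test_assignment_uses_band_edges(self, small_cohort):
        scheme = StratumScheme()
        strata = scheme.assign(small_cohort)
        in_band = (small_cohort["age"] >= strata["age_lo"]) & (
            small_cohort["age"] < strata["age_hi"]
        )
        assert in_band.all()

    def test_super_region_broadcast(self, small_cohort):
        scheme = StratumScheme(by_region=False, super_region="east_asia")
        strata = scheme.assign(small_cohort)
        assert (strata["region"] == "east_asia").all()


@pytest.fixture
def scored_cohort(clean_truth, hand_model):
    cohort = generate_cohort(two_region_specs(2.0, 0.8), clean_truth, 4000, seed=21)
    preds = score_cohort(cohort, hand_model)
    return cohort, preds


class TestEstimateTable:
    def test_degenerate_stratum_all_lp_zero(self, clean_truth):
        model = toy_model(beta_age=0.0, beta_smoker=0.0, beta_sbp=0.0, beta_bmi=0.0)
        cohort = generate_cohort(two_region_specs(), clean_truth, 2000, seed=22)
        preds = score_cohort(cohort, model)
        scheme = StratumScheme(
            age_bands=((40.0, 80.0),), by_region=False, super_region="all"
        )
        table = estimate_recalibration_table(cohort, preds, scheme)
        assert np.allclose(table["mean_rr"], 1.0)
        for st in (CORONARY, STROKE):
            for sex in (FEMALE, MALE):
                sub = cohort[cohort.sex == sex]
                out = first_event_outcome(sub, f"{st}_only")
                km, _ = km_risk(out["time"], out["event"], 10.0)
                got = table[(table.subtype == st) & (table.sex == sex)]
                assert got["expected_risk"].iloc[0] == pytest.approx(km, abs=1e-12)

    def test_no_censoring_km_equals_proportion(self, scored_cohort):
        """Within a stratum with no censoring before t0, the expected risk
        equals the plain event proportion."""
        cohort, preds = scored_cohort
        scheme = StratumScheme(age_bands=((40.0, 80.0),))
        table = estimate_recalibration_table(cohort, preds, scheme)
        row = table[
            (table.region == "reg_a") & (table.sex == FEMALE) & (table.subtype == STROKE)
        ].iloc[0]
        sub = cohort[(cohort.region_id == "reg_a") & (cohort.sex == FEMALE)]
        out = first_event_outcome(sub, "stroke_only")
        # administrative censoring only (horizon 12 > t0): KM = proportion
        assert row["expected_risk"] == pytest.approx(
            (out["time"][out["event"]] <= 10.0).sum() / len(sub), abs=1e-12
        )

    def test_known_rate_recovered(self):
        zeros = {
            sex: {st: {k: 0.0 for k in ("age", "smoker", "sbp", "bmi")} for st in (CORONARY, STROKE)}
            for sex in (FEMALE, MALE)
        }
        lam = 0.008
        truth = TrueHazardSpec(
            log_hr=zeros, baseline_rate={CORONARY: 0.002, STROKE: lam},
            male_multiplier=1.0, loss_to_followup_prob=0.0,
            prior_cvd_frac=0.0, underage_frac=0.0, missing_bmi_frac=0.0,
        )
        cohort = generate_cohort(two_region_specs(), truth, 30_000, seed=23)
        preds = score_cohort(cohort, toy_model())
        scheme = StratumScheme(age_bands=((40.0, 80.0),), by_region=False, super_region="all")
        table = estimate_recalibration_table(cohort, preds, scheme)
        expected = 1 - np.exp(-10 * lam)
        for _, row in table[table.subtype == STROKE].iterrows():
            n = (cohort.sex == row.sex).sum()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(row["expected_risk"] - expected) < 3 * se

    def test_zero_event_stratum_gets_floor_with_warning(self, clean_truth):
        truth = TrueHazardSpec(
            baseline_rate={CORONARY: 1e-8, STROKE: 0.005},
            loss_to_followup_prob=0.0, prior_cvd_frac=0.0,
            underage_frac=0.0, missing_bmi_frac=0.0,
        )
        cohort = generate_cohort(two_region_specs(), truth, 500, seed=24)
        preds = score_cohort(cohort, toy_model())
        scheme = StratumScheme(age_bands=((40.0, 80.0),), by_region=False, super_region="all")
        with pytest.warns(UserWarning, match="floor"):
            table = estimate_recalibration_table(cohort, preds, scheme)
        floored = table[table.subtype == CORONARY]
        assert (floored["expected_risk"] > 0).all()
        assert (floored["expected_risk"] < 0.01).all()

    def test_requires_uncalibrated_stage(self, scored_cohort):
        cohort, preds = scored_cohort
        staged = preds.assign(stage="recalibrated")
        with pytest.raises(ValueError, match="uncalibrated"):
            estimate_recalibration_table(cohort, staged, StratumScheme())


class TestRecalibrate:
    def test_participant_at_stratum_mean_gets_expected_risk(self, scored_cohort):
        cohort, preds = scored_cohort
        scheme = StratumScheme()
        table = estimate_recalibration_table(cohort, preds, scheme)
        recal = recalibrate(preds, table, cohort)
        strata = scheme.assign(cohort)
        key0 = strata.iloc[0]
        mask = (strata == key0).all(axis=1) & (cohort.region_id == key0.region)
        row = table[
            (table.region == key0.region) & (table.sex == key0.sex)
            & (table.age_lo == key0.age_lo) & (table.subtype == STROKE)
        ].iloc[0]
        # synthetic participant whose exp(lp) equals the stratum mean
        w = np.exp(preds.loc[mask, "lp_stroke"]) / row["mean_rr"]
        p_new = recal.loc[mask, "p_stroke"].to_numpy()
        expect = 1 - (1 - row["expected_risk"]) ** w.to_numpy()
        assert np.allclose(p_new, expect, atol=1e-12)
        at_mean = np.argmin(np.abs(w.to_numpy() - 1.0))
        assert p_new[at_mean] == pytest.approx(
            row["expected_risk"], abs=2 * abs(w.to_numpy()[at_mean] - 1.0) + 1e-12
        )

    def test_closed_form_doubled_weight(self):
        # p' = 1 - (1 - 0.05)^2 when exp(lp)/mean_rr = 2
        table = pd.DataFrame(
            {
                "region": ["all"] * 2,
                "sex": [FEMALE] * 2,
                "age_lo": [40.0] * 2,
                "age_hi": [80.0] * 2,
                "subtype": [CORONARY, STROKE],
                "expected_risk": [0.05, 0.05],
                "mean_rr": [1.0, 1.0],
                "provenance": ["unit"] * 2,
            }
        )
        cohort = pd.DataFrame(
            {"id": ["a"], "region_id": ["x"], "sex": [FEMALE], "age": [50.0]}
        )
        preds = pd.DataFrame(
            {
                "id": ["a"],
                "lp_coronary": [np.log(2.0)],
                "lp_stroke": [0.0],
                "p_coronary": [0.1],
                "p_stroke": [0.05],
                "p_total": [0.145],
                "stage": ["uncalibrated"],
            }
        )
        recal = recalibrate(preds, table, cohort)
        assert recal["p_coronary"].iloc[0] == pytest.approx(1 - 0.95**2, abs=1e-12)
        assert recal["p_stroke"].iloc[0] == pytest.approx(0.05, abs=1e-12)
        assert recal["stage"].iloc[0] == "recalibrated"

    def test_rank_preservation_within_stratum(self, scored_cohort):
        cohort, preds = scored_cohort
        scheme = StratumScheme()
        table = estimate_recalibration_table(cohort, preds, scheme)
        recal = recalibrate(preds, table, cohort)
        strata = scheme.assign(cohort)
        key = strata.apply(tuple, axis=1)
        for stratum in key.unique()[:4]:
            m = (key == stratum).to_numpy()
            lp = preds.loc[m, "lp_stroke"]
            tau = stats.kendalltau(lp, recal.loc[m, "p_stroke"]).statistic
            assert tau == pytest.approx(1.0, abs=1e-12)

    def test_missing_stratum_rejected(self, scored_cohort):
        cohort, preds = scored_cohort
        table = estimate_recalibration_table(cohort, preds, StratumScheme())
        dropped = table[table.region != "reg_b"]
        with pytest.raises(KeyError, match="no recalibration stratum"):
            recalibrate(preds, dropped, cohort)

    def test_discrimination_invariance_per_subtype(self, scored_cohort):
        """Within a recalibration stratum, subtype-specific C is exactly
        unchanged: the transform is monotone in lp."""
        cohort, preds = scored_cohort
        scheme = StratumScheme(age_bands=((40.0, 60.0), (60.0, 80.0)))
        table = estimate_recalibration_table(cohort, preds, scheme)
        recal = recalibrate(preds, table, cohort)
        strata = scheme.assign(cohort)
        key = strata.apply(tuple, axis=1)
        checked = 0
        for stratum in key.unique():
            m = (key == stratum).to_numpy()
            out = first_event_outcome(cohort.loc[m], "stroke_only")
            if out["event"].sum() < 5:
                continue
            before = harrell_c(out["time"], out["event"], preds.loc[m, "p_stroke"])
            after = harrell_c(out["time"], out["event"], recal.loc[m, "p_stroke"])
            assert abs(after.c - before.c) <= 1e-12
            checked += 1
        assert checked >= 4

    def test_self_recalibration_fixpoint(self, scored_cohort):
        """Recalibrating against the table estimated from the same cohort
        drives each stratum's P/O ratio to ~1 (small-sample version)."""
        cohort, preds = scored_cohort
        scheme = StratumScheme(age_bands=((40.0, 80.0),))
        table = estimate_recalibration_table(cohort, preds, scheme)
        recal = recalibrate(preds, table, cohort)
        strata = scheme.assign(cohort)
        key = strata.apply(tuple, axis=1)
        out = first_event_outcome(cohort, "total_cvd")
        for stratum in key.unique():
            m = (key == stratum).to_numpy()
            ratio = po_ratio(out.loc[m, "time"], out.loc[m, "event"],
                             recal.loc[m, "p_total"], 10.0)
            assert 0.9 < ratio < 1.1


class TestTableIO:
    def _minimal_table(self):
        return pd.DataFrame(
            {
                "region": ["east_asia"],
                "sex": [FEMALE],
                "age_lo": [40.0],
                "age_hi": [80.0],
                "subtype": [STROKE],
                "expected_risk": [0.12],
                "mean_rr": [1.4],
                "provenance": ["2017"],
            }
        )

    def test_round_trip(self, tmp_path):
        path = tmp_path / "table.csv"
        table = self._minimal_table()
        save_recalibration_table(table, path)
        back = load_recalibration_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_out_of_range_expected_risk_names_stratum(self, tmp_path):
        table = self._minimal_table()
        table.loc[0, "expected_risk"] = 1.2
        path = tmp_path / "bad.csv"
        table.to_csv(path, index=False)
        with pytest.raises(ValueError, match="east_asia.*expected_risk"):
            load_recalibration_table(path)

    def test_missing_column_rejected(self, tmp_path):
        table = self._minimal_table().drop(columns=["mean_rr"])
        path = tmp_path / "bad.csv"
        table.to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            load_recalibration_table(path)
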