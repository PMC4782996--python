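"""Validation machinery: chi-square, weighted KS, grid search, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bmimatch.matching import MatchConfig
from bmimatch.survey import SurveyDataset
from bmimatch.validation import (GridSearchResult, chi2_prevalence,
                                 evaluation_report, grid_search_thresholds,
                                 misclassified_count, state_table, weighted_ks)
from bmimatch.weighted import PrevalenceEstimate, WeightedSample
from conftest import make_donor_frame, make_recipient_frame


def estimate(p, n_eff, cutoff=30.0):
    return PrevalenceEstimate(prevalence=p, ci_low=max(0.0, p - 0.1),
                              ci_high=min(1.0, p + 0.1), n=int(n_eff),
                              n_eff=float(n_eff), cutoff=cutoff)


class TestChi2Prevalence:
    def test_identical_estimates_give_zero(self):
        res = chi2_prevalence(estimate(0.3, 100), estimate(0.3, 100))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_pearson(self):
        # effective counts 30/100 vs 50/100
        res = chi2_prevalence(estimate(0.30, 100), estimate(0.50, 100))
        assert res.statistic == pytest.approx(200 * (30 * 50 - 70 * 50) ** 2
                                              / (100 * 100 * 80 * 120))
        assert res.statistic == pytest.approx(8.333, abs=1e-3)

    def test_textbook_quantile(self):
        assert stats.chi2.sf(3.841, df=1) == pytest.approx(0.05, abs=1e-3)

    def test_equal_weight_reduction_to_scipy(self, rng):
        x, y = 37, 61
        na, nb = 120, 150
        res = chi2_prevalence(estimate(x / na, na), estimate(y / nb, nb))
        table = np.array([[x, na - x], [y, nb - y]])
        expected = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(expected.statistic)
        assert res.p_value == pytest.approx(expected.pvalue)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi2_prevalence(estimate(0.0, 50), estimate(0.0, 80))


class TestWeightedKS:
    def test_identical_samples_d_zero(self):
        s = WeightedSample(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 1.0]))
        res = weighted_ks(s, s)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_supports_d_one(self):
        a = WeightedSample(np.array([1.0, 2.0]), np.ones(2))
        b = WeightedSample(np.array([10.0, 11.0]), np.ones(2))
        assert weighted_ks(a, b).statistic == pytest.approx(1.0)

    def test_replication_oracle_matches_scipy(self, rng):
        for trial in range(25):
            va = rng.integers(0, 20, size=rng.integers(2, 8)).astype(float)
            vb = rng.integers(0, 20, size=rng.integers(2, 8)).astype(float)
            wa = rng.integers(1, 4, size=va.size)
            wb = rng.integers(1, 4, size=vb.size)
            ours = weighted_ks(WeightedSample(va, wa.astype(float)),
                               WeightedSample(vb, wb.astype(float)))
            ref = stats.ks_2samp(np.repeat(va, wa), np.repeat(vb, wb))
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_asymptotic_pvalue_formula(self):
        a = WeightedSample(np.arange(50.0), np.ones(50))
        b = WeightedSample(np.arange(50.0) + 3.0, np.ones(50))
        res = weighted_ks(a, b)
        en = 25.0  # 50*50/100
        assert res.p_value == pytest.approx(
            stats.kstwobign.sf(np.sqrt(en) * res.statistic))


class TestGridSearch:
    def build_pair(self, rng):
        donor = SurveyDataset(records=pd.concat(
            [make_donor_frame(150, rng, sex=s) for s in ("male", "female")],
            ignore_index=True), role="donor")
        recipient = SurveyDataset(records=pd.concat(
            [make_recipient_frame(300, rng, sex=s) for s in ("male", "female")],
            ignore_index=True), role="recipient")
        return donor, recipient

    def test_single_candidate_returned_unconditionally(self, rng):
        donor, recipient = self.build_pair(rng)
        res = grid_search_thresholds(donor, recipient, candidates=[40],
                                     eval_iterations=2, seed=0)
        assert res.selected_global == 40
        assert set(res.selected.values()) == {40}

    def test_objective_equals_recomputation_from_cell_table(self, rng):
        donor, recipient = self.build_pair(rng)
        res = grid_search_thresholds(donor, recipient, candidates=[30, 80],
                                     eval_iterations=2, seed=1)
        for cand, obj in res.objective.items():
            cells = res.d_table[res.d_table.candidate == cand]
            assert obj == pytest.approx(cells["d"].max())

    def test_tie_breaks_toward_smaller_threshold(self):
        table = pd.DataFrame({
            "candidate": [10, 20], "sex": "male", "age_band": "40-44",
            "d": [0.1, 0.1], "p_value": [0.5, 0.5]})
        objective = {10: 0.1, 20: 0.1}
        best = min(objective, key=lambda c: (objective[c], c))
        res = GridSearchResult(d_table=table, objective=objective,
                               selected_global=best)
        assert res.selected_global == 10

    def test_empty_candidates_rejected(self, rng):
        donor, recipient = self.build_pair(rng)
        with pytest.raises(ValueError):
            grid_search_thresholds(donor, recipient, candidates=[])


class TestEvaluationReport:
    def test_reference_self_comparison_is_null(self, rng):
        donor = SurveyDataset(records=pd.concat(
            [make_donor_frame(100, rng, sex=s) for s in ("male", "female")],
            ignore_index=True), role="donor")
        ddf = donor.records
        mirror = pd.DataFrame({
            "sex": ddf["sex"], "age_band": ddf["age_band"],
            "sample_weight": ddf["sample_weight"],
            "corrected_bmi": donor.measured_bmi(),
        })
        report = evaluation_report({"mirror": mirror}, donor)
        prev = report["prevalence"]
        mirror_rows = prev[prev.method == "mirror"]
        assert np.allclose(mirror_rows["chi2"], 0.0, atol=1e-9)
        assert np.allclose(report["ks"]["d"], 0.0, atol=1e-12)

    def test_biased_set_flagged_significant(self, rng):
        donor = SurveyDataset(records=make_donor_frame(400, rng), role="donor")
        ddf = donor.records
        shifted = pd.DataFrame({
            "sex": ddf["sex"], "age_band": ddf["age_band"],
            "sample_weight": ddf["sample_weight"],
            "corrected_bmi": donor.measured_bmi() - 3.0,
        })
        report = evaluation_report({"shifted": shifted}, donor)
        overall = report["prevalence"]
        row = overall[(overall.method == "shifted") & (overall.stratum == "overall")
                      & (overall.cutoff == 30.0)].iloc[0]
        assert row.p_value < 0.01

    def test_requires_at_least_one_set(self, rng):
        donor = SurveyDataset(records=make_donor_frame(50, rng), role="donor")
        with pytest.raises(ValueError):
            evaluation_report({}, donor)


class TestStateTable:
    def make_corrected(self, rng, states, shift_by_state):
        frames = []
        for i, state in enumerate(states):
            df = make_recipient_frame(400, rng, state=state)
            df["record_id"] = [f"{state}{j}" for j in range(len(df))]
            df["corrected_bmi"] = (28 + shift_by_state.get(state, 0.0)
                                   + rng.normal(0, 5, len(df)))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_shifted_state_orders_higher(self, rng):
        corrected = self.make_corrected(rng, ["AA", "BB"], {"BB": 3.0})
        table = state_table(corrected)
        prev = table.set_index("state")["prev_30"]
        assert prev["BB"] > prev["AA"]

    def test_single_state_equals_national(self, rng):
        corrected = self.make_corrected(rng, ["AA"], {})
        table = state_table(corrected)
        national = np.average(corrected["corrected_bmi"] >= 30,
                              weights=corrected["sample_weight"])
        assert len(table) == 1
        assert table["prev_30"].iloc[0] == pytest.approx(national)

    def test_equal_weights_match_unweighted_proportions(self, rng):
        corrected = self.make_corrected(rng, ["AA", "BB"], {})
        corrected["sample_weight"] = 1.0
        table = state_table(corrected)
        for state, sub in corrected.groupby("state"):
            expected = np.mean(sub["corrected_bmi"] >= 35)
            got = table.set_index("state").loc[state, "prev_35"]
            assert got == pytest.approx(expected)

    def test_missing_state_column_rejected(self, rng):
        df = self.make_corrected(rng, ["AA"], {}).drop(columns=["state"])
        with pytest.raises(ValueError, match="state"):
            state_table(df)


class TestMisclassifiedCount:
    def test_identity(self):
        assert misclassified_count(0.30, 0.30, 1e6) == 0.0

    def test_published_national_gap(self):
        # corrected 33.79% vs uncorrected 28.67% on 10^8 adults
        assert misclassified_count(0.3379, 0.2867, 1e8) == pytest.approx(5.12e6)

    def test_linear_in_population(self):
        one = misclassified_count(0.4, 0.3, 1e6)
        ten = misclassified_count(0.4, 0.3, 1e7)
        assert ten == pytest.approx(10 * one)

    def test_positive_population_required(self):
        with pytest.raises(ValueError):
            misclassified_count(0.3, 0.2, 0)
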