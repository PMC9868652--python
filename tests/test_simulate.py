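"""Synthetic-cohort generator: determinism, missingness calibration,
signal localization, exchangeability under zero drift, and control
index-date assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import strudem as sd
from strudem.simulate import assign_control_index_dates, rereference_records
from strudem.stats import two_sample_ttest


@pytest.fixture(scope="module")
def small_panel():
    return sd.pancreas_panel(32)


class TestConfigValidation:
    def test_zero_cases_rejected(self, small_panel):
        with pytest.raises(ValueError, match="n_cases"):
            sd.GeneratorConfig(n_cases=0, n_controls=10,
                               taxonomy=small_panel).validate()

    def test_unknown_signal_group_named(self, small_panel):
        with pytest.raises(ValueError, match="pancreatitis group"):
            sd.GeneratorConfig(taxonomy=small_panel,
                               signal_groups=("pancreatitis group",)).validate()

    def test_missingness_bounds(self, small_panel):
        with pytest.raises(ValueError, match="missingness"):
            sd.GeneratorConfig(taxonomy=small_panel, missingness=1.2).validate()


class TestGeneration:
    def test_determinism(self, small_panel):
        cfg = dict(n_cases=20, n_controls=20, taxonomy=small_panel,
                   lookback_months=12.0, seed=5)
        r1, c1, n1 = sd.generate_cohort(sd.GeneratorConfig(**cfg))
        r2, c2, n2 = sd.generate_cohort(sd.GeneratorConfig(**cfg))
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(n1, n2)

    def test_every_record_patient_in_cohort(self, toy_cohort):
        assert set(toy_cohort["records"]["patient_id"]) <= set(
            toy_cohort["cohort"]["patient_id"])

    def test_values_finite_and_ranges_ordered(self, toy_cohort):
        assert np.isfinite(toy_cohort["records"]["value"]).all()
        r = toy_cohort["ranges"]
        assert (r["low"] < r["high"]).all()

    def test_realized_missingness_calibrated(self, small_panel):
        cfg = sd.GeneratorConfig(n_cases=40, n_controls=40,
                                 taxonomy=small_panel, lookback_months=24.0,
                                 missingness=0.6, drift_per_month=0.0,
                                 signal_groups=(), seed=3)
        records, _, _ = sd.generate_cohort(cfg)
        n_visits = records.groupby("patient_id")["t_days"].nunique().sum()
        measured_frac = len(records) / (n_visits * 32)
        assert measured_frac == pytest.approx(0.4, abs=0.02)

    def test_signal_localized_to_group(self, small_panel):
        """Drift changes case values of signal-group variables only."""
        base = dict(n_cases=15, n_controls=15, taxonomy=small_panel,
                    lookback_months=12.0, seed=9,
                    signal_groups=("liver function group",))
        r0, _, _ = sd.generate_cohort(sd.GeneratorConfig(drift_per_month=0.0, **base))
        r1, _, _ = sd.generate_cohort(sd.GeneratorConfig(drift_per_month=0.3, **base))
        liver_vars = set(small_panel.composite_variables(
            "g1", "liver function group"))
        merged = r0.assign(v1=r1["value"])
        changed = merged[merged["value"] != merged["v1"]]
        assert set(changed["variable_id"]) <= liver_vars
        assert changed["patient_id"].str.startswith("case").all()
        # and the drift really moves signal variables for cases
        assert len(changed) > 0

    def test_exchangeable_under_zero_drift(self, small_panel):
        """With no injected drift, case and control value distributions
        are exchangeable: two-sample t-test p values look uniform."""
        pvals = []
        for seed in range(10):
            cfg = sd.GeneratorConfig(n_cases=25, n_controls=25,
                                     taxonomy=small_panel, lookback_months=12.0,
                                     drift_per_month=0.0, signal_groups=(),
                                     seed=seed)
            records, cohort, _ = sd.generate_cohort(cfg)
            labels = cohort.set_index("patient_id")["label"]
            records = records.assign(
                label=labels.reindex(records["patient_id"]).to_numpy())
            for vid in small_panel.variables[:5]:
                sub = records[records["variable_id"] == vid]
                res = two_sample_ttest(
                    sub.loc[sub["label"] == "case", "value"],
                    sub.loc[sub["label"] == "control", "value"])
                pvals.append(res["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_case_covariates_confounded(self, signal_cohort):
        coh = signal_cohort["cohort"]
        cases = coh[coh["label"] == "case"]
        ctrls = coh[coh["label"] == "control"]
        assert cases["age"].mean() > ctrls["age"].mean() + 3
        assert cases["smoking"].mean() > ctrls["smoking"].mean() + 0.1


def _control_records(n_controls: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_controls):
        pid = f"ctrl_{i:04d}"
        for t in np.sort(rng.uniform(-800, 0, size=40)):
            for v in ("v1", "v2", "v3"):
                if rng.random() < 0.5:
                    rows.append((pid, v, t, rng.standard_normal()))
    records = pd.DataFrame(rows, columns=["patient_id", "variable_id",
                                          "t_days", "value"])
    cohort = pd.DataFrame({
        "patient_id": [f"ctrl_{i:04d}" for i in range(n_controls)],
        "label": "control",
        "index_day": np.nan,
    })
    return records, cohort


class TestControlIndexDates:
    def test_zero_fraction_removes_nothing(self):
        records, cohort = _control_records(20, seed=0)
        profile = pd.Series({"v1": 0.0, "v2": 0.0, "v3": 0.0})
        out = assign_control_index_dates(records, cohort, profile, seed=1)
        reref = rereference_records(records, out)
        assert (reref["t_days"] < 0).all()

    def test_unit_fraction_removes_everything(self):
        records, cohort = _control_records(20, seed=0)
        profile = pd.Series({"v1": 1.0, "v2": 1.0, "v3": 1.0})
        out = assign_control_index_dates(records, cohort, profile, seed=1)
        reref = rereference_records(records, out)
        assert (reref["t_days"] >= 0).all()

    def test_fraction_out_of_bounds(self):
        records, cohort = _control_records(5, seed=0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            assign_control_index_dates(records, cohort,
                                       pd.Series({"v1": 1.3}), seed=1)

    def test_monte_carlo_reduction_calibration(self):
        """Target fraction 0.3 over 500 controls: realized per-variable
        reduction within ±0.05."""
        records, cohort = _control_records(500, seed=2)
        profile = pd.Series({"v1": 0.3, "v2": 0.3, "v3": 0.3})
        out = assign_control_index_dates(records, cohort, profile, seed=3)
        reref = rereference_records(records, out)
        realized = reref.groupby("variable_id")["t_days"].apply(
            lambda t: (t >= 0).mean())
        assert np.allclose(realized, 0.3, atol=0.05)

    def test_deterministic_under_seed(self):
        records, cohort = _control_records(30, seed=4)
        profile = pd.Series({"v1": 0.25, "v2": 0.25, "v3": 0.25})
        a = assign_control_index_dates(records, cohort, profile, seed=9)
        b = assign_control_index_dates(records, cohort, profile, seed=9)
        pd.testing.assert_frame_equal(a, b)
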