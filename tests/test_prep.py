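"""Cohort-preparation: pre-diagnosis/censoring filters, tensorization and
propensity matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strudem as sd
from strudem.prep import propensity_match
from strudem.simulate import DAYS_PER_MONTH


def _records(t_days, patient="p1", variable="v1", values=None):
    return pd.DataFrame({
        "patient_id": patient if isinstance(patient, list) else [patient] * len(t_days),
        "variable_id": variable if isinstance(variable, list) else [variable] * len(t_days),
        "t_days": list(t_days),
        "value": values if values is not None else [1.0] * len(t_days),
    })


def _cohort(patients=("p1",), label="case"):
    return pd.DataFrame({
        "patient_id": list(patients),
        "label": [label] * len(patients),
        "index_day": [0.0] * len(patients),
    })


class TestPrediagnosisFilter:
    def test_at_and_after_index_removed(self):
        rec = _records([-10.0, 0.0, 5.0])
        out = sd.make_prediagnosis(rec, _cohort())
        assert list(out["t_days"]) == [-10.0]

    def test_empty_identity(self):
        rec = _records([])
        out = sd.make_prediagnosis(rec, _cohort())
        assert len(out) == 0

    def test_hand_counted_survivors(self):
        rec = _records([-40.0, -3.0, -1.0, -0.5, 0.0, 2.0, 30.0])
        out = sd.make_prediagnosis(rec, _cohort())
        assert len(out) == 4

    def test_unknown_patient_named(self):
        rec = _records([-1.0], patient="ghost")
        with pytest.raises(ValueError, match="ghost"):
            sd.make_prediagnosis(rec, _cohort())

    def test_idempotent(self):
        rec = _records([-40.0, -3.0, 0.0, 2.0])
        once = sd.make_prediagnosis(rec, _cohort())
        twice = sd.make_prediagnosis(once, _cohort())
        pd.testing.assert_frame_equal(once, twice)


class TestCensoring:
    def test_k0_equals_prediagnosis(self):
        rec = _records([-40.0, -0.5, 0.0, 2.0])
        pd.testing.assert_frame_equal(
            sd.censor_at_months(rec, _cohort(), 0),
            sd.make_prediagnosis(rec, _cohort()),
        )

    def test_exact_boundary_removed(self):
        rec = _records([-12 * DAYS_PER_MONTH])
        assert len(sd.censor_at_months(rec, _cohort(), 12)) == 0

    def test_hand_counted_survivors(self):
        rec = _records([-6 * DAYS_PER_MONTH, -13 * DAYS_PER_MONTH,
                        -20 * DAYS_PER_MONTH])
        assert len(sd.censor_at_months(rec, _cohort(), 12)) == 2

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            sd.censor_at_months(_records([-1.0]), _cohort(), -1)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        times=st.lists(st.floats(-2000, 100, allow_nan=False), max_size=30),
        k1=st.floats(0, 24), k2=st.floats(0, 24),
    )
    def test_composition_law(self, times, k1, k2):
        """Censoring at k2 after k1 equals censoring at max(k1, k2)."""
        rec = _records(times)
        coh = _cohort()
        seq = sd.censor_at_months(sd.censor_at_months(rec, coh, k1), coh, k2)
        direct = sd.censor_at_months(rec, coh, max(k1, k2))
        pd.testing.assert_frame_equal(seq, direct)


class TestTensorize:
    def test_single_placement(self, toy_tax):
        rec = _records([-1 * DAYS_PER_MONTH], variable="var_1", values=[7.0])
        tc = sd.tensorize(rec, _cohort(), toy_tax, n_bins=6,
                          standardize=False)
        grid = tc.values[0, 0]
        assert grid[1] == 7.0
        assert np.count_nonzero(tc.values) == 1

    def test_within_bin_mean(self, toy_tax):
        rec = _records([-3.0, -10.0], variable="var_1", values=[4.0, 6.0])
        tc = sd.tensorize(rec, _cohort(), toy_tax, n_bins=6, standardize=False)
        assert tc.values[0, 0, 0] == 5.0

    def test_hand_computed_grid(self, toy_tax):
        # months before index: 0.5, 0.9 (bin 0); 1.5 (bin 1); 2.2, 2.9 (bin 2)
        months = np.array([0.5, 0.9, 1.5, 2.2, 2.9])
        rec = _records(list(-months * DAYS_PER_MONTH), variable="var_2",
                       values=[1.0, 3.0, 10.0, 4.0, 8.0])
        tc = sd.tensorize(rec, _cohort(), toy_tax, n_bins=4, standardize=False)
        j = toy_tax.variables.index("var_2")
        assert tc.values[0, j].tolist() == [2.0, 10.0, 6.0, 0.0]

    def test_out_of_window_dropped_and_counted(self, toy_tax):
        rec = _records([-400.0, 5.0, -10.0], variable="var_1")
        tc = sd.tensorize(rec, _cohort(), toy_tax, n_bins=6, standardize=False)
        assert tc.n_dropped == 2

    def test_conservation_of_information(self, toy_cohort, toy_tax):
        """Sum over bins of (bin mean x bin count) equals the sum of the
        raw retained values, per patient-variable."""
        pre = toy_cohort["pre"]
        coh = toy_cohort["cohort"]
        tc = sd.tensorize(pre, coh, toy_tax, n_bins=12, bin_width_months=2.0,
                          standardize=False)
        months = -pre["t_days"].to_numpy() / DAYS_PER_MONTH
        b = np.floor(months / 2.0).astype(int)
        keep = (months > 0) & (b < 12)
        sub = pre[keep].assign(bin=b[keep])
        counts = np.zeros_like(tc.values)
        p_ix = {p: i for i, p in enumerate(tc.patients)}
        v_ix = {v: i for i, v in enumerate(tc.variables)}
        np.add.at(counts, (
            [p_ix[p] for p in sub["patient_id"]],
            [v_ix[v] for v in sub["variable_id"]],
            sub["bin"].to_numpy()), 1.0)
        lhs = (tc.values * counts).sum(axis=2)
        rhs = np.zeros_like(lhs)
        np.add.at(rhs, (
            [p_ix[p] for p in sub["patient_id"]],
            [v_ix[v] for v in sub["variable_id"]]), sub["value"].to_numpy())
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_scaler_transfer(self, toy_cohort, toy_tax):
        """A fitted tensorizer applies training statistics to new data."""
        t = sd.CohortTensorizer(taxonomy=toy_tax, n_bins=12,
                                bin_width_months=2.0)
        tc = t.fit_transform(toy_cohort["pre"], toy_cohort["cohort"])
        censored = sd.censor_at_months(toy_cohort["pre"],
                                       toy_cohort["cohort"], 6)
        tc2 = t.transform(censored, toy_cohort["cohort"])
        assert np.array_equal(tc2.var_means, tc.var_means)
        assert tc2.values.shape == tc.values.shape


def _covariate_cohort(n, confounded, seed):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 5) + [0] * (n - n // 5))
    shift = 1.0 if confounded else 0.0
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "label": np.where(y == 1, "case", "control"),
        "index_day": 0.0,
        "x1": rng.normal(shift * y, 1.0),
        "x2": (rng.random(n) < (0.3 + 0.25 * shift * y)).astype(int),
    })


class TestPropensityMatching:
    def test_null_covariates_stay_inseparable(self):
        coh = _covariate_cohort(400, confounded=False, seed=0)
        res = propensity_match(coh, covariates=["x1", "x2"], seed=1)
        assert abs(res.pre_match_separability - 0.5) < 0.06
        assert abs(res.post_match_separability - 0.5) < 0.06

    def test_confounding_reduced_toward_half(self):
        coh = _covariate_cohort(600, confounded=True, seed=2)
        res = propensity_match(coh, covariates=["x1", "x2"], seed=3)
        assert res.pre_match_separability > 0.6
        assert res.post_match_separability < res.pre_match_separability
        assert abs(res.post_match_separability - 0.5) < \
            abs(res.pre_match_separability - 0.5)

    def test_never_increases_separability(self, signal_cohort):
        res = propensity_match(signal_cohort["cohort"],
                               covariates=["age", "sex", "smoking", "obesity"],
                               seed=4)
        assert res.post_match_separability <= res.pre_match_separability + 0.02

    def test_perfectly_determined_label_warns(self):
        n = 120
        y = np.array([1] * 40 + [0] * 80)
        coh = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "label": np.where(y == 1, "case", "control"),
            "index_day": 0.0,
            "x1": y * 10.0,
        })
        with pytest.warns(RuntimeWarning, match="separable"):
            res = propensity_match(coh, covariates=["x1"], seed=5)
        assert res.pre_match_separability > 0.9

    def test_requires_two_per_class(self):
        coh = _covariate_cohort(10, confounded=False, seed=6).iloc[:1]
        with pytest.raises(ValueError, match="at least 2"):
            propensity_match(coh, covariates=["x1"])
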