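"""Shared fixtures: small toy cohorts for unit tests and one session-scoped
desk-scale run (400 patients, 10 repeats per hierarchy level) shared by the
evaluation-protocol and interpretability tests."""

from __future__ import annotations

import numpy as np
import pytest

import strudem as sd


@pytest.fixture(scope="session")
def panel() -> sd.Taxonomy:
    return sd.pancreas_panel()


@pytest.fixture(scope="session")
def toy_tax() -> sd.Taxonomy:
    return sd.toy_taxonomy(n_variables=10, n_combos=5, n_composites=2)


@pytest.fixture(scope="session")
def toy_cohort(toy_tax):
    """Small cohort with signal in group_1 of the toy hierarchy."""
    cfg = sd.GeneratorConfig(
        n_cases=60, n_controls=60, taxonomy=toy_tax, lookback_months=24.0,
        signal_groups=("group_1",), drift_per_month=0.2, seed=7,
    )
    records, cohort, ranges = sd.generate_cohort(cfg)
    pre = sd.make_prediagnosis(records, cohort)
    tc = sd.tensorize(pre, cohort, toy_tax, n_bins=12, bin_width_months=2.0)
    return dict(records=records, cohort=cohort, ranges=ranges, pre=pre, tc=tc)


@pytest.fixture(scope="session")
def signal_cohort(panel):
    """Desk-scale study cohort: 200 cases / 200 controls, 24-month lookback,
    drift 0.15 sd/month confined to the liver function group."""
    cfg = sd.GeneratorConfig(
        n_cases=200, n_controls=200, taxonomy=panel, lookback_months=24.0,
        signal_groups=("liver function group",), drift_per_month=0.15, seed=1,
    )
    records, cohort, ranges = sd.generate_cohort(cfg)
    pre = sd.make_prediagnosis(records, cohort)
    tc = sd.tensorize(pre, cohort, panel, n_bins=24)
    return dict(records=records, cohort=cohort, ranges=ranges, pre=pre, tc=tc,
                config=cfg)


@pytest.fixture(scope="session")
def parity_results(panel, signal_cohort):
    """The repeated-split protocol for all three hierarchy levels."""
    tc = signal_cohort["tc"]
    out = {}
    for level in ("base", "combo", "composite"):
        spec = sd.ModelSpec(level=level,
                            strategy="g1" if level == "composite" else None)
        out[level] = sd.train_eval(
            spec, panel, tc, sd.TrainConfig(n_repeats=10, seed=11),
            keep_models=(level == "composite"),
        )
    return out


@pytest.fixture(scope="session")
def composite_model(parity_results):
    return parity_results["composite"].models[0]
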