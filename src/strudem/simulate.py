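"""Seeded synthetic cohorts of longitudinal lab records.

Emulates the shape of a hospital-warehouse extract: irregular visit times
(homogeneous Poisson process per patient), high per-visit missingness,
variable-specific baselines inside clinical normal ranges, and — for case
patients — a group-structured drift that strengthens as measurements
approach the diagnosis (index) date. Baseline covariates are confounded
with the label so that propensity matching has measurable work to do.

Tables are plain pandas DataFrames:

``records``
    columns ``patient_id, variable_id, t_days, value`` with ``t_days``
    relative to the patient's index date (negative = before).
``cohort``
    columns ``patient_id, label, index_day, age, sex, smoking, obesity``.
``normal_ranges``
    columns ``variable_id, low, high``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import Taxonomy, pancreas_panel

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "assign_control_index_dates",
    "rereference_records",
]

DAYS_PER_MONTH = 30.4375

# Confounding link: case covariates are shifted so that a Bayes-optimal
# classifier on (age, smoking) alone separates at roughly 70% accuracy
# (by Bayes' rule an equal-variance Gaussian shift is a logistic link).
_AGE_MEAN_CONTROL = 62.0
_AGE_SHIFT_CASE = 8.0
_AGE_SD = 10.0
_SMOKING_P = {0: 0.28, 1: 0.53}
_OBESITY_P = {0: 0.30, 1: 0.40}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 200
    n_controls: int = 200
    taxonomy: Taxonomy = field(default_factory=pancreas_panel)
    lookback_months: float = 60.0
    visit_rate: float = 12.0          # expected visits per patient-year
    missingness: float = 0.6          # P(variable unmeasured at a visit)
    signal_groups: tuple[str, ...] = ("liver function group",)
    signal_strategy: str = "g1"
    drift_per_month: float = 0.15     # in within-variable sd units
    ramp_months: float = 18.0         # months before index over which drift builds
    noise_sd: float = 1.0             # multiplier on the variable's intrinsic sd
    postdx_months: float = 3.0        # post-index history generated for cases
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError(
                f"need n_cases >= 1 and n_controls >= 1, got "
                f"({self.n_cases}, {self.n_controls})"
            )
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError(f"missingness must be in [0, 1], got {self.missingness}")
        if self.signal_groups:
            known = set(self.taxonomy.composites(self.signal_strategy))
            for g in self.signal_groups:
                if g not in known:
                    raise ValueError(
                        f"unknown signal group {g!r} for strategy "
                        f"{self.signal_strategy!r}; known: {sorted(known)}"
                    )
        return self


def _normal_ranges(taxonomy: Taxonomy, rng: np.random.Generator) -> pd.DataFrame:
    """Per-variable clinical reference intervals (low, high).

    Centers span ~2 decades on a log scale, widths 20-60% of center, which
    is the spread seen across a routine chemistry/CBC panel.
    """
    n = len(taxonomy.variables)
    center = 10.0 ** rng.uniform(0.3, 2.3, size=n)
    width = center * rng.uniform(0.2, 0.6, size=n)
    return pd.DataFrame(
        {
            "variable_id": taxonomy.variables,
            "low": center - width / 2.0,
            "high": center + width / 2.0,
        }
    )


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a seeded synthetic cohort.

    Returns ``(records, cohort, normal_ranges)``. Case index dates sit at
    day 0 of each case's own axis (records extend ``postdx_months`` past
    it); control index dates are assigned by
    :func:`assign_control_index_dates` from the per-variable reduction
    profile realized when truncating the cases, and control records are
    re-referenced to them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tax = config.taxonomy
    variables = np.asarray(tax.variables)
    V = len(variables)

    ranges = _normal_ranges(tax, rng)
    baseline = ((ranges["low"] + ranges["high"]) / 2.0).to_numpy()
    sd = ((ranges["high"] - ranges["low"]) / 4.0).to_numpy()

    signal_vars = set()
    for g in config.signal_groups:
        signal_vars.update(tax.composite_variables(config.signal_strategy, g))
    in_signal = np.isin(variables, sorted(signal_vars))

    lookback_days = config.lookback_months * DAYS_PER_MONTH
    post_days = config.postdx_months * DAYS_PER_MONTH

    labels = np.array([1] * config.n_cases + [0] * config.n_controls)
    patient_ids = np.array(
        [f"case_{i:05d}" for i in range(config.n_cases)]
        + [f"ctrl_{i:05d}" for i in range(config.n_controls)]
    )

    rec_pid: list[np.ndarray] = []
    rec_var: list[np.ndarray] = []
    rec_t: list[np.ndarray] = []
    rec_val: list[np.ndarray] = []

    for pid, lab in zip(patient_ids, labels):
        if lab == 1:
            t0, t1 = -lookback_days, post_days
        else:
            # provisional axis: t relative to end of observation
            t0, t1 = -(lookback_days + post_days), 0.0
        window_years = (t1 - t0) / 365.25
        n_visits = rng.poisson(config.visit_rate * window_years)
        if n_visits == 0:
            continue
        t_visits = np.sort(rng.uniform(t0, t1, size=n_visits))
        measured = rng.random((n_visits, V)) < (1.0 - config.missingness)
        noise = rng.standard_normal((n_visits, V))
        values = baseline[None, :] + config.noise_sd * sd[None, :] * noise
        if lab == 1 and config.drift_per_month != 0.0 and in_signal.any():
            months_before = -t_visits / DAYS_PER_MONTH
            ramp = np.clip(config.ramp_months - np.maximum(months_before, 0.0),
                           0.0, config.ramp_months)
            shift = config.drift_per_month * np.outer(ramp, sd)
            values = values + np.where(in_signal[None, :], shift, 0.0)
        vi, vj = np.nonzero(measured)
        rec_pid.append(np.repeat(pid, len(vi)))
        rec_var.append(variables[vj])
        rec_t.append(t_visits[vi])
        rec_val.append(values[vi, vj])

    records = pd.DataFrame(
        {
            "patient_id": np.concatenate(rec_pid),
            "variable_id": np.concatenate(rec_var),
            "t_days": np.concatenate(rec_t),
            "value": np.concatenate(rec_val),
        }
    )

    is_case = labels == 1
    age = np.clip(
        rng.normal(_AGE_MEAN_CONTROL + _AGE_SHIFT_CASE * is_case, _AGE_SD), 30, 92
    )
    sex = rng.integers(0, 2, size=len(labels))
    smoking = (rng.random(len(labels))
               < np.where(is_case, _SMOKING_P[1], _SMOKING_P[0])).astype(int)
    obesity = (rng.random(len(labels))
               < np.where(is_case, _OBESITY_P[1], _OBESITY_P[0])).astype(int)
    cohort = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "label": np.where(is_case, "case", "control"),
            "index_day": np.where(is_case, 0.0, np.nan),
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "obesity": obesity,
        }
    )

    profile = case_reduction_profile(records, cohort)
    cohort = assign_control_index_dates(
        records, cohort, profile, seed=int(rng.integers(2**31))
    )
    records = rereference_records(records, cohort)
    return records, cohort, ranges


def case_reduction_profile(records: pd.DataFrame, cohort: pd.DataFrame) -> pd.Series:
    """Per-variable fraction of case measurements removed when truncating
    each case's history at its diagnosis date (``t >= 0`` removed)."""
    cases = set(cohort.loc[cohort["label"] == "case", "patient_id"])
    sub = records[records["patient_id"].isin(cases)]
    if sub.empty:
        return pd.Series(dtype=float)
    return sub.groupby("variable_id")["t_days"].apply(lambda t: float((t >= 0).mean()))


def assign_control_index_dates(
    records: pd.DataFrame,
    cohort: pd.DataFrame,
    reduction_profile: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each control a random index date calibrated so that truncating
    its history at the index reproduces, in expectation, the cases' average
    per-variable fractional measurement reduction.

    The index is drawn by jittering the span quantile ``1 - f`` of the
    control's record span, where ``f`` is the profile mean; with
    Poisson-uniform visit times the expected realized reduction equals
    ``f``. Boundary conventions: ``f = 0`` places the index strictly after
    the last measurement, ``f = 1`` strictly before the first.
    """
    frac = float(np.mean(reduction_profile)) if len(reduction_profile) else 0.0
    if not 0.0 <= frac <= 1.0 or not np.all(
        (np.asarray(reduction_profile, dtype=float) >= 0)
        & (np.asarray(reduction_profile, dtype=float) <= 1)
    ):
        raise ValueError("reduction fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cohort = cohort.copy()
    ctrl_ids = cohort.loc[cohort["label"] == "control", "patient_id"]
    spans = (
        records[records["patient_id"].isin(set(ctrl_ids))]
        .groupby("patient_id")["t_days"]
        .agg(["min", "max"])
    )
    index_days: dict[str, float] = {}
    for pid in ctrl_ids:
        if pid not in spans.index:
            index_days[pid] = 0.0
            continue
        lo, hi = spans.loc[pid, "min"], spans.loc[pid, "max"]
        span = hi - lo
        if frac == 0.0:
            idx = hi + 1.0
        elif frac == 1.0:
            idx = lo - 1.0
        else:
            q = 1.0 - frac
            idx = lo + span * float(np.clip(q + rng.uniform(-0.05, 0.05), 0.0, 1.0))
        index_days[pid] = idx
    mask = cohort["label"] == "control"
    cohort.loc[mask, "index_day"] = cohort.loc[mask, "patient_id"].map(index_days)
    return cohort


def rereference_records(records: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Express ``t_days`` relative to each patient's ``index_day``."""
    offsets = cohort.set_index("patient_id")["index_day"]
    if offsets.isna().any():
        missing = offsets[offsets.isna()].index.tolist()
        raise ValueError(f"patients without an index date: {missing[:5]}")
    records = records.copy()
    records["t_days"] = (
        records["t_days"].to_numpy()
        - offsets.reindex(records["patient_id"]).to_numpy()
    )
    return records
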