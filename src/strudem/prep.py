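"""Cohort preparation: pre-diagnosis filtering, early-detection censoring,
tensorization of irregular time series, and propensity-score matching.

The network consumes a fixed grid: for each patient and each taxonomy
variable, measurements are averaged into fixed-width bins of months before
the index date (most recent bin first), and empty bins are filled with 0
— the zero-imputation convention used throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .simulate import DAYS_PER_MONTH
from .taxonomy import Taxonomy

__all__ = [
    "TensorizedCohort",
    "CohortTensorizer",
    "MatchResult",
    "PropensityMatcher",
    "make_prediagnosis",
    "censor_at_months",
    "tensorize",
    "propensity_match",
]

logger = logging.getLogger(__name__)


def _check_patients_known(records: pd.DataFrame, cohort: pd.DataFrame) -> None:
    known = set(cohort["patient_id"])
    unknown = set(records["patient_id"]) - known
    if unknown:
        raise ValueError(f"records reference unknown patient(s): {sorted(unknown)[:5]}")


def make_prediagnosis(records: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Keep only measurements strictly before the index date.

    Records at or after the diagnosis date (``t_days >= 0``) are removed;
    input row order is preserved.
    """
    _check_patients_known(records, cohort)
    return records[records["t_days"] < 0]


def censor_at_months(
    records: pd.DataFrame, cohort: pd.DataFrame, k: float
) -> pd.DataFrame:
    """Keep only measurements more than ``k`` months before the index date
    (strict inequality; a record at exactly ``-k`` months is removed).

    ``k = 0`` coincides with :func:`make_prediagnosis`.
    """
    if k < 0:
        raise ValueError(f"censoring horizon must be >= 0 months, got {k}")
    _check_patients_known(records, cohort)
    return records[records["t_days"] < -k * DAYS_PER_MONTH]


@dataclass
class TensorizedCohort:
    """Fixed-grid view of a cohort.

    ``values[p, v, b]`` is the (optionally standardized) mean of patient
    ``p``'s measurements of variable ``v`` in month-bin ``b``; bin 0 is the
    most recent (months-before-index in ``[0, w)``) and empty bins hold
    exactly 0.
    """

    patients: list[str]
    variables: list[str]
    values: np.ndarray                      # (n_patients, n_vars, n_bins)
    bin_edges: np.ndarray                   # months, length n_bins + 1
    labels: np.ndarray                      # 1 = case, 0 = control
    var_means: np.ndarray | None = None     # standardization stats, per variable
    var_sds: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def as_matrix(self) -> np.ndarray:
        """Flatten to the 2-D ``(n_patients, n_vars * n_bins)`` layout that
        sklearn-style estimators accept."""
        return self.values.reshape(len(self.patients), -1)


def tensorize(
    records: pd.DataFrame,
    cohort: pd.DataFrame,
    taxonomy: Taxonomy,
    n_bins: int = 60,
    bin_width_months: float = 1.0,
    standardize: bool = True,
    var_means: np.ndarray | None = None,
    var_sds: np.ndarray | None = None,
) -> TensorizedCohort:
    """Bin each patient-variable series into a fixed monthly grid.

    Bin ``b`` collects measurements with months-before-index in
    ``[b*w, (b+1)*w)``; the bin value is their mean. Records at or after
    the index date or beyond the last bin are dropped (count logged).
    When ``standardize`` is set, raw values are z-scored per variable
    before binning, using either the supplied statistics (to apply a
    training-set scaling to new data) or statistics of the retained
    records.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    _check_patients_known(records, cohort)
    patients = list(cohort["patient_id"])
    variables = list(taxonomy.variables)
    p_index = {p: i for i, p in enumerate(patients)}
    v_index = {v: i for i, v in enumerate(variables)}

    unknown_vars = set(records["variable_id"]) - set(variables)
    if unknown_vars:
        raise ValueError(f"records reference unknown variable(s): "
                         f"{sorted(unknown_vars)[:5]}")

    months_before = -records["t_days"].to_numpy() / DAYS_PER_MONTH
    b = np.floor(months_before / bin_width_months).astype(int)
    keep = (months_before > 0) & (b < n_bins)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("tensorize: dropped %d record(s) outside the bin window",
                    n_dropped)

    sub = records[keep]
    pi = np.array([p_index[p] for p in sub["patient_id"]], dtype=int)
    vi = np.array([v_index[v] for v in sub["variable_id"]], dtype=int)
    bi = b[keep]
    vals = sub["value"].to_numpy(dtype=float)

    if standardize:
        if var_means is None or var_sds is None:
            var_means = np.zeros(len(variables))
            var_sds = np.ones(len(variables))
            for j in range(len(variables)):
                vv = vals[vi == j]
                if len(vv):
                    var_means[j] = vv.mean()
                    s = vv.std()
                    var_sds[j] = s if s > 0 else 1.0
        vals = (vals - var_means[vi]) / var_sds[vi]

    shape = (len(patients), len(variables), n_bins)
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    np.add.at(sums, (pi, vi, bi), vals)
    np.add.at(counts, (pi, vi, bi), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)

    labels = (cohort["label"].to_numpy() == "case").astype(int)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_months
    return TensorizedCohort(
        patients=patients,
        variables=variables,
        values=values,
        bin_edges=edges,
        labels=labels,
        var_means=var_means,
        var_sds=var_sds,
        n_dropped=n_dropped,
    )


class CohortTensorizer(BaseEstimator):
    """Transformer-style wrapper around :func:`tensorize` that learns the
    per-variable standardization on one cohort and applies it to others
    (e.g. censored evaluation sets)."""

    def __init__(self, taxonomy: Taxonomy | None = None, n_bins: int = 60,
                 bin_width_months: float = 1.0, standardize: bool = True):
        self.taxonomy = taxonomy
        self.n_bins = n_bins
        self.bin_width_months = bin_width_months
        self.standardize = standardize

    def fit(self, records: pd.DataFrame, cohort: pd.DataFrame) -> "CohortTensorizer":
        tc = tensorize(records, cohort, self.taxonomy, self.n_bins,
                       self.bin_width_months, standardize=self.standardize)
        self.var_means_ = tc.var_means
        self.var_sds_ = tc.var_sds
        return self

    def transform(self, records: pd.DataFrame, cohort: pd.DataFrame) -> TensorizedCohort:
        return tensorize(
            records, cohort, self.taxonomy, self.n_bins, self.bin_width_months,
            standardize=self.standardize,
            var_means=getattr(self, "var_means_", None),
            var_sds=getattr(self, "var_sds_", None),
        )

    def fit_transform(self, records: pd.DataFrame, cohort: pd.DataFrame) -> TensorizedCohort:
        return self.fit(records, cohort).transform(records, cohort)


# ---------------------------------------------------------------------------
# Propensity-score matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    matched_control_ids: list[str]
    pre_match_separability: float
    post_match_separability: float
    pre_match_separability_insample: float
    post_match_separability_insample: float
    iterations_run: int
    n_unmatched_cases: int = 0


def _separability(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int,
    tolerance: float,
    rng: np.random.Generator,
) -> tuple[float, float, int]:
    """Average held-out (and in-sample) accuracy of logistic fits on
    balanced resamples; stops once the running held-out mean settles
    within ``tolerance`` of 0.5 (minimum 10 fits)."""
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    m = min(len(idx_case), len(idx_ctrl))
    held, ins = [], []
    for it in range(n_iterations):
        take = np.concatenate([
            rng.choice(idx_case, size=m, replace=False),
            rng.choice(idx_ctrl, size=m, replace=False),
        ])
        Xb, yb = X[take], y[take]
        Xtr, Xte, ytr, yte = train_test_split(
            Xb, yb, test_size=0.3, stratify=yb,
            random_state=int(rng.integers(2**31)),
        )
        clf = LogisticRegression(max_iter=1000)
        clf.fit(Xtr, ytr)
        held.append(clf.score(Xte, yte))
        ins.append(clf.score(Xtr, ytr))
        if it + 1 >= 10 and abs(float(np.mean(held)) - 0.5) <= tolerance:
            break
    return float(np.mean(held)), float(np.mean(ins)), len(held)


def propensity_match(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    n_iterations: int = 100,
    target_accuracy: float = 0.5,
    tolerance: float = 0.02,
    seed: int = 0,
) -> MatchResult:
    """1:1 nearest-neighbor matching on the logit of the propensity score.

    Separability — the accuracy with which baseline covariates alone
    distinguish cases from controls — is estimated before and after
    matching by averaging held-out accuracies of repeated logistic fits on
    balanced resamples; 0.5 means the matched populations are
    indistinguishable.
    """
    if covariates is None:
        covariates = [c for c in cohort.columns
                      if c not in ("patient_id", "label", "index_day")]
    y = (cohort["label"].to_numpy() == "case").astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    X = StandardScaler().fit_transform(cohort[covariates].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    pre_held, pre_ins, it_pre = _separability(X, y, n_iterations, tolerance, rng)

    ps_model = LogisticRegression(max_iter=1000)
    ps_model.fit(X, y)
    logit = X @ ps_model.coef_.ravel() + ps_model.intercept_[0]

    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    n_unmatched = max(0, len(case_idx) - len(ctrl_idx))
    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} case(s) cannot be matched 1:1 (too few controls)",
            RuntimeWarning, stacklevel=2,
        )
    order = rng.permutation(case_idx)
    available = dict.fromkeys(ctrl_idx.tolist())
    matched: list[int] = []
    for ci in order:
        if not available:
            break
        pool = np.fromiter(available, dtype=int)
        j = pool[np.argmin(np.abs(logit[pool] - logit[ci]))]
        matched.append(int(j))
        del available[j]

    keep = np.concatenate([case_idx, np.array(matched, dtype=int)])
    post_held, post_ins, it_post = _separability(
        X[keep], y[keep], n_iterations, tolerance, rng
    )
    if post_held > target_accuracy + 10 * tolerance and pre_held > 0.9:
        warnings.warn(
            "matched populations remain highly separable; covariate supports "
            "may not overlap", RuntimeWarning, stacklevel=2,
        )
    ids = cohort["patient_id"].to_numpy()
    return MatchResult(
        matched_control_ids=[str(ids[j]) for j in matched],
        pre_match_separability=pre_held,
        post_match_separability=post_held,
        pre_match_separability_insample=pre_ins,
        post_match_separability_insample=post_ins,
        iterations_run=it_pre + it_post,
        n_unmatched_cases=n_unmatched,
    )


class PropensityMatcher(BaseEstimator):
    """Estimator-style facade over :func:`propensity_match`."""

    def __init__(self, covariates: list[str] | None = None,
                 n_iterations: int = 100, target_accuracy: float = 0.5,
                 tolerance: float = 0.02, random_state: int = 0):
        self.covariates = covariates
        self.n_iterations = n_iterations
        self.target_accuracy = target_accuracy
        self.tolerance = tolerance
        self.random_state = random_state

    def fit(self, cohort: pd.DataFrame) -> "PropensityMatcher":
        self.result_ = propensity_match(
            cohort, self.covariates, self.n_iterations,
            self.target_accuracy, self.tolerance, self.random_state,
        )
        keep = (cohort["label"] == "case") | cohort["patient_id"].isin(
            set(self.result_.matched_control_ids)
        )
        self.matched_cohort_ = cohort[keep].reset_index(drop=True)
        return self
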