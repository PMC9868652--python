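"""Repeated train/test evaluation and early-detection censoring sweeps.

The protocol: 10 repeated experiments, each with a fresh stratified 80/20
split and fresh initialization, trained up to 50 epochs with early
stopping monitored on the held-out test loss (the test set deliberately
doubles as the stopping monitor; an optional three-way split avoids
this), and discrimination summarized as AUROC / AUPRC with mean and a
normal-theory 95% CI across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .models import ModelSpec, StructuredEmbeddingClassifier, build_model
from .prep import TensorizedCohort, censor_at_months, tensorize
from .taxonomy import Taxonomy

__all__ = ["TrainConfig", "EvaluationResult", "train_eval", "early_detection_sweep"]


@dataclass
class TrainConfig:
    n_repeats: int = 10
    test_fraction: float = 0.2
    max_epochs: int = 50
    patience: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 32
    three_way_split: bool = False   # carve a validation set out of train
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class EvaluationResult:
    auroc: list[float]
    auprc: list[float]
    epochs_run: list[int]
    models: list[StructuredEmbeddingClassifier] = field(default_factory=list)
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @staticmethod
    def _ci(x: list[float]) -> tuple[float, float, float]:
        a = np.asarray(x, dtype=float)
        m = float(a.mean())
        se = float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0
        return m, m - 1.96 * se, m + 1.96 * se

    @property
    def auroc_mean(self) -> float:
        return self._ci(self.auroc)[0]

    @property
    def auprc_mean(self) -> float:
        return self._ci(self.auprc)[0]

    def summary(self) -> dict:
        am, alo, ahi = self._ci(self.auroc)
        pm, plo, phi = self._ci(self.auprc)
        return {
            "auroc_mean": am, "auroc_ci": [alo, ahi],
            "auprc_mean": pm, "auprc_ci": [plo, phi],
            "n_repeats": len(self.auroc),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, (a, p) in enumerate(zip(self.auroc, self.auprc)):
            rows.append({"repeat": r, "metric": "auroc", "value": a})
            rows.append({"repeat": r, "metric": "auprc", "value": p})
        return pd.DataFrame(rows)


def _repeat_seed(seed: int, r: int) -> int:
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))


def train_eval(
    model_spec: ModelSpec,
    taxonomy: Taxonomy,
    tensorized: TensorizedCohort,
    config: TrainConfig | None = None,
    keep_models: bool = False,
) -> EvaluationResult:
    """Run the repeated split/train/evaluate protocol for one model spec."""
    config = config or TrainConfig()
    X = tensorized.values
    y = tensorized.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    result = EvaluationResult(auroc=[], auprc=[], epochs_run=[])
    for r in range(config.n_repeats):
        rs = _repeat_seed(config.seed, r)
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, test_size=config.test_fraction, stratify=y, random_state=rs
        )
        if config.three_way_split:
            tr, va = train_test_split(
                tr, test_size=0.25, stratify=y[tr], random_state=rs + 1
            )
            monitor = (X[va], y[va])
        else:
            monitor = (X[te], y[te])
        model = build_model(taxonomy, ModelSpec(
            level=model_spec.level, strategy=model_spec.strategy,
            embed_hidden=model_spec.embed_hidden, seed=rs,
        ))
        model.set_params(learning_rate=config.learning_rate,
                         batch_size=config.batch_size,
                         max_epochs=config.max_epochs,
                         patience=config.patience)
        model.fit(X[tr], y[tr], eval_set=monitor)
        score = model.decision_function(X[te])
        result.auroc.append(float(roc_auc_score(y[te], score)))
        result.auprc.append(float(average_precision_score(y[te], score)))
        result.epochs_run.append(model.epochs_run_)
        if keep_models:
            result.models.append(model)
            result.splits.append((tr, te))
    return result


def early_detection_sweep(
    model: StructuredEmbeddingClassifier,
    records: pd.DataFrame,
    cohort: pd.DataFrame,
    months: list[float],
    taxonomy: Taxonomy,
    n_bins: int,
    bin_width_months: float = 1.0,
    eval_patients: np.ndarray | None = None,
    reference: TensorizedCohort | None = None,
) -> dict[float, dict]:
    """Evaluate a trained, frozen model on progressively censored inputs.

    For each horizon ``k`` the records are re-censored to those more than
    ``k`` months before the index date, re-tensorized with the training
    standardization (taken from ``reference``), and scored — no
    retraining. Patients whose history empties keep an all-zero grid.
    ``eval_patients`` restricts scoring to (e.g.) a held-out split.
    """
    out: dict[float, dict] = {}
    for k in months:
        kept = censor_at_months(records, cohort, k)
        tc = tensorize(
            kept, cohort, taxonomy, n_bins, bin_width_months,
            standardize=reference is not None,
            var_means=None if reference is None else reference.var_means,
            var_sds=None if reference is None else reference.var_sds,
        )
        X, y = tc.values, tc.labels
        if eval_patients is not None:
            X, y = X[eval_patients], y[eval_patients]
        score = model.decision_function(X)
        out[k] = {
            "auroc": float(roc_auc_score(y, score)),
            "auprc": float(average_precision_score(y, score)),
            "n": int(len(y)),
        }
    return out
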