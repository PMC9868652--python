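"""Interpretability of the composite indices and the grouping hierarchy.

Two complementary views:

* feature-importance rankings of the composite embeddings under four
  off-the-shelf classifiers (logistic regression, decision tree, random
  forest, xgboost), repeated over seeded bootstrap refits;
* mean-absolute Shapley attributions of the model's own case
  log-probability at every hierarchy level (variables, combos,
  composites), each level explained through the model's actual
  downstream layers, plus the accumulated roll-up of base-model variable
  attributions into composites for architecture-dependence comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .models import StructuredEmbeddingClassifier
from .shapley import shapley_values
from .taxonomy import Taxonomy

__all__ = [
    "ImportanceReport",
    "LayerShapReport",
    "composite_importance",
    "layer_shap",
    "accumulated_shap",
    "plot_layer_shap",
]

IMPORTANCE_METHODS = ("logistic_regression", "decision_tree", "random_forest",
                      "xgboost")
TREE_METHODS = ("decision_tree", "random_forest", "xgboost")


@dataclass
class ImportanceReport:
    """Normalized composite-importance scores per method (sum to 1)."""

    scores: pd.DataFrame   # columns: method, composite, mean, sd

    def ranking(self, method: str) -> list[str]:
        sub = self.scores[self.scores["method"] == method]
        return list(sub.sort_values("mean", ascending=False)["composite"])


def _fit_importance(method: str, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    if method == "logistic_regression":
        clf = LogisticRegression(max_iter=1000)
        clf.fit(StandardScaler().fit_transform(X), y)
        imp = np.abs(clf.coef_.ravel())
    elif method == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed, max_depth=5)
        clf.fit(X, y)
        imp = clf.feature_importances_
    elif method == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
        clf.fit(X, y)
        imp = clf.feature_importances_
    elif method == "xgboost":
        clf = XGBClassifier(
            n_estimators=100, max_depth=3, random_state=seed,
            verbosity=0, eval_metric="logloss",
        )
        clf.fit(X, y)
        imp = clf.feature_importances_
    else:
        raise ValueError(f"unknown method {method!r}")
    s = imp.sum()
    if s == 0:
        return np.full(X.shape[1], 1.0 / X.shape[1])
    return imp / s


def composite_importance(
    level3_embeddings: np.ndarray,
    labels: np.ndarray,
    composite_names: list[str],
    n_repeats: int = 10,
    seed: int = 0,
    methods: tuple[str, ...] = IMPORTANCE_METHODS,
) -> ImportanceReport:
    """Rank composites by four-classifier importance on the embeddings.

    Logistic importance is the absolute standardized coefficient; the
    tree family uses impurity-based split-criterion reduction. Each
    method is refit ``n_repeats`` times on seeded bootstrap resamples;
    scores are normalized to sum to 1 per fit.
    """
    X = np.asarray(level3_embeddings, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] != len(composite_names):
        raise ValueError("embedding width differs from composite count")
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant embedding column(s) {np.flatnonzero(const).tolist()} "
            "carry zero importance", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    for method in methods:
        reps = []
        for r in range(n_repeats):
            idx = rng.integers(0, len(y), size=len(y))
            if len(np.unique(y[idx])) < 2:       # bootstrap lost a class
                idx = np.arange(len(y))
            reps.append(_fit_importance(method, X[idx], y[idx],
                                        int(rng.integers(2**31))))
        reps = np.asarray(reps)
        reps[:, const] = 0.0
        ssum = reps.sum(axis=1, keepdims=True)
        reps = reps / np.where(ssum > 0, ssum, 1.0)
        for j, name in enumerate(composite_names):
            rows.append({
                "method": method, "composite": name,
                "mean": float(reps[:, j].mean()),
                "sd": float(reps[:, j].std(ddof=1)) if n_repeats > 1 else 0.0,
            })
    return ImportanceReport(scores=pd.DataFrame(rows))


@dataclass
class LayerShapReport:
    """Mean-absolute Shapley value per unit at each hierarchy layer.

    ``tables[level]`` has columns ``unit, parent, mean_abs_shap, sd``;
    ``parent`` links a variable to its combo (level 1) and a combo to its
    composite (level 2), enabling the cross-layer linked view.
    ``raw[level]`` holds the per-patient attribution matrices and
    ``base_values[level]`` the explainer base value.
    """

    tables: dict[int, pd.DataFrame]
    raw: dict[int, np.ndarray]
    base_values: dict[int, float]

    def ranking(self, level: int) -> list[str]:
        t = self.tables[level]
        return list(t.sort_values("mean_abs_shap", ascending=False)["unit"])


def layer_shap(
    model: StructuredEmbeddingClassifier,
    X: np.ndarray,
    background_size: int = 100,
    explain_size: int | None = None,
    n_permutations: int = 32,
    seed: int = 0,
    levels: tuple[int, ...] | None = None,
) -> LayerShapReport:
    """Shapley attributions of the case log-probability at every layer.

    Each level's embeddings are the explained features and the model's
    own downstream layers are the explained function; absent features are
    drawn from a seeded background sample of patients (capped at the
    cohort size, with a warning, if larger).
    """
    emb = model.embeddings(X)
    available = {1: emb.level1}
    if emb.level2 is not None:
        available[2] = emb.level2
    if emb.level3 is not None:
        available[3] = emb.level3
    levels = levels or tuple(sorted(available))

    n = emb.level1.shape[0]
    rng = np.random.default_rng(seed)
    if background_size > n:
        warnings.warn("background larger than cohort; capped",
                      RuntimeWarning, stacklevel=2)
        background_size = n
    bg_idx = rng.choice(n, size=background_size, replace=False)
    if explain_size is not None and explain_size < n:
        ex_idx = rng.choice(n, size=explain_size, replace=False)
    else:
        ex_idx = np.arange(n)

    tax: Taxonomy = model.taxonomy
    parents = {
        1: dict(tax.combo_map),
        2: ({c: model.taxonomy.strategies[model.strategy][c]
             for c in model.combos_} if model.level == "composite" else {}),
        3: {},
    }
    unit_names = {1: model.variables_, 2: model.combos_,
                  3: model.composites_ or []}

    tables: dict[int, pd.DataFrame] = {}
    raw: dict[int, np.ndarray] = {}
    bases: dict[int, float] = {}
    for lvl in levels:
        E = available[lvl]
        f = lambda Z, lvl=lvl: model.head_from_embeddings(lvl, Z)
        phi = shapley_values(
            f, E[ex_idx], E[bg_idx],
            n_permutations=n_permutations, seed=int(rng.integers(2**31)),
        )
        raw[lvl] = phi
        bases[lvl] = float(np.mean(f(E[bg_idx])))
        absphi = np.abs(phi)
        tables[lvl] = pd.DataFrame({
            "unit": unit_names[lvl],
            "parent": [parents[lvl].get(u, "") for u in unit_names[lvl]],
            "mean_abs_shap": absphi.mean(axis=0),
            "sd": absphi.std(axis=0, ddof=1) if len(ex_idx) > 1 else 0.0,
        })
    return LayerShapReport(tables=tables, raw=raw, base_values=bases)


def accumulated_shap(
    base_variable_shap: pd.DataFrame,
    taxonomy: Taxonomy,
    strategy: str,
) -> pd.DataFrame:
    """Roll base-model per-variable mean-|SHAP| up into composites.

    Sums member-variable values per composite under ``strategy``; the
    grand total is conserved exactly. Comparing this roll-up against the
    composite model's own level-3 attributions shows how attribution
    depends on architecture.
    """
    values = dict(zip(base_variable_shap["unit"], base_variable_shap["mean_abs_shap"]))
    missing = set(values) - set(taxonomy.variables)
    if missing:
        raise ValueError(f"variables outside the strategy closure: "
                         f"{sorted(missing)[:5]}")
    rows = []
    for comp in taxonomy.composites(strategy):
        members = taxonomy.composite_variables(strategy, comp)
        rows.append({
            "composite": comp,
            "accumulated_shap": float(sum(values.get(v, 0.0) for v in members)),
        })
    return pd.DataFrame(rows)


def plot_layer_shap(report: LayerShapReport, path=None):
    """Linked horizontal bar charts of mean |SHAP| per layer, colored by
    level-3 composite affiliation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = sorted(report.tables)
    fig, axes = plt.subplots(1, len(levels), figsize=(5 * len(levels), 8))
    axes = np.atleast_1d(axes)
    comp_table = report.tables.get(max(levels))
    palette = plt.get_cmap("tab10")
    comp_color = {u: palette(i % 10)
                  for i, u in enumerate(comp_table["unit"])} if comp_table is not None else {}

    def composite_of(level: int, unit: str) -> str:
        t = report.tables[level]
        row = t[t["unit"] == unit]
        parent = row["parent"].iloc[0] if len(row) else ""
        if level == max(levels):
            return unit
        if parent and level + 1 in report.tables:
            return composite_of(level + 1, parent)
        return unit

    for ax, lvl in zip(axes, levels):
        t = report.tables[lvl].sort_values("mean_abs_shap")
        top = t.tail(20)
        colors = [comp_color.get(composite_of(lvl, u), "grey") for u in top["unit"]]
        ax.barh(top["unit"], top["mean_abs_shap"], xerr=top["sd"], color=colors)
        ax.set_title(f"level {lvl}")
        ax.set_xlabel("mean |SHAP|")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
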