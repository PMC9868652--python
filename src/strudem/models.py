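"""Structured deep embedding models.

Three hierarchy levels share one architecture family:

* **base** — each variable's binned time series passes through its own
  small perceptron (bins -> hidden -> 1), yielding one scalar embedding
  per variable (206 on the packaged panel); a linear prediction layer
  with log-softmax maps the concatenated embeddings to the binary output.
* **combo** — a grouping layer bundles each combo's member-variable
  scalars into one combo embedding (32) before the prediction layer.
* **composite** — a second grouping layer bundles combos into composite
  indices under a named strategy (5 / 3 / 7 on the packaged panel).

Grouping layers are hard-masked linear maps followed by tanh: weights
outside a group's membership are structurally zero in the forward pass
and their gradients are masked to zero, so information can never flow
across groups. All intermediate embeddings are exposed for inspection.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import Adam, log_softmax, nll_loss
from .taxonomy import Taxonomy

__all__ = [
    "ModelSpec",
    "EmbeddingOutputs",
    "StructuredEmbeddingClassifier",
    "build_model",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]

_LEVELS = ("base", "combo", "composite")


@dataclass
class ModelSpec:
    """Declarative description of one structured model."""

    level: str = "composite"
    strategy: str | None = "g1"
    embed_hidden: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValueError(f"level must be one of {_LEVELS}, got {self.level!r}")
        if self.level == "composite" and not self.strategy:
            raise ValueError("composite level requires a grouping strategy")


@dataclass
class EmbeddingOutputs:
    """All readable intermediate embeddings plus the prediction."""

    level1: np.ndarray                 # (n, n_variables)
    level2: np.ndarray | None          # (n, n_combos) for combo/composite
    level3: np.ndarray | None          # (n, n_composites) for composite
    logits: np.ndarray                 # (n, 2) log-probabilities

    @property
    def final(self) -> np.ndarray:
        for e in (self.level3, self.level2, self.level1):
            if e is not None:
                return e
        raise AssertionError("unreachable")


def _membership_mask(groups: list[str], members: dict[str, list[str]],
                     order: list[str]) -> np.ndarray:
    idx = {name: j for j, name in enumerate(order)}
    M = np.zeros((len(groups), len(order)))
    for i, g in enumerate(groups):
        for m in members[g]:
            M[i, idx[m]] = 1.0
    return M


class StructuredEmbeddingClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchy-constrained embedding network with an sklearn interface.

    Parameters
    ----------
    taxonomy
        Validated variable hierarchy; fixes the input ordering and the
        group structure.
    level
        ``"base"``, ``"combo"`` or ``"composite"``.
    strategy
        Grouping strategy name (composite level only).
    embed_hidden
        Hidden width of each per-variable embedding perceptron.
    learning_rate, batch_size, max_epochs, patience
        Training protocol; ``patience`` counts epochs without improvement
        of the monitored loss before stopping.
    group_decay
        L2 penalty applied to the grouping layers only; encourages even
        credit across redundant members of a group and suppresses
        co-adapted noise pathways through the bottleneck.
    random_state
        Seeds initialization and batch shuffling; identical settings give
        bit-identical weights.

    ``fit(X, y, eval_set=(Xe, ye))`` monitors loss on ``eval_set`` for
    early stopping (when omitted, training runs all epochs). ``X`` may be
    ``(n, n_variables, n_bins)`` or flattened 2-D.
    """

    def __init__(self, taxonomy: Taxonomy | None = None, level: str = "composite",
                 strategy: str | None = "g1", embed_hidden: int = 8,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 50, patience: int = 5,
                 group_decay: float = 0.1, random_state: int = 0):
        self.taxonomy = taxonomy
        self.level = level
        self.strategy = strategy
        self.embed_hidden = embed_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.group_decay = group_decay
        self.random_state = random_state

    # -- construction --------------------------------------------------
    def _structure(self) -> None:
        tax = self.taxonomy
        if tax is None:
            raise ValueError("taxonomy is required")
        ModelSpec(level=self.level, strategy=self.strategy,
                  embed_hidden=self.embed_hidden, seed=self.random_state)
        self.variables_ = list(tax.variables)
        self.combos_ = list(tax.combos)
        self.combo_mask_ = _membership_mask(
            self.combos_, {c: tax.combo_members(c) for c in self.combos_},
            self.variables_)
        if self.level == "composite":
            self.composites_ = list(tax.composites(self.strategy))
            self.composite_mask_ = _membership_mask(
                self.composites_,
                {k: tax.composite_members(self.strategy, k)
                 for k in self.composites_},
                self.combos_)
        else:
            self.composites_ = None
            self.composite_mask_ = None

    def initialize(self, n_bins: int) -> "StructuredEmbeddingClassifier":
        """Build seeded initial weights for inputs with ``n_bins`` bins.

        Initialization encodes a composite-index prior: every weight
        starts at the positive mean-pooling value (1/fan-in) perturbed by
        50% multiplicative noise, so each embedding begins life as
        roughly the mean of its standardized children — the hierarchy is
        clinically meaningful from epoch 0 and the sign symmetry that
        stalls deep masked stacks is broken, while the noise decouples
        hidden units. Biases start at zero.
        """
        self._structure()
        rng = np.random.default_rng(self.random_state)
        V, H = len(self.variables_), self.embed_hidden
        B = int(n_bins)

        def mean_init(shape, fan):
            return (1.0 / fan) * (1.0 + 0.5 * rng.standard_normal(shape))

        w: dict[str, np.ndarray] = {
            "W1": mean_init((V, B, H), B),
            "b1": np.zeros((V, H)),
            "w2": mean_init((V, H), H),
            "b2": np.zeros(V),
        }
        if self.level in ("combo", "composite"):
            C = len(self.combos_)
            fan = self.combo_mask_.sum(axis=1, keepdims=True)
            w["A"] = mean_init((C, V), fan) * self.combo_mask_
            w["bA"] = np.zeros(C)
        if self.level == "composite":
            K = len(self.composites_)
            fan = self.composite_mask_.sum(axis=1, keepdims=True)
            w["G"] = mean_init((K, C), fan) * self.composite_mask_
            w["bG"] = np.zeros(K)
        F = self.final_layer_width
        w["Wp"] = rng.standard_normal((2, F)) / np.sqrt(F)
        w["bp"] = np.zeros(2)
        self.weights_ = w
        self.n_bins_ = B
        self.n_features_in_ = V * B
        self.classes_ = np.array([0, 1])
        return self

    @property
    def final_layer_width(self) -> int:
        """Width of the final embedding layer (206 / 32 / |composites|
        on the packaged panel)."""
        if not hasattr(self, "variables_"):
            self._structure()
        if self.level == "base":
            return len(self.variables_)
        if self.level == "combo":
            return len(self.combos_)
        return len(self.composites_)

    def n_parameters(self) -> int:
        """Free (unmasked) parameter count."""
        w = self.weights_
        n = w["W1"].size + w["b1"].size + w["w2"].size + w["b2"].size
        if "A" in w:
            n += int(self.combo_mask_.sum()) + w["bA"].size
        if "G" in w:
            n += int(self.composite_mask_.sum()) + w["bG"].size
        return n + w["Wp"].size + w["bp"].size

    # -- forward / backward --------------------------------------------
    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        V, B = len(self.variables_), self.n_bins_
        if X.ndim == 2:
            if X.shape[1] != V * B:
                raise ValueError(
                    f"feature axis: expected {V} variables x {B} bins = "
                    f"{V * B}, got {X.shape[1]}")
            X = X.reshape(-1, V, B)
        elif X.ndim == 3:
            if X.shape[1] != V:
                raise ValueError(f"variables axis: expected {V}, got {X.shape[1]}")
            if X.shape[2] != B:
                raise ValueError(f"bins axis: expected {B}, got {X.shape[2]}")
        else:
            raise ValueError("X must be 2-D or 3-D")
        return X

    def _forward(self, X3: np.ndarray) -> dict[str, np.ndarray]:
        w = self.weights_
        h1 = np.tanh(np.einsum("nvb,vbh->nvh", X3, w["W1"]) + w["b1"])
        e1 = np.einsum("nvh,vh->nv", h1, w["w2"]) + w["b2"]
        out: dict[str, np.ndarray] = {"h1": h1, "e1": e1}
        f = e1
        if "A" in w:
            e2 = np.tanh(e1 @ w["A"].T + w["bA"])
            out["e2"] = e2
            f = e2
        if "G" in w:
            e3 = np.tanh(out["e2"] @ w["G"].T + w["bG"])
            out["e3"] = e3
            f = e3
        logits = f @ w["Wp"].T + w["bp"]
        out["logp"] = log_softmax(logits)
        return out

    def _backward(self, X3: np.ndarray, y: np.ndarray,
                  cache: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        w = self.weights_
        n = len(y)
        p = np.exp(cache["logp"])
        p[np.arange(n), y] -= 1.0
        dlogits = p / n
        f = cache.get("e3", cache.get("e2", cache["e1"]))
        g: dict[str, np.ndarray] = {
            "Wp": dlogits.T @ f,
            "bp": dlogits.sum(axis=0),
        }
        df = dlogits @ w["Wp"]
        if "G" in w:
            e3 = cache["e3"]
            dz3 = df * (1.0 - e3 * e3)
            g["G"] = (dz3.T @ cache["e2"]) * self.composite_mask_
            g["bG"] = dz3.sum(axis=0)
            df = dz3 @ w["G"]
        if "A" in w:
            e2 = cache["e2"]
            dz2 = df * (1.0 - e2 * e2)
            g["A"] = (dz2.T @ cache["e1"]) * self.combo_mask_
            g["bA"] = dz2.sum(axis=0)
            df = dz2 @ w["A"]
        de1 = df
        h1 = cache["h1"]
        g["w2"] = np.einsum("nv,nvh->vh", de1, h1)
        g["b2"] = de1.sum(axis=0)
        dz1 = de1[:, :, None] * w["w2"][None, :, :] * (1.0 - h1 * h1)
        g["W1"] = np.einsum("nvb,nvh->vbh", X3, dz1)
        g["b1"] = dz1.sum(axis=(0,))
        return g

    # -- sklearn surface ------------------------------------------------
    def fit(self, X, y, eval_set=None):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("fit requires both classes present")
        X = np.asarray(X, dtype=float)
        n_bins = X.shape[-1] if X.ndim == 3 else None
        if n_bins is None:
            self._structure()
            V = len(self.variables_)
            if X.shape[1] % V:
                raise ValueError(
                    f"feature axis: {X.shape[1]} not divisible by {V} variables")
            n_bins = X.shape[1] // V
        self.initialize(n_bins)
        X3 = self._check_X(X)
        if eval_set is not None:
            Xe = self._check_X(np.asarray(eval_set[0], dtype=float))
            ye = np.asarray(eval_set[1], dtype=int)
        rng = np.random.default_rng(self.random_state + 1)
        opt = Adam(self.weights_, lr=self.learning_rate)
        best_loss, best_w, best_epoch, stall = np.inf, None, 0, 0
        self.loss_history_, self.val_loss_history_ = [], []
        n = len(y)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                cache = self._forward(X3[idx])
                grads = self._backward(X3[idx], y[idx], cache)
                # L2 on grouping layers only: spreads weight evenly across
                # redundant group members and damps co-adapted noise paths
                # (masked entries are zero, so masking is preserved)
                for k in ("A", "G"):
                    if k in grads:
                        grads[k] = grads[k] + self.group_decay * self.weights_[k]
                opt.step(grads)
            self.loss_history_.append(nll_loss(self._forward(X3)["logp"], y))
            if eval_set is not None:
                vloss = nll_loss(self._forward(Xe)["logp"], ye)
                self.val_loss_history_.append(vloss)
                if vloss < best_loss - 1e-6:
                    best_loss, best_epoch, stall = vloss, epoch, 0
                    best_w = copy.deepcopy(self.weights_)
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if eval_set is not None and best_w is not None:
            self.weights_ = best_w
        self.best_epoch_ = best_epoch
        self.epochs_run_ = len(self.loss_history_)
        return self

    def predict_log_proba(self, X) -> np.ndarray:
        return self._forward(self._check_X(np.asarray(X, dtype=float)))["logp"]

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_log_proba(X).argmax(axis=1)]

    def decision_function(self, X) -> np.ndarray:
        lp = self.predict_log_proba(X)
        return lp[:, 1] - lp[:, 0]

    # -- inspection -----------------------------------------------------
    def embeddings(self, X) -> EmbeddingOutputs:
        """Run the network and expose every intermediate embedding."""
        cache = self._forward(self._check_X(np.asarray(X, dtype=float)))
        return EmbeddingOutputs(
            level1=cache["e1"],
            level2=cache.get("e2"),
            level3=cache.get("e3"),
            logits=cache["logp"],
        )

    def head_from_embeddings(self, level: int, E: np.ndarray) -> np.ndarray:
        """Case-class log-probability as a function of the embeddings at a
        hierarchy level, running only the downstream layers.

        ``level`` is 1 (variables), 2 (combos) or 3 (composites); the
        requested level must exist in this model.
        """
        w = self.weights_
        E = np.asarray(E, dtype=float)
        f = E
        if level == 1:
            if "A" in w:
                f = np.tanh(f @ w["A"].T + w["bA"])
            if "G" in w:
                f = np.tanh(f @ w["G"].T + w["bG"])
        elif level == 2:
            if "A" not in w:
                raise ValueError("model has no combo layer")
            if "G" in w:
                f = np.tanh(f @ w["G"].T + w["bG"])
        elif level == 3:
            if "G" not in w:
                raise ValueError("model has no composite layer")
        else:
            raise ValueError("level must be 1, 2 or 3")
        logits = f @ w["Wp"].T + w["bp"]
        return log_softmax(logits)[:, 1]


def build_model(taxonomy: Taxonomy, spec: ModelSpec,
                n_bins: int | None = None) -> StructuredEmbeddingClassifier:
    """Construct (and, when ``n_bins`` is given, initialize) a model."""
    model = StructuredEmbeddingClassifier(
        taxonomy=taxonomy, level=spec.level, strategy=spec.strategy,
        embed_hidden=spec.embed_hidden, random_state=spec.seed,
    )
    if n_bins is not None:
        model.initialize(n_bins)
    else:
        model._structure()
    return model


def forward(model: StructuredEmbeddingClassifier, tensorized) -> EmbeddingOutputs:
    """Evaluate a model on a :class:`~strudem.prep.TensorizedCohort`."""
    if list(tensorized.variables) != list(model.variables_):
        raise ValueError("variables axis: cohort ordering differs from taxonomy")
    return model.embeddings(tensorized.values)


def save_checkpoint(model: StructuredEmbeddingClassifier, path) -> None:
    """Serialize weights with the taxonomy hash pinned."""
    meta = dict(
        level=model.level, strategy=model.strategy or "",
        embed_hidden=model.embed_hidden, n_bins=model.n_bins_,
        taxonomy_hash=model.taxonomy.content_hash(),
    )
    np.savez(path, __meta__=np.array([repr(meta)]),
             **{f"w_{k}": v for k, v in model.weights_.items()})


def load_checkpoint(path, taxonomy: Taxonomy) -> StructuredEmbeddingClassifier:
    """Load a checkpoint, refusing a mismatched taxonomy."""
    import ast
    with np.load(path, allow_pickle=False) as z:
        meta = ast.literal_eval(str(z["__meta__"][0]))
        weights = {k[2:]: z[k] for k in z.files if k.startswith("w_")}
    if meta["taxonomy_hash"] != taxonomy.content_hash():
        raise ValueError("checkpoint was trained against a different taxonomy")
    model = StructuredEmbeddingClassifier(
        taxonomy=taxonomy, level=meta["level"],
        strategy=meta["strategy"] or None, embed_hidden=int(meta["embed_hidden"]),
    )
    model.initialize(int(meta["n_bins"]))
    model.weights_ = weights
    return model
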