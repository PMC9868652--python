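"""Shapley-value attribution engine.

Attributes a scalar model output to input features by the Shapley value
of the game ``v(S) = E_b[f(x_S, b_{-S})]``, with absent features drawn
from a background sample. Two estimators are provided:

* exact subset enumeration (``2^F`` coalition evaluations) for small
  feature counts — the composite layer has at most a handful of indices;
* antithetic permutation sampling otherwise — marginal contributions
  along a permutation telescope, so the additivity identity
  ``sum_i phi_i = f(x) - E_b[f(b)]`` holds to float precision for any
  number of sampled permutations.
"""

from __future__ import annotations

from math import comb

import numpy as np

__all__ = ["shapley_values", "expected_value"]


def expected_value(f, background: np.ndarray) -> float:
    """Base value: mean model output over the background sample."""
    return float(np.mean(f(background)))


def _coalition_eval(f, X: np.ndarray, background: np.ndarray,
                    mask: np.ndarray) -> np.ndarray:
    """Mean over the background of f(x with mask features from x, rest
    from background), for every row of X. Returns (n_x,)."""
    n_x, F = X.shape
    n_b = background.shape[0]
    Z = np.repeat(background[None, :, :], n_x, axis=0)      # (n_x, n_b, F)
    Z[:, :, mask] = X[:, None, mask]
    vals = f(Z.reshape(n_x * n_b, F))
    return vals.reshape(n_x, n_b).mean(axis=1)


def shapley_values(
    f,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 64,
    exact_limit: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Shapley values of ``f`` for each row of ``X``.

    Parameters
    ----------
    f
        Vectorized map from ``(m, F)`` arrays to ``(m,)`` outputs.
    X
        Rows to explain, shape ``(n, F)``.
    background
        Reference sample supplying absent-feature values, shape ``(B, F)``.
    n_permutations
        Sampled permutations (rounded up to even for antithetic pairs)
        when ``F > exact_limit``.
    exact_limit
        Feature count up to which exact enumeration is used.

    Returns
    -------
    ndarray of shape ``(n, F)`` with
    ``phi.sum(1) == f(X) - mean(f(background))`` (exactly, both regimes).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, F = X.shape
    if background.shape[1] != F:
        raise ValueError("background feature count differs from X")
    if F <= exact_limit:
        return _exact(f, X, background)
    return _permutation(f, X, background, n_permutations, seed)


def _exact(f, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    n, F = X.shape
    # v(S) for all 2^F coalitions, indexed by bitmask
    v = np.empty((1 << F, n))
    for bits in range(1 << F):
        mask = np.array([(bits >> i) & 1 for i in range(F)], dtype=bool)
        v[bits] = _coalition_eval(f, X, background, mask)
    phi = np.zeros((n, F))
    fact_weight = [1.0 / (F * comb(F - 1, s)) for s in range(F)]
    for i in range(F):
        bit = 1 << i
        for bits in range(1 << F):
            if bits & bit:
                continue
            s = bin(bits).count("1")
            phi[:, i] += fact_weight[s] * (v[bits | bit] - v[bits])
    return phi


def _permutation(f, X: np.ndarray, background: np.ndarray,
                 n_permutations: int, seed: int) -> np.ndarray:
    n, F = X.shape
    rng = np.random.default_rng(seed)
    n_pairs = max(1, (n_permutations + 1) // 2)
    phi = np.zeros((n, F))
    total = 0
    for _ in range(n_pairs):
        perm = rng.permutation(F)
        for p in (perm, perm[::-1]):        # antithetic pair
            mask = np.zeros(F, dtype=bool)
            prev = _coalition_eval(f, X, background, mask)
            for i in p:
                mask[i] = True
                cur = _coalition_eval(f, X, background, mask)
                phi[:, i] += cur - prev
                prev = cur
            total += 1
    return phi / total
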