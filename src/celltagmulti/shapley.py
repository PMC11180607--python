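"""Interventional Shapley values for model interpretation.

Attributes a model's per-class output for one sample to its input features.
The value function of a feature subset S is the expectation of the model
output when features in S are fixed to the explained sample and the
remaining features are drawn from a background sample:

    v(S) = E_b[ f(x_S, b_{~S}) ]

The Shapley value of feature i is the weighted average of its marginal
contributions v(S + i) - v(S) over all subsets S not containing i. With
exact subset enumeration the attributions satisfy the additivity identity
``base_value + sum_i phi_i == f(x)`` exactly, where ``base_value = v(empty)``
is the mean model output over the background.

Exact enumeration costs ``2^p * n_background`` model evaluations per sample
and is used up to ``max_exact_features``; beyond that a Monte-Carlo
permutation estimator (mean marginal contribution over sampled feature
orderings) is used, which converges to the same values.
"""

from __future__ import annotations

from collections.abc import Callable
from math import factorial

import numpy as np

PredictFn = Callable[[np.ndarray], np.ndarray]


def _subset_masks(p: int) -> np.ndarray:
    """(2^p, p) boolean matrix; row m is the bitmask of subset m."""
    masks = np.arange(2**p, dtype=np.uint32)
    return (masks[:, None] >> np.arange(p)) & 1 == 1


def _exact_one(
    predict: PredictFn, x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    p = x.size
    masks = _subset_masks(p)  # (2^p, p)
    n_bg = background.shape[0]
    # hybrid rows: x where the subset holds the feature, background elsewhere
    hybrids = np.where(masks[:, None, :], x[None, None, :], background[None, :, :])
    values = predict(hybrids.reshape(-1, p)).reshape(2**p, n_bg).mean(axis=1)

    weights = np.array(
        [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
    )
    sizes = masks.sum(axis=1)
    phi = np.zeros(p)
    bit = 1 << np.arange(p, dtype=np.uint32)
    idx = np.arange(2**p, dtype=np.uint32)
    for i in range(p):
        without = (idx & bit[i]) == 0
        s_idx = idx[without]
        phi[i] = np.sum(
            weights[sizes[without]] * (values[s_idx | bit[i]] - values[s_idx])
        )
    return phi, float(values[0])


def _permutation_one(
    predict: PredictFn,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    p = x.size
    n_bg = background.shape[0]
    phi = np.zeros(p)
    base = float(predict(background).mean())
    for _ in range(n_permutations):
        order = rng.permutation(p)
        current = background.copy()
        prev = float(predict(current).mean())
        for i in order:
            current[:, i] = x[i]
            val = float(predict(current).mean())
            phi[i] += val - prev
            prev = val
    return phi / n_permutations, base


def shapley_values(
    predict: PredictFn,
    X_explain: np.ndarray,
    background: np.ndarray,
    method: str = "auto",
    max_exact_features: int = 12,
    n_permutations: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Shapley attributions for each row of ``X_explain``.

    Parameters
    ----------
    predict
        Vectorised model output, ``(n, p) -> (n,)`` — e.g. the predicted
        probability of one class.
    background
        (n_bg, p) reference sample defining the interventional expectation.
    method
        ``"exact"``, ``"permutation"`` or ``"auto"`` (exact while
        ``p <= max_exact_features``).

    Returns
    -------
    phi : (n, p) array of attributions.
    base_value : mean model output over the background.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = X_explain.shape[1]
    if background.shape[1] != p:
        raise ValueError("background feature dimension mismatch")
    if method == "auto":
        method = "exact" if p <= max_exact_features else "permutation"
    if method not in ("exact", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    phis = np.empty_like(X_explain)
    base = 0.0
    for r, x in enumerate(X_explain):
        if method == "exact":
            phis[r], base = _exact_one(predict, x, background)
        else:
            phis[r], base = _permutation_one(
                predict, x, background, n_permutations, rng
            )
    return phis, base
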