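"""Exact Shapley-value feature attribution for black-box models.

Computes interventional Shapley values by full enumeration of feature
coalitions: the value of a coalition S for a sample x is the model's mean
prediction over a background dataset with the features in S fixed to x's
values.  With d features this costs 2^d model evaluations over
n_samples × n_background rows — exact (no sampling error) and feasible for
the small predictor sets used in multivariate prognostic models.

Local accuracy holds by construction: per sample, attributions sum to the
model's prediction minus the mean background prediction.  A feature the
model never uses receives attribution exactly 0.
"""

from __future__ import annotations

from math import factorial
from typing import Callable

import numpy as np
import pandas as pd  # noqa: F401  (DataFrame inputs accepted)

MAX_EXACT_FEATURES = 14


def exact_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray | pd.DataFrame,
    background: np.ndarray | pd.DataFrame | None = None,
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley attributions.

    Parameters
    ----------
    predict : callable mapping an (m, d) array to m scalar predictions.
    X : samples to explain, (n, d).
    background : reference distribution for marginalising absent features;
        defaults to ``X`` itself.

    Returns
    -------
    (phi, base) — phi is (n, d) attributions; base the mean background
    prediction, so ``phi.sum(axis=1) + base == predict(X)`` exactly (up to
    float roundoff).
    """
    X = np.asarray(X, dtype=float)
    bg = X if background is None else np.asarray(background, dtype=float)
    n, d = X.shape
    if d > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration over {d} features is intractable (max {MAX_EXACT_FEATURES})"
        )
    n_bg = len(bg)
    n_masks = 1 << d

    # v[i, mask] = mean over background of predict(x_i on mask, bg elsewhere)
    v = np.empty((n, n_masks))
    tiled_bg = np.tile(bg, (n, 1))  # row-major blocks of bg per sample
    rep_X = np.repeat(X, n_bg, axis=0)
    for mask in range(n_masks):
        cols = [j for j in range(d) if mask >> j & 1]
        block = tiled_bg.copy()
        if cols:
            block[:, cols] = rep_X[:, cols]
        preds = np.asarray(predict(block), dtype=float).reshape(n, n_bg)
        v[:, mask] = preds.mean(axis=1)

    # Shapley weights by coalition size
    w = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    phi = np.zeros((n, d))
    for mask in range(n_masks):
        s = bin(mask).count("1")
        for j in range(d):
            if mask >> j & 1:
                continue
            phi[:, j] += w[s] * (v[:, mask | (1 << j)] - v[:, mask])
    # v[:, 0] is identical across samples (pure background mean)
    base = float(v[0, 0]) if n else 0.0
    return phi, base
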