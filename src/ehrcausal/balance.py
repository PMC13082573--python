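"""Covariate balance diagnostics.

Standardized mean differences between arms, unweighted and under ATE
(inverse-propensity) weighting, with the conventional |SMD| > 0.1 flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    return m, v


def standardized_mean_differences(
    X: np.ndarray,
    A: np.ndarray,
    propensity: np.ndarray | None = None,
    columns: list[str] | None = None,
    flag_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-covariate SMD table, unweighted and (optionally) ATE-weighted.

    ``SMD_j = (mean_1j - mean_0j) / sqrt((var_1j + var_0j) / 2)``; with a
    propensity supplied, means and variances use ATE weights
    ``1{A=a} / pi_a``.  Zero pooled variance reports SMD 0 with a flag.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.asarray(A).astype(int)
    if not (np.any(A == 1) and np.any(A == 0)):
        raise ValueError("both arms must be present")
    n, p = X.shape
    cols = columns if columns is not None else [f"x{j}" for j in range(p)]

    def smd(weights1: np.ndarray, weights0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = np.zeros(p)
        degenerate = np.zeros(p, dtype=bool)
        for j in range(p):
            m1, v1 = _weighted_mean_var(X[A == 1, j], weights1)
            m0, v0 = _weighted_mean_var(X[A == 0, j], weights0)
            pooled = (v1 + v0) / 2
            if pooled <= 0:
                degenerate[j] = True
            else:
                vals[j] = (m1 - m0) / np.sqrt(pooled)
        return vals, degenerate

    raw, degen_raw = smd(np.ones(int(A.sum())), np.ones(int((1 - A).sum())))
    out = pd.DataFrame({"covariate": cols, "smd_unweighted": raw,
                        "degenerate": degen_raw})
    if propensity is not None:
        pi = np.asarray(propensity, dtype=float)
        w1 = 1.0 / pi[A == 1]
        w0 = 1.0 / (1.0 - pi[A == 0])
        wtd, degen_w = smd(w1, w0)
        out["smd_weighted"] = wtd
        out["degenerate"] |= degen_w
        out["flag_weighted"] = np.abs(wtd) > flag_threshold
    out["flag_unweighted"] = np.abs(raw) > flag_threshold
    return out
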