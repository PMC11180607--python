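"""Small statistical primitives shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR control).

    Sorted p-values are scaled by m/rank and a reverse cumulative minimum
    enforces monotonicity; adjusted values are clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney–Wilcoxon rank-sum p-value.

    Uses the exact null distribution when both samples are small and
    untied, otherwise the normal approximation with tie correction.
    """
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
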