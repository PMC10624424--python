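"""Shared statistical helpers: BH-FDR and t-tests robust to degenerate cells."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "one_sample_t", "paired_t"]


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR correction.

    Returns (reject, qvals) where ``qvals`` are BH-adjusted p-values
    (monotone, ≥ p).  NaN p-values are never rejected and stay NaN.
    """
    p = np.asarray(pvals, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    qvals = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        reject[ok] = rej
        qvals[ok] = qv
    return reject, qvals


def one_sample_t(x: np.ndarray) -> tuple[float, float]:
    """One-sample t vs 0.

    Zero sample variance is degenerate: identically-zero samples give the
    conventional (t=0, p=1); a constant non-zero sample has no defined t
    and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan"), float("nan")
    if np.std(x, ddof=1) == 0:
        return (0.0, 1.0) if np.allclose(x, 0) else (float("nan"), float("nan"))
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t-test on a−b; (nan, nan) on zero-variance differences.

    The zero-variance guard also covers the identical-samples case, where
    the difference is exactly 0 for every pair and t is 0 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = np.isfinite(a) & np.isfinite(b)
    a, b = a[m], b[m]
    if a.size < 2:
        return float("nan"), float("nan")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return (0.0, 1.0) if np.allclose(d, 0) else (float("nan"), float("nan"))
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
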