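"""Infant haemodynamic / metabolic response-function estimation.

The impulse response linking neural events to chromophore changes is
modelled as a difference of two gamma densities (the canonical
double-gamma form):

    h(t) = g(t; a=delay_response, scale=1) - g(t; a=delay_undershoot, scale=1) / ratio

peak-normalised to max h = 1.  With unit scale the gamma shape parameter
is the delay (mode at a-1 s, conventionally quoted as the "delay" of the
6/16 adult canonical).  Infant kernels are recovered by exhaustively
fitting grand-average block responses with every parameter combination on
a 1 s grid (delays 5–15 s, undershoots 5–20 s, ratios 2–6) and keeping
the combination with the highest statistically significant β.

β-values are comparable across candidate kernels only if the regressors
share a scale, so the event-convolved regressor is z-scored before the
fit; argmax β then coincides with argmax correlation, i.e. the best fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ADULT_CANONICAL,
    BasisParams,
    Block,
    DegenerateDesignError,
    GridSearchResult,
    InvalidArgumentError,
    ResponseFunction,
    StimulusSchedule,
)

__all__ = [
    "double_gamma",
    "single_block_schedule",
    "build_regressor",
    "fit_grand_average",
    "grid_search_hrf",
    "default_grid",
    "ADULT_CANONICAL",
]

#: Default kernel support (s): covers the slowest grid undershoot (20 s
#: delay) and its decay.
KERNEL_DURATION_S = 45.0


def double_gamma(
    params: BasisParams,
    sample_period_s: float,
    duration_s: float = KERNEL_DURATION_S,
) -> ResponseFunction:
    """Sample the peak-normalised double-gamma kernel on a uniform grid."""
    if sample_period_s <= 0:
        raise InvalidArgumentError("sample_period_s must be positive")
    if duration_s <= params.delay_undershoot_s:
        raise InvalidArgumentError("duration_s must cover the undershoot delay")
    t = np.arange(0.0, duration_s + 0.5 * sample_period_s, sample_period_s)
    h = (
        stats.gamma.pdf(t, a=params.delay_response_s)
        - stats.gamma.pdf(t, a=params.delay_undershoot_s)
        / params.ratio_response_undershoot
    )
    peak = h.max()
    if peak <= 0:
        raise InvalidArgumentError("kernel has no positive lobe")
    return ResponseFunction(kernel=h / peak, params=params,
                            sample_period_s=sample_period_s)


def single_block_schedule(
    stimulus_duration_s: float = 10.0, baseline_s: float = 8.0
) -> StimulusSchedule:
    """A one-event schedule matching a block-averaged epoch: ``baseline_s``
    of pre-stimulus baseline then one stimulus block."""
    blocks = [
        Block("baseline", 0.0, baseline_s),
        Block("social", baseline_s, stimulus_duration_s),
    ]
    return StimulusSchedule(blocks=blocks,
                            total_duration_s=baseline_s + stimulus_duration_s)


def build_regressor(
    params: BasisParams,
    schedule: StimulusSchedule,
    time_s: np.ndarray,
    standardize: bool = True,
) -> np.ndarray:
    """Event boxcar convolved with the double-gamma kernel on ``time_s``.

    The convolution is a causal Riemann sum (boxcar ⊛ kernel · dt) anchored
    at the grid origin.  With ``standardize`` the result is z-scored.
    """
    time_s = np.asarray(time_s, dtype=float)
    dt = float(time_s[1] - time_s[0])
    rf = double_gamma(params, dt)
    boxcar = schedule.boxcar(time_s)
    reg = np.convolve(boxcar, rf.kernel)[: time_s.size] * dt
    if standardize:
        sd = reg.std()
        if sd < 1e-12:
            raise DegenerateDesignError("regressor is constant on this grid")
        reg = (reg - reg.mean()) / sd
    return reg


@dataclass(frozen=True)
class FitResult:
    beta: float
    t: float
    p: float


def _ols_slope(y: np.ndarray, x: np.ndarray) -> FitResult:
    """Slope of OLS of y on [1, x] with its t statistic and two-sided p."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx < 1e-24:
        raise DegenerateDesignError("zero-variance regressor")
    beta = float(xc @ (y - y.mean())) / sxx
    resid = y - y.mean() - beta * xc
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else np.inf
    se = np.sqrt(s2 / sxx)
    if se == 0:
        tval, p = np.inf * np.sign(beta), 0.0
    else:
        tval = beta / se
        p = 2.0 * stats.t.sf(abs(tval), dof)
    return FitResult(beta=beta, t=float(tval), p=float(p))


def fit_grand_average(
    grand_avg: np.ndarray,
    params: BasisParams,
    schedule: StimulusSchedule,
    time_s: np.ndarray | None = None,
    sample_period_s: float = 1.0,
) -> FitResult:
    """GLM fit of a grand-average trace on the event-convolved kernel.

    Returns the slope β (on the z-scored regressor), its t and two-sided p.
    """
    grand_avg = np.asarray(grand_avg, dtype=float)
    if np.ptp(grand_avg) < 1e-15:
        raise DegenerateDesignError("grand average is constant")
    if time_s is None:
        time_s = np.arange(grand_avg.size) * sample_period_s
    if time_s.size != grand_avg.size:
        raise InvalidArgumentError("grand_avg and time grid differ in length")
    x = build_regressor(params, schedule, time_s)
    return _ols_slope(grand_avg, x)


def default_grid() -> dict[str, np.ndarray]:
    """The exhaustive search grid: response delay 5–15 s, undershoot delay
    5–20 s, ratio 2–6, all in steps of 1 (11 × 16 × 5 = 880 combinations)."""
    return {
        "delay_response_s": np.arange(5.0, 16.0),
        "delay_undershoot_s": np.arange(5.0, 21.0),
        "ratio_response_undershoot": np.arange(2.0, 7.0),
    }


def grid_search_hrf(
    grand_avg: np.ndarray,
    schedule: StimulusSchedule,
    time_s: np.ndarray | None = None,
    sample_period_s: float = 1.0,
    grid: dict[str, np.ndarray] | None = None,
    p_threshold: float = 0.05,
) -> GridSearchResult:
    """Exhaustive double-gamma grid search on a grand-average response.

    Every parameter combination is fitted by :func:`fit_grand_average`; the
    best combination is the one with the highest β among significant fits
    (p < ``p_threshold``).  Ties break lexicographically on
    (delay_response, delay_undershoot, ratio) by iteration order.  If no
    fit is significant the overall argmax β is returned flagged
    non-significant.
    """
    if grid is None:
        grid = default_grid()
    if any(v.size == 0 for v in grid.values()):
        raise InvalidArgumentError("grid must be non-empty")
    grand_avg = np.asarray(grand_avg, dtype=float)
    if np.ptp(grand_avg) < 1e-15:
        raise DegenerateDesignError("grand average is constant; nothing to fit")

    rows = []
    for dr, du, ratio in itertools.product(
        grid["delay_response_s"],
        grid["delay_undershoot_s"],
        grid["ratio_response_undershoot"],
    ):
        params = BasisParams(float(dr), float(du), float(ratio))
        fit = fit_grand_average(grand_avg, params, schedule,
                                time_s=time_s, sample_period_s=sample_period_s)
        rows.append((float(dr), float(du), float(ratio),
                     fit.beta, fit.t, fit.p))
    table = pd.DataFrame(
        rows,
        columns=["delay_response_s", "delay_undershoot_s",
                 "ratio_response_undershoot", "beta", "t", "p"],
    )

    sig = table[table["p"] < p_threshold]
    pool = sig if len(sig) else table
    # idxmax on the lexicographically ordered table keeps the first maximum
    best_row = pool.loc[pool["beta"].idxmax()]
    best = BasisParams(
        best_row["delay_response_s"],
        best_row["delay_undershoot_s"],
        best_row["ratio_response_undershoot"],
    )
    return GridSearchResult(
        table=table,
        best=best,
        best_beta=float(best_row["beta"]),
        best_p=float(best_row["p"]),
        significant=bool(len(sig)),
        p_threshold=p_threshold,
        grid=grid,
    )
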