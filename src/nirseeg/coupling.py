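"""Neurovascular / neurometabolic coupling GLM.

For each infant, chromophore, bNIRS channel, EEG channel and band the
reconstructed infant HRF/MRF is convolved with the stimulus events to
give a predicted bNIRS series; that series is convolved with the
stimulus-period EEG RMS power block to form the neural regressor, which
is fitted to the block-averaged bNIRS stimulus window (both conditions in
one design).  Group-level one-sample t-tests on β (and paired social vs
non-social contrasts) are BH-FDR corrected across the selected bNIRS
channels within each (EEG channel, band, chromophore, condition) family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .statsutil import bh_fdr, one_sample_t, paired_t
from .types import (
    CHROMOPHORES,
    DegenerateDesignError,
    InvalidArgumentError,
    NeuralRegressor,
    ResponseFunction,
    StimulusSchedule,
    SubjectGLMResult,
)

__all__ = [
    "select_coupling_channels",
    "build_neural_regressor",
    "fit_subject_glm",
    "fit_subject_conditions",
    "group_coupling_stats",
    "condition_contrast",
]

STIM_WINDOW_S = 8.0


def select_coupling_channels(
    per_condition_lists: dict[tuple[str, str], set[int] | list[int]],
) -> list[int]:
    """Union of the channels showing haemodynamic–metabolic coupling across
    conditions and chromophores, sorted — the channel set is kept identical
    across chromophores and conditions for consistency."""
    union: set[int] = set()
    for chans in per_condition_lists.values():
        union |= set(chans)
    return sorted(union)


def build_neural_regressor(
    rf: ResponseFunction,
    schedule: StimulusSchedule | None,
    rms_block: np.ndarray,
    bnirs_grid_s: np.ndarray,
    source: tuple[str, str, str] = ("", "", ""),
    stim_duration_s: float = STIM_WINDOW_S,
) -> NeuralRegressor:
    """Double-convolution neural regressor.

    predicted(t) = (event boxcar ⊛ kernel)(t) on a 1 s working grid;
    regressor = (predicted ⊛ rms_block), causal and onset-anchored,
    truncated to the stimulus window, linearly interpolated onto the bNIRS
    grid and z-scored.  ``rms_block`` is the 8-sample stimulus-period RMS
    power at 1 s resolution; ``bnirs_grid_s`` is in seconds from stimulus
    onset.
    """
    rms_block = np.asarray(rms_block, dtype=float)
    if rms_block.size == 0 or np.allclose(rms_block, 0.0) or not np.all(
        np.isfinite(rms_block)
    ):
        raise DegenerateDesignError("RMS power block is zero/non-finite")
    bnirs_grid_s = np.asarray(bnirs_grid_s, dtype=float)
    event_s = stim_duration_s
    if schedule is not None:
        exp = schedule.experimental_blocks()
        if exp:
            event_s = exp[0].duration_s

    dt = 1.0
    work_t = np.arange(0.0, event_s + rf.kernel.size * rf.sample_period_s, dt)
    boxcar = (work_t < event_s).astype(float)
    # resample kernel to the 1 s working grid
    kt = rf.time_s
    kernel = np.interp(work_t, kt, rf.kernel, right=0.0)
    predicted = np.convolve(boxcar, kernel)[: work_t.size] * dt
    reg_full = np.convolve(predicted, rms_block)[: work_t.size]
    n_keep = int(round(stim_duration_s / dt))
    reg = reg_full[:n_keep]
    values = np.interp(bnirs_grid_s, np.arange(n_keep) * dt, reg)
    sd = values.std()
    if sd < 1e-12:
        raise DegenerateDesignError("regressor is constant on the bNIRS grid")
    values = (values - values.mean()) / sd
    return NeuralRegressor(values=values, source=source,
                           predicted_bnirs=predicted, working_grid_s=work_t)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    cond = float(np.linalg.cond(X))
    if cond > 1e10:
        raise DegenerateDesignError(f"collinear design (cond={cond:.2e})")
    return beta, cond


def fit_subject_glm(
    bnirs_trace: np.ndarray, regressor: NeuralRegressor | np.ndarray
) -> float:
    """OLS slope of one stimulus-window chromophore trace on the neural
    regressor (with intercept)."""
    x = regressor.values if isinstance(regressor, NeuralRegressor) else np.asarray(regressor)
    y = np.asarray(bnirs_trace, dtype=float)
    if y.size != x.size:
        raise InvalidArgumentError("trace and regressor lengths differ")
    if x.std() < 1e-12:
        raise DegenerateDesignError("degenerate regressor")
    X = np.column_stack([np.ones_like(x), x])
    beta, _ = _ols(y, X)
    return float(beta[1])


def fit_subject_conditions(
    subject_id: str,
    bnirs_windows: dict[str, np.ndarray],
    regressors: dict[tuple[str, str, str], NeuralRegressor],
    bnirs_channel_ids: list[int],
    chromophores: tuple[str, ...] = CHROMOPHORES,
) -> SubjectGLMResult:
    """Joint GLM over both conditions for every cell.

    ``bnirs_windows[cond]`` is the block-averaged stimulus window,
    (n_sel_channels, 3, n_t); ``regressors`` is keyed by
    (eeg_channel, band, condition).  The two condition windows are
    concatenated and fitted with one intercept plus one regressor per
    condition (each zero outside its own span), yielding a per-condition β
    from a single fit.
    """
    conditions = sorted(bnirs_windows)
    pairs = sorted({(eeg, band) for (eeg, band, _) in regressors})
    n_t = {c: bnirs_windows[c].shape[-1] for c in conditions}
    rows = []
    max_cond_num = 0.0
    for eeg_ch, band in pairs:
        # block-diagonal condition regressors over the concatenated span
        cols = []
        for c in conditions:
            reg = regressors[(eeg_ch, band, c)].values
            col = np.concatenate([
                reg if cc == c else np.zeros(n_t[cc]) for cc in conditions
            ])
            cols.append(col)
        X = np.column_stack([np.ones(sum(n_t.values()))] + cols)
        for ch_i, ch_id in enumerate(bnirs_channel_ids):
            for ci, chromo in enumerate(chromophores):
                y = np.concatenate([bnirs_windows[c][ch_i, ci] for c in conditions])
                beta, cond_num = _ols(y, X)
                max_cond_num = max(max_cond_num, cond_num)
                for k, c in enumerate(conditions):
                    rows.append({
                        "bnirs_channel": ch_id, "chromophore": chromo,
                        "eeg_channel": eeg_ch, "band": band,
                        "condition": c, "beta": float(beta[1 + k]),
                    })
    return SubjectGLMResult(subject_id=subject_id, beta=pd.DataFrame(rows),
                            design_condition_number=max_cond_num)


CELL_KEYS = ["bnirs_channel", "chromophore", "eeg_channel", "band", "condition"]
FAMILY_KEYS = ["chromophore", "eeg_channel", "band", "condition"]


def _beta_matrix(subject_results: list[SubjectGLMResult]) -> pd.DataFrame:
    frames = []
    for r in subject_results:
        df = r.beta.copy()
        df["subject"] = r.subject_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def group_coupling_stats(
    subject_results: list[SubjectGLMResult],
    channels: list[int],
    q: float = 0.05,
) -> pd.DataFrame:
    """Group one-sample t-tests of β against 0 per cell, BH-FDR corrected
    across the selected bNIRS channels within each
    (chromophore, EEG channel, band, condition) family."""
    if len(subject_results) < 3:
        raise InvalidArgumentError("need ≥3 subjects")
    allb = _beta_matrix(subject_results)
    allb = allb[allb["bnirs_channel"].isin(channels)]
    rows = []
    for keys, fam in allb.groupby(FAMILY_KEYS):
        cells = []
        for ch, cell in fam.groupby("bnirs_channel"):
            t, p = one_sample_t(cell["beta"].to_numpy())
            cells.append((ch, float(cell["beta"].mean()), len(cell), t, p))
        pvec = np.array([c[4] for c in cells])
        reject, qvals = bh_fdr(pvec, q=q)
        for (ch, bmean, n, t, p), rej, qv in zip(cells, reject, qvals):
            rows.append(dict(zip(FAMILY_KEYS, keys)) | {
                "bnirs_channel": ch, "beta_mean": bmean, "n": n,
                "t": t, "p": p, "q": qv,
                "sig_uncorrected": bool(np.isfinite(p) and p < q),
                "sig_fdr": bool(rej),
                "note": "" if np.isfinite(t) else "undefined-t",
            })
    return pd.DataFrame(rows)[
        ["bnirs_channel"] + FAMILY_KEYS
        + ["beta_mean", "n", "t", "p", "q", "sig_uncorrected", "sig_fdr", "note"]
    ]


def condition_contrast(
    subject_results: list[SubjectGLMResult],
    channels: list[int],
    q: float = 0.05,
    conditions: tuple[str, str] = ("social", "non-social"),
) -> pd.DataFrame:
    """Paired social vs non-social contrast on per-subject β, BH-FDR
    corrected across the selected bNIRS channels per family; subjects
    missing either condition are excluded with a warning."""
    import warnings

    allb = _beta_matrix(subject_results)
    allb = allb[allb["bnirs_channel"].isin(channels)]
    a, b = conditions
    wide = allb.pivot_table(
        index=["subject", "bnirs_channel", "chromophore", "eeg_channel", "band"],
        columns="condition", values="beta",
    ).reset_index()
    if a not in wide.columns or b not in wide.columns:
        raise InvalidArgumentError(f"both conditions {conditions} required")
    unpaired = wide[wide[[a, b]].isna().any(axis=1)]["subject"].unique()
    if len(unpaired):
        warnings.warn(f"excluding unpaired subjects: {sorted(unpaired)}",
                      UserWarning, stacklevel=2)
        wide = wide.dropna(subset=[a, b])
    rows = []
    fam_keys = ["chromophore", "eeg_channel", "band"]
    for keys, fam in wide.groupby(fam_keys):
        cells = []
        for ch, cell in fam.groupby("bnirs_channel"):
            t, p = paired_t(cell[a].to_numpy(), cell[b].to_numpy())
            cells.append((ch, float((cell[a] - cell[b]).mean()), len(cell), t, p))
        pvec = np.array([c[4] for c in cells])
        reject, qvals = bh_fdr(pvec, q=q)
        for (ch, dmean, n, t, p), rej, qv in zip(cells, reject, qvals):
            rows.append(dict(zip(fam_keys, keys)) | {
                "bnirs_channel": ch, "contrast": f"{a}-{b}",
                "beta_diff_mean": dmean, "n": n, "t": t, "p": p, "q": qv,
                "sig_uncorrected": bool(np.isfinite(p) and p < q),
                "sig_fdr": bool(rej),
                "note": "" if np.isfinite(t) else "undefined-t",
            })
    return pd.DataFrame(rows)
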