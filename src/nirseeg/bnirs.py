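"""Broadband-NIRS preprocessing.

Attenuation-change recordings are motion-corrected with a wavelet
outlier filter, resolved into Δ[HbO2]/Δ[HHb]/Δ[oxCCO] by multiwavelength
least squares on the modified Beer–Lambert law (the UCLn inversion,
default 120 wavelengths between 780 and 900 nm, DPF 5.13), band-pass
filtered 0.01–0.4 Hz with a zero-phase Butterworth filter, quality
controlled on raw intensity counts (2000–40,000; subjects dropped above
60% channel loss) and block averaged per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .types import (
    BroadbandRecording,
    ChannelQCReport,
    ChromophoreTimeSeries,
    DegenerateSystemError,
    EmptyConditionError,
    ExtinctionTable,
    InvalidArgumentError,
    StimulusSchedule,
)

__all__ = [
    "wavelet_motion_correct",
    "ucln_invert",
    "bandpass_bnirs",
    "qc_channels",
    "block_average_bnirs",
    "BlockAverageBnirs",
]


def _wavelet_despike(x: np.ndarray, alpha: float, wavelet: str) -> np.ndarray:
    """Zero detail coefficients outside [Q1-α·IQR, Q3+α·IQR] per level."""
    n = x.size
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=max_level)
    cleaned = [coeffs[0]]
    for d in coeffs[1:]:
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        out = (d < q1 - alpha * iqr) | (d > q3 + alpha * iqr)
        d = d.copy()
        d[out] = 0.0
        cleaned.append(d)
    return pywt.waverec(cleaned, wavelet)[:n]


def wavelet_motion_correct(
    rec: BroadbandRecording, alpha: float = 0.8, wavelet: str = "db5"
) -> BroadbandRecording:
    """Wavelet motion correction of attenuation signals.

    Per channel and wavelength: discrete wavelet decomposition (Daubechies-5
    at the maximum depth the length allows), detail coefficients outside the
    interquartile fence [Q1 − α·IQR, Q3 + α·IQR] zeroed at every level, and
    inverse transform.  α = 0.8 by default.
    """
    if alpha <= 0:
        raise InvalidArgumentError("alpha must be positive")
    rec._check_uniform_grid()
    n_ch, n_wl, n_t = rec.attenuation.shape
    out = np.empty_like(rec.attenuation)
    for c in range(n_ch):
        for w in range(n_wl):
            out[c, w] = _wavelet_despike(rec.attenuation[c, w], alpha, wavelet)
    return BroadbandRecording(
        attenuation=out,
        wavelengths_nm=rec.wavelengths_nm.copy(),
        time_s=rec.time_s.copy(),
        intensity_counts=rec.intensity_counts.copy(),
        layout=rec.layout,
    )


def ucln_invert(
    rec: BroadbandRecording,
    extinction: ExtinctionTable,
    dpf: float = 5.13,
    fit_range_nm: tuple[float, float] = (780.0, 900.0),
    dpf_table: np.ndarray | None = None,
) -> ChromophoreTimeSeries:
    """Multiwavelength least-squares chromophore resolution.

    Solves, per channel and time point, ΔA(λ) = E(λ)·Δc·d·DPF over the
    wavelengths inside ``fit_range_nm``; d is the source–detector
    separation from the probe layout.  ``dpf_table`` optionally supplies a
    per-wavelength DPF(λ) in place of the fixed scalar (default 5.13).
    """
    lo, hi = fit_range_nm
    mask = (rec.wavelengths_nm >= lo) & (rec.wavelengths_nm <= hi)
    if mask.sum() < 3:
        raise InvalidArgumentError(
            f"need ≥3 wavelengths in [{lo}, {hi}] nm, found {int(mask.sum())}"
        )
    wl = rec.wavelengths_nm[mask]
    eps = extinction.at(wl)  # (n_wl, 3)
    if np.linalg.matrix_rank(eps) < 3:
        raise DegenerateSystemError("extinction submatrix is rank-deficient")
    d = rec.layout.separation_cm
    if dpf_table is not None:
        dpf_vec = np.asarray(dpf_table, dtype=float)
        if dpf_vec.size != wl.size:
            raise InvalidArgumentError("dpf_table length must match fit wavelengths")
        design = eps * (d * dpf_vec)[:, None]
    else:
        if dpf <= 0:
            raise InvalidArgumentError("dpf must be positive")
        design = eps * d * dpf
    pinv = np.linalg.pinv(design)  # (3, n_wl)
    # (ch, 3, t) = pinv (3, wl) x atten (ch, wl, t)
    conc = np.einsum("iw,cwt->cit", pinv, rec.attenuation[:, mask, :])
    return ChromophoreTimeSeries(conc=conc, time_s=rec.time_s.copy())


def bandpass_bnirs(
    ts: ChromophoreTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.4,
    order: int = 4,
) -> ChromophoreTimeSeries:
    """Zero-phase Butterworth band-pass of the chromophore traces.

    The 0.4 Hz upper edge exceeds Nyquist at the 1.4 s multiplexing period
    (0.357 Hz); in that case the edge is clamped just below Nyquist with a
    warning rather than guessing a different acquisition rate.
    """
    fs = 1.0 / ts.sample_period_s
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz):
        raise InvalidArgumentError("need 0 < low_hz < high_hz")
    if low_hz >= nyq:
        raise InvalidArgumentError(f"low edge {low_hz} Hz is at/above Nyquist {nyq:.3g} Hz")
    if high_hz >= nyq:
        clamped = 0.95 * nyq
        warnings.warn(
            f"band edge {high_hz} Hz ≥ Nyquist {nyq:.3g} Hz; clamped to {clamped:.3g} Hz",
            UserWarning,
            stacklevel=2,
        )
        high_hz = clamped
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    conc = sps.sosfiltfilt(sos, ts.conc, axis=-1)
    return ChromophoreTimeSeries(conc=conc, time_s=ts.time_s.copy(),
                                 excluded_channels=set(ts.excluded_channels))


def qc_channels(
    rec: BroadbandRecording,
    low_counts: float = 2000.0,
    high_counts: float = 40000.0,
    subject_threshold: float = 0.60,
) -> ChannelQCReport:
    """Intensity-count quality control.

    Channels with mean counts below ``low_counts`` or above ``high_counts``
    are excluded; the subject is excluded when more than
    ``subject_threshold`` of channels are lost.
    """
    counts = rec.intensity_counts
    if counts.size != rec.layout.n_channels:
        raise InvalidArgumentError("counts missing for some channels")
    keep = (counts >= low_counts) & (counts <= high_counts)
    frac = float((~keep).sum()) / counts.size
    return ChannelQCReport(
        mean_counts=counts.copy(),
        keep=keep,
        subject_excluded=frac > subject_threshold,
        exclusion_fraction=frac,
        low_counts=low_counts,
        high_counts=high_counts,
        subject_threshold=subject_threshold,
    )


@dataclass
class BlockAverageBnirs:
    """Condition block average of chromophore traces: mean epoch per
    channel/chromophore on a time axis relative to stimulus onset."""

    condition: str
    time_rel_s: np.ndarray        # (n_t,) negative during the baseline span
    mean: np.ndarray              # (n_ch, 3, n_t)
    n_blocks: int
    baseline_s: float


def block_average_bnirs(
    ts: ChromophoreTimeSeries,
    schedule: StimulusSchedule,
    condition: str,
    window_s: float = 20.0,
    baseline_s: float = 8.0,
) -> BlockAverageBnirs:
    """Average stimulus-locked epochs of one condition.

    Epochs run from ``baseline_s`` before each block onset to ``window_s``
    after it; only epochs fully inside the recording contribute.
    """
    dt = ts.sample_period_s
    n_pre = int(round(baseline_s / dt))
    n_post = int(round(window_s / dt))
    epochs = []
    for b in schedule.condition_blocks(condition):
        i_on = int(round((b.onset_s - ts.time_s[0]) / dt))
        i0, i1 = i_on - n_pre, i_on + n_post
        if i0 < 0 or i1 > ts.time_s.size:
            continue
        epochs.append(ts.conc[:, :, i0:i1])
    if not epochs:
        raise EmptyConditionError(f"no usable '{condition}' blocks in recording")
    mean = np.mean(epochs, axis=0)
    time_rel = (np.arange(-n_pre, n_post) * dt)
    return BlockAverageBnirs(condition=condition, time_rel_s=time_rel,
                             mean=mean, n_blocks=len(epochs),
                             baseline_s=baseline_s)
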