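"""EEG preprocessing: filtering, re-referencing, bad-channel interpolation,
1 s segmentation with two-stage baseline correction, artifact rejection,
band RMS power and channel-level condition statistics.

The processing chain follows the infant block design: the raw signal is
band-pass filtered 0.1–100 Hz with a 48–52 Hz notch, each stimulus block
(8 s baseline + 8–12 s stimulus) is cut into 1 s segments that carry
200 ms of the preceding second for within-segment baseline correction,
segments exceeding 200 μV or overlapping inattention are rejected, RMS
power is computed per band (theta 3–6, alpha 8–12, beta 13–30, gamma
20–60, high-gamma 60–80 Hz), block-baseline corrected by the final 2 s of
the baseline period, and averaged across trials.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .statsutil import bh_fdr, paired_t
from .types import (
    DEFAULT_BANDS,
    BandPowerSeries,
    BlockAverageResponse,
    EEGRecording,
    EmptyConditionError,
    InvalidArgumentError,
    SegmentedBlock,
    SegmentedBlocks,
    StimulusSchedule,
)

__all__ = [
    "filter_eeg",
    "rereference_average",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "montage_positions",
    "segment_and_baseline",
    "reject_artifact_segments",
    "band_rms",
    "block_baseline_correct_and_average",
    "eeg_condition_stats",
]

AMP_THRESHOLD_UV = 200.0


def filter_eeg(
    rec: EEGRecording,
    band: tuple[float, float] = (0.1, 100.0),
    notch: tuple[float, float] = (48.0, 52.0),
    order: int = 4,
) -> EEGRecording:
    """Zero-phase band-pass (0.1–100 Hz) followed by a line-noise band-stop
    notch (48–52 Hz)."""
    if rec.fs <= 2 * band[1]:
        raise InvalidArgumentError(
            f"fs={rec.fs} Hz cannot support a {band[1]} Hz band edge"
        )
    sos_bp = sps.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    sos_notch = sps.butter(order, notch, btype="bandstop", fs=rec.fs, output="sos")
    # the 0.1 Hz high-pass transient is seconds long; default filtfilt
    # padding is far too short and leaks edge drift into the record
    padlen = min(rec.signal.shape[1] - 1, int(30 * rec.fs))
    sig = sps.sosfiltfilt(sos_bp, rec.signal, axis=1, padlen=padlen)
    sig = sps.sosfiltfilt(sos_notch, sig, axis=1, padlen=padlen)
    return EEGRecording(signal=sig, fs=rec.fs, montage=rec.montage,
                        attention_mask=rec.attention_mask)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous average across channels."""
    if rec.signal.shape[0] < 2:
        raise InvalidArgumentError("average reference needs ≥2 channels")
    sig = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return EEGRecording(signal=sig, fs=rec.fs, montage=rec.montage,
                        attention_mask=rec.attention_mask)


def montage_positions(labels: tuple[str, ...]) -> np.ndarray:
    """3-D electrode positions (m) for 10/20 labels, from the standard
    montage shipped with MNE."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    try:
        return np.array([pos[lbl] for lbl in labels])
    except KeyError as exc:  # pragma: no cover - label typo guard
        raise InvalidArgumentError(f"unknown 10/20 label: {exc}") from exc


def detect_bad_channels(
    rec: EEGRecording,
    amp_threshold_uv: float = AMP_THRESHOLD_UV,
    bad_fraction: float = 0.30,
) -> set[str]:
    """Channels whose 1 s windows exceed the amplitude threshold in more
    than ``bad_fraction`` of windows are flagged for interpolation."""
    n = int(rec.fs)
    n_win = rec.signal.shape[1] // n
    if n_win == 0:
        return set()
    wins = rec.signal[:, : n_win * n].reshape(rec.signal.shape[0], n_win, n)
    frac = (np.abs(wins).max(axis=2) > amp_threshold_uv).mean(axis=1)
    return {rec.montage[i] for i in np.flatnonzero(frac > bad_fraction)}


def interpolate_bad_channels(
    rec: EEGRecording, bad: set[str], n_neighbors: int = 3
) -> EEGRecording:
    """Replace each bad channel by the inverse-distance-weighted mean of its
    ``n_neighbors`` nearest good channels (montage geometry)."""
    if not bad:
        return rec
    unknown = bad - set(rec.montage)
    if unknown:
        raise InvalidArgumentError(f"bad channels not in montage: {sorted(unknown)}")
    good_idx = [i for i, lbl in enumerate(rec.montage) if lbl not in bad]
    if len(good_idx) < n_neighbors:
        raise InvalidArgumentError(
            f"unrecoverable recording: only {len(good_idx)} good channels left"
        )
    pos = montage_positions(rec.montage)
    sig = rec.signal.copy()
    for i, lbl in enumerate(rec.montage):
        if lbl not in bad:
            continue
        dists = np.linalg.norm(pos[good_idx] - pos[i], axis=1)
        order = np.argsort(dists)[:n_neighbors]
        w = 1.0 / np.maximum(dists[order], 1e-9)
        w /= w.sum()
        sig[i] = w @ rec.signal[[good_idx[j] for j in order]]
    return EEGRecording(signal=sig, fs=rec.fs, montage=rec.montage,
                        attention_mask=rec.attention_mask)


# ---------------------------------------------------------------------------
# segmentation

def segment_and_baseline(
    rec: EEGRecording,
    schedule: StimulusSchedule,
    baseline_s: float = 8.0,
) -> SegmentedBlocks:
    """Cut each stimulus block (baseline + stimulus period) into 1 s segments.

    Each segment holds the last 200 ms of the preceding second plus 800 ms
    of its own second and is baseline-corrected by the mean of that leading
    200 ms; for the first stimulus segment the leading 200 ms therefore
    comes from the end of the baseline period.  Segments whose second is
    marked inattentive in the recording's attention mask are flagged
    rejected.  Blocks running past the recording end lose their partial
    segments with a warning.
    """
    fs = rec.fs
    n_samp = int(round(fs))
    n_lead = int(round(0.2 * fs))
    n_t = rec.signal.shape[1]
    blocks: list[SegmentedBlock] = []
    for b in schedule.experimental_blocks():
        block_start = b.onset_s - baseline_s
        if block_start - 0.2 < 0:
            warnings.warn(f"block at {b.onset_s:.1f}s lacks pre-block context; skipped",
                          UserWarning, stacklevel=2)
            continue
        n_seg_nominal = int(np.floor(baseline_s)) + int(np.floor(b.duration_s))
        segs, phases, rej, reasons = [], [], [], []
        for k in range(n_seg_nominal):
            t0 = block_start + k - 0.2
            i0 = int(round(t0 * fs))
            if i0 + n_samp > n_t:
                warnings.warn(
                    f"block at {b.onset_s:.1f}s truncated by recording end; "
                    f"dropped {n_seg_nominal - k} segment(s)",
                    UserWarning, stacklevel=2)
                break
            seg = rec.signal[:, i0:i0 + n_samp].copy()
            seg -= seg[:, :n_lead].mean(axis=1, keepdims=True)
            segs.append(seg)
            phases.append("baseline" if k < baseline_s else "stimulus")
            second_idx = int(np.floor(block_start + k))
            inattentive = (
                rec.attention_mask is not None
                and second_idx < rec.attention_mask.size
                and not rec.attention_mask[second_idx]
            )
            rej.append(bool(inattentive))
            reasons.append("inattention" if inattentive else "")
        if not segs:
            continue
        blocks.append(SegmentedBlock(
            condition=b.condition,
            block_onset_s=block_start,
            stimulus_onset_s=b.onset_s,
            segments=np.stack(segs),
            phase=np.array(phases),
            rejected=np.array(rej),
            reject_reason=np.array(reasons),
        ))
    return SegmentedBlocks(blocks=blocks, fs=fs, montage=rec.montage)


def reject_artifact_segments(
    seg: SegmentedBlocks, amp_threshold_uv: float = AMP_THRESHOLD_UV
) -> SegmentedBlocks:
    """Reject 1 s segments whose absolute amplitude exceeds the threshold on
    any channel; blocks left with no retained segments are dropped."""
    if not seg.blocks:
        raise InvalidArgumentError("no segments present")
    kept_blocks = []
    for b in seg.blocks:
        rejected = b.rejected.copy()
        reasons = b.reject_reason.copy()
        over = np.abs(b.segments).max(axis=(1, 2)) > amp_threshold_uv
        newly = over & ~rejected
        rejected |= over
        reasons = np.where(newly, "amplitude", reasons)
        nb = SegmentedBlock(
            condition=b.condition, block_onset_s=b.block_onset_s,
            stimulus_onset_s=b.stimulus_onset_s, segments=b.segments,
            phase=b.phase, rejected=rejected, reject_reason=reasons,
        )
        if rejected.all():
            warnings.warn(
                f"block at {b.stimulus_onset_s:.1f}s: all segments rejected; dropped",
                UserWarning, stacklevel=2)
            continue
        kept_blocks.append(nb)
    return SegmentedBlocks(blocks=kept_blocks, fs=seg.fs, montage=seg.montage)


# ---------------------------------------------------------------------------
# band power

def band_rms(
    seg: SegmentedBlocks,
    bands: dict[str, tuple[float, float]] | None = None,
    order: int = 4,
    method: str = "butter",
) -> BandPowerSeries:
    """RMS power per segment, channel and band.

    Each accepted segment is band-pass filtered (zero-phase Butterworth per
    band; ``method='fft'`` selects an FFT band-power alternative) and the
    RMS is taken over the segment's unique 800 ms portion.  Rejected
    segments yield NaN.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    fs = seg.fs
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if hi >= nyq:
            raise InvalidArgumentError(
                f"band '{name}' edge {hi} Hz is at/above Nyquist {nyq} Hz")
    n_lead = int(round(0.2 * fs))
    sos = {name: sps.butter(order, edges, btype="bandpass", fs=fs, output="sos")
           for name, edges in bands.items()}

    block_rms, block_phase, block_cond = [], [], []
    for b in seg.blocks:
        n_seg, n_ch, _ = b.segments.shape
        rms = np.full((n_ch, len(bands), n_seg), np.nan)
        for bi, name in enumerate(bands):
            if method == "fft":
                core = b.segments[:, :, n_lead:]
                freqs = np.fft.rfftfreq(core.shape[-1], 1.0 / fs)
                spec = np.fft.rfft(core, axis=-1)
                lo, hi = bands[name]
                sel = (freqs >= lo) & (freqs <= hi)
                # Parseval: mean square in band
                power = (np.abs(spec[:, :, sel]) ** 2).sum(axis=-1)
                power *= 2.0 / core.shape[-1] ** 2
                vals = np.sqrt(power)
            else:
                # maximal padding: 1 s segments are short relative to the
                # filter transient, so default padlen biases the RMS down
                filt = sps.sosfiltfilt(sos[name], b.segments, axis=-1,
                                       padlen=b.segments.shape[-1] - 1)
                vals = np.sqrt((filt[:, :, n_lead:] ** 2).mean(axis=-1))
            rms[:, bi, :] = vals.T  # (n_seg, n_ch) -> (n_ch, n_seg)
        rms[:, :, b.rejected] = np.nan
        block_rms.append(rms)
        block_phase.append(b.phase.copy())
        block_cond.append(b.condition)
    return BandPowerSeries(block_rms=block_rms, block_phase=block_phase,
                           block_condition=block_cond, bands=dict(bands),
                           montage=seg.montage)


def block_baseline_correct_and_average(
    bp: BandPowerSeries,
    baseline_correct_s: float = 2.0,
    n_baseline_segments: int = 8,
    n_stimulus_segments: int = 8,
) -> dict[str, BlockAverageResponse]:
    """Block baseline correction and across-trial averaging, per condition.

    The mean RMS over the final ``baseline_correct_s`` seconds of each
    block's baseline is subtracted from the whole block; blocks are then
    aligned on stimulus onset (8 baseline + first 8 stimulus segments) and
    averaged.  Returns one averaged response per condition, carrying both
    corrected traces and the uncorrected baseline/stimulus means used for
    condition statistics.
    """
    conditions = sorted(set(bp.block_condition))
    out: dict[str, BlockAverageResponse] = {}
    n_corr = int(round(baseline_correct_s))
    for cond in conditions:
        aligned, base_means, stim_means = [], [], []
        for rms, phase, c in zip(bp.block_rms, bp.block_phase, bp.block_condition):
            if c != cond:
                continue
            base_idx = np.flatnonzero(phase == "baseline")
            stim_idx = np.flatnonzero(phase == "stimulus")
            if base_idx.size < n_corr or stim_idx.size == 0:
                continue
            ref = np.nanmean(rms[:, :, base_idx[-n_corr:]], axis=2)
            if np.all(np.isnan(ref)):
                continue
            corrected = rms - ref[:, :, None]
            n_ch, n_band, _ = rms.shape
            frame = np.full((n_ch, n_band, n_baseline_segments + n_stimulus_segments),
                            np.nan)
            nb = min(n_baseline_segments, base_idx.size)
            frame[:, :, n_baseline_segments - nb:n_baseline_segments] = \
                corrected[:, :, base_idx[-nb:]]
            ns = min(n_stimulus_segments, stim_idx.size)
            frame[:, :, n_baseline_segments:n_baseline_segments + ns] = \
                corrected[:, :, stim_idx[:ns]]
            aligned.append(frame)
            base_means.append(np.nanmean(rms[:, :, base_idx], axis=2))
            stim_means.append(np.nanmean(rms[:, :, stim_idx[:n_stimulus_segments]], axis=2))
        if not aligned:
            raise EmptyConditionError(f"no usable blocks for condition '{cond}'")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            corrected_avg = np.nanmean(aligned, axis=0)
            baseline_mean = np.nanmean(base_means, axis=0)
            stim_mean_raw = np.nanmean(stim_means, axis=0)
        stim_mean = np.nanmean(
            corrected_avg[:, :, n_baseline_segments:], axis=2)
        out[cond] = BlockAverageResponse(
            condition=cond,
            corrected=corrected_avg,
            stimulus_mean=stim_mean,
            baseline_mean=baseline_mean,
            stimulus_mean_raw=stim_mean_raw,
            n_blocks=len(aligned),
            bands=dict(bp.bands),
            montage=bp.montage,
            n_baseline_segments=n_baseline_segments,
            n_stimulus_segments=n_stimulus_segments,
        )
    return out


# ---------------------------------------------------------------------------
# condition statistics

CONTRASTS = ("social-baseline", "nonsocial-baseline", "social-nonsocial")


def eeg_condition_stats(
    subject_responses: list[dict[str, BlockAverageResponse]],
    q: float = 0.05,
) -> pd.DataFrame:
    """Channel-level paired t-tests of stimulus-averaged RMS power.

    For every (channel, band): social vs its baseline, non-social vs its
    baseline, and social vs non-social, paired across subjects, with
    BH-FDR across the channels within each (band, contrast) family.
    Cells with zero-variance differences carry NaN t with an
    'undefined-t' note.
    """
    if len(subject_responses) < 3:
        raise InvalidArgumentError("need at least 3 subjects")
    ref = next(iter(subject_responses[0].values()))
    montage, bands = ref.montage, list(ref.bands)

    def stack(cond: str, attr: str) -> np.ndarray:
        return np.stack([getattr(s[cond], attr) for s in subject_responses])

    soc_stim = stack("social", "stimulus_mean_raw")
    soc_base = stack("social", "baseline_mean")
    non_stim = stack("non-social", "stimulus_mean_raw")
    non_base = stack("non-social", "baseline_mean")

    pairs = {
        "social-baseline": (soc_stim, soc_base),
        "nonsocial-baseline": (non_stim, non_base),
        "social-nonsocial": (soc_stim, non_stim),
    }
    rows = []
    for contrast, (a, b) in pairs.items():
        for bi, band in enumerate(bands):
            stats_cells = [paired_t(a[:, ci, bi], b[:, ci, bi])
                           for ci in range(len(montage))]
            pvec = np.array([p for _, p in stats_cells])
            reject, qvals = bh_fdr(pvec, q=q)
            for ci, (t, p) in enumerate(stats_cells):
                rows.append({
                    "channel": montage[ci], "band": band, "contrast": contrast,
                    "t": t, "p": p, "q": qvals[ci],
                    "sig_uncorrected": bool(np.isfinite(p) and p < q),
                    "sig_fdr": bool(reject[ci]),
                    "note": "" if np.isfinite(t) else "undefined-t",
                })
    return pd.DataFrame(rows)
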