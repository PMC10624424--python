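"""End-to-end pipeline: synthetic cohort generation, per-subject bNIRS and
EEG preprocessing, grand-average response-function estimation, and group
coupling statistics.

Every stage logs counts (channels kept, segments rejected, blocks
averaged) to stderr with a stage prefix; all randomness derives from the
configuration seed, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bnirs as bn
from . import coupling as cp
from . import eeg as ee
from . import hrf as hf
from . import synthetic as syn
from .io import PipelineConfig
from .types import (
    CHROMOPHORES,
    BlockAverageResponse,
    BroadbandRecording,
    EEGRecording,
    GroundTruth,
    ProbeLayout,
    StimulusSchedule,
)

logger = logging.getLogger("nirseeg")

__all__ = ["SubjectData", "PlantedCoupling", "generate_cohort",
           "process_subject", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class PlantedCoupling:
    """Ground-truth coupling planted in the synthetic cohort: the named
    bNIRS channel responds (per chromophore defaults) during the condition
    and the named EEG channel's band gains amplitude."""

    bnirs_channel: int = 14
    eeg_channel: str = "Pz"
    band: str = "beta"
    chromophore: str = "HbO2"
    condition: str = "social"
    eeg_gain: float = 2.0
    amplitude_um: float = 1.0


@dataclass
class SubjectData:
    subject_id: str
    schedule: StimulusSchedule
    bnirs: BroadbandRecording
    eeg: EEGRecording
    truth: GroundTruth


def _subject_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def generate_cohort(
    config: PipelineConfig,
    planted: PlantedCoupling | None = None,
    layout: ProbeLayout | None = None,
) -> list[SubjectData]:
    """Simulate a cohort with one planted coupling (all other bNIRS
    channels respond with noise only)."""
    if planted is None:
        planted = PlantedCoupling()
    layout = layout or ProbeLayout()
    extinction = syn.synthetic_extinction_table()
    seeds = _subject_seeds(config.rng_seed, config.n_subjects)
    cohort = []
    for i, seed in enumerate(seeds):
        schedule = syn.generate_schedule(config.n_trials, rng_seed=seed)
        amplitude = {
            (planted.bnirs_channel, planted.condition): {
                c: syn.DEFAULT_AMPLITUDES_UM[c] * planted.amplitude_um
                for c in CHROMOPHORES
            }
        }
        truth_ts = syn.simulate_chromophore_truth(
            schedule, layout, amplitude=amplitude,
            sample_period_s=config.bnirs_sample_period_s)
        rec = syn.forward_attenuation(
            truth_ts, extinction, layout, dpf=config.dpf,
            noise_sd=config.bnirs_noise_sd_od, rng_seed=seed + 1)
        gt = GroundTruth(
            chromo_truth=truth_ts,
            eeg_band_gain={(planted.eeg_channel, planted.band,
                            planted.condition): planted.eeg_gain},
            coupling_spec=[(planted.bnirs_channel, planted.eeg_channel,
                            planted.band, planted.chromophore, +1)],
            rng_seed=seed + 2,
        )
        eeg_rec = syn.simulate_eeg(schedule, gt, fs=config.eeg_fs_hz,
                                   bands=config.bands)
        cohort.append(SubjectData(subject_id=f"sub-{i + 1:02d}",
                                  schedule=schedule, bnirs=rec,
                                  eeg=eeg_rec, truth=gt))
    logger.info("[simulate] generated %d subjects, %d trials each",
                len(cohort), config.n_trials)
    return cohort


@dataclass
class SubjectProcessed:
    subject_id: str
    qc: "object"
    chromo: "object"
    bnirs_block_avg: dict[str, bn.BlockAverageBnirs]
    eeg_response: dict[str, BlockAverageResponse]


def process_subject(
    sub: SubjectData,
    config: PipelineConfig,
    extinction=None,
) -> SubjectProcessed:
    """Run the full per-subject preprocessing chain on one recording pair."""
    if extinction is None:
        extinction = syn.synthetic_extinction_table()

    # --- bNIRS chain
    rec = bn.wavelet_motion_correct(sub.bnirs, alpha=config.wavelet_alpha)
    qc = bn.qc_channels(rec, config.qc_low_counts, config.qc_high_counts,
                        config.qc_subject_threshold)
    chromo = bn.ucln_invert(rec, extinction, dpf=config.dpf,
                            fit_range_nm=config.fit_range_nm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # 0.4 Hz > Nyquist clamp
        chromo = bn.bandpass_bnirs(chromo, *config.bnirs_band_hz,
                                   order=config.bnirs_filter_order)
    chromo.excluded_channels = set(qc.excluded_channel_ids)
    block_avg = {}
    for cond in ("social", "non-social"):
        block_avg[cond] = bn.block_average_bnirs(
            chromo, sub.schedule, cond, window_s=16.0)
    logger.info("[bnirs:%s] kept %d/%d channels; %d+%d blocks averaged",
                sub.subject_id, int(qc.keep.sum()), qc.keep.size,
                block_avg["social"].n_blocks, block_avg["non-social"].n_blocks)

    # --- EEG chain
    eeg = ee.filter_eeg(sub.eeg, band=config.eeg_band_hz,
                        notch=config.eeg_notch_hz)
    bad = ee.detect_bad_channels(eeg, config.amp_threshold_uv)
    if bad:
        eeg = ee.interpolate_bad_channels(eeg, bad)
    eeg = ee.rereference_average(eeg)
    seg = ee.segment_and_baseline(eeg, sub.schedule)
    seg = ee.reject_artifact_segments(seg, config.amp_threshold_uv)
    counts = seg.counts()
    bp = ee.band_rms(seg, bands=config.bands)
    response = ee.block_baseline_correct_and_average(bp)
    logger.info("[eeg:%s] %d bad channels interpolated; %d/%d segments kept",
                sub.subject_id, len(bad), counts["retained"], counts["total"])
    return SubjectProcessed(subject_id=sub.subject_id, qc=qc, chromo=chromo,
                            bnirs_block_avg=block_avg, eeg_response=response)


def _grand_average(
    processed: list[SubjectProcessed],
    channels: list[int],
    pool_conditions: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-condition, channel-averaged, group-mean block response:
    (time_rel_s, array (3, n_t))."""
    per_subject = []
    ref = processed[0].bnirs_block_avg["social"]
    ch_idx = [c - 1 for c in channels]
    for p in processed:
        conds = list(p.bnirs_block_avg.values()) if pool_conditions else \
            [p.bnirs_block_avg["social"]]
        stack = np.mean([ba.mean[ch_idx].mean(axis=0) for ba in conds], axis=0)
        per_subject.append(stack)
    return ref.time_rel_s, np.mean(per_subject, axis=0)


@dataclass
class PipelineResult:
    qc_table: pd.DataFrame
    eeg_stats: pd.DataFrame
    grid_results: dict[str, "object"]
    coupling_table: pd.DataFrame
    contrast_table: pd.DataFrame
    channels: list[int]
    processed: list[SubjectProcessed] = field(repr=False, default_factory=list)


def run_pipeline(
    config: PipelineConfig,
    cohort: list[SubjectData] | None = None,
    planted: PlantedCoupling | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage and (optionally) write the four result tables."""
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    if cohort is None:
        cohort = generate_cohort(config, planted=planted)
    extinction = syn.synthetic_extinction_table()

    processed = [process_subject(s, config, extinction) for s in cohort]
    kept = [p for p in processed if not p.qc.subject_excluded]
    if len(kept) < len(processed):
        logger.info("[qc] excluded %d subject(s) (>%.0f%% channels lost)",
                    len(processed) - len(kept),
                    100 * config.qc_subject_threshold)
    processed = kept

    qc_rows = []
    for p in processed:
        for i, (cnt, keep) in enumerate(zip(p.qc.mean_counts, p.qc.keep)):
            qc_rows.append({"subject": p.subject_id, "channel": i + 1,
                            "mean_counts": cnt, "keep": bool(keep),
                            "subject_excluded": p.qc.subject_excluded})
    qc_table = pd.DataFrame(qc_rows)

    # --- EEG condition statistics
    eeg_stats = ee.eeg_condition_stats(
        [p.eeg_response for p in processed], q=config.q_fdr)
    n_sig = int(eeg_stats["sig_fdr"].sum())
    logger.info("[eeg-stats] %d significant (FDR) channel×band×contrast cells",
                n_sig)

    # --- response-function estimation on the grand averages
    channels = cp.select_coupling_channels(config.coupling_channel_lists)
    time_rel, grand = _grand_average(processed, channels)
    fit_sched = hf.single_block_schedule(
        stimulus_duration_s=10.0,
        baseline_s=float(-time_rel[0]))
    grid = config.grid()
    grid_results = {}
    for ci, chromo in enumerate(CHROMOPHORES):
        trace = grand[ci]
        # HHb deactivates; fit its inverted trace so β stays positive
        if chromo == "HHb":
            trace = -trace
        res = hf.grid_search_hrf(trace, fit_sched,
                                 time_s=time_rel - time_rel[0],
                                 grid=grid, p_threshold=config.p_threshold)
        grid_results[chromo] = res
        logger.info("[hrf] %s best=(%g, %g, %g) beta=%.3f p=%.3g sig=%s",
                    chromo, res.best.delay_response_s,
                    res.best.delay_undershoot_s,
                    res.best.ratio_response_undershoot,
                    res.best_beta, res.best_p, res.significant)

    # --- coupling GLM
    subject_results = []
    ref_ba = processed[0].bnirs_block_avg["social"]
    sel = (ref_ba.time_rel_s >= 0) & (ref_ba.time_rel_s < cp.STIM_WINDOW_S)
    bnirs_grid = ref_ba.time_rel_s[sel]
    for p in processed:
        windows = {
            cond: ba.mean[[c - 1 for c in channels]][:, :, sel]
            for cond, ba in p.bnirs_block_avg.items()
        }
        frames = []
        for chromo in CHROMOPHORES:
            rf = hf.double_gamma(grid_results[chromo].best, 1.0)
            regs = {}
            for cond, resp in p.eeg_response.items():
                stim = resp.stimulus_window  # (n_eeg, n_band, 8)
                for ei, eeg_ch in enumerate(resp.montage):
                    for bi, band in enumerate(resp.bands):
                        rms_block = stim[ei, bi]
                        if not np.all(np.isfinite(rms_block)) or np.allclose(
                                rms_block, 0):
                            continue
                        regs[(eeg_ch, band, cond)] = cp.build_neural_regressor(
                            rf, fit_sched, rms_block,
                            bnirs_grid, source=(eeg_ch, band, cond))
            # keep only (eeg, band) pairs present in both conditions
            pairs = {}
            for (eeg_ch, band, cond) in list(regs):
                if all((eeg_ch, band, c) in regs
                       for c in windows):
                    pairs[(eeg_ch, band, cond)] = regs[(eeg_ch, band, cond)]
            ci = CHROMOPHORES.index(chromo)
            windows_c = {cond: w[:, ci:ci + 1, :] for cond, w in windows.items()}
            res = cp.fit_subject_conditions(
                p.subject_id, windows_c, pairs, channels,
                chromophores=(chromo,))
            frames.append(res.beta)
        merged = cp.SubjectGLMResult(
            subject_id=p.subject_id, beta=pd.concat(frames, ignore_index=True),
            design_condition_number=0.0)
        subject_results.append(merged)

    coupling_table = cp.group_coupling_stats(subject_results, channels,
                                             q=config.q_fdr)
    contrast_table = cp.condition_contrast(subject_results, channels,
                                           q=config.q_fdr)
    logger.info("[coupling] %d cells, %d significant after FDR",
                len(coupling_table), int(coupling_table["sig_fdr"].sum()))

    result = PipelineResult(
        qc_table=qc_table, eeg_stats=eeg_stats, grid_results=grid_results,
        coupling_table=coupling_table, contrast_table=contrast_table,
        channels=channels, processed=processed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qc_table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        eeg_stats.to_csv(out / "eeg_stats.tsv", sep="\t", index=False)
        for chromo, res in grid_results.items():
            res.table.to_csv(out / f"hrf_grid_{chromo}.tsv", sep="\t",
                             index=False)
        best = {
            chromo: {
                "delay_response_s": res.best.delay_response_s,
                "delay_undershoot_s": res.best.delay_undershoot_s,
                "ratio_response_undershoot": res.best.ratio_response_undershoot,
                "beta": res.best_beta, "p": res.best_p,
                "significant": res.significant,
            } for chromo, res in grid_results.items()
        }
        (out / "hrf_best.json").write_text(json.dumps(best, indent=1))
        coupling_table.to_csv(out / "coupling.tsv", sep="\t", index=False)
        contrast_table.to_csv(out / "contrast.tsv", sep="\t", index=False)
        logger.info("[io] wrote result tables to %s", out)
    return result
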