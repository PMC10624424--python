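"""EEG preprocessing: filtering, referencing, interpolation, segmentation,
artifact rejection, band RMS and condition statistics."""

import numpy as np
import pytest

import nirseeg as ng
from nirseeg import eeg as ee
from nirseeg import synthetic as syn
from nirseeg.types import (
    Block,
    EmptyConditionError,
    InvalidArgumentError,
    SegmentedBlock,
    SegmentedBlocks,
)


def make_eeg(signal, fs=500.0, montage=None, attention=None):
    if montage is None:
        montage = tuple(f"C{i}" for i in range(signal.shape[0]))
    return ng.EEGRecording(signal=signal, fs=fs, montage=montage,
                           attention_mask=attention)


class TestFilterEEG:
    fs = 500.0
    t = np.arange(0, 20, 1 / 500.0)

    def _gain(self, freq):
        sig = np.sin(2 * np.pi * freq * self.t)[None, :].repeat(2, axis=0)
        out = ee.filter_eeg(make_eeg(sig, montage=("Fz", "Cz"))).signal[0]
        core = slice(2000, -2000)
        return out[core].std() / sig[0][core].std()

    def test_line_noise_notched_out(self):
        assert self._gain(50.0) < 0.05

    def test_alpha_band_passes(self):
        assert 0.9 <= self._gain(10.0) <= 1.1

    def test_dc_removed(self):
        sig = np.full((2, self.t.size), 100.0)
        out = ee.filter_eeg(make_eeg(sig, montage=("Fz", "Cz"))).signal
        assert np.abs(out[:, 2000:-2000].mean()) < 1.0

    def test_low_fs_rejected(self):
        sig = np.zeros((2, 400))
        with pytest.raises(InvalidArgumentError):
            ee.filter_eeg(make_eeg(sig, fs=150.0, montage=("Fz", "Cz")))


class TestRereference:
    def test_two_channel_closed_form(self):
        a = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        out = ee.rereference_average(make_eeg(a, montage=("Fz", "Cz"))).signal
        assert np.allclose(out[0], (a[0] - a[1]) / 2)
        assert np.allclose(out[1], (a[1] - a[0]) / 2)

    def test_idempotent_on_zero_mean(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(4, 100))
        sig -= sig.mean(axis=0, keepdims=True)
        rec = make_eeg(sig, montage=("F3", "F4", "P3", "P4"))
        out = ee.rereference_average(rec).signal
        assert np.allclose(out, sig)

    def test_column_means_vanish(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(10.0, 5.0, size=(32, 50))
        rec = make_eeg(sig, montage=ng.EEG_MONTAGE_32)
        out = ee.rereference_average(rec).signal
        assert np.abs(out.mean(axis=0)).max() < 1e-12


class TestInterpolation:
    def test_constant_neighbours_reproduced(self):
        sig = np.full((32, 100), 7.5)
        sig[ng.EEG_MONTAGE_32.index("Cz")] = 999.0
        rec = make_eeg(sig, montage=ng.EEG_MONTAGE_32)
        out = ee.interpolate_bad_channels(rec, {"Cz"})
        assert np.allclose(out.signal[ng.EEG_MONTAGE_32.index("Cz")], 7.5)

    def test_no_bad_channels_is_identity(self):
        rng = np.random.default_rng(2)
        sig = rng.normal(size=(32, 60))
        rec = make_eeg(sig, montage=ng.EEG_MONTAGE_32)
        assert ee.interpolate_bad_channels(rec, set()) is rec

    def test_reconstruction_beats_noise(self):
        """A channel equal to the mean of its neighbours plus noise is
        reconstructed with error below the noise SD."""
        rng = np.random.default_rng(3)
        sig = rng.normal(size=(32, 2000)) * 10
        i = ng.EEG_MONTAGE_32.index("Cz")
        pos = ee.montage_positions(ng.EEG_MONTAGE_32)
        good = [j for j in range(32) if j != i]
        d = np.linalg.norm(pos[good] - pos[i], axis=1)
        nb = [good[k] for k in np.argsort(d)[:3]]
        noise_sd = 1.0
        sig[i] = sig[nb].mean(axis=0) + rng.normal(0, noise_sd, 2000)
        truth = sig[nb].mean(axis=0)
        rec = make_eeg(sig, montage=ng.EEG_MONTAGE_32)
        out = ee.interpolate_bad_channels(rec, {ng.EEG_MONTAGE_32[i]})
        err = np.sqrt(np.mean((out.signal[i] - truth) ** 2))
        assert err < noise_sd

    def test_all_bad_unrecoverable(self):
        sig = np.zeros((4, 10))
        rec = make_eeg(sig, montage=("F3", "F4", "P3", "P4"))
        with pytest.raises(InvalidArgumentError):
            ee.interpolate_bad_channels(rec, {"F3", "F4", "P3", "P4"})

    def test_detect_bad_channels_by_amplitude_fraction(self):
        fs = 100.0
        sig = np.zeros((2, int(10 * fs)))
        sig[1, : int(5 * fs)] = 500.0  # 50% of seconds exceed 200 μV
        rec = make_eeg(sig, fs=fs, montage=("Fz", "Pz"))
        assert ee.detect_bad_channels(rec) == {"Pz"}


def periodic_schedule(durations, baseline_s=8.0, start=12.0, cond="social"):
    blocks, t0 = [], start
    for d in durations:
        blocks.append(Block("baseline", t0, baseline_s))
        blocks.append(Block(cond, t0 + baseline_s, d))
        t0 += baseline_s + d
    return ng.StimulusSchedule(blocks, t0 + 5.0)


class TestSegmentation:
    fs = 500.0

    def _rec(self, total_s, value=0.0):
        sig = np.full((2, int(total_s * self.fs)), value)
        return make_eeg(sig, fs=self.fs, montage=("Fz", "Pz"))

    @pytest.mark.parametrize("duration,n_stim", [(8.0, 8), (12.0, 12), (9.7, 9)])
    def test_stimulus_segment_count(self, duration, n_stim):
        sched = periodic_schedule([duration])
        rec = self._rec(sched.total_duration_s)
        seg = ee.segment_and_baseline(rec, sched)
        b = seg.blocks[0]
        assert (b.phase == "stimulus").sum() == n_stim
        assert (b.phase == "baseline").sum() == 8
        assert b.segments.shape[-1] == int(self.fs)

    def test_constant_segment_zeroed_by_correction(self):
        sched = periodic_schedule([8.0])
        rec = self._rec(sched.total_duration_s, value=42.0)
        seg = ee.segment_and_baseline(rec, sched)
        assert np.allclose(seg.blocks[0].segments, 0.0)

    def test_leading_200ms_used_as_reference(self):
        """A step in the middle of a segment survives; the leading 200 ms
        sets the zero level."""
        sched = periodic_schedule([8.0])
        n = int(sched.total_duration_s * self.fs)
        sig = np.zeros((2, n))
        on = sched.blocks[1].onset_s  # stimulus onset
        j0 = int((on + 0.5) * self.fs)
        sig[:, j0:j0 + 100] = 10.0
        rec = make_eeg(sig, fs=self.fs, montage=("Fz", "Pz"))
        seg = ee.segment_and_baseline(rec, sched)
        first_stim = np.flatnonzero(seg.blocks[0].phase == "stimulus")[0]
        s = seg.blocks[0].segments[first_stim]
        assert s.max() == pytest.approx(10.0, abs=0.2)

    def test_truncated_block_drops_partial_segments(self):
        sched = periodic_schedule([12.0])
        rec = self._rec(sched.blocks[1].onset_s + 5.0)  # ends mid-stimulus
        with pytest.warns(UserWarning, match="truncated"):
            seg = ee.segment_and_baseline(rec, sched)
        assert seg.blocks[0].n_segments < 20

    def test_inattention_flags_segments(self):
        sched = periodic_schedule([8.0])
        n_sec = int(np.floor(sched.total_duration_s))
        attention = np.ones(n_sec, dtype=bool)
        attention[int(sched.blocks[1].onset_s) + 2] = False
        rec = make_eeg(np.zeros((2, int(sched.total_duration_s * self.fs))),
                       fs=self.fs, montage=("Fz", "Pz"), attention=attention)
        seg = ee.segment_and_baseline(rec, sched)
        assert seg.blocks[0].rejected.sum() == 1
        assert "inattention" in seg.blocks[0].reject_reason


class TestArtifactRejection:
    def _blocks(self, amps):
        fs = 100
        segs = np.zeros((len(amps), 1, fs))
        for i, a in enumerate(amps):
            segs[i, 0, 50] = a
        blk = SegmentedBlock("social", 0.0, 8.0, segs,
                             np.array(["stimulus"] * len(amps)),
                             np.zeros(len(amps), bool),
                             np.array([""] * len(amps)))
        return SegmentedBlocks([blk], float(fs), ("Pz",))

    def test_threshold_rule(self):
        seg = ee.reject_artifact_segments(self._blocks([250.0, 150.0, 10.0]))
        assert list(seg.blocks[0].rejected) == [True, False, False]
        assert seg.blocks[0].reject_reason[0] == "amplitude"

    def test_infinite_threshold_rejects_nothing(self):
        seg = ee.reject_artifact_segments(self._blocks([1e6, 500.0]),
                                          amp_threshold_uv=np.inf)
        assert not seg.blocks[0].rejected.any()

    def test_counts_conserved(self):
        seg = ee.reject_artifact_segments(self._blocks([250.0, 150.0, 300.0]))
        c = seg.counts()
        assert c["retained"] + c["rejected"] == c["total"] == 3

    def test_fully_rejected_block_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            seg = ee.reject_artifact_segments(self._blocks([300.0, 400.0]))
        assert seg.blocks == []


class TestBandRMS:
    def _seg_blocks(self, sig_fn, n_seg=3, fs=500.0):
        t = np.arange(int(fs)) / fs
        seg = sig_fn(t)
        segs = np.tile(seg, (n_seg, 1, 1))
        blk = SegmentedBlock("social", 0.0, 8.0, segs,
                             np.array(["stimulus"] * n_seg),
                             np.zeros(n_seg, bool), np.array([""] * n_seg))
        return SegmentedBlocks([blk], fs, ("Pz",))

    def test_sinusoid_rms_is_amplitude_over_sqrt2(self):
        sb = self._seg_blocks(lambda t: 10 * np.sin(2 * np.pi * 10 * t)[None, :])
        bp = ee.band_rms(sb)
        alpha = bp.block_rms[0][0, list(bp.bands).index("alpha"), 0]
        assert alpha == pytest.approx(10 / np.sqrt(2), rel=0.02)

    def test_out_of_band_leakage_small(self):
        sb = self._seg_blocks(lambda t: 10 * np.sin(2 * np.pi * 10 * t)[None, :])
        bp = ee.band_rms(sb)
        names = list(bp.bands)
        theta = bp.block_rms[0][0, names.index("theta"), 0]
        alpha = bp.block_rms[0][0, names.index("alpha"), 0]
        assert theta < 0.1 * alpha

    def test_zero_signal_zero_rms(self):
        sb = self._seg_blocks(lambda t: np.zeros((1, t.size)))
        bp = ee.band_rms(sb)
        assert np.allclose(np.nan_to_num(np.concatenate(
            [r.ravel() for r in bp.block_rms])), 0.0)

    def test_sign_flip_invariance(self):
        sb_pos = self._seg_blocks(lambda t: 10 * np.sin(2 * np.pi * 10 * t)[None, :])
        sb_neg = self._seg_blocks(lambda t: -10 * np.sin(2 * np.pi * 10 * t)[None, :])
        a = ee.band_rms(sb_pos).block_rms[0]
        b = ee.band_rms(sb_neg).block_rms[0]
        assert np.allclose(a, b)
        assert np.nanmin(a) >= 0

    def test_band_above_nyquist_rejected(self):
        sb = self._seg_blocks(lambda t: np.zeros((1, t.size)), fs=100.0)
        with pytest.raises(InvalidArgumentError):
            ee.band_rms(sb)

    def test_fft_method_agrees_roughly(self):
        sb = self._seg_blocks(lambda t: 10 * np.sin(2 * np.pi * 10 * t)[None, :])
        a = ee.band_rms(sb, method="butter").block_rms[0]
        b = ee.band_rms(sb, method="fft").block_rms[0]
        i = list(ee.DEFAULT_BANDS).index("alpha")
        assert b[0, i, 0] == pytest.approx(a[0, i, 0], rel=0.1)


def make_band_power(rms_blocks, conditions, bands=("alpha",)):
    """Hand-built BandPowerSeries: each block is (1 ch, n_band, 16 segs)
    with 8 baseline + 8 stimulus segments."""
    blocks, phases = [], []
    for arr in rms_blocks:
        blocks.append(np.asarray(arr, float)[None, None, :].repeat(len(bands), axis=1))
        phases.append(np.array(["baseline"] * 8 + ["stimulus"] * 8))
    return ng.types.BandPowerSeries(
        block_rms=blocks, block_phase=phases, block_condition=list(conditions),
        bands={b: (8.0, 12.0) for b in bands}, montage=("Pz",))


class TestBlockBaselineCorrection:
    def test_flat_block_corrects_to_zero(self):
        bp = make_band_power([np.full(16, 3.0)], ["social"])
        out = ee.block_baseline_correct_and_average(bp)
        assert np.allclose(out["social"].corrected, 0.0)

    def test_baseline_subtraction_level(self):
        block = np.array([2.0] * 8 + [5.0] * 8)
        bp = make_band_power([block], ["social"])
        out = ee.block_baseline_correct_and_average(bp)
        assert np.allclose(out["social"].stimulus_window, 3.0)
        assert out["social"].baseline_mean[0, 0] == pytest.approx(2.0)

    def test_average_across_blocks(self):
        b1 = np.array([0.0] * 8 + [1.0] * 8)
        b2 = np.array([0.0] * 8 + [3.0] * 8)
        bp = make_band_power([b1, b2], ["social", "social"])
        out = ee.block_baseline_correct_and_average(bp)
        assert np.allclose(out["social"].stimulus_window, 2.0)
        assert out["social"].n_blocks == 2

    def test_final_two_baseline_seconds_define_reference(self):
        block = np.array([9.0] * 6 + [1.0, 1.0] + [4.0] * 8)
        bp = make_band_power([block], ["social"])
        out = ee.block_baseline_correct_and_average(bp)
        assert np.allclose(out["social"].stimulus_window, 3.0)

    def test_missing_condition_raises(self):
        bp = make_band_power([], [])
        with pytest.raises((EmptyConditionError, KeyError, ValueError)):
            ee.block_baseline_correct_and_average(bp)["social"]


class TestConditionStats:
    def _responses(self, rng, n_sub, effect=0.0, channel=0):
        subs = []
        for _ in range(n_sub):
            resp = {}
            for cond in ("social", "non-social"):
                block = rng.normal(1.0, 0.2, size=(2, 1, 16))
                if cond == "social":
                    block[channel, :, 8:] += effect
                bp = ng.types.BandPowerSeries(
                    block_rms=[block],
                    block_phase=[np.array(["baseline"] * 8 + ["stimulus"] * 8)],
                    block_condition=[cond], bands={"alpha": (8.0, 12.0)},
                    montage=("Fz", "Pz"))
                resp.update(ee.block_baseline_correct_and_average(bp))
            subs.append(resp)
        return subs

    def test_null_data_mostly_insignificant(self):
        rng = np.random.default_rng(0)
        subs = self._responses(rng, 10)
        table = ee.eeg_condition_stats(subs)
        assert not table["sig_fdr"].any()

    def test_identical_conditions_give_zero_t(self):
        subs = []
        for _ in range(4):
            block = np.ones((2, 1, 16)) * 2.0
            resp = {}
            for cond in ("social", "non-social"):
                bp = ng.types.BandPowerSeries(
                    block_rms=[block.copy()],
                    block_phase=[np.array(["baseline"] * 8 + ["stimulus"] * 8)],
                    block_condition=[cond], bands={"alpha": (8.0, 12.0)},
                    montage=("Fz", "Pz"))
                resp.update(ee.block_baseline_correct_and_average(bp))
            subs.append(resp)
        table = ee.eeg_condition_stats(subs)
        assert np.allclose(table["t"], 0.0)
        assert not table["sig_fdr"].any()

    def test_planted_channel_detected(self):
        rng = np.random.default_rng(7)
        subs = self._responses(rng, 14, effect=0.5, channel=1)
        table = ee.eeg_condition_stats(subs)
        cell = table[(table.channel == "Pz")
                     & (table.contrast == "social-baseline")]
        assert bool(cell["sig_uncorrected"].iloc[0])
        null_cell = table[(table.channel == "Fz")
                          & (table.contrast == "nonsocial-baseline")]
        assert not bool(null_cell["sig_fdr"].iloc[0])

    def test_requires_three_subjects(self):
        rng = np.random.default_rng(1)
        with pytest.raises(InvalidArgumentError):
            ee.eeg_condition_stats(self._responses(rng, 2))
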