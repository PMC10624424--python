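"""Core containers and errors shared across the pipeline.

Units are fixed package-wide: time in seconds, chromophore concentration
changes in micromolar (μM), EEG in microvolts (μV), attenuation changes in
optical density (OD), wavelengths in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHROMOPHORES = ("HbO2", "HHb", "oxCCO")

#: EEG frequency bands (Hz). Gamma deliberately overlaps beta: the band
#: definitions are conventional for infant work and are used as printed.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 6.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (20.0, 60.0),
    "high_gamma": (60.0, 80.0),
}

#: Standard 32-electrode 10/20 montage labels (BioSemi-32 style).
EEG_MONTAGE_32 = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)


# ---------------------------------------------------------------------------
# errors

class InvalidArgumentError(ValueError):
    """A precondition on an argument was violated."""


class MissingSpectraError(KeyError):
    """A requested wavelength is not covered by the extinction table."""


class DegenerateSystemError(np.linalg.LinAlgError):
    """Rank-deficient inversion system (extinction submatrix not full rank)."""


class DegenerateDesignError(ValueError):
    """GLM design matrix is degenerate (constant or collinear regressor)."""


class EmptyConditionError(ValueError):
    """No usable blocks exist for the requested condition."""


class SchemaError(ValueError):
    """An on-disk file is missing a required field."""


# ---------------------------------------------------------------------------
# stimulus schedule

@dataclass(frozen=True)
class Block:
    condition: str  # "social" | "non-social" | "baseline"
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class StimulusSchedule:
    """Ordered, non-overlapping stimulus blocks.

    Experimental blocks alternate social/non-social with durations of
    8–12 s; each is preceded by an 8 s baseline composed of 1–3 s
    static images.  The recording opens with a ≥10 s rest, so the first
    block onset is at or after 10 s.
    """

    blocks: list[Block]
    total_duration_s: float
    #: sub-image boundaries of each baseline block (seconds within block)
    baseline_subimages: dict[int, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = [b.onset_s for b in self.blocks]
        if any(b.duration_s <= 0 for b in self.blocks):
            raise InvalidArgumentError("block durations must be positive")
        if any(o2 < o1 + b.duration_s - 1e-9
               for (o1, b), o2 in zip(zip(onsets, self.blocks), onsets[1:])):
            raise InvalidArgumentError("blocks overlap or are out of order")

    def experimental_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.condition != "baseline"]

    def condition_blocks(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]

    def boxcar(self, time_s: np.ndarray, condition: str | None = None) -> np.ndarray:
        """Indicator of experimental blocks (optionally one condition) on a grid."""
        out = np.zeros_like(time_s, dtype=float)
        for b in self.experimental_blocks():
            if condition is None or b.condition == condition:
                out[(time_s >= b.onset_s) & (time_s < b.end_s)] = 1.0
        return out


# ---------------------------------------------------------------------------
# probe / optics

@dataclass(frozen=True)
class ProbeLayout:
    """bNIRS optode layout; the default mirrors the infant probe geometry:
    4 sources × 14 detectors forming 19 channels at 2.5 cm separation,
    channels numbered 1–19."""

    n_sources: int = 4
    n_detectors: int = 14
    channel_pairs: tuple[tuple[int, int], ...] = ()
    separation_cm: float = 2.5

    def __post_init__(self) -> None:
        if not self.channel_pairs:
            # deterministic synthetic pairing: cycle sources over detectors
            pairs = tuple(
                (i % self.n_sources + 1, i % self.n_detectors + 1) for i in range(19)
            )
            object.__setattr__(self, "channel_pairs", pairs)

    @property
    def n_channels(self) -> int:
        return len(self.channel_pairs)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_channels + 1))


@dataclass
class ExtinctionTable:
    """Specific extinction coefficients ε(λ) in OD·μM⁻¹·cm⁻¹ for the
    chromophore triple (HbO2, HHb, oxCCO), one row per wavelength."""

    wavelengths_nm: np.ndarray  # (n_wl,)
    epsilon: np.ndarray         # (n_wl, 3)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (self.wavelengths_nm.size, 3):
            raise InvalidArgumentError("epsilon must be (n_wavelengths, 3)")
        if np.any(self.epsilon[:, :2] < 0):
            raise InvalidArgumentError("haemoglobin extinctions must be non-negative")

    def subtable(self, lo_nm: float, hi_nm: float) -> "ExtinctionTable":
        m = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        return ExtinctionTable(self.wavelengths_nm[m], self.epsilon[m])

    def at(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Extinction rows at exactly the requested wavelengths."""
        idx = np.searchsorted(self.wavelengths_nm, wavelengths_nm)
        idx = np.clip(idx, 0, self.wavelengths_nm.size - 1)
        if not np.allclose(self.wavelengths_nm[idx], wavelengths_nm, atol=1e-6):
            missing = np.asarray(wavelengths_nm)[
                ~np.isclose(self.wavelengths_nm[idx], wavelengths_nm, atol=1e-6)
            ]
            raise MissingSpectraError(
                f"wavelengths not in extinction table: {missing[:5].tolist()}"
            )
        return self.epsilon[idx]


# ---------------------------------------------------------------------------
# recordings and derived series

@dataclass
class BroadbandRecording:
    """Attenuation changes ΔA(channel, wavelength, time) in OD, with the raw
    mean detector counts per channel used for signal-quality control."""

    attenuation: np.ndarray        # (n_ch, n_wl, n_t)
    wavelengths_nm: np.ndarray     # (n_wl,)
    time_s: np.ndarray             # (n_t,) uniform
    intensity_counts: np.ndarray   # (n_ch,)
    layout: ProbeLayout

    def __post_init__(self) -> None:
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity_counts = np.asarray(self.intensity_counts, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise InvalidArgumentError("wavelengths must be strictly increasing")
        if self.wavelengths_nm.size and (
            self.wavelengths_nm[0] < 504 or self.wavelengths_nm[-1] > 1068
        ):
            raise InvalidArgumentError("wavelengths must lie within 504–1068 nm")
        if np.any(self.intensity_counts < 0):
            raise InvalidArgumentError("intensity counts must be non-negative")
        self._check_uniform_grid()

    def _check_uniform_grid(self) -> None:
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidArgumentError("time grid must be uniform")

    @property
    def sample_period_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass
class ChromophoreTimeSeries:
    """Δ[HbO2], Δ[HHb], Δ[oxCCO] per channel over time, in μM."""

    conc: np.ndarray              # (n_ch, 3, n_t)
    time_s: np.ndarray            # (n_t,)
    excluded_channels: set[int] = field(default_factory=set)
    chromophores: tuple[str, ...] = CHROMOPHORES

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if not np.all(np.isfinite(self.conc)):
            raise InvalidArgumentError("concentrations must be finite")

    @property
    def sample_period_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass
class ChannelQCReport:
    mean_counts: np.ndarray      # (n_ch,)
    keep: np.ndarray             # (n_ch,) bool
    subject_excluded: bool
    exclusion_fraction: float
    low_counts: float
    high_counts: float
    subject_threshold: float

    @property
    def excluded_channel_ids(self) -> list[int]:
        return [i + 1 for i in np.flatnonzero(~self.keep)]


# ---------------------------------------------------------------------------
# EEG containers

@dataclass
class EEGRecording:
    """Multichannel EEG in μV at a fixed sampling rate, with optional
    per-second attention mask (True = infant attending)."""

    signal: np.ndarray                     # (n_ch, n_t)
    fs: float = 500.0
    montage: tuple[str, ...] = EEG_MONTAGE_32
    attention_mask: np.ndarray | None = None  # bool per 1 s segment

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if len(set(self.montage)) != len(self.montage):
            raise InvalidArgumentError("montage labels must be unique")
        if self.signal.shape[0] != len(self.montage):
            raise InvalidArgumentError(
                f"signal has {self.signal.shape[0]} rows but montage has "
                f"{len(self.montage)} labels"
            )
        if not np.all(np.isfinite(self.signal)):
            raise InvalidArgumentError("EEG signal must be finite")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        return self.montage.index(label)


@dataclass
class SegmentedBlock:
    """One stimulus block cut into 1 s segments.

    Each segment spans 200 ms of the preceding second plus 800 ms of the
    current second and has been baseline-corrected by its leading 200 ms.
    ``phase`` marks each segment 'baseline' or 'stimulus'.
    """

    condition: str
    block_onset_s: float          # start of the baseline period
    stimulus_onset_s: float
    segments: np.ndarray          # (n_seg, n_ch, n_samples)
    phase: np.ndarray             # (n_seg,) of {'baseline','stimulus'}
    rejected: np.ndarray          # (n_seg,) bool
    reject_reason: np.ndarray     # (n_seg,) of str ('' if retained)

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


@dataclass
class SegmentedBlocks:
    blocks: list[SegmentedBlock]
    fs: float
    montage: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        total = sum(b.n_segments for b in self.blocks)
        rejected = sum(int(b.rejected.sum()) for b in self.blocks)
        return {"total": total, "rejected": rejected, "retained": total - rejected}


@dataclass
class BandPowerSeries:
    """Per-block RMS power: for each block an array (n_ch, n_band, n_seg) in
    μV, NaN where the segment was rejected."""

    block_rms: list[np.ndarray]
    block_phase: list[np.ndarray]
    block_condition: list[str]
    bands: dict[str, tuple[float, float]]
    montage: tuple[str, ...]
    baseline_corrected: bool = False


@dataclass
class BlockAverageResponse:
    """Block-baseline-corrected RMS responses averaged across a condition's
    blocks: arrays indexed (channel, band, segment) with the segment axis
    covering 8 baseline + 8 stimulus seconds."""

    condition: str
    corrected: np.ndarray          # (n_ch, n_band, 16)
    stimulus_mean: np.ndarray      # (n_ch, n_band) mean over stimulus segs
    baseline_mean: np.ndarray      # (n_ch, n_band) uncorrected baseline mean
    stimulus_mean_raw: np.ndarray  # (n_ch, n_band) uncorrected stimulus mean
    n_blocks: int
    bands: dict[str, tuple[float, float]]
    montage: tuple[str, ...]
    n_baseline_segments: int = 8
    n_stimulus_segments: int = 8

    @property
    def stimulus_window(self) -> np.ndarray:
        """Corrected RMS over the 8 s stimulus window, (n_ch, n_band, 8)."""
        return self.corrected[:, :, self.n_baseline_segments:]


# ---------------------------------------------------------------------------
# response functions

@dataclass(frozen=True)
class BasisParams:
    """Double-gamma basis parameters: shape ('delay') of the response and
    undershoot gamma densities (unit scale, so the shape parameter is the
    delay in seconds) and the response:undershoot amplitude ratio."""

    delay_response_s: float
    delay_undershoot_s: float
    ratio_response_undershoot: float

    def __post_init__(self) -> None:
        if self.ratio_response_undershoot == 0:
            raise InvalidArgumentError("ratio must be non-zero")
        if min(self.delay_response_s, self.delay_undershoot_s,
               self.ratio_response_undershoot) <= 0:
            raise InvalidArgumentError("basis parameters must be positive")


#: Adult canonical double-gamma parameters (6 s response delay, 16 s
#: undershoot delay, ratio 6).
ADULT_CANONICAL = BasisParams(6.0, 16.0, 6.0)


@dataclass
class ResponseFunction:
    """A sampled, peak-normalised HRF/MRF kernel (dimensionless)."""

    kernel: np.ndarray
    params: BasisParams
    sample_period_s: float

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.kernel.size) * self.sample_period_s


@dataclass
class GridSearchResult:
    table: "object"               # pandas DataFrame: one row per combination
    best: BasisParams
    best_beta: float
    best_p: float
    significant: bool
    p_threshold: float
    grid: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# coupling containers

@dataclass
class NeuralRegressor:
    """The z-scored neural regressor on the bNIRS stimulus-period grid,
    tagged with its EEG source, plus the intermediate predicted-bNIRS series
    retained for inspection."""

    values: np.ndarray            # on the bNIRS grid, z-scored
    source: tuple[str, str, str]  # (eeg_channel, band, condition)
    predicted_bnirs: np.ndarray   # 1 s working-grid predicted series
    working_grid_s: np.ndarray


@dataclass
class SubjectGLMResult:
    subject_id: str
    #: β indexed by (bnirs_channel, chromophore, eeg_channel, band, condition)
    beta: "object"                # pandas DataFrame
    design_condition_number: float


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic dataset."""

    chromo_truth: ChromophoreTimeSeries | None
    #: (eeg_channel, band, condition) → multiplicative RMS amplitude factor
    eeg_band_gain: dict[tuple[str, str, str], float]
    #: planted couplings (bnirs_channel, eeg_channel, band, chromophore, sign)
    coupling_spec: list[tuple[int, str, str, str, int]]
    rng_seed: int

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.eeg_band_gain.values()):
            raise InvalidArgumentError("amplitude factors must be positive")
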