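"""Synthetic study generator.

Emulates the structure of a simultaneous broadband-NIRS / EEG infant
recording with known ground truth, so that every downstream stage —
chromophore inversion, band-power extraction, response-function recovery
and coupling statistics — can be exercised and validated without any
recorded data.

The emulated design: a ≥10 s opening rest, then alternating 8 s baselines
(static images of 1–3 s) and social/non-social stimulus blocks of 8–12 s.
Chromophore responses arise by convolving the stimulus boxcar with
double-gamma kernels; broadband attenuation follows the modified
Beer–Lambert forward model ΔA(λ,t) = Σᵢ εᵢ(λ)·Δcᵢ(t)·d·DPF; EEG is pink
noise plus narrowband oscillations whose amplitude is modulated by
condition-dependent gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .hrf import double_gamma
from .types import (
    CHROMOPHORES,
    DEFAULT_BANDS,
    EEG_MONTAGE_32,
    BasisParams,
    Block,
    BroadbandRecording,
    ChromophoreTimeSeries,
    EEGRecording,
    ExtinctionTable,
    GroundTruth,
    InvalidArgumentError,
    MissingSpectraError,
    ProbeLayout,
    StimulusSchedule,
)

__all__ = [
    "generate_schedule",
    "synthetic_extinction_table",
    "simulate_chromophore_truth",
    "forward_attenuation",
    "simulate_eeg",
    "SpikeSpec",
    "default_basis",
    "DEFAULT_AMPLITUDES_UM",
]

#: Default bNIRS sample period (s): the probe's source pairs are
#: time-multiplexed on a 1.4 s cycle.
BNIRS_SAMPLE_PERIOD_S = 1.4

#: Ground-truth basis parameters per chromophore: the recovered infant
#: kernels (response delays 8/8/9 s, undershoot delay 7 s, ratios 2/2/3).
def default_basis() -> dict[str, BasisParams]:
    return {
        "HbO2": BasisParams(8.0, 7.0, 2.0),
        "HHb": BasisParams(8.0, 7.0, 2.0),
        "oxCCO": BasisParams(9.0, 7.0, 3.0),
    }


#: Realistic peak response amplitudes (μM): functional HbO2 increases of
#: order 1 μM, smaller HHb decreases, and oxCCO changes an order of
#: magnitude below haemoglobin.
DEFAULT_AMPLITUDES_UM = {"HbO2": 1.0, "HHb": -0.4, "oxCCO": 0.15}


# ---------------------------------------------------------------------------
# stimulus schedule

def _baseline_subimages(rng: np.random.Generator, total: float = 8.0) -> tuple[float, ...]:
    """Partition an 8 s baseline into pseudorandom 1–3 s static images."""
    parts: list[float] = []
    remaining = total
    while remaining > 0:
        hi = min(3.0, remaining)
        if remaining <= 3.0:
            d = remaining
        else:
            d = float(rng.integers(1, int(hi) + 1))
            # never leave an infeasible remainder < 1 s
            if 0 < remaining - d < 1.0:
                d = remaining
        parts.append(d)
        remaining -= d
    return tuple(parts)


def generate_schedule(
    n_trials: int,
    rng_seed: int,
    rest_s: float = 10.0,
    baseline_s: float = 8.0,
) -> StimulusSchedule:
    """Alternating baseline/stimulus schedule with ``n_trials`` stimulus
    blocks of 8–12 s, opening with a ``rest_s`` ≥ 10 s rest."""
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")
    if rest_s < 10.0:
        raise InvalidArgumentError("opening rest must be at least 10 s")
    rng = np.random.default_rng(rng_seed)
    first = rng.choice(["social", "non-social"])
    order = ["social", "non-social"] if first == "social" else ["non-social", "social"]

    blocks: list[Block] = []
    subimages: dict[int, tuple[float, ...]] = {}
    t = rest_s
    for i in range(n_trials):
        subimages[len(blocks)] = _baseline_subimages(rng, baseline_s)
        blocks.append(Block("baseline", t, baseline_s))
        t += baseline_s
        dur = float(rng.uniform(8.0, 12.0))
        blocks.append(Block(order[i % 2], t, dur))
        t += dur
    return StimulusSchedule(blocks=blocks, total_duration_s=t,
                            baseline_subimages=subimages)


# ---------------------------------------------------------------------------
# optics forward model

def synthetic_extinction_table(
    lo_nm: float = 780.0, hi_nm: float = 900.0, step_nm: float = 1.0
) -> ExtinctionTable:
    """Deterministic synthetic extinction spectra.

    Three smooth, linearly independent curves standing in for the compiled
    published ε(λ) of HbO2, HHb and oxCCO (synthetic: the shapes echo the
    qualitative NIR features — HbO2 rising towards 900 nm, HHb with its
    ~760 nm shoulder decaying across the window, oxCCO with a broad ~830 nm
    band — but the values are not measured coefficients).  Units
    OD·μM⁻¹·cm⁻¹ at physiologically plausible magnitudes (~1e-3).
    """
    wl = np.arange(lo_nm, hi_nm + 0.5 * step_nm, step_nm)
    x = (wl - lo_nm) / (hi_nm - lo_nm)  # 0..1
    eps_hbo2 = 1e-3 * (0.6 + 0.9 * x + 0.15 * np.sin(2.2 * np.pi * x))
    eps_hhb = 1e-3 * (1.6 - 1.1 * x + 0.12 * np.cos(3.1 * np.pi * x))
    eps_ox = 1e-3 * (0.8 + 1.1 * np.exp(-0.5 * ((wl - 830.0) / 28.0) ** 2))
    eps = np.column_stack([eps_hbo2, eps_hhb, eps_ox])
    return ExtinctionTable(wavelengths_nm=wl, epsilon=eps)


def simulate_chromophore_truth(
    schedule: StimulusSchedule,
    layout: ProbeLayout,
    basis: dict[str, BasisParams] | None = None,
    amplitude: dict[tuple[int, str], dict[str, float]] | None = None,
    sample_period_s: float = BNIRS_SAMPLE_PERIOD_S,
) -> ChromophoreTimeSeries:
    """Ground-truth chromophore traces: per channel the sum over stimulus
    blocks of amplitude × (boxcar ⊛ kernel) on a uniform grid.

    ``amplitude`` maps (channel_id, condition) → {chromophore: μM}; channels
    or conditions absent from the map respond with the default amplitudes.
    """
    if sample_period_s <= 0:
        raise InvalidArgumentError("sample_period_s must be positive")
    if not schedule.blocks or schedule.total_duration_s <= 0:
        raise InvalidArgumentError("schedule is empty")
    basis = basis if basis is not None else default_basis()
    time_s = np.arange(0.0, schedule.total_duration_s, sample_period_s)
    n_ch = layout.n_channels
    conc = np.zeros((n_ch, len(CHROMOPHORES), time_s.size))

    kernels = {c: double_gamma(basis[c], sample_period_s).kernel
               for c in CHROMOPHORES}
    conditions = sorted({b.condition for b in schedule.experimental_blocks()})
    for cond in conditions:
        boxcar = schedule.boxcar(time_s, cond)
        for ci, chromo in enumerate(CHROMOPHORES):
            drive = np.convolve(boxcar, kernels[chromo])[: time_s.size] * sample_period_s
            for ch_i, ch_id in enumerate(layout.channel_ids):
                amp = DEFAULT_AMPLITUDES_UM[chromo]
                if amplitude is not None:
                    amp = amplitude.get((ch_id, cond), {}).get(chromo, 0.0)
                if not np.isfinite(amp):
                    raise InvalidArgumentError("amplitudes must be finite")
                conc[ch_i, ci] += amp * drive
    return ChromophoreTimeSeries(conc=conc, time_s=time_s)


@dataclass(frozen=True)
class SpikeSpec:
    """Motion-spike artifacts: brief additive attenuation transients shared
    by all wavelengths of a channel (optode-coupling events, not
    chromophore changes)."""

    n_spikes: int = 0
    amplitude_od: float = 0.05
    duration_s: float = 0.5


def forward_attenuation(
    truth: ChromophoreTimeSeries,
    extinction: ExtinctionTable,
    layout: ProbeLayout,
    dpf: float = 5.13,
    noise_sd: float = 0.0,
    spike_spec: SpikeSpec | None = None,
    rng_seed: int = 0,
    wavelengths_nm: np.ndarray | None = None,
    counts_range: tuple[float, float] = (5000.0, 35000.0),
) -> BroadbandRecording:
    """Modified Beer–Lambert forward model with optional noise and spikes.

    ΔA(ch, λ, t) = Σᵢ εᵢ(λ)·Δcᵢ(ch, t)·d·DPF + N(0, noise_sd) [+ spikes].
    Also fabricates per-channel mean intensity counts for QC testing.
    """
    if dpf <= 0:
        raise InvalidArgumentError("dpf must be positive")
    if wavelengths_nm is None:
        wavelengths_nm = extinction.wavelengths_nm
    eps = extinction.at(np.asarray(wavelengths_nm, dtype=float))  # (n_wl, 3)
    d = layout.separation_cm
    # (ch, wl, t) = eps (wl, i) x conc (ch, i, t)
    atten = np.einsum("wi,cit->cwt", eps, truth.conc) * d * dpf

    rng = np.random.default_rng(rng_seed)
    if noise_sd > 0:
        atten = atten + rng.normal(0.0, noise_sd, size=atten.shape)
    if spike_spec is not None and spike_spec.n_spikes > 0:
        dt = truth.sample_period_s
        width = max(1, int(round(spike_spec.duration_s / dt)))
        n_t = truth.time_s.size
        for _ in range(spike_spec.n_spikes):
            ch = rng.integers(0, atten.shape[0])
            t0 = rng.integers(0, max(1, n_t - width))
            sign = rng.choice([-1.0, 1.0])
            atten[ch, :, t0:t0 + width] += sign * spike_spec.amplitude_od

    counts = rng.uniform(*counts_range, size=atten.shape[0])
    return BroadbandRecording(
        attenuation=atten,
        wavelengths_nm=np.asarray(wavelengths_nm, dtype=float),
        time_s=truth.time_s.copy(),
        intensity_counts=counts,
        layout=layout,
    )


# ---------------------------------------------------------------------------
# EEG forward model

def _pink_noise(rng: np.random.Generator, n_ch: int, n_t: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit RMS per channel."""
    white = rng.standard_normal((n_ch, n_t))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_t)
    f[0] = f[1] if n_t > 1 else 1.0
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=n_t, axis=1)
    rms = pink.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return pink / rms


def simulate_eeg(
    schedule: StimulusSchedule,
    truth: GroundTruth,
    fs: float = 500.0,
    n_channels: int = 32,
    background_rms_uv: float = 20.0,
    band_rms_uv: float = 8.0,
    bands: dict[str, tuple[float, float]] | None = None,
    artifact_rate_per_min: float = 0.0,
    inattention_prob: float = 0.0,
    montage: tuple[str, ...] | None = None,
) -> EEGRecording:
    """Condition-modulated synthetic EEG.

    Pink-noise background plus, for every band, a narrowband noise carrier
    whose amplitude during a condition's blocks is multiplied by
    ``truth.eeg_band_gain[(channel, band, condition)]`` (default 1).
    Optional >200 μV artifact bursts and a Bernoulli inattention mask.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    top = max(hi for _, hi in bands.values())
    if fs <= 2 * top:
        raise InvalidArgumentError(
            f"fs={fs} Hz aliases the {top} Hz band edge; need fs > {2 * top}"
        )
    if montage is None:
        montage = EEG_MONTAGE_32[:n_channels]
    if len(montage) != n_channels:
        raise InvalidArgumentError("montage length must equal n_channels")

    rng = np.random.default_rng(truth.rng_seed)
    n_t = int(round(schedule.total_duration_s * fs))
    t = np.arange(n_t) / fs
    sig = background_rms_uv * _pink_noise(rng, n_channels, n_t)

    conditions = sorted({b.condition for b in schedule.experimental_blocks()})
    for band_name, (lo, hi) in bands.items():
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal((n_channels, n_t)), axis=1)
        crms = carrier.std(axis=1, keepdims=True)
        crms[crms == 0] = 1.0
        carrier = band_rms_uv * carrier / crms
        envelope = np.ones((n_channels, n_t))
        for cond in conditions:
            box = schedule.boxcar(t, cond)
            for ch_i, label in enumerate(montage):
                g = truth.eeg_band_gain.get((label, band_name, cond), 1.0)
                if g != 1.0:
                    envelope[ch_i] += (g - 1.0) * box
        sig += carrier * envelope

    if artifact_rate_per_min > 0:
        n_art = max(1, int(round(artifact_rate_per_min * schedule.total_duration_s / 60.0)))
        seg_len = int(fs)
        for _ in range(n_art):
            ch = rng.integers(0, n_channels)
            s0 = int(rng.integers(0, max(1, n_t - seg_len)))
            burst = 300.0 * np.hanning(seg_len)
            sig[ch, s0:s0 + seg_len] += rng.choice([-1.0, 1.0]) * burst

    n_seg = int(np.floor(schedule.total_duration_s))
    attention = np.ones(n_seg, dtype=bool)
    if inattention_prob > 0:
        attention = rng.random(n_seg) >= inattention_prob

    return EEGRecording(signal=sig, fs=fs, montage=tuple(montage),
                        attention_mask=attention)
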