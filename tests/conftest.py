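import numpy as np
import pytest

import nirseeg as ng
from nirseeg import synthetic as syn


@pytest.fixture(scope="session")
def layout() -> ng.ProbeLayout:
    return ng.ProbeLayout()


@pytest.fixture(scope="session")
def one_channel_layout() -> ng.ProbeLayout:
    return ng.ProbeLayout(n_sources=1, n_detectors=1, channel_pairs=((1, 1),))


@pytest.fixture(scope="session")
def extinction() -> ng.ExtinctionTable:
    return syn.synthetic_extinction_table()


@pytest.fixture(scope="session")
def schedule() -> ng.StimulusSchedule:
    return syn.generate_schedule(4, rng_seed=7)


def make_recording(signal_1d: np.ndarray, time_s: np.ndarray,
                   wavelength_nm: float = 800.0,
                   counts: float = 10000.0) -> ng.BroadbandRecording:
    """Single-channel, single-wavelength broadband recording wrapper."""
    lay = ng.ProbeLayout(n_sources=1, n_detectors=1, channel_pairs=((1, 1),))
    return ng.BroadbandRecording(
        attenuation=signal_1d[None, None, :],
        wavelengths_nm=np.array([wavelength_nm]),
        time_s=time_s,
        intensity_counts=np.array([counts]),
        layout=lay,
    )


def bh_stepup_oracle(pvals: np.ndarray, q: float) -> np.ndarray:
    """Independent Benjamini–Hochberg step-up: reject the k smallest p-values
    where k = max{i : p_(i) <= i*q/m}, by direct enumeration."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject
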