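"""On-disk formats and pipeline configuration.

bNIRS recordings are written either as wide CSV (one column per
channel×wavelength, with a JSON sidecar carrying counts and probe layout)
or as a minimal SNIRF-style HDF5 layout; EEG as wide CSV (μV, one column
per electrode); schedules as 3-column TSV; ground truth and configuration
as JSON.  All headers state units: time in seconds, concentration in μM,
EEG in μV, attenuation in OD.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    DEFAULT_BANDS,
    Block,
    BroadbandRecording,
    EEGRecording,
    ExtinctionTable,
    GroundTruth,
    ProbeLayout,
    SchemaError,
    StimulusSchedule,
)

__all__ = [
    "read_schedule", "write_schedule",
    "read_bnirs", "write_bnirs_csv", "write_bnirs_snirf",
    "read_eeg", "write_eeg_csv",
    "read_extinction_csv", "write_extinction_csv",
    "write_ground_truth", "read_ground_truth",
    "PipelineConfig",
]


# ---------------------------------------------------------------------------
# stimulus schedule (TSV: onset_s, duration_s, condition)

def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    df = pd.DataFrame(
        [(b.onset_s, b.duration_s, b.condition) for b in schedule.blocks],
        columns=["onset_s", "duration_s", "condition"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_schedule(path: str | Path) -> StimulusSchedule:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "duration_s", "condition"):
        if col not in df.columns:
            raise SchemaError(f"schedule file missing column '{col}'")
    blocks = [Block(r.condition, float(r.onset_s), float(r.duration_s))
              for r in df.itertuples()]
    total = max(b.end_s for b in blocks) if blocks else 0.0
    return StimulusSchedule(blocks=blocks, total_duration_s=total)


# ---------------------------------------------------------------------------
# bNIRS

def _layout_to_dict(layout: ProbeLayout) -> dict:
    return {
        "n_sources": layout.n_sources,
        "n_detectors": layout.n_detectors,
        "channel_pairs": [list(p) for p in layout.channel_pairs],
        "separation_cm": layout.separation_cm,
    }


def _layout_from_dict(d: dict) -> ProbeLayout:
    return ProbeLayout(
        n_sources=d["n_sources"], n_detectors=d["n_detectors"],
        channel_pairs=tuple(tuple(p) for p in d["channel_pairs"]),
        separation_cm=d["separation_cm"],
    )


def write_bnirs_csv(rec: BroadbandRecording, path: str | Path) -> None:
    """Wide CSV of ΔA (OD) with a '<path>.meta.json' sidecar."""
    path = Path(path)
    n_ch, n_wl, n_t = rec.attenuation.shape
    cols = {"time_s": rec.time_s}
    for c in range(n_ch):
        for w in range(n_wl):
            cols[f"ch{c + 1:02d}_wl{rec.wavelengths_nm[w]:g}"] = rec.attenuation[c, w]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "units": {"time": "s", "attenuation": "OD", "wavelength": "nm"},
        "wavelengths_nm": rec.wavelengths_nm.tolist(),
        "intensity_counts": rec.intensity_counts.tolist(),
        "layout": _layout_to_dict(rec.layout),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def _read_bnirs_csv(path: Path) -> BroadbandRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError("bNIRS CSV missing column 'time_s'")
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise SchemaError(f"missing sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    if "wavelengths_nm" not in meta:
        raise SchemaError("bNIRS sidecar missing 'wavelengths'")
    for key in ("intensity_counts", "layout"):
        if key not in meta:
            raise SchemaError(f"bNIRS sidecar missing '{key}'")
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    layout = _layout_from_dict(meta["layout"])
    n_ch = layout.n_channels
    atten = np.empty((n_ch, wavelengths.size, len(df)))
    for c in range(n_ch):
        for w, wl in enumerate(wavelengths):
            col = f"ch{c + 1:02d}_wl{wl:g}"
            if col not in df.columns:
                raise SchemaError(f"bNIRS CSV missing column '{col}'")
            atten[c, w] = df[col].to_numpy()
    return BroadbandRecording(
        attenuation=atten, wavelengths_nm=wavelengths,
        time_s=df["time_s"].to_numpy(),
        intensity_counts=np.asarray(meta["intensity_counts"], dtype=float),
        layout=layout,
    )


def write_bnirs_snirf(rec: BroadbandRecording, path: str | Path) -> None:
    """Minimal SNIRF-style HDF5: processed ΔA time series plus probe and
    per-channel intensity counts (aux)."""
    n_ch, n_wl, n_t = rec.attenuation.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        data = nirs.create_group("data1")
        flat = rec.attenuation.reshape(n_ch * n_wl, n_t).T  # (time, measurement)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.time_s)
        k = 1
        for c in range(n_ch):
            src, det = rec.layout.channel_pairs[c]
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=src)
                ml.create_dataset("detectorIndex", data=det)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=99999)  # processed
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=rec.wavelengths_nm)
        probe.create_dataset("sourceDetectorSeparation_cm", data=rec.layout.separation_cm)
        probe.create_dataset("nSources", data=rec.layout.n_sources)
        probe.create_dataset("nDetectors", data=rec.layout.n_detectors)
        probe.create_dataset(
            "channelPairs", data=np.asarray(rec.layout.channel_pairs))
        aux = nirs.create_group("aux1")
        aux.create_dataset("name", data="intensity_counts")
        aux.create_dataset("dataTimeSeries", data=rec.intensity_counts)


def _read_bnirs_snirf(path: Path) -> BroadbandRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs1"]
        probe = nirs["probe"]
        if "wavelengths" not in probe:
            raise SchemaError("SNIRF file missing 'wavelengths'")
        wavelengths = probe["wavelengths"][()]
        layout = ProbeLayout(
            n_sources=int(probe["nSources"][()]),
            n_detectors=int(probe["nDetectors"][()]),
            channel_pairs=tuple(map(tuple, probe["channelPairs"][()].tolist())),
            separation_cm=float(probe["sourceDetectorSeparation_cm"][()]),
        )
        flat = nirs["data1"]["dataTimeSeries"][()]
        time_s = nirs["data1"]["time"][()]
        n_ch = layout.n_channels
        n_wl = wavelengths.size
        atten = flat.T.reshape(n_ch, n_wl, time_s.size)
        counts = nirs["aux1"]["dataTimeSeries"][()]
    return BroadbandRecording(attenuation=atten, wavelengths_nm=wavelengths,
                              time_s=time_s, intensity_counts=counts,
                              layout=layout)


def read_bnirs(path: str | Path) -> BroadbandRecording:
    """Read a broadband recording from SNIRF (.snirf/.h5) or wide CSV."""
    path = Path(path)
    if path.suffix.lower() in {".snirf", ".h5", ".hdf5"}:
        return _read_bnirs_snirf(path)
    return _read_bnirs_csv(path)


# ---------------------------------------------------------------------------
# EEG (wide CSV, one column per electrode, μV)

def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    t = np.arange(rec.signal.shape[1]) / rec.fs
    cols = {"time_s": t}
    for i, lbl in enumerate(rec.montage):
        cols[lbl] = rec.signal[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    if rec.attention_mask is not None:
        meta = {"attention_mask": rec.attention_mask.astype(int).tolist()}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_eeg(path: str | Path, montage: tuple[str, ...] | None = None) -> EEGRecording:
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError("EEG CSV missing column 'time_s' (sampling rate undefined)")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise SchemaError("EEG CSV too short to infer fs")
    fs = 1.0 / float(t[1] - t[0])
    labels = tuple(c for c in df.columns if c != "time_s")
    if montage is not None and set(labels) != set(montage):
        raise SchemaError(
            f"EEG channels do not match montage: {len(labels)} found, "
            f"{len(montage)} expected")
    order = montage if montage is not None else labels
    sig = np.vstack([df[lbl].to_numpy() for lbl in order])
    attention = None
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if "attention_mask" in meta:
            attention = np.asarray(meta["attention_mask"], dtype=bool)
    return EEGRecording(signal=sig, fs=fs, montage=tuple(order),
                        attention_mask=attention)


# ---------------------------------------------------------------------------
# extinction table (CSV: wavelength_nm, eps_hbo2, eps_hhb, eps_oxcco)

EXTINCTION_COLUMNS = ["wavelength_nm", "eps_hbo2", "eps_hhb", "eps_oxcco"]


def write_extinction_csv(table: ExtinctionTable, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([table.wavelengths_nm, table.epsilon]),
        columns=EXTINCTION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_extinction_csv(path: str | Path) -> ExtinctionTable:
    df = pd.read_csv(path)
    for col in EXTINCTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"extinction CSV missing column '{col}'")
    return ExtinctionTable(
        wavelengths_nm=df["wavelength_nm"].to_numpy(),
        epsilon=df[EXTINCTION_COLUMNS[1:]].to_numpy(),
    )


# ---------------------------------------------------------------------------
# ground truth sidecar

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "rng_seed": truth.rng_seed,
        "eeg_band_gain": [
            {"eeg_channel": k[0], "band": k[1], "condition": k[2], "gain": v}
            for k, v in truth.eeg_band_gain.items()
        ],
        "coupling_spec": [
            {"bnirs_channel": c[0], "eeg_channel": c[1], "band": c[2],
             "chromophore": c[3], "sign": c[4]}
            for c in truth.coupling_spec
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        chromo_truth=None,
        eeg_band_gain={(g["eeg_channel"], g["band"], g["condition"]): g["gain"]
                       for g in d["eeg_band_gain"]},
        coupling_spec=[(c["bnirs_channel"], c["eeg_channel"], c["band"],
                        c["chromophore"], c["sign"]) for c in d["coupling_spec"]],
        rng_seed=d["rng_seed"],
    )


# ---------------------------------------------------------------------------
# configuration

#: Channel sets showing significant haemodynamic–metabolic coupling per
#: (condition, chromophore); consumed as inputs to channel selection.
DEFAULT_COUPLING_CHANNEL_LISTS: dict[tuple[str, str], list[int]] = {
    ("social", "HbO2"): [12, 13, 14],
    ("social", "HHb"): [11, 12, 14, 18],
    ("social", "oxCCO"): [11, 12, 13, 14, 18],
    ("non-social", "HbO2"): [12, 14],
    ("non-social", "HHb"): [12, 14, 16],
    ("non-social", "oxCCO"): [12, 14, 16],
}


@dataclass
class PipelineConfig:
    """All thresholds and defaults of the analysis pipeline.

    Every numeric default is the analysis value: DPF 5.13, wavelet α 0.8,
    bNIRS band 0.01–0.4 Hz (order 4), QC counts 2000–40,000 with 60%
    subject exclusion, EEG band 0.1–100 Hz with 48–52 Hz notch, 200 μV
    rejection, the five RMS bands, the 11×16×5 response-function grid and
    q = 0.05 BH-FDR.
    """

    rng_seed: int = 0
    # synthetic cohort
    n_subjects: int = 14
    n_trials: int = 6
    bnirs_sample_period_s: float = 1.4
    bnirs_noise_sd_od: float = 0.002
    eeg_fs_hz: float = 500.0
    # bNIRS preprocessing
    dpf: float = 5.13
    wavelet_alpha: float = 0.8
    bnirs_band_hz: tuple[float, float] = (0.01, 0.4)
    bnirs_filter_order: int = 4
    fit_range_nm: tuple[float, float] = (780.0, 900.0)
    qc_low_counts: float = 2000.0
    qc_high_counts: float = 40000.0
    qc_subject_threshold: float = 0.60
    # EEG preprocessing
    eeg_band_hz: tuple[float, float] = (0.1, 100.0)
    eeg_notch_hz: tuple[float, float] = (48.0, 52.0)
    amp_threshold_uv: float = 200.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    # response function grid
    grid_delay_response_s: tuple[float, float] = (5.0, 15.0)
    grid_delay_undershoot_s: tuple[float, float] = (5.0, 20.0)
    grid_ratio: tuple[float, float] = (2.0, 6.0)
    grid_step_s: float = 1.0
    p_threshold: float = 0.05
    # coupling
    q_fdr: float = 0.05
    coupling_channel_lists: dict = field(
        default_factory=lambda: {k: list(v) for k, v
                                 in DEFAULT_COUPLING_CHANNEL_LISTS.items()})
    # paths (optional; synthetic cohort is generated when absent)
    out_dir: str = "nirseeg_out"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("bnirs_band_hz", "fit_range_nm", "eeg_band_hz",
                    "eeg_notch_hz", "grid_delay_response_s",
                    "grid_delay_undershoot_s", "grid_ratio"):
            if key in d:
                d[key] = tuple(d[key])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        if "coupling_channel_lists" in d and isinstance(
                d["coupling_channel_lists"], dict):
            lists = {}
            for k, v in d["coupling_channel_lists"].items():
                key = tuple(k.split("|")) if isinstance(k, str) else tuple(k)
                lists[key] = list(v)
            d["coupling_channel_lists"] = lists
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupling_channel_lists"] = {
            "|".join(k): v for k, v in self.coupling_channel_lists.items()
        }
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def grid(self) -> dict[str, np.ndarray]:
        s = self.grid_step_s
        return {
            "delay_response_s": np.arange(self.grid_delay_response_s[0],
                                          self.grid_delay_response_s[1] + s / 2, s),
            "delay_undershoot_s": np.arange(self.grid_delay_undershoot_s[0],
                                            self.grid_delay_undershoot_s[1] + s / 2, s),
            "ratio_response_undershoot": np.arange(self.grid_ratio[0],
                                                   self.grid_ratio[1] + s / 2, s),
        }
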