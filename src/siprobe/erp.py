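"""Minimal probe-ERP chain: preprocess, epoch, average, extract components.

The chain mirrors a standard auditory probe-ERP workflow: resample to 250 Hz,
re-reference to linked mastoids (TP9/TP10), zero-phase FIR bandpass
0.1-30 Hz, cut 500-ms epochs ([-100, 400) ms around probe onset) with a
100-ms pre-stimulus baseline, average within condition, and extract
window-mean amplitudes and peak latencies for the P1 (40-80 ms, positive)
and N1 (120-160 ms, negative) components.

Amplitudes are kept in microvolts throughout; MNE (which works in volts)
is used for resampling, re-referencing, filtering and BrainVision/EDF
reading behind the scenes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .load import ProbeTrain

logger = logging.getLogger(__name__)

#: Electrode subset used for P1/N1 amplitude and latency analyses.
ANALYSIS_CHANNELS = (
    "Fp1", "Fz", "F3", "F7", "FC5", "FC1", "C3", "CP5", "CP1", "Pz", "P3",
    "P4", "CP6", "CP2", "Cz", "C4", "FC6", "FC2", "F4", "F8", "Fp2",
)

#: Default topographic factor cells over the analysis subset.
ANTERIORITY_MAP = {
    **{ch: "Front" for ch in ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")},
    **{ch: "Center" for ch in ("FC5", "FC1", "FC2", "FC6", "C3", "Cz", "C4")},
    **{ch: "Back" for ch in ("CP5", "CP1", "CP2", "CP6", "P3", "Pz", "P4")},
}
LATERALITY_MAP = {
    **{ch: "Left" for ch in ("Fp1", "F7", "F3", "FC5", "FC1", "C3", "CP5", "CP1", "P3")},
    **{ch: "Middle" for ch in ("Fz", "Cz", "Pz")},
    **{ch: "Right" for ch in ("Fp2", "F8", "F4", "FC6", "FC2", "C4", "CP6", "CP2", "P4")},
}


def load_topography(path: str | Path) -> tuple[dict, dict]:
    """Load a user topographic map (YAML: anteriority/laterality -> cell -> channels)."""
    import yaml

    with open(path, encoding="utf-8") as handle:
        spec = yaml.safe_load(handle)
    ant = {ch: cell for cell, chans in spec["anteriority"].items() for ch in chans}
    lat = {ch: cell for cell, chans in spec["laterality"].items() for ch in chans}
    return ant, lat


@dataclass(frozen=True)
class ComponentWindow:
    """A named post-stimulus analysis window with its expected polarity."""

    name: str
    start: float  # seconds post-stimulus
    end: float
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


P1_WINDOW = ComponentWindow("P1", 0.040, 0.080, "positive")
N1_WINDOW = ComponentWindow("N1", 0.120, 0.160, "negative")
COMPONENT_WINDOWS = (P1_WINDOW, N1_WINDOW)


@dataclass
class ContinuousEEG:
    """Multichannel continuous EEG in microvolts with probe events."""

    data: np.ndarray  # (n_channels, n_samples), uV
    sfreq: float
    ch_names: list[str]
    events: np.ndarray | None = None  # (n_events, 2): sample index, code

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples) matching ch_names")
        if self.events is not None:
            self.events = np.asarray(self.events, dtype=int)
            if self.events.size and (
                self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.n_samples
            ):
                raise ValueError("event sample indices outside the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def to_raw(self):
        import mne

        info = mne.create_info(list(self.ch_names), self.sfreq, ch_types="eeg", verbose="error")
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")


def preprocess(
    eeg: ContinuousEEG,
    *,
    sfreq_out: float = 250.0,
    l_freq: float = 0.1,
    h_freq: float = 30.0,
    mastoids: tuple[str, str] = ("TP9", "TP10"),
) -> ContinuousEEG:
    """Resample, linked-mastoid re-reference, zero-phase FIR bandpass.

    The FIR is a windowed-sinc (firwin/Hamming) design with MNE's default
    transition bandwidths, applied with zero-phase (linear-phase compensated)
    convolution; event indices are remapped to the output rate.
    """
    missing = [ch for ch in mastoids if ch not in eeg.ch_names]
    if missing:
        raise ConfigurationError(f"mastoid channels missing for re-referencing: {missing}")
    if eeg.sfreq <= 2 * h_freq:
        raise ConfigurationError(
            f"sampling rate {eeg.sfreq} Hz too low for a {h_freq} Hz filter edge"
        )
    raw = eeg.to_raw()
    if abs(eeg.sfreq - sfreq_out) > 1e-9:
        raw = raw.resample(sfreq_out, verbose="error")
    raw = raw.set_eeg_reference(list(mastoids), projection=False, verbose="error")
    raw = raw.filter(
        l_freq, h_freq, method="fir", phase="zero", fir_design="firwin", verbose="error"
    )
    events = None
    if eeg.events is not None:
        events = eeg.events.copy()
        scale = sfreq_out / eeg.sfreq
        events[:, 0] = np.clip(
            np.round(events[:, 0] * scale).astype(int), 0, raw.n_times - 1
        )
    return ContinuousEEG(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        events=events,
    )


@dataclass
class EpochSet:
    """Probe-locked epochs with per-epoch load values and condition labels."""

    data: np.ndarray  # (n_epochs, n_channels, n_times), uV
    times: np.ndarray  # seconds relative to probe onset
    sfreq: float
    ch_names: list[str]
    loads: np.ndarray
    labels: np.ndarray
    subject: str | None = None
    direction: str | None = None
    method: str | None = None
    n_edge_skipped: int = 0
    n_rejected: int = 0

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if not (len(self.loads) == len(self.labels) == n):
            raise ValueError("loads/labels must match the number of epochs")

    def __len__(self) -> int:
        return int(self.data.shape[0])

    def with_labels(self, loads: np.ndarray, labels: np.ndarray, method: str | None = None):
        """Same epochs, different per-epoch covariate (e.g. another load method)."""
        return replace(
            self, loads=np.asarray(loads), labels=np.asarray(labels), method=method
        )

    def pick(self, channels: list[str]) -> "EpochSet":
        idx = [self.ch_names.index(ch) for ch in channels]
        return replace(self, data=self.data[:, idx, :], ch_names=list(channels))


def epoch(
    eeg: ContinuousEEG,
    probes: ProbeTrain | np.ndarray,
    loads: np.ndarray,
    labels: np.ndarray,
    *,
    tmin: float = -0.100,
    tmax: float = 0.400,
    reject_ptp_uv: float | None = 150.0,
    subject: str | None = None,
    direction: str | None = None,
    method: str | None = None,
) -> EpochSet:
    """Cut baseline-corrected probe-locked epochs on the half-open [tmin, tmax).

    At 250 Hz and the default window this yields exactly 125 samples per
    epoch. The baseline is the mean over [tmin, 0) per channel. Probes too
    close to a recording edge are skipped with a warning; epochs whose
    peak-to-peak amplitude on any channel exceeds ``reject_ptp_uv`` are
    dropped and logged.
    """
    onsets = probes.onsets if isinstance(probes, ProbeTrain) else np.asarray(probes, float)
    loads = np.asarray(loads, dtype=float)
    labels = np.asarray(labels)
    if not (len(onsets) == len(loads) == len(labels)):
        raise ValueError("probes, loads and labels must have equal lengths")

    n_pre = int(round(-tmin * eeg.sfreq))
    n_post = int(round(tmax * eeg.sfreq))
    n_times = n_pre + n_post
    times = (np.arange(n_times) - n_pre) / eeg.sfreq

    kept, kept_idx = [], []
    n_edge = 0
    for i, onset in enumerate(onsets):
        center = int(round(onset * eeg.sfreq))
        start, stop = center - n_pre, center + n_post
        if start < 0 or stop > eeg.n_samples:
            n_edge += 1
            continue
        seg = eeg.data[:, start:stop].copy()
        seg -= seg[:, :n_pre].mean(axis=1, keepdims=True)
        kept.append(seg)
        kept_idx.append(i)
    if n_edge:
        warnings.warn(f"{n_edge} probes too close to the recording edge were skipped",
                      stacklevel=2)

    data = np.stack(kept) if kept else np.empty((0, len(eeg.ch_names), n_times))
    kept_idx = np.asarray(kept_idx, dtype=int)
    n_rejected = 0
    if reject_ptp_uv is not None and len(data):
        ptp = data.max(axis=2) - data.min(axis=2)
        good = (ptp <= reject_ptp_uv).all(axis=1)
        n_rejected = int((~good).sum())
        if n_rejected:
            logger.info("rejected %d epochs exceeding %.0f uV peak-to-peak",
                        n_rejected, reject_ptp_uv)
        data, kept_idx = data[good], kept_idx[good]

    return EpochSet(
        data=data,
        times=times,
        sfreq=eeg.sfreq,
        ch_names=list(eeg.ch_names),
        loads=loads[kept_idx],
        labels=labels[kept_idx],
        subject=subject,
        direction=direction,
        method=method,
        n_edge_skipped=n_edge,
        n_rejected=n_rejected,
    )


def condition_averages(
    epochs: EpochSet, conditions: tuple[str, ...] = ("low", "medium", "high")
) -> dict[str, np.ndarray]:
    """Arithmetic mean waveform (n_channels x n_times) per condition label.

    Empty cells are flagged with a warning and omitted from the result.
    """
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        mask = epochs.labels == cond
        if not mask.any():
            warnings.warn(f"no epochs in condition {cond!r}; cell flagged missing",
                          stacklevel=2)
            continue
        out[cond] = epochs.data[mask].mean(axis=0)
    return out


def grand_average(waveforms: list[np.ndarray]) -> np.ndarray:
    """Grand average weighting subjects equally (mean of subject means)."""
    if not waveforms:
        raise ValueError("no waveforms to average")
    return np.mean(np.stack(waveforms), axis=0)


def _window_mask(times: np.ndarray, win: ComponentWindow) -> np.ndarray:
    if win.start < times[0] or win.end > times[-1]:
        raise ValueError(
            f"window {win.name} [{win.start}, {win.end}] s outside epoch "
            f"[{times[0]}, {times[-1]}] s"
        )
    eps = 1e-9
    return (times >= win.start - eps) & (times <= win.end + eps)


def window_mean_amplitude(
    waveform: np.ndarray, times: np.ndarray, win: ComponentWindow
) -> np.ndarray | float:
    """Mean amplitude over samples whose times fall in the window (inclusive)."""
    mask = _window_mask(times, win)
    value = np.asarray(waveform)[..., mask].mean(axis=-1)
    return float(value) if value.ndim == 0 else value


def peak_latency(waveform: np.ndarray, times: np.ndarray, win: ComponentWindow) -> float:
    """Latency (ms) of the window extremum: max for P1-like, min for N1-like.

    Ties resolve to the earliest sample; a perfectly flat window returns the
    earliest sample with a flatness warning.
    """
    wave = np.asarray(waveform, dtype=float)
    if wave.ndim != 1:
        raise ValueError("peak_latency expects a single-channel waveform")
    mask = _window_mask(times, win)
    seg = wave[mask]
    if np.ptp(seg) == 0:
        warnings.warn(f"flat waveform in the {win.name} window; returning earliest sample",
                      stacklevel=2)
    idx = int(np.argmax(seg) if win.polarity == "positive" else np.argmin(seg))
    return float(times[mask][idx] * 1000.0)


def summarize_erp(
    epoch_sets: list[EpochSet],
    *,
    components: tuple[ComponentWindow, ...] = COMPONENT_WINDOWS,
    channels: tuple[str, ...] = ANALYSIS_CHANNELS,
    anteriority: dict | None = None,
    laterality: dict | None = None,
) -> pd.DataFrame:
    """Tidy per subject x direction x condition x channel component summary.

    One row per (subject, direction, condition, channel, component) with the
    window-mean amplitude (uV), peak latency (ms) and topographic factor
    cells. Input epoch sets should already carry condition labels (one set
    per subject x direction, per load method).
    """
    anteriority = anteriority or ANTERIORITY_MAP
    laterality = laterality or LATERALITY_MAP
    rows = []
    for es in epoch_sets:
        averages = condition_averages(es)
        present = [ch for ch in channels if ch in es.ch_names]
        for cond, wave in averages.items():
            for ch in present:
                ch_idx = es.ch_names.index(ch)
                for win in components:
                    rows.append(
                        {
                            "subject": es.subject,
                            "direction": es.direction,
                            "method": es.method,
                            "condition": cond,
                            "channel": ch,
                            "component": win.name,
                            "amplitude_uv": float(
                                window_mean_amplitude(wave[ch_idx], es.times, win)
                            ),
                            "latency_ms": peak_latency(wave[ch_idx], es.times, win),
                            "anteriority": anteriority.get(ch),
                            "laterality": laterality.get(ch),
                            "n_epochs": int((es.labels == cond).sum()),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EEG interchange: BrainVision writer (text header + IEEE float32) and
# BrainVision/EDF readers through MNE.
# ---------------------------------------------------------------------------

def write_brainvision(eeg: ContinuousEEG, basepath: str | Path) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg), multiplexed float32, uV."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    stem = basepath.stem
    vhdr, vmrk, eeg_path = (basepath.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by siprobe",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(eeg.ch_names)}",
        f"SamplingInterval={1e6 / eeg.sfreq:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    header += [
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(eeg.ch_names)
    ]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    if eeg.events is not None:
        for k, (sample, code) in enumerate(eeg.events, start=2):
            markers.append(f"Mk{k}=Stimulus,S{int(code):>3},{int(sample) + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    eeg.data.T.astype("<f4").tofile(eeg_path)
    return vhdr


def read_brainvision(vhdr_path: str | Path) -> ContinuousEEG:
    """Read a BrainVision recording (markers become probe events)."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return _from_raw(raw)


def read_edf(path: str | Path) -> ContinuousEEG:
    """Read an EDF recording through MNE (annotations become events)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _from_raw(raw)


def read_eeg(path: str | Path) -> ContinuousEEG:
    """Dispatch on extension: .vhdr -> BrainVision, .edf -> EDF."""
    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        return read_brainvision(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    raise ConfigurationError(f"unsupported EEG container: {path.suffix!r}")


def _from_raw(raw) -> ContinuousEEG:
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if "Stimulus" in desc or desc.startswith("S"):
            digits = "".join(c for c in desc if c.isdigit())
            code = int(digits) if digits else 1
            events.append((int(round(ann["onset"] * raw.info["sfreq"])), code))
    return ContinuousEEG(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        events=np.asarray(events, dtype=int) if events else None,
    )
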