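"""Forward simulator: transcripts, probe trains, and EEG with known truth.

The generator emulates the structure of a probe-tone interpreting session so
that every pipeline stage can be tested against ground truth without any
recorded data:

* a source word stream at a constant 105 words/min with Zipf-distributed
  lemma frequencies, pseudo-word surfaces of known syllable count, and a
  configurable content-word fraction;
* a right-skewed ear-voice-span (lag) process — a mean-reverting AR(1) on the
  log lag in words, hence stationary log-normal — whose mean is shifted by
  ``direction_delta_words`` in the L1->L2 direction;
* probe tones with i.i.d. uniform 450-750 ms inter-stimulus intervals;
* EEG as a sum of probe-locked Gaussian-shaped P1 (positive, ~60 ms) and N1
  (negative, ~140 ms) components whose amplitudes and latencies vary linearly
  with the session-z-scored WM load, on a fixed fronto-central spatial gain
  profile, in 1/f plus 10-Hz-alpha Gaussian background noise. The mastoid
  channels carry noise only.

Everything is a deterministic function of ``SimConfig.seed``: the same
config regenerates bit-identical transcripts, probes and EEG.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .load import ProbeTrain
from .erp import ContinuousEEG
from .transcripts import FrequencyTable, TimedWord, Transcript
from .lexical import function_words

# stream ids keep the per-stage random substreams independent
_STREAMS = {"vocab": 11, "transcript": 23, "probes": 37, "eeg": 53}
_DIR_INDEX = {"L1-L2": 0, "L2-L1": 1}

# approximate 2-D 10-20 layout (x: left -1 .. +1 right, y: back -1 .. +1 front)
_CH_POS = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.42, 0.55), "Fz": (0.0, 0.52),
    "F4": (0.42, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.67, 0.30), "FC1": (-0.22, 0.28), "FC2": (0.22, 0.28), "FC6": (0.67, 0.30),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0), "C4": (0.50, 0.0),
    "T8": (1.0, 0.0),
    "CP5": (-0.67, -0.30), "CP1": (-0.22, -0.28), "CP2": (0.22, -0.28), "CP6": (0.67, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.42, -0.55), "Pz": (0.0, -0.52),
    "P4": (0.42, -0.55), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -0.95), "O2": (0.31, -0.95),
    "TP9": (-1.08, -0.35), "TP10": (1.08, -0.35),
}

DEFAULT_CHANNELS = (
    "Fp1", "Fz", "F3", "F7", "FC5", "FC1", "C3", "CP5", "CP1", "Pz", "P3",
    "P4", "CP6", "CP2", "Cz", "C4", "FC6", "FC2", "F4", "F8", "Fp2",
    "TP9", "TP10",
)


@dataclass
class SimConfig:
    """All tunable study conditions for one simulated experiment."""

    seed: int = 0
    n_subjects: int = 9
    session_duration_s: float = 300.0
    # source speech
    word_rate_wpm: float = 105.0
    content_word_fraction: float = 0.62
    articulation_fraction: float = 0.85  # spoken part of each word slot
    vocab_size: int = 4000
    zipf_exponent: float = 1.1
    corpus_top_frequency: int = 1_000_000
    # ear-voice-span (lag) process, in words
    lag_mean_words: float = 4.0
    lag_sigma_log: float = 0.45
    lag_ar: float = 0.85
    direction_delta_words: float = 1.5  # added to the L1->L2 mean lag
    lag_min_words: float = 0.5
    lag_max_words: float = 15.0
    # probe train
    isi_low_s: float = 0.450
    isi_high_s: float = 0.750
    probe_start_s: float = 1.0
    # EEG
    sfreq: float = 250.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    p1_peak_s: float = 0.060
    p1_sigma_s: float = 0.008
    p1_base_uv: float = 1.5
    n1_peak_s: float = 0.140
    n1_sigma_s: float = 0.012
    n1_base_uv: float = -2.5
    p1_amp_slope_uv: float = 0.3  # uV per load z-unit
    n1_amp_slope_uv: float = -0.5
    p1_lat_slope_ms: float = 2.0  # ms per load z-unit
    n1_lat_slope_ms: float = 0.0
    noise_sigma_uv: float = 2.5  # residual background after artifact cleaning
    pink_exponent: float = 1.0
    alpha_ratio: float = 0.3
    alpha_freq_hz: float = 10.0
    alpha_width_hz: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.isi_low_s < self.isi_high_s):
            raise ConfigurationError("need 0 < isi_low_s < isi_high_s")
        if self.session_duration_s <= 10:
            raise ConfigurationError("session_duration_s must exceed 10 s")
        if not (0 < self.lag_min_words < self.lag_max_words):
            raise ConfigurationError("need 0 < lag_min_words < lag_max_words")
        for name in ("p1_amp_slope_uv", "n1_amp_slope_uv", "p1_lat_slope_ms", "n1_lat_slope_ms"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


@dataclass
class SimTruth:
    """Ground truth emitted alongside generated EEG, for recovery tests."""

    seed: int
    subject: int
    direction: str
    probe_onsets: list[float]
    loads: list[float]
    load_z: list[float]
    p1_amplitudes_uv: list[float]
    n1_amplitudes_uv: list[float]
    p1_latencies_s: list[float]
    n1_latencies_s: list[float]
    p1_amp_slope_uv: float
    n1_amp_slope_uv: float
    p1_lat_slope_ms: float
    n1_lat_slope_ms: float
    channel_gains: dict[str, float]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _rng(cfg: SimConfig, stream: str, *keys: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream], *keys])


# ---------------------------------------------------------------------------
# Vocabulary and frequency table
# ---------------------------------------------------------------------------

_SYLLS = {
    # 'e' and 'y' excluded from the EN inventory so the silent-e heuristic
    # never fires and generated words have exactly n_units syllables
    "en": ([c for c in "bdfgklmnprstvz"], [v for v in "aiou"]),
    "ru": ([c for c in "бвгдзклмнпрст"], [v for v in "аиоу"]),
}


def _pseudo_word(rng: np.random.Generator, language: str, n_syllables: int) -> str:
    cons, vows = _SYLLS[language]
    parts = []
    for _ in range(n_syllables):
        parts.append(cons[rng.integers(len(cons))] + vows[rng.integers(len(vows))])
    return "".join(parts)


def generate_vocabulary(cfg: SimConfig, language: str) -> tuple[list[str], FrequencyTable]:
    """Zipf-ranked pseudo-lemma vocabulary with an absolute-frequency table.

    Rank r (1-based) receives frequency ``round(corpus_top_frequency *
    r^-zipf_exponent)``, floored at 1, mimicking the straight rank-frequency
    line of a natural corpus. Deterministic given the config seed and
    language (shared across subjects and directions).
    """
    rng = _rng(cfg, "vocab", 0 if language == "ru" else 1)
    syll_counts = rng.choice([1, 2, 3, 4], size=cfg.vocab_size, p=[0.3, 0.35, 0.22, 0.13])
    lemmas: list[str] = []
    # avoid clashes with the shipped function-word lists: generated content
    # lemmas must classify as content when transcripts are re-read from disk
    taken = set(function_words(language))
    for i, k in enumerate(syll_counts):
        word = _pseudo_word(rng, language, int(k))
        for _ in range(20):
            if word not in taken:
                break
            word = _pseudo_word(rng, language, int(k))
        if word in taken:  # small syllable inventories exhaust; digits keep counts
            word = f"{word}{i}"
        taken.add(word)
        lemmas.append(word)
    ranks = np.arange(1, cfg.vocab_size + 1, dtype=float)
    freqs = np.maximum(
        1, np.rint(cfg.corpus_top_frequency * ranks**-cfg.zipf_exponent)
    ).astype(int)
    table = FrequencyTable(dict(zip(lemmas, freqs.tolist())))
    return lemmas, table


# ---------------------------------------------------------------------------
# Lag process and transcripts
# ---------------------------------------------------------------------------

def simulate_lag_words(
    cfg: SimConfig, n: int, direction: str, rng: np.random.Generator
) -> np.ndarray:
    """Right-skewed stationary lag process (in words) for one session.

    AR(1) on the log lag with stationary mean ``log(mu_dir)`` and stationary
    standard deviation ``lag_sigma_log``; the L1->L2 direction's mean lag is
    shifted by ``+direction_delta_words``. Values are clipped to the
    configured word bounds.
    """
    mu = cfg.lag_mean_words + (
        cfg.direction_delta_words if direction == "L1-L2" else 0.0
    )
    m = np.log(mu)
    innovation_sd = cfg.lag_sigma_log * np.sqrt(1.0 - cfg.lag_ar**2)
    x = np.empty(n)
    state = m + cfg.lag_sigma_log * rng.standard_normal()
    for i in range(n):
        state = cfg.lag_ar * state + (1.0 - cfg.lag_ar) * m + innovation_sd * rng.standard_normal()
        x[i] = state
    return np.clip(np.exp(x), cfg.lag_min_words, cfg.lag_max_words)


def _source_language(direction: str) -> str:
    # L1 = Russian, L2 = English: interpreting L1->L2 means a Russian source
    return "ru" if direction == "L1-L2" else "en"


def generate_transcript_pair(
    cfg: SimConfig, direction: str = "L1-L2", subject: int = 0
) -> tuple[Transcript, Transcript, FrequencyTable]:
    """Aligned source/target transcripts plus the source-language frequency table.

    The source stream runs at exactly ``word_rate_wpm`` (fixed word slots);
    each source word's translation chunk is one target word whose offset —
    the clear time — trails the source offset by the lag process, made
    non-decreasing so the overt translation is sequential.
    """
    if direction not in _DIR_INDEX:
        raise ConfigurationError(f"unknown direction {direction!r}")
    src_lang = _source_language(direction)
    tgt_lang = "en" if src_lang == "ru" else "ru"
    lemmas, table = generate_vocabulary(cfg, src_lang)
    rng = _rng(cfg, "transcript", subject, _DIR_INDEX[direction])

    slot = 60.0 / cfg.word_rate_wpm
    n_words = int(round(cfg.session_duration_s * cfg.word_rate_wpm / 60.0))
    ranks = np.arange(1, cfg.vocab_size + 1, dtype=float)
    zipf_p = ranks**-cfg.zipf_exponent
    zipf_p /= zipf_p.sum()
    fn_words = sorted(function_words(src_lang))

    is_content = rng.random(n_words) < cfg.content_word_fraction
    content_ranks = rng.choice(cfg.vocab_size, size=n_words, p=zipf_p)
    fn_choice = rng.integers(len(fn_words), size=n_words)
    lags_w = simulate_lag_words(cfg, n_words, direction, rng)

    source_words: list[TimedWord] = []
    target_words: list[TimedWord] = []
    prev_clear = 0.0
    tgt_rng = _rng(cfg, "transcript", subject, _DIR_INDEX[direction], 99)
    for i in range(n_words):
        onset = i * slot
        offset = onset + cfg.articulation_fraction * slot
        if is_content[i]:
            lemma = lemmas[content_ranks[i]]
            word_class = "content"
        else:
            lemma = fn_words[fn_choice[i]]
            word_class = "function"
        source_words.append(
            TimedWord(lemma, lemma, src_lang, onset, offset, word_class, align_id=i)
        )
        clear = max(offset + lags_w[i] * slot, prev_clear + 0.020)
        prev_clear = clear
        n_syl = max(1, round(len(lemma) / 2))
        tgt_surface = _pseudo_word(tgt_rng, tgt_lang, n_syl)
        while tgt_surface in function_words(tgt_lang):
            tgt_surface = _pseudo_word(tgt_rng, tgt_lang, n_syl)
        target_words.append(
            TimedWord(
                tgt_surface, tgt_surface, tgt_lang,
                max(clear - cfg.articulation_fraction * slot, onset + 1e-3),
                clear, "content", align_id=i,
            )
        )

    source = Transcript(role="source", words=source_words, direction=direction)
    target = Transcript(role="target", words=target_words, direction=direction)
    return source, target, table


def generate_probe_train(
    cfg: SimConfig, subject: int = 0, direction: str = "L1-L2"
) -> ProbeTrain:
    """Probe tones with i.i.d. uniform ISIs, truncated at session end."""
    if cfg.session_duration_s <= cfg.isi_high_s:
        raise ConfigurationError("session shorter than one inter-stimulus interval")
    rng = _rng(cfg, "probes", subject, _DIR_INDEX[direction])
    n_max = int(np.ceil(cfg.session_duration_s / cfg.isi_low_s)) + 2
    isis = rng.uniform(cfg.isi_low_s, cfg.isi_high_s, size=n_max)
    onsets = cfg.probe_start_s + np.concatenate([[0.0], np.cumsum(isis)])
    onsets = onsets[onsets < cfg.session_duration_s]
    return ProbeTrain(onsets=onsets)


# ---------------------------------------------------------------------------
# EEG forward model
# ---------------------------------------------------------------------------

def channel_gains(channels: tuple[str, ...]) -> np.ndarray:
    """Fixed fronto-central spatial profile; mastoids carry no evoked signal."""
    center = np.array([0.0, 0.25])  # between Fz and Cz
    gains = np.empty(len(channels))
    for i, ch in enumerate(channels):
        if ch in ("TP9", "TP10"):
            gains[i] = 0.0
            continue
        pos = np.array(_CH_POS[ch])
        d2 = float(((pos - center) ** 2).sum())
        gains[i] = np.exp(-d2 / (2 * 0.55**2))
    return gains


def _shaped_noise(
    cfg: SimConfig, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """1/f^gamma Gaussian noise with a narrowband alpha component, unit-free."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / cfg.sfreq)
    shape = np.zeros_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-cfg.pink_exponent / 2.0)
    shape += cfg.alpha_ratio * np.exp(
        -((freqs - cfg.alpha_freq_hz) ** 2) / (2 * cfg.alpha_width_hz**2)
    )
    noise = np.fft.irfft(spec * shape, n=n_samples)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def zscore_loads(loads: np.ndarray) -> np.ndarray:
    """Per-session z-scoring of probe loads (slope units: uV per z)."""
    loads = np.asarray(loads, dtype=float)
    sd = loads.std()
    return (loads - loads.mean()) / sd if sd > 0 else np.zeros_like(loads)


def generate_eeg(
    cfg: SimConfig,
    probes: ProbeTrain,
    loads: np.ndarray,
    *,
    subject: int = 0,
    direction: str = "L1-L2",
) -> tuple[ContinuousEEG, SimTruth]:
    """Simulate continuous EEG with load-modulated probe-locked components.

    Per probe i, each component contributes a Gaussian-shaped bump
    ``a_i * exp(-(t - onset_i - lat_i)^2 / (2 sigma^2))`` where
    ``a_i = base + amp_slope * z(load_i)`` (signed microvolts) and
    ``lat_i = nominal + lat_slope * z(load_i)``; the bump is scaled by the
    per-channel spatial gain and summed with spectrally shaped noise.
    """
    if cfg.sfreq < 100:
        raise ConfigurationError("sampling rate below 100 Hz is not supported")
    loads = np.asarray(loads, dtype=float)
    if loads.shape != probes.onsets.shape:
        raise ValueError("loads must align one-to-one with probe onsets")
    z = zscore_loads(loads)
    amp_p1 = cfg.p1_base_uv + cfg.p1_amp_slope_uv * z
    amp_n1 = cfg.n1_base_uv + cfg.n1_amp_slope_uv * z
    lat_p1 = cfg.p1_peak_s + cfg.p1_lat_slope_ms * 1e-3 * z
    lat_n1 = cfg.n1_peak_s + cfg.n1_lat_slope_ms * 1e-3 * z

    n_samples = int(round(cfg.session_duration_s * cfg.sfreq))
    signal = np.zeros(n_samples)
    for onset, a_p, a_n, l_p, l_n in zip(probes.onsets, amp_p1, amp_n1, lat_p1, lat_n1):
        for amp, lat, sigma in ((a_p, l_p, cfg.p1_sigma_s), (a_n, l_n, cfg.n1_sigma_s)):
            mu = onset + lat
            i0 = max(0, int(np.floor((mu - 6 * sigma) * cfg.sfreq)))
            i1 = min(n_samples, int(np.ceil((mu + 6 * sigma) * cfg.sfreq)) + 1)
            if i0 >= i1:
                continue
            tt = np.arange(i0, i1) / cfg.sfreq
            signal[i0:i1] += amp * np.exp(-0.5 * ((tt - mu) / sigma) ** 2)

    gains = channel_gains(cfg.channels)
    rng = _rng(cfg, "eeg", subject, _DIR_INDEX[direction])
    data = np.empty((len(cfg.channels), n_samples))
    for c in range(len(cfg.channels)):
        noise = _shaped_noise(cfg, n_samples, rng) * cfg.noise_sigma_uv
        data[c] = gains[c] * signal + noise

    events = np.column_stack(
        [
            np.minimum(np.round(probes.onsets * cfg.sfreq).astype(int), n_samples - 1),
            np.ones(len(probes), dtype=int),
        ]
    )
    eeg = ContinuousEEG(
        data=data, sfreq=cfg.sfreq, ch_names=list(cfg.channels), events=events
    )
    truth = SimTruth(
        seed=cfg.seed,
        subject=subject,
        direction=direction,
        probe_onsets=probes.onsets.tolist(),
        loads=loads.tolist(),
        load_z=z.tolist(),
        p1_amplitudes_uv=amp_p1.tolist(),
        n1_amplitudes_uv=amp_n1.tolist(),
        p1_latencies_s=lat_p1.tolist(),
        n1_latencies_s=lat_n1.tolist(),
        p1_amp_slope_uv=cfg.p1_amp_slope_uv,
        n1_amp_slope_uv=cfg.n1_amp_slope_uv,
        p1_lat_slope_ms=cfg.p1_lat_slope_ms,
        n1_lat_slope_ms=cfg.n1_lat_slope_ms,
        channel_gains=dict(zip(cfg.channels, gains.tolist())),
    )
    return eeg, truth


def template_at(
    cfg: SimConfig, times: np.ndarray, amp_p1: float, amp_n1: float,
    lat_p1: float | None = None, lat_n1: float | None = None,
) -> np.ndarray:
    """Noise-free single-probe template evaluated at epoch times (seconds).

    Closed-form oracle for window-mean and latency tests: the same Gaussian
    bumps the forward model adds, expressed relative to probe onset.
    """
    lat_p1 = cfg.p1_peak_s if lat_p1 is None else lat_p1
    lat_n1 = cfg.n1_peak_s if lat_n1 is None else lat_n1
    times = np.asarray(times, dtype=float)
    return amp_p1 * np.exp(-0.5 * ((times - lat_p1) / cfg.p1_sigma_s) ** 2) + amp_n1 * np.exp(
        -0.5 * ((times - lat_n1) / cfg.n1_sigma_s) ** 2
    )
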