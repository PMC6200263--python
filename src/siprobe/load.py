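"""Instantaneous working-memory load from time-coded transcript pairs.

The buffer model: a counted source word enters working memory at its own
offset (the listener has just finished hearing it) and leaves at the *clear
time* of its aligned translation chunk — the offset of the last target word
sharing its ``align_id``. Three weighting schemes are supported:

* ``CW``  — content words, unit weight;
* ``CL``  — content words weighted by min-max normalized log corpus
  frequency (higher corpus frequency -> larger weight, as printed; pass
  ``invert_cl_weight=True`` for the 1 - f̂ reading);
* ``SYL`` — all words weighted by syllable count.

The load series is stored as event breakpoints ``(time, load-after-event)``.
Two evaluations are exposed: :meth:`LoadSeries.step_at` returns the exact
buffer content (piecewise constant, right-continuous), while
:meth:`LoadSeries.interpolate` linearly interpolates between breakpoints —
the estimator used to read load off at probe onsets, which generally fall
between word offsets.

Never-translated source words have no observable clear time; they are
excluded from the series and counted in :attr:`LoadSeries.n_omitted`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError
from .lexical import count_syllables
from .transcripts import FrequencyTable, Transcript

logger = logging.getLogger(__name__)

METHODS = ("CW", "CL", "SYL")
WORD_SCOPES = ("methods", "fig2")
LABELS = ("low", "medium", "high")


@dataclass
class ProbeTrain:
    """Onsets of the task-irrelevant probe tones, with tone metadata."""

    onsets: np.ndarray  # seconds, strictly increasing
    tone_freq_hz: float = 440.0
    tone_duration_ms: float = 52.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be a 1-D array of seconds")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("probe onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onsets.size)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.onsets)


def write_probe_events(train: ProbeTrain, path: str | Path) -> Path:
    """Write probe onsets as a BIDS-style events TSV (onset, duration, trial_type)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "onset": [f"{t:.6f}" for t in train.onsets],
            "duration": [f"{train.tone_duration_ms / 1000.0:.6f}"] * len(train),
            "trial_type": ["probe"] * len(train),
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_probe_events(path: str | Path) -> ProbeTrain:
    frame = pd.read_csv(path, sep="\t")
    if "onset" not in frame.columns:
        raise ValueError(f"{path}: expected an 'onset' column")
    if "trial_type" in frame.columns:
        frame = frame[frame["trial_type"] == "probe"]
    return ProbeTrain(onsets=frame["onset"].to_numpy(dtype=float))


@dataclass
class LabelingScheme:
    """Quantile boundaries for low/medium/high condition labels.

    Quantiles are computed within one subject x direction load distribution
    (the scope at which the boundaries are meaningful), with the
    linear-interpolation sample quantile.
    """

    q_low: float = 0.10
    q_high: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.q_low < self.q_high < 1.0):
            raise ConfigurationError("need 0 < q_low < q_high < 1")


@dataclass
class LoadSeries:
    """Piecewise WM-load series for one session and one weighting method."""

    method: str
    times: np.ndarray  # breakpoint times, strictly increasing
    values: np.ndarray  # load just after each breakpoint, >= 0
    direction: str | None = None
    subject_id: str | None = None
    n_omitted: int = 0  # counted source words without an observable clear time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size == 0:
            raise ValueError("a load series needs at least one breakpoint")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("load must be non-negative")

    @property
    def breakpoints(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.values.tolist()))

    def interpolate(self, query: np.ndarray) -> np.ndarray:
        """Linear interpolation between breakpoints, clamped outside the range.

        This is the probe-onset estimator: load changes are booked at word
        offsets and read off between them by linear interpolation.
        """
        query = np.asarray(query, dtype=float)
        if query.size and np.any(np.diff(query) < 0):
            raise ValueError("query times must be sorted")
        return np.interp(query, self.times, self.values)

    def step_at(self, query: np.ndarray) -> np.ndarray:
        """Exact buffer content: value ``v_i`` on ``[t_i, t_{i+1})``.

        Before the first breakpoint the buffer holds its initial value.
        """
        query = np.asarray(query, dtype=float)
        idx = np.searchsorted(self.times, query, side="right") - 1
        return self.values[np.clip(idx, 0, self.values.size - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, f"load_{self.method.lower()}": self.values})


def _counted_words(transcript: Transcript, method: str, word_scope: str):
    content_only = {
        "CW": True,
        "CL": word_scope == "methods",
        "SYL": word_scope == "fig2",
    }[method]
    for word in transcript.words:
        if content_only and word.word_class != "content":
            continue
        yield word


def _word_weight(word, method, ftable, invert_cl_weight):
    if method == "CW":
        return 1.0
    if method == "CL":
        w = ftable.weight(word.lemma)
        return 1.0 - w if invert_cl_weight else w
    return float(count_syllables(word.surface, word.language))


def compute_load_series(
    source: Transcript,
    target: Transcript,
    method: str,
    ftable: FrequencyTable | None = None,
    *,
    word_scope: str = "methods",
    invert_cl_weight: bool = False,
    subject_id: str | None = None,
) -> LoadSeries:
    """Sweep entry/clear events into a WM-load breakpoint series.

    Each counted source word contributes its weight from its own offset until
    the offset of the last target word sharing its ``align_id``. Simultaneous
    events coalesce into a single breakpoint at the net load; a leading
    ``(0, 0)`` breakpoint records the empty buffer at session start.
    """
    method = method.upper()
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; expected one of {METHODS}")
    if word_scope not in WORD_SCOPES:
        raise ConfigurationError(f"word_scope must be one of {WORD_SCOPES}")
    if method == "CL" and ftable is None:
        raise ConfigurationError("the CL method requires a frequency table")

    source_ids = {w.align_id for w in source.words if w.align_id is not None}
    clear_time: dict[int, float] = {}
    for word in target.words:
        if word.align_id is None:
            continue
        if word.align_id not in source_ids:
            raise AlignmentError(
                f"target align_id {word.align_id} has no source counterpart"
            )
        clear_time[word.align_id] = max(clear_time.get(word.align_id, -np.inf), word.offset)

    events: list[tuple[float, float]] = []
    n_omitted = 0
    for word in _counted_words(source, method, word_scope):
        cleared = clear_time.get(word.align_id) if word.align_id is not None else None
        if cleared is None:
            n_omitted += 1
            continue
        weight = _word_weight(word, method, ftable, invert_cl_weight)
        events.append((word.offset, weight))
        events.append((max(cleared, word.offset), -weight))
    if n_omitted:
        logger.warning(
            "%d counted source words have no translated chunk and were omitted "
            "from the %s load series",
            n_omitted,
            method,
        )

    if not events:
        return LoadSeries(
            method, np.array([0.0]), np.array([0.0]), direction=source.direction,
            subject_id=subject_id, n_omitted=n_omitted,
        )

    ev = np.array(events)
    order = np.argsort(ev[:, 0], kind="stable")
    times, deltas = ev[order, 0], ev[order, 1]
    uniq_times, start_idx = np.unique(times, return_index=True)
    load_after = np.maximum(np.add.reduceat(deltas, start_idx).cumsum(), 0.0)
    if uniq_times[0] > 0.0:
        uniq_times = np.concatenate([[0.0], uniq_times])
        load_after = np.concatenate([[0.0], load_after])
    return LoadSeries(
        method, uniq_times, load_after, direction=source.direction,
        subject_id=subject_id, n_omitted=n_omitted,
    )


def label_by_quantile(loads: np.ndarray, scheme: LabelingScheme | None = None) -> np.ndarray:
    """Label probe-onset loads low/medium/high by within-distribution quantiles.

    ``low`` iff load < Q(q_low), ``high`` iff load > Q(q_high), else
    ``medium``; strict inequalities, so a degenerate (constant) distribution
    labels everything medium. Quantiles use linear interpolation.
    """
    scheme = scheme or LabelingScheme()
    loads = np.asarray(loads, dtype=float)
    if loads.size == 0:
        raise ValueError("no load values to label")
    if loads.size < 10:
        warnings.warn(
            f"only {loads.size} load values; quantile boundaries will be unstable",
            stacklevel=2,
        )
    q_lo, q_hi = np.quantile(loads, [scheme.q_low, scheme.q_high])
    labels = np.full(loads.shape, "medium", dtype=object)
    labels[loads < q_lo] = "low"
    labels[loads > q_hi] = "high"
    return labels.astype(str)


@dataclass
class SessionLoads:
    """One subject x direction session: per-method load series + probe train."""

    subject_id: str
    direction: str
    series: dict[str, LoadSeries]
    probes: ProbeTrain

    def probe_loads(self, method: str) -> np.ndarray:
        return self.series[method].interpolate(self.probes.onsets)


def median_load_table(sessions: list[SessionLoads]) -> pd.DataFrame:
    """Per subject x direction x method median load at probe onsets.

    Subjects missing either direction are dropped with a warning (the table
    feeds a paired test across directions).
    """
    directions_by_subject: dict[str, set[str]] = {}
    for s in sessions:
        directions_by_subject.setdefault(s.subject_id, set()).add(s.direction)
    complete = {
        subj for subj, dirs in directions_by_subject.items() if len(dirs) >= 2
    }
    dropped = sorted(set(directions_by_subject) - complete)
    if dropped:
        warnings.warn(f"subjects missing a direction were dropped: {dropped}", stacklevel=2)

    rows = []
    for s in sessions:
        if s.subject_id not in complete:
            continue
        for method, series in s.series.items():
            loads = series.interpolate(s.probes.onsets)
            rows.append(
                {
                    "subject": s.subject_id,
                    "direction": s.direction,
                    "method": method,
                    "median_load": float(np.median(loads)),
                    "n_probes": int(len(s.probes)),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "direction", "method", "median_load", "n_probes"])


def paired_medians(table: pd.DataFrame, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-subject (L1-L2, L2-L1) median pairs for one method."""
    sub = table[table["method"] == method].pivot(
        index="subject", columns="direction", values="median_load"
    )
    sub = sub.dropna()
    return sub["L1-L2"].to_numpy(), sub["L2-L1"].to_numpy()
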