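"""Time-coded bilingual transcripts and corpus frequency tables.

A session is described by a pair of transcripts — the source speech and the
interpreter's overt translation — whose words carry onset/offset times in
seconds and alignment ids linking each source word to its translation chunk.
Everything downstream (working-memory load series, probe labeling) is driven
by these two word streams.

File formats are plain UTF-8 TSV:

* transcript TSV: ``role  index  surface  lemma  language  onset_s  offset_s
  align_id`` (``align_id`` may be empty for target-only fillers);
* frequency TSV: ``lemma  abs_freq``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import DegenerateTableError, TranscriptError
from .lexical import classify_word, normalized_log_frequency

logger = logging.getLogger(__name__)

ROLES = ("source", "target")
DIRECTIONS = ("L1-L2", "L2-L1")

TRANSCRIPT_COLUMNS = [
    "role",
    "index",
    "surface",
    "lemma",
    "language",
    "onset_s",
    "offset_s",
    "align_id",
]


@dataclass(frozen=True)
class TimedWord:
    """One transcribed word with timing, class and alignment metadata."""

    surface: str
    lemma: str
    language: str  # "en" | "ru"
    onset: float  # seconds, >= 0
    offset: float  # seconds, > onset
    word_class: str  # "content" | "function"
    align_id: int | None = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise TranscriptError(f"negative onset for {self.surface!r}")
        if self.offset <= self.onset:
            raise TranscriptError(
                f"offset must exceed onset for {self.surface!r} "
                f"({self.onset} .. {self.offset})"
            )
        if self.word_class not in ("content", "function"):
            raise TranscriptError(f"bad word_class {self.word_class!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Transcript:
    """Ordered word stream for one role (source or target) of one session."""

    role: str
    words: list[TimedWord] = field(default_factory=list)
    direction: str = "L1-L2"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TranscriptError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.direction not in DIRECTIONS:
            raise TranscriptError(f"direction must be one of {DIRECTIONS}")
        onsets = [w.onset for w in self.words]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise TranscriptError("words must be sorted by non-decreasing onset")
        languages = {w.language for w in self.words}
        if len(languages) > 1:
            raise TranscriptError(f"mixed languages in one transcript: {languages}")

    @property
    def language(self) -> str | None:
        return self.words[0].language if self.words else None

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


def make_word(
    surface: str,
    lemma: str,
    language: str,
    onset: float,
    offset: float,
    align_id: int | None = None,
    word_class: str | None = None,
) -> TimedWord:
    """Build a TimedWord, classifying it from the shipped lists when needed."""
    if word_class is None:
        word_class = classify_word(surface, language)
    return TimedWord(surface, lemma, language, onset, offset, word_class, align_id)


def write_transcript(transcript: Transcript, path: str | Path) -> Path:
    """Write a transcript to TSV (UTF-8, header row)."""
    path = Path(path)
    rows = []
    for i, w in enumerate(transcript.words):
        rows.append(
            {
                "role": transcript.role,
                "index": i,
                "surface": w.surface,
                "lemma": w.lemma,
                "language": w.language,
                "onset_s": f"{w.onset:.6f}",
                "offset_s": f"{w.offset:.6f}",
                "align_id": "" if w.align_id is None else int(w.align_id),
            }
        )
    frame = pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_transcript(path: str | Path, direction: str = "L1-L2") -> Transcript:
    """Read and validate a transcript TSV.

    Raises :class:`TranscriptError` naming the offending line for malformed
    rows (non-numeric times, offset <= onset) and for unsorted onsets.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in frame.columns]
    if missing:
        raise TranscriptError(f"{path}: missing columns {missing}")
    roles = set(frame["role"]) if len(frame) else set()
    if len(roles) > 1:
        raise TranscriptError(f"{path}: mixed roles {roles}")
    role = roles.pop() if roles else "source"

    words: list[TimedWord] = []
    for pos, row in frame.iterrows():
        line_no = pos + 2  # 1-based, after the header line
        try:
            onset = float(row["onset_s"])
            offset = float(row["offset_s"])
            align = row["align_id"].strip()
            align_id = int(float(align)) if align else None
            word = make_word(
                surface=row["surface"],
                lemma=row["lemma"],
                language=row["language"],
                onset=onset,
                offset=offset,
                align_id=align_id,
            )
        except (ValueError, TranscriptError) as exc:
            raise TranscriptError(f"{path}, line {line_no}: {exc}") from exc
        words.append(word)

    onsets = [w.onset for w in words]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise TranscriptError(f"{path}: onsets are not sorted")
    return Transcript(role=role, words=words, direction=direction)


class FrequencyTable:
    """Lemma -> absolute corpus frequency map with min-max log scaling.

    Stands in for a live corpus lookup: each lemma maps to its absolute count
    in a reference corpus, and ``weight`` returns the min-max normalized log
    frequency in [0, 1]. Out-of-vocabulary lemmas get the floor frequency
    F_min (maximum unfamiliarity) with a logged warning.
    """

    def __init__(self, entries: dict[str, int]):
        if not entries:
            raise ValueError("empty frequency table")
        bad = {k: v for k, v in entries.items() if v < 1}
        if bad:
            raise ValueError(f"frequencies must be >= 1, got {sorted(bad)[:5]}")
        self.entries = dict(entries)
        self.f_min = min(self.entries.values())
        self.f_max = max(self.entries.values())
        if self.f_min == self.f_max:
            raise DegenerateTableError("all frequencies equal; min-max scaling undefined")
        self._oov_seen = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries

    def frequency(self, lemma: str) -> int:
        """Absolute frequency; OOV lemmas fall back to F_min with a warning."""
        try:
            return self.entries[lemma]
        except KeyError:
            self._oov_seen += 1
            if self._oov_seen <= 5:
                logger.warning("OOV lemma %r assigned floor frequency F_min=%d", lemma, self.f_min)
            return self.f_min

    @property
    def n_oov_lookups(self) -> int:
        return self._oov_seen

    def weight(self, lemma: str) -> float:
        """Min-max normalized log frequency of ``lemma`` in [0, 1]."""
        return normalized_log_frequency(self.frequency(lemma), self.f_min, self.f_max)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        frame = pd.read_csv(path, sep="\t", dtype={"lemma": str, "abs_freq": int})
        if not {"lemma", "abs_freq"} <= set(frame.columns):
            raise ValueError(f"{path}: expected columns lemma, abs_freq")
        return cls(dict(zip(frame["lemma"], frame["abs_freq"])))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame = pd.DataFrame(
            {"lemma": list(self.entries), "abs_freq": list(self.entries.values())}
        )
        frame.to_csv(path, sep="\t", index=False)
        return path


def shifted(transcript: Transcript, dt: float) -> Transcript:
    """Time-shift every word by ``dt`` seconds (convenience for tests/demos)."""
    words = [replace(w, onset=w.onset + dt, offset=w.offset + dt) for w in transcript.words]
    return Transcript(role=transcript.role, words=words, direction=transcript.direction)
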