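"""Shared fixtures: toy transcripts and small simulation configs."""

import numpy as np
import pytest

from siprobe import SimConfig, Transcript, TimedWord


def word(surface, onset, offset, align_id=None, language="en",
         word_class=None, lemma=None):
    """Terse TimedWord builder for toy transcripts."""
    from siprobe.lexical import classify_word

    lemma = lemma if lemma is not None else surface
    if word_class is None:
        word_class = classify_word(surface, language)
    return TimedWord(surface, lemma, language, onset, offset, word_class, align_id)


@pytest.fixture
def toy_pair():
    """Six-word source with interleaved clears; content and function words."""
    source = Transcript(
        role="source",
        words=[
            word("peace", 0.0, 0.5, align_id=0),
            word("the", 0.6, 0.9, align_id=1),
            word("treaty", 1.0, 1.5, align_id=2),
            word("and", 1.6, 1.9, align_id=3),
            word("security", 2.0, 2.6, align_id=4),
            word("council", 2.7, 3.3, align_id=5),
        ],
    )
    target = Transcript(
        role="target",
        words=[
            word("мир", 1.2, 1.8, align_id=0, language="ru"),
            word("договор", 2.2, 2.9, align_id=2, language="ru"),
            word("и", 3.0, 3.2, align_id=3, language="ru"),
            word("совет", 3.4, 4.0, align_id=5, language="ru"),
            word("безопасности", 4.1, 5.0, align_id=4, language="ru"),
        ],
    )
    return source, target


@pytest.fixture
def small_cfg():
    """Short session, few channels: fast but structurally complete."""
    return SimConfig(
        seed=11,
        session_duration_s=60.0,
        channels=("Fz", "Cz", "Pz", "TP9", "TP10"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
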