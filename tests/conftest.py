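import numpy as np
import pytest

from mealvoice.audio_io import AudioClip
from mealvoice.labels import (
    BLANK_SYMBOL,
    StrongLabelTrack,
    Vocabulary,
    WeakLabelSeq,
    make_token,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_vocab():
    return Vocabulary([BLANK_SYMBOL, "a", "b", "#", "$"])


@pytest.fixture
def sine_clip():
    """1 s, 1 kHz sinusoid at 16 kHz."""
    t = np.arange(16000) / 16000
    return AudioClip(0.5 * np.sin(2 * np.pi * 1000 * t), 16000, "sine1k")


@pytest.fixture
def chew_track():
    return StrongLabelTrack(
        [
            (0.1, 0.3, make_token("#")),
            (0.5, 0.6, make_token("#")),
            (1.0, 1.4, make_token("$")),
        ],
        clip_id="t",
    )


def random_posteriorgram(rng, T, V):
    """Row-normalized random log-probability matrix."""
    logits = rng.normal(0, 1.5, size=(T, V))
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return logp


@pytest.fixture
def make_posteriorgram(rng):
    from mealvoice.ctc_core import Posteriorgram

    def _make(T, V):
        return Posteriorgram(random_posteriorgram(rng, T, V))

    return _make
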