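"""Toy audio world: a stand-in for the private speech and eating corpora.

All fixtures here are synthetic. "Speech" is a fixed vocabulary of tone
bursts — each symbol a distinct carrier frequency — so transcripts are
variable-length sequences that a CTC model must align, yet learnable on a
CPU in minutes. "Eating" clips contain quasi-periodic broadband chew clicks
and longer band-limited swallow bursts with exact strong labels, mirroring
the qualitative structure of skin-contact-microphone recordings (a chew
train followed by a swallow). Carriers sit above the 100 Hz high-pass so
front-end conditioning leaves the toy signals intact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .audio_io import AudioClip
from .labels import (
    CHEW,
    SWALLOW,
    StrongLabelTrack,
    WeakLabelSeq,
    make_token,
    weak_from_strong,
)

DEFAULT_VOCAB = ("a", "b", "c", "d", "e", "f", "g", "h")


@dataclass
class ToySpec:
    """Parameters of the toy world.

    tone_map assigns each speech symbol a carrier (Hz), all distinct,
    between 200 Hz and Nyquist. Chews are ``chew_click_ms`` broadband
    clicks at ``chew_rate_hz``; swallows are ``swallow_burst_ms``
    band-limited noise bursts.
    """

    sample_rate: int = 16000
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    tone_map: dict[str, float] | None = None
    tone_ms: float = 120.0
    tone_gap_ms: float = 60.0
    chew_rate_hz: float = 1.5
    chew_click_ms: float = 30.0
    swallow_burst_ms: float = 400.0
    swallow_band_hz: tuple[float, float] = (300.0, 700.0)
    noise_floor_db: float = 40.0  # dB below unit peak
    n_speech: int = 20
    n_eating: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tone_map is None:
            nyq = self.sample_rate / 2
            freqs = np.geomspace(280.0, min(2400.0, 0.85 * nyq), len(self.vocab))
            self.tone_map = {s: float(f) for s, f in zip(self.vocab, freqs)}
        vals = list(self.tone_map.values())
        if len(set(vals)) != len(vals):
            raise ValueError("carrier frequencies must be distinct")
        if any(not (200.0 < f < self.sample_rate / 2) for f in vals):
            raise ValueError("carriers must lie in (200 Hz, Nyquist)")

    @property
    def noise_sigma(self) -> float:
        return 10.0 ** (-self.noise_floor_db / 20.0)


def _stable_seed(seed: int, tag: str, items, dur_s: float) -> int:
    """Process-independent derived seed (crc32, not Python's salted hash)."""
    key = f"{seed}|{tag}|{','.join(map(str, items))}|{dur_s:.6f}"
    return zlib.crc32(key.encode()) % (2 ** 31)


def _envelope(n: int, edge: int) -> np.ndarray:
    env = np.ones(n)
    ramp = np.linspace(0.0, 1.0, max(edge, 2))
    env[: len(ramp)] = ramp
    env[-len(ramp):] = ramp[::-1]
    return env


def gen_speech_clip(
    spec: ToySpec, transcript: list[str], dur_s: float
) -> tuple[AudioClip, WeakLabelSeq]:
    """Render a transcript as tone bursts over a low noise floor."""
    for s in transcript:
        if s not in spec.tone_map:
            raise ValueError(f"token {s!r} outside the toy vocabulary")
    if dur_s >= 10.0:
        raise ValueError("toy clips are kept under 10 s")
    rate = spec.sample_rate
    rng = np.random.default_rng(_stable_seed(spec.seed, "speech", transcript, dur_s))
    n = int(round(dur_s * rate))
    wave = rng.normal(0.0, spec.noise_sigma, n)
    n_tone = int(round(spec.tone_ms / 1000 * rate))
    n_gap = int(round(spec.tone_gap_ms / 1000 * rate))
    need = len(transcript) * (n_tone + n_gap)
    if need > n:
        raise ValueError("transcript does not fit in the requested duration")
    pos = int(rng.integers(0, n - need + 1)) if n > need else 0
    t = np.arange(n_tone) / rate
    env = _envelope(n_tone, int(0.005 * rate))
    for sym in transcript:
        tone = 0.8 * env * np.sin(2 * np.pi * spec.tone_map[sym] * t)
        wave[pos : pos + n_tone] += tone
        pos += n_tone + n_gap
    clip = AudioClip(wave, rate, source_id=f"toyspeech:{''.join(transcript)}")
    weak = WeakLabelSeq([make_token(s) for s in transcript], clip_id=clip.source_id)
    return clip, weak


def gen_eating_clip(
    spec: ToySpec, n_chews: int, n_swallows: int, dur_s: float, seed: int | None = None
) -> tuple[AudioClip, StrongLabelTrack]:
    """Render a chew train (with onset jitter) followed by swallow bursts."""
    rate = spec.sample_rate
    rng = np.random.default_rng(
        seed if seed is not None
        else _stable_seed(spec.seed, "eating", [n_chews, n_swallows], dur_s)
    )
    n = int(round(dur_s * rate))
    chew_len = spec.chew_click_ms / 1000
    swallow_len = spec.swallow_burst_ms / 1000
    period = 1.0 / spec.chew_rate_hz
    need = n_chews * period + n_swallows * (swallow_len + 0.5)
    if need > dur_s:
        raise ValueError("events do not fit at the configured chew rate")
    wave = rng.normal(0.0, spec.noise_sigma, n)
    entries = []
    t0 = rng.uniform(0.05, max(0.06, dur_s - need))
    # chew train: quasi-periodic clicks, +-10% period jitter
    for i in range(n_chews):
        onset = t0 + i * period + rng.uniform(-0.1, 0.1) * period
        onset = min(max(onset, 0.0), dur_s - chew_len - 1e-3)
        i0 = int(round(onset * rate))
        n_click = int(round(chew_len * rate))
        click = rng.normal(0.0, 1.0, n_click) * _envelope(n_click, max(2, n_click // 6))
        wave[i0 : i0 + n_click] += 0.9 * click / max(1e-9, np.abs(click).max())
        entries.append((i0 / rate, i0 / rate + chew_len, CHEW))
    # swallow bursts after the chew train
    s_start = t0 + n_chews * period + 0.1
    for j in range(n_swallows):
        onset = min(s_start + j * (swallow_len + 0.5), dur_s - swallow_len - 1e-3)
        i0 = int(round(onset * rate))
        n_b = int(round(swallow_len * rate))
        noise = rng.normal(0.0, 1.0, n_b)
        spectrum = np.fft.rfft(noise)
        freqs = np.fft.rfftfreq(n_b, d=1.0 / rate)
        lo, hi = spec.swallow_band_hz
        spectrum[(freqs < lo) | (freqs > hi)] = 0.0
        burst = np.fft.irfft(spectrum, n=n_b)
        burst = burst / max(1e-9, np.abs(burst).max()) * _envelope(n_b, n_b // 8)
        wave[i0 : i0 + n_b] += 0.8 * burst
        entries.append((i0 / rate, i0 / rate + swallow_len, SWALLOW))
    clip = AudioClip(wave, rate, source_id=f"toyeat:{n_chews}c{n_swallows}s")
    track = StrongLabelTrack(entries, clip_id=clip.source_id)
    return clip, track


@dataclass
class ToyDataset:
    """Pools of toy source material plus held-out test clips."""

    speech_pool: list  # (AudioClip, WeakLabelSeq)
    eating_pool: list  # (AudioClip, StrongLabelTrack)
    speech_test: list
    eating_test: list


def gen_toy_dataset(spec: ToySpec) -> ToyDataset:
    """Generate training pools and a disjoint test split.

    Durations are stratified so both synthesis branches are exercised: some
    clips land in [7, 10) s (padding path) and some under 7 s
    (concatenation path). Test clips come from a disjoint seed group,
    emulating held-out subjects.
    """
    if spec.n_speech < 4 or spec.n_eating < 4:
        raise ValueError("need at least 4 clips per pool")
    rng = np.random.default_rng(spec.seed)

    def speech_batch(count: int, salt: int) -> list:
        out = []
        for i in range(count):
            # stratified: every third clip long enough for the pad branch
            if i % 3 == 0:
                dur = rng.uniform(7.2, 9.5)
            else:
                dur = rng.uniform(1.5, 5.5)
            max_tokens = int((dur - 0.3) / ((spec.tone_ms + spec.tone_gap_ms) / 1000))
            length = int(rng.integers(2, max(3, min(12, max_tokens)) + 1))
            transcript = [spec.vocab[k] for k in rng.integers(0, len(spec.vocab), length)]
            sub = ToySpec(**{**spec.__dict__, "seed": spec.seed * 1000 + salt * 100 + i})
            clip, weak = gen_speech_clip(sub, transcript, dur)
            clip.source_id = f"{clip.source_id}:{salt}-{i}"
            weak.clip_id = clip.source_id
            out.append((clip, weak))
        return out

    def eating_batch(count: int, salt: int) -> list:
        out = []
        for i in range(count):
            if i % 3 == 0:
                dur = rng.uniform(7.2, 9.5)
            else:
                dur = rng.uniform(2.5, 6.5)
            # leave room for at least one swallow in most clips (chew trains
            # ending in a swallow mirror real mastication sequences)
            max_chews = int((dur - 2.0) * spec.chew_rate_hz)
            n_chews = int(rng.integers(1, max(2, max_chews) + 1))
            room = dur - n_chews / spec.chew_rate_hz - 0.4
            n_swallows = min(2, int(room / 1.1)) if room > 1.1 else 0
            if n_swallows > 1 and rng.random() < 0.5:
                n_swallows = 1
            clip, track = gen_eating_clip(
                spec, n_chews, n_swallows, dur,
                seed=(spec.seed * 1000 + salt * 100 + i) % (2 ** 31),
            )
            clip.source_id = f"{clip.source_id}:{salt}-{i}"
            track.clip_id = clip.source_id
            out.append((clip, track))
        return out

    return ToyDataset(
        speech_pool=speech_batch(spec.n_speech, salt=1),
        eating_pool=eating_batch(spec.n_eating, salt=2),
        speech_test=speech_batch(max(4, spec.n_speech // 4), salt=7),
        eating_test=eating_batch(max(4, spec.n_eating // 4), salt=8),
    )


def bayes_detector(
    clip: AudioClip, spec: ToySpec
) -> list[tuple[str, float, float]]:
    """Hand-coded oracle detector for toy eating events.

    Chews: short-time broadband high-frequency energy peaks; swallows:
    sustained energy in the swallow band. Establishes that the toy task is
    solvable and the strong labels are placed correctly.
    """
    from scipy import signal as sp_signal

    rate = clip.sample_rate
    x = clip.mono()
    nyq = rate / 2
    lo, hi = spec.swallow_band_hz
    # chew detector: energy above the swallow band (clicks are broadband)
    b_hi = sp_signal.butter(4, min(hi * 1.6, 0.9 * nyq), btype="highpass", fs=rate, output="sos")
    chew_env = np.abs(sp_signal.sosfiltfilt(b_hi, x))
    win = max(1, int(0.01 * rate))
    kernel = np.ones(win) / win
    chew_env = np.convolve(chew_env, kernel, mode="same")
    thresh = 6.0 * np.median(chew_env) + 1e-6
    events: list[tuple[str, float, float]] = []
    above = chew_env > thresh
    segs = []
    i = 0
    while i < len(x):
        if above[i]:
            j = i
            while j < len(x) and above[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    for i0, j0 in segs:
        if (j0 - i0) / rate < 0.005:
            continue
        if (j0 - i0) / rate < 0.1:  # clicks are short
            events.append(("chew", i0 / rate, j0 / rate))
    # swallow detector: band energy sustained ~ burst length
    b_band = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    sw_env = np.convolve(
        np.abs(sp_signal.sosfiltfilt(b_band, x)),
        np.ones(int(0.05 * rate)) / int(0.05 * rate),
        mode="same",
    )
    sw_thresh = 6.0 * np.median(sw_env) + 1e-6
    above = sw_env > sw_thresh
    i = 0
    while i < len(x):
        if above[i]:
            j = i
            while j < len(x) and above[j]:
                j += 1
            if (j - i) / rate > 0.15:
                events.append(("swallow", i / rate, j / rate))
            i = j
        else:
            i += 1
    return sorted(events, key=lambda e: e[1])
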