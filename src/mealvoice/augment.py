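"""Acoustic augmentation and label-initiated segmentation (LISA).

Three waveform augmentations are used on both corpora: speed modulation via
the sampling-rate trick, time-domain dropout (zeroing a random interval), and
frequency-domain dropout (masking random bands). LISA expands long eating
recordings into up-to-10 s windows, one starting at each label onset, which
counteracts the dominance of long chew runs in the raw recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio_io import AudioClip
from .labels import StrongLabelTrack


@dataclass
class AugmentSpec:
    """Parameters for the seeded augmentations.

    speed_factors : candidate playback-speed multipliers
    time_dropout_max_s : maximum total zeroed duration (one interval drawn)
    freq_dropout_bands : number of masked bands (each <= 1 kHz wide)
    """

    speed_factors: tuple[float, ...] = (0.9, 1.0, 1.1)
    time_dropout_max_s: float = 0.2
    freq_dropout_bands: int = 1
    freq_band_max_hz: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.speed_factors):
            raise ValueError("speed factors must be positive")
        if self.time_dropout_max_s < 0 or self.freq_dropout_bands < 0:
            raise ValueError("dropout amounts must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def speed_perturb(clip: AudioClip, factor: float) -> AudioClip:
    """Change playback speed by ``factor`` via resampling; rate label unchanged.

    Output duration is the input duration divided by ``factor`` (within one
    sample). Strong-label times on the perturbed clip scale by 1/factor.
    """
    if factor <= 0:
        raise ValueError("speed factor must be positive")
    if factor == 1.0:
        return AudioClip(clip.samples.copy(), clip.sample_rate, clip.source_id)
    n_out = int(round(clip.n_samples / factor))
    # Rational approximation of 1/factor keeps the polyphase filter exact.
    from fractions import Fraction

    frac = Fraction(factor).limit_denominator(1000)
    out = signal.resample_poly(clip.samples, frac.denominator, frac.numerator, axis=-1)
    if out.shape[-1] > n_out:
        out = out[..., :n_out]
    elif out.shape[-1] < n_out:
        out = np.pad(out, [(0, 0)] * (out.ndim - 1) + [(0, n_out - out.shape[-1])])
    return AudioClip(out, clip.sample_rate, clip.source_id)


def scale_track_for_speed(track: StrongLabelTrack, factor: float) -> StrongLabelTrack:
    """Rescale strong-label times after :func:`speed_perturb` by 1/factor."""
    return StrongLabelTrack(
        [(s / factor, e / factor, tok) for s, e, tok in track.entries],
        clip_id=track.clip_id,
    )


def time_dropout(clip: AudioClip, spec: AugmentSpec) -> AudioClip:
    """Zero one random interval of duration uniform in [0, max]; length preserved."""
    if spec.time_dropout_max_s == 0:
        return AudioClip(clip.samples.copy(), clip.sample_rate, clip.source_id)
    if spec.time_dropout_max_s >= clip.duration_s:
        raise ValueError("max dropout must be shorter than the clip")
    rng = spec.rng()
    n_drop = int(round(rng.uniform(0, spec.time_dropout_max_s) * clip.sample_rate))
    out = clip.samples.copy()
    if n_drop > 0:
        start = int(rng.integers(0, clip.n_samples - n_drop + 1))
        out[..., start : start + n_drop] = 0.0
    return AudioClip(out, clip.sample_rate, clip.source_id)


def freq_dropout(clip: AudioClip, spec: AugmentSpec, bands_hz: list[tuple[float, float]] | None = None) -> AudioClip:
    """Mask random frequency bands by zeroing rFFT bins; length preserved.

    ``bands_hz`` overrides the random draw with explicit (low, high) bands.
    """
    if bands_hz is None:
        if spec.freq_dropout_bands == 0:
            return AudioClip(clip.samples.copy(), clip.sample_rate, clip.source_id)
        rng = spec.rng()
        nyquist = clip.sample_rate / 2
        bands_hz = []
        for _ in range(spec.freq_dropout_bands):
            width = rng.uniform(0, min(spec.freq_band_max_hz, nyquist / 2))
            low = rng.uniform(0, nyquist - width)
            bands_hz.append((low, low + width))
    if not bands_hz:
        return AudioClip(clip.samples.copy(), clip.sample_rate, clip.source_id)
    spectrum = np.fft.rfft(clip.samples, axis=-1)
    freqs = np.fft.rfftfreq(clip.n_samples, d=1.0 / clip.sample_rate)
    for low, high in bands_hz:
        spectrum[..., (freqs >= low) & (freqs <= high)] = 0.0
    out = np.fft.irfft(spectrum, n=clip.n_samples, axis=-1)
    return AudioClip(out, clip.sample_rate, clip.source_id)


def lisa_split(
    clip: AudioClip,
    track: StrongLabelTrack,
    max_dur_s: float = 10.0,
) -> list[tuple[AudioClip, StrongLabelTrack]]:
    """Label-initiated segmentation: one window per label entry.

    Window ``i`` starts at entry ``i``'s onset and extends ``max_dur_s`` or to
    the end of the clip. Each returned track holds the source entries that lie
    fully inside the window, re-based so the window starts at time 0. Entries
    cut by the right edge are excluded.
    """
    if len(track) == 0:
        raise ValueError("lisa_split requires a non-empty label track")
    if any(e > clip.duration_s + 1e-9 for _, e, _ in track.entries):
        raise ValueError("label entries extend past the clip")
    segments: list[tuple[AudioClip, StrongLabelTrack]] = []
    rate = clip.sample_rate
    for i, (start, _, _) in enumerate(track.entries):
        win_start = start
        win_end = min(start + max_dur_s, clip.duration_s)
        i0 = int(round(win_start * rate))
        i1 = int(round(win_end * rate))
        seg = AudioClip(
            clip.samples[..., i0:i1], rate, source_id=f"{clip.source_id}:lisa{i}"
        )
        inside = [
            (s - win_start, e - win_start, tok)
            for s, e, tok in track.entries
            if s >= win_start - 1e-9 and e <= win_end + 1e-9
        ]
        segments.append(
            (seg, StrongLabelTrack(inside, clip_id=f"{track.clip_id}:lisa{i}"))
        )
    return segments
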