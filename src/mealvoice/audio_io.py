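"""WAV ingestion and front-end signal conditioning.

Skin-contact (throat) microphones pick up blood-flow vibration below roughly
100 Hz, so the standard front end is a 100 Hz high-pass, downsampling of the
44.1 kHz recordings to a 16 kHz working rate, summation of the microphone
channels into a single input, and peak normalization of the raw waveform.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile


@dataclass
class AudioClip:
    """A sampled waveform.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Float samples in [-1, 1]. Mono clips still carry a leading axis of 1.
    sample_rate : int
        Sampling rate in Hz.
    source_id : str
        Opaque provenance identifier.
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError("samples must be 1-D or (n_channels, n_samples)")
        if arr.shape[1] < 1:
            raise ValueError("clip must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = arr
        self.sample_rate = int(self.sample_rate)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def mono(self) -> np.ndarray:
        """Return the (first-channel) 1-D sample view; requires a mono clip."""
        if self.n_channels != 1:
            raise ValueError(f"clip {self.source_id!r} is not mono")
        return self.samples[0]


_PCM_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31}


def read_wav(path: str | os.PathLike) -> AudioClip:
    """Read a PCM or float WAV file into an :class:`AudioClip`.

    Integer PCM is mapped to floats in [-1, 1] by dividing by the type's
    full-scale magnitude (32768 for 16-bit).
    """
    path = os.fspath(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header, truncated chunk, ...
        raise IOError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path!r}")
    if samples.ndim == 2:  # scipy returns (n_samples, n_channels)
        samples = samples.T
    return AudioClip(samples, rate, source_id=os.path.basename(path))


def write_wav(path: str | os.PathLike, clip: AudioClip, dtype: str = "int16") -> None:
    """Write a clip as PCM WAV (``int16``, default) or ``float32``."""
    data = clip.samples.T if clip.n_channels > 1 else clip.samples[0]
    if dtype == "int16":
        scaled = np.clip(np.round(data * 32767.0), -32768, 32767).astype(np.int16)
        wavfile.write(os.fspath(path), clip.sample_rate, scaled)
    elif dtype == "float32":
        wavfile.write(os.fspath(path), clip.sample_rate, data.astype(np.float32))
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")


def peak_normalize(samples: np.ndarray) -> np.ndarray:
    """Scale so max |sample| = 1; silent input is returned untouched."""
    peak = np.max(np.abs(samples))
    if peak == 0.0:
        return samples
    return samples / peak


def highpass(samples: np.ndarray, sample_rate: int, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass along the last axis.

    Forward-backward filtering keeps chew transients phase-aligned with their
    strong labels (a causal filter would delay them).
    """
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, samples, axis=-1)


def resample(samples: np.ndarray, sample_rate: int, target_rate: int) -> np.ndarray:
    """Polyphase rational resampling (160/441 for 44.1 kHz -> 16 kHz)."""
    if target_rate == sample_rate:
        return samples
    from math import gcd

    g = gcd(target_rate, sample_rate)
    return signal.resample_poly(samples, target_rate // g, sample_rate // g, axis=-1)


def preprocess(
    clip: AudioClip,
    cutoff_hz: float = 100.0,
    target_rate: int = 16000,
) -> AudioClip:
    """High-pass at ``cutoff_hz``, downsample to ``target_rate``, peak-normalize.

    Raises
    ------
    ValueError
        If ``target_rate`` exceeds the source rate (no upsampling) or the
        source rate cannot represent the cutoff.
    """
    if target_rate > clip.sample_rate:
        raise ValueError(
            f"target rate {target_rate} Hz exceeds source rate {clip.sample_rate} Hz"
        )
    if clip.sample_rate < 2 * cutoff_hz:
        raise ValueError("sample rate too low for the requested cutoff")
    filtered = highpass(clip.samples, clip.sample_rate, cutoff_hz)
    resampled = resample(filtered, clip.sample_rate, target_rate)
    return AudioClip(peak_normalize(resampled), target_rate, source_id=clip.source_id)


def sum_channels(clip: AudioClip) -> AudioClip:
    """Sum all channels into one, then peak-renormalize (silence passes through)."""
    summed = clip.samples.sum(axis=0, keepdims=True)
    return AudioClip(peak_normalize(summed), clip.sample_rate, source_id=clip.source_id)
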