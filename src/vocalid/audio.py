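"""WAV clip I/O and the additive mixing primitive used by both augmentation schemes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

TARGET_RATE = 44100


@dataclass
class AudioClip:
    """A mono waveform: float samples in [-1, 1] plus a sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def read_audio(path: str | Path) -> AudioClip:
    """Read a PCM WAV file as a mono clip.

    Multichannel audio is averaged down to mono.  Files not at 44.1 kHz are
    resampled to 44.1 kHz (polyphase) with a logged warning, so every clip in
    a session shares one rate.
    """
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise ValueError(f"could not read WAV file {path}: {exc}") from None
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:  # float WAV
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    if rate != TARGET_RATE:
        logger.warning("resampling %s from %d Hz to %d Hz", path, rate, TARGET_RATE)
        g = np.gcd(int(rate), TARGET_RATE)
        samples = resample_poly(samples, TARGET_RATE // g, int(rate) // g)
        rate = TARGET_RATE
    return AudioClip(samples, int(rate))


def write_audio(clip: AudioClip, path: str | Path) -> Path:
    """Write a clip as 16-bit PCM WAV.  Samples must already lie in [-1, 1]."""
    peak = float(np.max(np.abs(clip.samples))) if clip.n else 0.0
    if peak > 1.0 + 1e-12:
        raise ValueError(
            f"samples out of range for 16-bit PCM (peak {peak:.4f}); normalize first"
        )
    pcm = np.round(np.clip(clip.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(str(path), clip.sample_rate, pcm)
    return Path(path)


def mix_additive(
    fg: AudioClip, bg: AudioClip, rng: np.random.Generator | None = None
) -> AudioClip:
    """Additively mix a background clip under a foreground clip.

    Each input is scaled by 1/2 before summation, so the output can never
    clip.  The output length equals the foreground length: a longer background
    contributes a uniformly random contiguous crop, a shorter one is tiled.
    """
    if fg.sample_rate != bg.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: {fg.sample_rate} vs {bg.sample_rate}"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    n = fg.n
    b = bg.samples
    if bg.n > n:
        off = int(rng.integers(0, bg.n - n + 1))
        b = b[off : off + n]
    elif bg.n < n:
        reps = -(-n // bg.n)
        b = np.tile(b, reps)[:n]
    return AudioClip(0.5 * fg.samples + 0.5 * b, fg.sample_rate)
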