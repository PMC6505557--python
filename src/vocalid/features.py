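"""Mel spectrograms, median-filter noise reduction and fixed-length summaries.

The spectral front end follows the common bioacoustic recipe: 1024-sample
frames (about 23 ms at 44.1 kHz) with Hamming windows and 50% overlap, the
magnitude spectrum mapped through a 40-filter mel-scale filterbank spanning
0 Hz to Nyquist.  Noise reduction subtracts each band's median over time and
half-wave rectifies — the median is a robust estimate of a stationary noise
floor, so steady background energy is removed while transient vocal energy
survives.

Conventions (implementations of the mel dialect differ, so ours is pinned
here): HTK mel scale ``m = 2595 log10(1 + f/700)``; triangular filters
area-normalized Slaney-style (each filter scaled by 2 / its bandwidth in Hz);
magnitude (not power) energies with no log compression by default — an
optional ``log1p`` switch is available where features are assembled.  Frames
are fully contained in the clip; no zero padding of a final partial frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .audio import AudioClip

FRAME_LENGTH = 1024
HOP = 512
N_MELS = 40


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    sample_rate: int, n_fft: int = FRAME_LENGTH, n_mels: int = N_MELS
) -> np.ndarray:
    """Triangular mel filterbank, shape ``(n_mels, n_fft // 2 + 1)``."""
    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(nyquist), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    fft_freqs = np.linspace(0.0, nyquist, n_fft // 2 + 1)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        rising = (fft_freqs - lo) / (ctr - lo)
        falling = (hi - fft_freqs) / (hi - ctr)
        fb[i] = np.maximum(0.0, np.minimum(rising, falling))
        fb[i] *= 2.0 / (hi - lo)  # area normalization
    return fb


@dataclass
class MelSpectrogram:
    """Nonnegative T x B matrix of mel-band magnitudes over time."""

    values: np.ndarray  # (T, B)
    sample_rate: int
    frame_length: int = FRAME_LENGTH
    hop: int = HOP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (frames x bands)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def frame_count(n_samples: int, frame_length: int = FRAME_LENGTH, hop: int = HOP) -> int:
    if n_samples < frame_length:
        raise ValueError(f"clip of {n_samples} samples is shorter than one frame")
    return (n_samples - frame_length) // hop + 1


def mel_spectrogram(
    clip: AudioClip,
    n_mels: int = N_MELS,
    frame_length: int = FRAME_LENGTH,
    hop: int = HOP,
) -> MelSpectrogram:
    """Magnitude mel spectrogram of a clip (Hamming window, 50% overlap)."""
    n = clip.n
    frame_count(n, frame_length, hop)  # validates length
    frames = sliding_window_view(clip.samples, frame_length)[::hop]
    window = np.hamming(frame_length)
    spectra = np.abs(np.fft.rfft(frames * window, axis=1))
    fb = mel_filterbank(clip.sample_rate, frame_length, n_mels)
    return MelSpectrogram(spectra @ fb.T, clip.sample_rate, frame_length, hop)


def median_noise_reduce(spec: MelSpectrogram) -> MelSpectrogram:
    """Subtract each band's median over time; clamp negatives to zero."""
    if spec.n_frames < 1:
        raise ValueError("empty spectrogram")
    med = np.median(spec.values, axis=0, keepdims=True)
    return MelSpectrogram(
        np.maximum(spec.values - med, 0.0), spec.sample_rate, spec.frame_length, spec.hop
    )


def summarize_features(series: np.ndarray) -> np.ndarray:
    """Collapse a T x F time series to per-dimension mean then population SD.

    This turns variable-length feature sequences into fixed-length vectors of
    size 2F, the representation the classifier consumes.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2 or series.shape[0] < 1:
        raise ValueError("series must be a non-empty T x F matrix")
    return np.concatenate([series.mean(axis=0), series.std(axis=0)])
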