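"""Synthetic soundscape generator for individual-identification experiments.

Real datasets for acoustic individual ID have two entangled layers: each
individual's *vocal signature* (what the animal itself sounds like) and its
*territory soundscape* (the habitat heard behind it — which, for territorial
animals, is also individually distinctive and therefore a potential
confound).  This module fabricates both layers with independent dials:

``signature_strength`` (s)
    0 — every individual draws vocalizations from one shared repertoire
    (no identity information in the voice); 1 — fully individual-specific
    syllable parameters.
``confound_strength`` (c)
    0 — one shared background parameterization for everyone (no identity
    information in the habitat); 1 — fully individual-specific backgrounds.

Foreground clips are a rendered vocalization mixed into the *same
individual's own* background at a configured SNR, reproducing the
foreground–background correlation that makes territory cues a confound.
Background clips contain the background layer alone.

Vocalizations are sequences of frequency-modulated tone syllables drawn from
a per-individual repertoire; backgrounds are spectrally tilted noise plus
persistent narrowband habitat tones and Poisson-timed transient chirps
centred on individual-specific frequencies.  The transient chirps carry most
of the background's identity information deliberately: steady tones are
largely removed by per-band median noise reduction downstream, whereas sparse
transients (well under half of the frames) survive it, so the confound dial
stays effective through the standard front end.

Everything is reproducible: all draws descend from a single seed via spawned
generator streams, and rerunning with the same config yields byte-identical
WAV files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import AudioClip, write_audio
from .manifest import ClipRecord, Dataset, Role, save_manifest

# Background layer is rendered at this RMS; the vocal layer is scaled above it
# by snr_db.  Chosen to leave ample 16-bit headroom after summation.
BACKGROUND_RMS = 0.04

# Season start for date assignment within each configured year.
_SEASON_START = (4, 1)  # April 1


@dataclass(frozen=True)
class Syllable:
    """A single FM tone: base frequency (Hz), sweep rate (Hz/s), duration (s)."""

    base_freq: float
    sweep_rate: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("syllable duration must be positive")
        if self.base_freq <= 0:
            raise ValueError("syllable base frequency must be positive")


@dataclass
class SynthConfig:
    K: int = 8
    clips_per_individual_fg: int = 20
    clips_per_individual_bg: int = 20
    clip_seconds: float = 2.0
    sample_rate: int = 44100
    signature_strength: float = 1.0
    confound_strength: float = 1.0
    snr_db: float = 10.0
    years: tuple[int, ...] = (2013,)
    drift: float = 0.0
    repertoire_size: int = 5
    n_habitat_tones: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signature_strength", "confound_strength", "drift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.clip_seconds <= 0:
            raise ValueError("clip_seconds must be positive")
        if self.K < 2:
            raise ValueError("need at least 2 individuals")
        if not self.years:
            raise ValueError("years must be non-empty")
        self.years = tuple(int(y) for y in self.years)


@dataclass
class BackgroundParams:
    """Territory soundscape parameters for one individual."""

    tilt: float  # spectral tilt exponent, energy ~ (f/1 kHz)^tilt
    habitat_tones: tuple[float, ...]  # persistent narrowband tone centres, Hz
    event_rate: float  # transient chirps per second


@dataclass
class IndividualProfile:
    individual: str
    repertoire_by_year: dict[int, list[Syllable]]
    background: BackgroundParams

    def __post_init__(self) -> None:
        for year, rep in self.repertoire_by_year.items():
            if not rep:
                raise ValueError(f"empty repertoire for year {year}")

    def repertoire(self, year: int | None = None) -> list[Syllable]:
        if year is None:
            year = min(self.repertoire_by_year)
        return self.repertoire_by_year[year]


def _draw_syllable(rng: np.random.Generator, nyquist: float) -> Syllable:
    f0 = float(rng.uniform(2000.0, 7000.0))
    sweep = float(rng.uniform(-40000.0, 40000.0))
    dur = float(rng.uniform(0.08, 0.18))
    # keep the sweep inside the band
    end = f0 + sweep * dur
    if end <= 200.0 or end >= nyquist - 200.0:
        sweep = (np.clip(end, 300.0, nyquist - 300.0) - f0) / dur
    return Syllable(f0, sweep, dur)


def _draw_background(rng: np.random.Generator, cfg: SynthConfig) -> BackgroundParams:
    tones = tuple(sorted(float(f) for f in rng.uniform(1000.0, 8000.0, cfg.n_habitat_tones)))
    return BackgroundParams(
        tilt=float(rng.uniform(-0.8, 0.2)),
        habitat_tones=tones,
        event_rate=float(rng.uniform(2.0, 6.0)),
    )


def _lerp(a: float, b: float, t: float) -> float:
    return (1.0 - t) * a + t * b


def build_profiles(cfg: SynthConfig, rng: np.random.Generator | None = None) -> list[IndividualProfile]:
    """Draw shared and per-individual parameters and blend them by s and c.

    With ``signature_strength == 0`` every individual's repertoire equals the
    shared one; with ``confound_strength == 0`` every background parameter set
    equals the shared one (directly assertable on the returned profiles).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    ny = cfg.sample_rate / 2.0
    s, c = cfg.signature_strength, cfg.confound_strength

    shared_rep = [_draw_syllable(rng, ny) for _ in range(cfg.repertoire_size)]
    shared_bg = _draw_background(rng, cfg)

    profiles = []
    for i in range(cfg.K):
        ind_rep = [_draw_syllable(rng, ny) for _ in range(cfg.repertoire_size)]
        base_rep = [
            Syllable(
                _lerp(sh.base_freq, ow.base_freq, s),
                _lerp(sh.sweep_rate, ow.sweep_rate, s),
                _lerp(sh.duration, ow.duration, s),
            )
            for sh, ow in zip(shared_rep, ind_rep)
        ]
        ind_bg = _draw_background(rng, cfg)
        bg = BackgroundParams(
            tilt=_lerp(shared_bg.tilt, ind_bg.tilt, c),
            habitat_tones=tuple(
                _lerp(a, b, c) for a, b in zip(shared_bg.habitat_tones, ind_bg.habitat_tones)
            ),
            event_rate=_lerp(shared_bg.event_rate, ind_bg.event_rate, c),
        )
        # repertoire drift across years: a fraction d of syllables is resampled
        rep_by_year: dict[int, list[Syllable]] = {}
        rep = base_rep
        for yi, year in enumerate(cfg.years):
            if yi > 0 and cfg.drift > 0:
                rep = [
                    _draw_syllable(rng, ny) if rng.random() < cfg.drift else syl
                    for syl in rep
                ]
            rep_by_year[year] = list(rep)
        profiles.append(
            IndividualProfile(
                individual=f"ind{i:02d}", repertoire_by_year=rep_by_year, background=bg
            )
        )
    return profiles


def _fm_tone(
    syl: Syllable, sample_rate: int, n_max: int
) -> np.ndarray:
    n = min(int(round(syl.duration * sample_rate)), n_max)
    if n <= 0:
        return np.zeros(0)
    t = np.arange(n) / sample_rate
    phase = 2.0 * np.pi * (syl.base_freq * t + 0.5 * syl.sweep_rate * t * t)
    return np.sin(phase) * np.hanning(n)


def render_vocalization(
    profile: IndividualProfile,
    cfg: SynthConfig,
    rng: np.random.Generator,
    year: int | None = None,
) -> AudioClip:
    """A clip_seconds sequence of FM syllables drawn from the repertoire.

    Syllables are separated by short random gaps; amplitude is nominal
    (unit-peak syllables) — SNR scaling happens at dataset assembly.
    """
    n = int(round(cfg.clip_seconds * cfg.sample_rate))
    out = np.zeros(n)
    rep = profile.repertoire(year)
    pos = int(rng.uniform(0.02, 0.08) * cfg.sample_rate)
    while pos < n - 64:
        syl = rep[int(rng.integers(len(rep)))]
        tone = _fm_tone(syl, cfg.sample_rate, n - pos)
        out[pos : pos + tone.size] += tone
        pos += tone.size + int(rng.uniform(0.04, 0.12) * cfg.sample_rate)
    return AudioClip(out, cfg.sample_rate)


def render_background(
    profile: IndividualProfile, cfg: SynthConfig, rng: np.random.Generator
) -> AudioClip:
    """Tilted broadband noise + habitat tones + Poisson transient chirps.

    Returned at unit RMS (callers scale to the session background level).
    """
    n = int(round(cfg.clip_seconds * cfg.sample_rate))
    bg = profile.background

    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.sample_rate)
    shape = (np.maximum(freqs, 20.0) / 1000.0) ** (bg.tilt / 2.0)  # amplitude tilt
    noise = np.fft.irfft(spectrum * shape, n)
    noise /= max(np.sqrt(np.mean(noise**2)), 1e-12)

    t = np.arange(n) / cfg.sample_rate
    tones = np.zeros(n)
    for f in bg.habitat_tones:
        tones += 0.08 * np.sin(2.0 * np.pi * f * t + rng.uniform(0.0, 2.0 * np.pi))

    chirps = np.zeros(n)
    n_events = int(rng.poisson(bg.event_rate * cfg.clip_seconds))
    for _ in range(n_events):
        centre = bg.habitat_tones[int(rng.integers(len(bg.habitat_tones)))] if bg.habitat_tones else 3000.0
        f = float(np.clip(rng.normal(centre, 150.0), 200.0, cfg.sample_rate / 2 - 200.0))
        dur = 0.05
        m = int(dur * cfg.sample_rate)
        start = int(rng.integers(0, max(n - m, 1)))
        tt = np.arange(m) / cfg.sample_rate
        chirps[start : start + m] += (
            0.8 * np.sin(2.0 * np.pi * (f * tt + 4000.0 * tt * tt)) * np.hanning(m)
        )

    total = noise + tones + chirps
    total /= max(np.sqrt(np.mean(total**2)), 1e-12)
    return AudioClip(total, cfg.sample_rate)


def _assign_dates(cfg: SynthConfig, n_clips: int) -> list[_dt.date]:
    """Spread clips over the configured years; successive season days within a year."""
    dates = []
    n_years = len(cfg.years)
    for j in range(n_clips):
        yi = j * n_years // n_clips
        year = cfg.years[yi]
        occurrence = j - (yi * n_clips + n_years - 1) // n_years
        start = _dt.date(year, *_SEASON_START)
        dates.append(start + _dt.timedelta(days=max(occurrence, 0)))
    return dates


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> Dataset:
    """Render the full clip inventory to WAV files plus a manifest CSV.

    Per individual: ``clips_per_individual_fg`` foreground clips (vocalization
    mixed into that individual's *own* background at ``snr_db``) and
    ``clips_per_individual_bg`` background-only clips.  Deterministic in
    ``cfg.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = np.random.SeedSequence(cfg.seed)
    n_streams = 1 + cfg.K * (cfg.clips_per_individual_fg + cfg.clips_per_individual_bg)
    streams = base.spawn(n_streams)
    profiles = build_profiles(cfg, np.random.default_rng(streams[0]))

    voc_rms_target = BACKGROUND_RMS * 10.0 ** (cfg.snr_db / 20.0)
    fg_dates = _assign_dates(cfg, cfg.clips_per_individual_fg)
    bg_dates = _assign_dates(cfg, cfg.clips_per_individual_bg)

    records: list[ClipRecord] = []
    si = 1
    for profile in profiles:
        for j in range(cfg.clips_per_individual_fg):
            rng = np.random.default_rng(streams[si]); si += 1
            year = fg_dates[j].year
            voc = render_vocalization(profile, cfg, rng, year=year)
            bgc = render_background(profile, cfg, rng)
            v = voc.samples
            vr = np.sqrt(np.mean(v**2))
            v = v * (voc_rms_target / max(vr, 1e-12))
            mix = v + bgc.samples * BACKGROUND_RMS
            peak = np.max(np.abs(mix))
            if peak > 0.99:
                mix *= 0.99 / peak  # scales both layers: SNR preserved
            path = out_dir / f"fg_{profile.individual}_{j:03d}.wav"
            write_audio(AudioClip(mix, cfg.sample_rate), path)
            records.append(
                ClipRecord(
                    path=str(path),
                    individual=profile.individual,
                    role=Role.FOREGROUND,
                    date=fg_dates[j],
                )
            )
        for j in range(cfg.clips_per_individual_bg):
            rng = np.random.default_rng(streams[si]); si += 1
            bgc = render_background(profile, cfg, rng)
            samples = bgc.samples * BACKGROUND_RMS
            path = out_dir / f"bg_{profile.individual}_{j:03d}.wav"
            write_audio(AudioClip(samples, cfg.sample_rate), path)
            records.append(
                ClipRecord(
                    path=str(path),
                    individual=profile.individual,
                    role=Role.BACKGROUND,
                    date=bg_dates[j],
                )
            )
    ds = Dataset(records)
    save_manifest(ds, out_dir / "manifest.csv")
    return ds
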