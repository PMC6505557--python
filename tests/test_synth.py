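import numpy as np
import pytest
from scipy.stats import spearmanr

from vocalid import (
    SynthConfig,
    build_profiles,
    generate_dataset,
    mel_filterbank,
    mel_spectrogram,
    read_audio,
    render_background,
    render_vocalization,
)
from vocalid.manifest import Role
from vocalid.synth import BACKGROUND_RMS, BackgroundParams, IndividualProfile, Syllable


def small_cfg(**kw):
    defaults = dict(
        K=4,
        clips_per_individual_fg=3,
        clips_per_individual_bg=2,
        clip_seconds=0.5,
        seed=5,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


def profile_with(tones=(3000.0,), tilt=-0.5, rate=0.0, syllables=None):
    rep = syllables or [Syllable(4000.0, 0.0, 0.12)]
    return IndividualProfile(
        individual="indXX",
        repertoire_by_year={2013: rep},
        background=BackgroundParams(tilt=tilt, habitat_tones=tuple(tones), event_rate=rate),
    )


class TestConfigAndProfiles:
    def test_strength_parameters_bounded(self):
        with pytest.raises(ValueError):
            small_cfg(signature_strength=1.2)
        with pytest.raises(ValueError):
            small_cfg(confound_strength=-0.1)
        with pytest.raises(ValueError):
            small_cfg(K=1)

    def test_zero_confound_gives_identical_background_params(self):
        profiles = build_profiles(small_cfg(confound_strength=0.0))
        first = profiles[0].background
        assert all(p.background == first for p in profiles)

    def test_zero_signature_gives_identical_repertoires(self):
        profiles = build_profiles(small_cfg(signature_strength=0.0))
        first = profiles[0].repertoire(2013)
        assert all(p.repertoire(2013) == first for p in profiles)

    def test_full_confound_gives_distinct_backgrounds(self):
        profiles = build_profiles(small_cfg(confound_strength=1.0))
        tones = {p.background.habitat_tones for p in profiles}
        assert len(tones) == len(profiles)

    def test_empty_repertoire_rejected(self):
        with pytest.raises(ValueError):
            IndividualProfile(
                individual="x",
                repertoire_by_year={2013: []},
                background=BackgroundParams(0.0, (), 0.0),
            )

    def test_zero_duration_syllable_rejected(self):
        with pytest.raises(ValueError):
            Syllable(4000.0, 0.0, 0.0)

    def test_year_drift_changes_some_syllables(self):
        cfg = small_cfg(years=(2013, 2014), drift=1.0, signature_strength=1.0)
        profiles = build_profiles(cfg)
        assert profiles[0].repertoire(2013) != profiles[0].repertoire(2014)


class TestRenderVocalization:
    def test_constant_tone_syllable_energy_in_matching_band(self):
        cfg = small_cfg()
        rng = np.random.default_rng(0)
        clip = render_vocalization(profile_with(), cfg, rng)
        spec = mel_spectrogram(clip)
        fb = mel_filterbank(44100)
        freqs = np.linspace(0, 22050, fb.shape[1])
        expected = np.argmin([abs(freqs[np.argmax(fb[b])] - 4000.0) for b in range(40)])
        assert abs(int(np.argmax(spec.values.mean(axis=0))) - int(expected)) <= 1

    def test_disjoint_frequency_ranges_give_different_dominant_bands(self):
        cfg = small_cfg()
        lo = profile_with(syllables=[Syllable(2000.0, 0.0, 0.12)])
        hi = profile_with(syllables=[Syllable(7000.0, 0.0, 0.12)])
        band = lambda p: np.argmax(
            mel_spectrogram(render_vocalization(p, cfg, np.random.default_rng(1))).values.mean(axis=0)
        )
        assert band(lo) != band(hi)

    def test_clip_duration_matches_config(self):
        cfg = small_cfg(clip_seconds=0.7)
        clip = render_vocalization(profile_with(), cfg, np.random.default_rng(2))
        assert clip.n == round(0.7 * 44100)


class TestRenderBackground:
    def test_pure_tilted_noise_band_medians_monotone_in_tilt(self):
        cfg = small_cfg(clip_seconds=1.0)
        for tilt, sign in [(-0.8, -1), (0.5, 1)]:
            prof = profile_with(tones=(), tilt=tilt, rate=0.0)
            clip = render_background(prof, cfg, np.random.default_rng(3))
            spec = mel_spectrogram(clip)
            med = np.median(spec.values, axis=0)
            rho = spearmanr(np.arange(40), med).statistic
            assert np.sign(rho) == sign and abs(rho) > 0.5

    def test_distinct_habitat_tones_give_distinct_band_peaks(self):
        from vocalid import median_noise_reduce

        cfg = small_cfg(clip_seconds=1.0)
        a = profile_with(tones=(1000.0,), tilt=0.0, rate=8.0)
        b = profile_with(tones=(6000.0,), tilt=0.0, rate=8.0)
        # the identity cue that survives median noise reduction is the
        # transient chirps centred on the habitat-tone frequencies
        peak = lambda p: np.argmax(
            median_noise_reduce(
                mel_spectrogram(render_background(p, cfg, np.random.default_rng(4)))
            ).values.mean(axis=0)
        )
        assert abs(int(peak(a)) - int(peak(b))) > 3

    def test_rms_scales_linearly_with_gain(self):
        cfg = small_cfg()
        clip = render_background(profile_with(), cfg, np.random.default_rng(5))
        r1 = np.sqrt(np.mean(clip.samples**2))
        r2 = np.sqrt(np.mean((0.3 * clip.samples) ** 2))
        assert r2 == pytest.approx(0.3 * r1, rel=1e-12)


class TestGenerateDataset:
    def test_record_counts(self, tmp_path):
        ds = generate_dataset(small_cfg(K=4, clips_per_individual_fg=10, clips_per_individual_bg=10), tmp_path)
        assert len(ds) == 80
        assert ds.K == 4

    def test_same_seed_gives_byte_identical_wavs(self, tmp_path):
        cfg = small_cfg()
        a = generate_dataset(cfg, tmp_path / "a")
        b = generate_dataset(cfg, tmp_path / "b")
        for ra, rb in zip(a.records, b.records):
            assert open(ra.path, "rb").read() == open(rb.path, "rb").read()

    def test_samples_within_unit_range(self, tmp_path):
        ds = generate_dataset(small_cfg(), tmp_path)
        for rec in ds.records[:6]:
            clip = read_audio(rec.path)
            assert np.max(np.abs(clip.samples)) <= 1.0

    def test_declared_snr_matches_measured_within_1db(self, tmp_path):
        cfg = small_cfg(clip_seconds=2.0, snr_db=10.0, K=2,
                        clips_per_individual_fg=3, clips_per_individual_bg=1)
        ds = generate_dataset(cfg, tmp_path)
        # foreground power = vocal power + background power (independent
        # layers); recover the vocal RMS from the written clips
        fg = [r for r in ds.records if r.role is Role.FOREGROUND]
        ratios = []
        for rec in fg:
            clip = read_audio(rec.path)
            total_p = np.mean(clip.samples**2)
            voc_p = max(total_p - BACKGROUND_RMS**2, 1e-12)
            ratios.append(10 * np.log10(voc_p / BACKGROUND_RMS**2))
        assert np.mean(ratios) == pytest.approx(10.0, abs=1.0)

    def test_dates_span_configured_years(self, tmp_path):
        cfg = small_cfg(years=(2013, 2014), clips_per_individual_fg=4)
        ds = generate_dataset(cfg, tmp_path)
        years = {r.year for r in ds.records if r.role is Role.FOREGROUND}
        assert years == {2013, 2014}

    def test_manifest_written_alongside_audio(self, tmp_path):
        from vocalid import load_manifest

        ds = generate_dataset(small_cfg(), tmp_path)
        loaded = load_manifest(tmp_path / "manifest.csv")
        assert [r.path for r in loaded.records] == [r.path for r in ds.records]
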