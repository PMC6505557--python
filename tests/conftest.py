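import datetime as dt

import numpy as np
import pytest

from vocalid import (
    AudioClip,
    ClipRecord,
    Dataset,
    Role,
    Split,
    SynthConfig,
    generate_dataset,
    temporal_split,
)


def make_record(
    path="clips/a.wav",
    individual="ind00",
    role=Role.FOREGROUND,
    date=dt.date(2013, 4, 1),
    split=Split.UNASSIGNED,
    **kw,
):
    return ClipRecord(path=path, individual=individual, role=role, date=date, split=split, **kw)


def tone_clip(freq_hz, seconds=0.5, sample_rate=44100, amplitude=0.5):
    t = np.arange(int(seconds * sample_rate)) / sample_rate
    return AudioClip(amplitude * np.sin(2 * np.pi * freq_hz * t), sample_rate)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small generated dataset with a mid-season train/eval split: 3
    individuals, 4 foreground + 3 background clips each, 0.5 s clips."""
    out = tmp_path_factory.mktemp("tiny_synth")
    cfg = SynthConfig(
        K=3,
        clips_per_individual_fg=4,
        clips_per_individual_bg=3,
        clip_seconds=0.5,
        seed=42,
    )
    ds = generate_dataset(cfg, out)
    return temporal_split(ds, "within_year", dt.date(2013, 4, 3))
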