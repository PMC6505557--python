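"""Mitigate a background confound with stratified augmentation + learned features.

Both a real vocal signature and a fully individual background are present
(signature_strength 1, confound_strength 1).  A baseline mel-feature
classifier leans partly on the background; the improved pipeline — every
training item additionally mixed with each other individual's background,
plus spherical-k-means codebook features — keeps foreground accuracy while
dropping background recognition toward chance and shrinking the adversarial
score deviation severalfold.
"""

import datetime as dt
import tempfile
from pathlib import Path

from vocalid import (
    Role,
    SpectrogramCache,
    Split,
    SynthConfig,
    adversarial_probe,
    background_only_probe,
    foreground_auc,
    generate_dataset,
    stratified_augment,
    temporal_split,
    train_model,
)

cfg = SynthConfig(
    K=6,
    clips_per_individual_fg=12,
    clips_per_individual_bg=12,
    clip_seconds=1.0,
    signature_strength=1.0,
    confound_strength=1.0,
    seed=1,
)
work = Path(tempfile.mkdtemp())
ds = temporal_split(generate_dataset(cfg, work), "within_year", dt.date(2013, 4, 7))
cache = SpectrogramCache()

baseline = train_model(ds, feature_space="mel", seed=2, cache=cache)
augmented = stratified_augment(ds, 3, work / "augmented")
improved = train_model(augmented, feature_space="learned", seed=2, cache=cache, codebook_k=32)

print(f"{'pipeline':10s} {'fg AUC':>7s} {'bg AUC':>7s} {'adv RMSE':>9s}")
for name, model in [("baseline", baseline), ("improved", improved)]:
    fg = foreground_auc(model, ds, cache)
    bg = background_only_probe(model, ds.subset(role=Role.BACKGROUND, split=Split.EVAL), cache)
    adv = adversarial_probe(model, ds, 3, work / f"adv_{name}", cache)
    print(f"{name:10s} {fg.auc:7.3f} {bg.auc:7.3f} {adv.rmse:9.4f}")

print()
print("Foreground AUC should stay high for both; the improved pipeline's")
print("background-only AUC falls toward 0.5 (confound no longer used) and its")
print("adversarial RMSE is a fraction of the baseline's (scores barely move")
print("when an alien background is mixed in).")
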