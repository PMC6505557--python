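"""Structured data augmentation: stratified (training) and adversarial (evaluation).

Both schemes additively mix foreground clips with *background* clips recorded
in other individuals' territories, chosen by identity metadata rather than at
random:

* **Stratified** augmentation enlarges a training set so that every
  foreground item of individual *i* also appears mixed with a background
  example from each other individual *j* — after which background identity
  carries no information about foreground identity, removing the incentive
  for a classifier to learn territory cues.  With K individuals the
  foreground set grows by a factor of K (the original plus K-1 mixtures).
* **Adversarial** augmentation probes a trained classifier: each evaluation
  foreground item is replaced by a single mixture with some *other*
  individual's background.  Labels are unchanged — the vocalizing individual
  is the same — so any change in the classifier's outputs reflects reliance
  on the background.

Donor backgrounds are always drawn from the same split as the items being
augmented (train donors for stratified, eval donors for adversarial) so that
augmentation never leaks audio across the temporal split.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .audio import mix_additive, read_audio, write_audio
from .manifest import ClipRecord, Dataset, Provenance, Role, Split

__all__ = ["stratified_augment", "adversarial_augment", "hybrid_training_set"]


def _bg_by_individual(ds: Dataset, split: Split) -> dict[str, list[ClipRecord]]:
    out: dict[str, list[ClipRecord]] = {}
    for r in ds.records:
        if r.role is Role.BACKGROUND and r.split is split:
            out.setdefault(r.individual, []).append(r)
    for recs in out.values():
        recs.sort(key=lambda r: r.path)
    return out


def stratified_augment(train: Dataset, seed: int, out_dir: str | Path) -> Dataset:
    """Mix every foreground training item with one background item of each
    other individual; mixed WAVs are written under ``out_dir``.

    The returned dataset keeps all original records and appends the mixtures,
    so the foreground count becomes K times the input foreground count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    individuals = train.individuals
    if len(individuals) < 2:
        return Dataset(list(train.records))
    bg_pool = _bg_by_individual(train, Split.TRAIN)
    for ind in individuals:
        if not bg_pool.get(ind):
            raise ValueError(
                f"individual {ind!r} has no background training clips to donate"
            )

    fg = sorted(
        (r for r in train.records if r.role is Role.FOREGROUND and r.split is Split.TRAIN),
        key=lambda r: r.path,
    )
    mixtures: list[ClipRecord] = []
    for rec in fg:
        fg_clip = read_audio(rec.path)
        for donor in individuals:
            if donor == rec.individual:
                continue
            donor_rec = bg_pool[donor][int(rng.integers(len(bg_pool[donor])))]
            mixed = mix_additive(fg_clip, read_audio(donor_rec.path), rng)
            out_path = out_dir / f"{Path(rec.path).stem}__strat_{donor}.wav"
            write_audio(mixed, out_path)
            mixtures.append(
                replace(
                    rec,
                    path=str(out_path),
                    provenance=Provenance.STRATIFIED_MIX,
                    mixed_with_individual=donor,
                )
            )
    return Dataset(list(train.records) + mixtures)


def adversarial_augment(eval_ds: Dataset, seed: int, out_dir: str | Path) -> Dataset:
    """Replace each foreground evaluation item by one mixture with another
    individual's background; the set size and all labels are unchanged.

    The donor individual is chosen uniformly among the others, then a donor
    clip uniformly within that individual's background evaluation clips.
    Output records keep the order of their source items.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    individuals = eval_ds.individuals
    if len(individuals) < 2:
        raise ValueError("adversarial augmentation requires at least 2 individuals")
    bg_pool = _bg_by_individual(eval_ds, Split.EVAL)

    out: list[ClipRecord] = []
    for rec in eval_ds.records:
        if not (rec.role is Role.FOREGROUND and rec.split is Split.EVAL):
            out.append(rec)
            continue
        donors = [i for i in individuals if i != rec.individual and bg_pool.get(i)]
        if not donors:
            raise ValueError(
                f"no eligible background donor for item {rec.path} "
                f"(individual {rec.individual!r})"
            )
        donor = donors[int(rng.integers(len(donors)))]
        donor_rec = bg_pool[donor][int(rng.integers(len(bg_pool[donor])))]
        mixed = mix_additive(read_audio(rec.path), read_audio(donor_rec.path), rng)
        out_path = out_dir / f"{Path(rec.path).stem}__adv_{donor}.wav"
        write_audio(mixed, out_path)
        out.append(
            replace(
                rec,
                path=str(out_path),
                provenance=Provenance.ADVERSARIAL_MIX,
                mixed_with_individual=donor,
            )
        )
    return Dataset(out)


def hybrid_training_set(original: Dataset, augmented: Dataset, seed: int) -> Dataset:
    """Half-size augmented training set with per-individual counts preserved.

    Per individual: the chronologically earliest half of the original
    foreground items, plus the complementary count sampled without
    replacement from that individual's stratified mixtures — so the hybrid
    set has exactly the original's per-individual foreground counts, but half
    of its items carry decorrelated backgrounds.  Background records pass
    through from the original.
    """
    rng = np.random.default_rng(seed)
    out: list[ClipRecord] = []
    for ind in original.individuals:
        orig_fg = sorted(
            (
                r
                for r in original.records
                if r.individual == ind and r.role is Role.FOREGROUND and r.split is Split.TRAIN
            ),
            key=lambda r: (r.date, r.path),
        )
        n = len(orig_fg)
        n_keep = (n + 1) // 2
        n_mix = n - n_keep
        mixes = sorted(
            (
                r
                for r in augmented.records
                if r.individual == ind and r.provenance is Provenance.STRATIFIED_MIX
            ),
            key=lambda r: (r.path, r.mixed_with_individual or ""),
        )
        if len(mixes) < n_mix:
            raise ValueError(
                f"individual {ind!r} has only {len(mixes)} mixture items; "
                f"{n_mix} needed for the hybrid set"
            )
        out.extend(orig_fg[:n_keep])
        if n_mix:
            chosen = rng.choice(len(mixes), size=n_mix, replace=False)
            out.extend(mixes[i] for i in sorted(chosen))
    out.extend(
        r for r in original.records if not (r.role is Role.FOREGROUND and r.split is Split.TRAIN)
    )
    return Dataset(out)
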