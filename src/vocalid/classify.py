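"""Multi-class ensemble classification of clips from summary feature vectors.

The classifier is a seeded random forest over fixed-length per-clip features:
either the 40 noise-reduced mel bands summarized by mean and SD over time
(80 dims), or the spherical-k-means codebook responses summarized the same
way (2k dims).  An optional explicit-background ("wastebasket") class adds
the background-only training clips as one extra class meaning "none of the
known individuals".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .audio import read_audio
from .codebook import Codebook, learn_codebook, project_spectrogram
from .features import MelSpectrogram, mel_spectrogram, median_noise_reduce, summarize_features
from .manifest import BACKGROUND_LABEL, ClipRecord, Dataset, Role, Split

logger = logging.getLogger(__name__)

DEFAULT_HYPERPARAMS = {"n_estimators": 200, "max_features": "sqrt", "max_depth": None}

_MODEL_FORMAT_VERSION = 1


class SpectrogramCache:
    """Noise-reduced mel spectrograms keyed by clip path, computed on demand.

    Sharing one cache across models avoids re-reading and re-transforming
    audio when several pipelines score the same clips.
    """

    def __init__(self) -> None:
        self._store: dict[str, MelSpectrogram] = {}

    def reduced_spec(self, path: str) -> MelSpectrogram:
        spec = self._store.get(path)
        if spec is None:
            spec = median_noise_reduce(mel_spectrogram(read_audio(path)))
            self._store[path] = spec
        return spec


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    class_labels: list[str]
    feature_space: str  # "mel" | "learned"
    codebook: Codebook | None
    use_explicit_background: bool
    seed: int

    def save(self, path: str | Path) -> Path:
        joblib.dump({"version": _MODEL_FORMAT_VERSION, "model": self}, path)
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model file version {blob.get('version')}")
        return blob["model"]


@dataclass
class ScoreMatrix:
    """Per-item class-probability scores; rows sum to one."""

    scores: np.ndarray  # (items, classes)
    item_ids: list[str]
    class_labels: list[str]

    def drop_background(self) -> "ScoreMatrix":
        """Remove the wastebasket column and renormalize rows.

        Renormalization is a monotone rescaling per row, so the ranking of
        the remaining individual classes is unchanged.
        """
        if BACKGROUND_LABEL not in self.class_labels:
            return self
        keep = [i for i, c in enumerate(self.class_labels) if c != BACKGROUND_LABEL]
        sub = self.scores[:, keep]
        sums = sub.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return ScoreMatrix(
            sub / sums,
            list(self.item_ids),
            [self.class_labels[i] for i in keep],
        )


def _canonical(records: Iterable[ClipRecord]) -> list[ClipRecord]:
    return sorted(
        records,
        key=lambda r: (r.path, r.provenance.value, r.mixed_with_individual or ""),
    )


def _clip_features(
    record_path: str,
    feature_space: str,
    codebook: Codebook | None,
    cache: SpectrogramCache,
) -> np.ndarray:
    spec = cache.reduced_spec(record_path)
    if feature_space == "mel":
        return summarize_features(spec.values)
    if feature_space == "learned":
        if codebook is None:
            raise ValueError("learned feature space requires a codebook")
        return summarize_features(project_spectrogram(spec, codebook))
    raise ValueError(f"unknown feature space {feature_space!r}")


def train_model(
    train: Dataset,
    feature_space: str = "mel",
    use_explicit_background: bool = False,
    hyperparams: dict | None = None,
    seed: int = 0,
    cache: SpectrogramCache | None = None,
    codebook_k: int = 256,
    codebook_w: int = 4,
) -> TrainedModel:
    """Fit the pipeline on a training dataset.

    Features are extracted from all foreground training items (and, with the
    explicit-background flag, the background training items as one extra
    class).  For the learned feature space a codebook is first fit,
    unsupervised, on the same training items' spectrograms — never on
    evaluation audio.
    """
    cache = cache or SpectrogramCache()
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})

    items = _canonical(
        r for r in train.records if r.role is Role.FOREGROUND and r.split is Split.TRAIN
    )
    labels = [r.individual for r in items]
    if use_explicit_background:
        bg_items = _canonical(
            r for r in train.records if r.role is Role.BACKGROUND and r.split is Split.TRAIN
        )
        items = items + bg_items
        labels = labels + [BACKGROUND_LABEL] * len(bg_items)
    if len(set(labels)) < 2:
        raise ValueError("training requires at least 2 classes with items")
    for lab in set(labels):
        if labels.count(lab) == 0:  # pragma: no cover - defensive
            raise ValueError(f"class {lab!r} has no items")

    codebook = None
    if feature_space == "learned":
        specs = [cache.reduced_spec(r.path) for r in items]
        codebook = learn_codebook(specs, k=codebook_k, w=codebook_w, seed=seed)

    X = np.vstack([_clip_features(r.path, feature_space, codebook, cache) for r in items])
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    forest.fit(X, labels)

    class_labels = sorted(set(labels))
    return TrainedModel(
        forest=forest,
        class_labels=class_labels,
        feature_space=feature_space,
        codebook=codebook,
        use_explicit_background=use_explicit_background,
        seed=seed,
    )


def predict_scores(
    model: TrainedModel,
    items: Dataset | Sequence[ClipRecord],
    cache: SpectrogramCache | None = None,
    individual_only: bool = False,
) -> ScoreMatrix:
    """Class-probability scores for each item, in the items' given order.

    Unreadable clips are logged and omitted rather than aborting the run.
    With ``individual_only`` the wastebasket column (if any) is dropped and
    rows renormalized, giving scores over the known individuals only.
    """
    cache = cache or SpectrogramCache()
    records = list(items.records if isinstance(items, Dataset) else items)
    rows = []
    ids = []
    for rec in records:
        try:
            rows.append(_clip_features(rec.path, model.feature_space, model.codebook, cache))
        except (OSError, ValueError) as exc:
            logger.error("skipping unreadable clip %s: %s", rec.path, exc)
            continue
        ids.append(rec.path)
    if not rows:
        raise ValueError("no readable items to score")
    proba = model.forest.predict_proba(np.vstack(rows))
    # align forest class order to the model's label order
    order = [list(model.forest.classes_).index(c) for c in model.class_labels]
    sm = ScoreMatrix(proba[:, order], ids, list(model.class_labels))
    return sm.drop_background() if individual_only else sm
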