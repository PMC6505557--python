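"""Evaluation metrics and the two confound probes.

The headline metric is the pooled one-vs-rest AUC: every (item, class) score
is treated as one binary decision (positive iff the class is the item's true
individual), and the AUC is the probability that a randomly chosen positive
outscores a randomly chosen negative, ties counted half.  A single number per
condition, interpretable as a rank statistic.

Two diagnostics probe whether a classifier keys on territory background
rather than the vocal signature:

* the **background-only probe** scores background clips (the focal
  individual silent) against the individual classes — anything clearly above
  0.5 AUC means identity is being read from the habitat;
* the **adversarial probe** rescoring each evaluation item after mixing in
  another individual's background — the RMS difference between the two score
  sets measures how much the classifier's outputs depend on the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .augment import adversarial_augment
from .classify import ScoreMatrix, SpectrogramCache, TrainedModel, predict_scores
from .manifest import Dataset, Provenance, Role, Split


@dataclass
class EvalResult:
    auc: float
    n_items: int
    n_classes: int
    scenario: str = ""
    flags: dict = field(default_factory=dict)
    rmse: float | None = None

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "n_items": self.n_items,
            "n_classes": self.n_classes,
            "scenario": self.scenario,
            "flags": dict(sorted(self.flags.items())),
        }
        if self.rmse is not None:
            d["rmse"] = self.rmse
        return d


def auc_pooled_ovr(scores: ScoreMatrix, truth: Mapping[str, str]) -> float:
    """Pooled one-vs-rest rank AUC over all (item, class) cells.

    Mann-Whitney formulation via midranks, so tied scores are credited 0.5
    per pair exactly.
    """
    missing = [i for i in scores.item_ids if i not in truth]
    if missing:
        raise ValueError(f"items without truth labels: {missing[:3]}...")
    pos_mask = np.zeros_like(scores.scores, dtype=bool)
    for row, item in enumerate(scores.item_ids):
        label = truth[item]
        if label not in scores.class_labels:
            raise ValueError(f"truth label {label!r} not among class labels")
        pos_mask[row, scores.class_labels.index(label)] = True
    vals = scores.scores.ravel()
    pos = pos_mask.ravel()
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both positive and negative cells")
    ranks = rankdata(vals)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def rmse_scores(a: ScoreMatrix, b: ScoreMatrix) -> float:
    """Root-mean-square difference over all item x class cells."""
    if a.item_ids != b.item_ids:
        raise ValueError("score matrices cover different items")
    if a.class_labels != b.class_labels:
        raise ValueError("score matrices cover different classes")
    if a.scores.shape != b.scores.shape:
        raise ValueError("score matrix shapes differ")
    return float(np.sqrt(np.mean((a.scores - b.scores) ** 2)))


def background_only_probe(
    model: TrainedModel,
    backgrounds: Dataset,
    cache: SpectrogramCache | None = None,
    scenario: str = "",
) -> EvalResult:
    """Score background-only clips against the individual classes.

    A pooled AUC near 0.5 means the classifier cannot tell individuals apart
    from their habitat alone; clearly higher values expose a confound.
    """
    recs = [r for r in backgrounds.records if r.role is Role.BACKGROUND]
    if not recs:
        raise ValueError("no background clips to probe")
    sm = predict_scores(model, recs, cache, individual_only=True)
    truth = {r.path: r.individual for r in recs}
    return EvalResult(
        auc=auc_pooled_ovr(sm, truth),
        n_items=len(sm.item_ids),
        n_classes=len(sm.class_labels),
        scenario=scenario,
        flags={"background_only": True},
    )


def adversarial_probe(
    model: TrainedModel,
    eval_ds: Dataset,
    seed: int,
    out_dir: str | Path,
    cache: SpectrogramCache | None = None,
    scenario: str = "",
) -> EvalResult:
    """Rescore the evaluation set after adversarial background mixing.

    Returns the adversarial foreground AUC together with the RMS difference
    between the adversarial and unmodified score sets (paired item by item).
    A classifier that ignores the background is invariant: RMSE near zero.
    """
    cache = cache or SpectrogramCache()
    clean = [
        r for r in eval_ds.records if r.role is Role.FOREGROUND and r.split is Split.EVAL
    ]
    if not clean:
        raise ValueError("no foreground evaluation items")
    adv_ds = adversarial_augment(eval_ds, seed, out_dir)
    adv = [r for r in adv_ds.records if r.provenance is Provenance.ADVERSARIAL_MIX]

    sm_clean = predict_scores(model, clean, cache, individual_only=True)
    sm_adv = predict_scores(model, adv, cache, individual_only=True)
    if len(sm_adv.item_ids) != len(sm_clean.item_ids):
        raise ValueError("adversarial and clean score sets are not paired")
    # adversarial items are 1:1 and order-preserving with their sources; carry
    # the source paths as item ids so the pairing is explicit
    sm_adv = ScoreMatrix(sm_adv.scores, list(sm_clean.item_ids), sm_adv.class_labels)

    truth = {r.path: r.individual for r in clean}
    return EvalResult(
        auc=auc_pooled_ovr(sm_adv, truth),
        n_items=len(sm_adv.item_ids),
        n_classes=len(sm_adv.class_labels),
        scenario=scenario,
        flags={"adversarial": True},
        rmse=rmse_scores(sm_adv, sm_clean),
    )


def foreground_auc(
    model: TrainedModel,
    eval_ds: Dataset,
    cache: SpectrogramCache | None = None,
    scenario: str = "",
    flags: dict | None = None,
) -> EvalResult:
    """Pooled foreground AUC of a model on the evaluation split."""
    recs = [
        r for r in eval_ds.records if r.role is Role.FOREGROUND and r.split is Split.EVAL
    ]
    if not recs:
        raise ValueError("no foreground evaluation items")
    sm = predict_scores(model, recs, cache, individual_only=True)
    truth = {r.path: r.individual for r in recs}
    return EvalResult(
        auc=auc_pooled_ovr(sm, truth),
        n_items=len(sm.item_ids),
        n_classes=len(sm.class_labels),
        scenario=scenario,
        flags=dict(flags or {}),
    )
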