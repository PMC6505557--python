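"""Configuration-driven experiment runner.

One config describes a full run: where the data comes from (the synthetic
generator or an existing manifest), how the temporal train/eval split is
drawn, and which interventions are switched on — stratified augmentation (or
its half-size hybrid), learned features, the explicit-background class, and
the two confound probes.  ``run_scenario`` executes the pipeline end to end,
writes manifests, the model, a results JSON and a plain-text log, and is
byte-reproducible for a fixed config.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .augment import hybrid_training_set, stratified_augment
from .classify import SpectrogramCache, train_model
from .evaluation import (
    EvalResult,
    adversarial_probe,
    background_only_probe,
    foreground_auc,
)
from .manifest import (
    Dataset,
    Role,
    Split,
    load_manifest,
    restrict_per_individual,
    save_manifest,
    temporal_split,
)
from .synth import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    # data source: exactly one of synth / manifest_path
    synth: SynthConfig | None = None
    manifest_path: str | None = None
    scenario: str = "within_year"  # within_year | across_year | only_n
    boundary: str | int | None = None  # ISO date (within_year) or year (across_year)
    n_restrict: int | None = None
    augmentation: bool = False
    hybrid: bool = False
    learned_features: bool = False
    explicit_background: bool = False
    adversarial_eval: bool = False
    background_only_eval: bool = False
    codebook_k: int = 64
    codebook_w: int = 4
    synthesis_seed: int = 0
    augmentation_seed: int = 1
    training_seed: int = 2
    out_dir: str = "runs/experiment"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.manifest_path is None):
            raise ValueError("config needs exactly one of synth / manifest_path")
        if self.scenario == "only_n" and (self.n_restrict is None or self.n_restrict < 1):
            raise ValueError("only_n scenario requires n_restrict >= 1")
        if self.scenario not in ("within_year", "across_year", "only_n"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synth", None)
        if synth is not None:
            if "years" in synth:
                synth["years"] = tuple(synth["years"])
            synth = SynthConfig(**synth)
        return cls(synth=synth, **raw)


def _auto_boundary(ds: Dataset, mode: str) -> _dt.date | int:
    dates = sorted({r.date for r in ds.records})
    if mode == "within_year":
        return dates[len(dates) // 2]
    return min(d.year for d in dates)


def resolve_boundary(cfg: ExperimentConfig, ds: Dataset) -> _dt.date | int:
    mode = "within_year" if cfg.scenario in ("within_year", "only_n") else "across_year"
    if cfg.boundary is None:
        return _auto_boundary(ds, mode)
    if mode == "within_year":
        return _dt.date.fromisoformat(str(cfg.boundary))
    return int(cfg.boundary)


def run_scenario(cfg: ExperimentConfig) -> list[EvalResult]:
    """Execute the configured pipeline; returns the evaluation results.

    Stages: generate/load -> temporal split -> (restrict) -> (stratified
    augment | hybrid) -> train (codebook if learned features) -> foreground
    AUC, plus the background-only and adversarial probes when toggled.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"scenario: {cfg.scenario}"]

    if cfg.synth is not None:
        ds = generate_dataset(cfg.synth, out / "data")
        log_lines.append(f"synthesized: K={ds.K}, {len(ds)} records (seed {cfg.synth.seed})")
    else:
        ds = load_manifest(cfg.manifest_path)
        log_lines.append(f"loaded manifest {cfg.manifest_path}: K={ds.K}, {len(ds)} records")

    mode = "within_year" if cfg.scenario in ("within_year", "only_n") else "across_year"
    boundary = resolve_boundary(cfg, ds)
    ds = temporal_split(ds, mode, boundary)
    if cfg.scenario == "only_n":
        ds = restrict_per_individual(ds, cfg.n_restrict)
    save_manifest(ds, out / "split_manifest.csv")

    def _count(role: Role, split: Split) -> int:
        return sum(1 for r in ds.records if r.role is role and r.split is split)

    log_lines.append(
        "counts after split: fg train {} : eval {}, bg train {} : eval {}".format(
            _count(Role.FOREGROUND, Split.TRAIN),
            _count(Role.FOREGROUND, Split.EVAL),
            _count(Role.BACKGROUND, Split.TRAIN),
            _count(Role.BACKGROUND, Split.EVAL),
        )
    )

    train_ds = ds
    if cfg.augmentation or cfg.hybrid:
        augmented = stratified_augment(ds, cfg.augmentation_seed, out / "augmented")
        if cfg.hybrid:
            train_ds = hybrid_training_set(ds, augmented, cfg.augmentation_seed)
            log_lines.append("hybrid half-size training set in use")
        else:
            train_ds = augmented
        n_fg = sum(
            1
            for r in train_ds.records
            if r.role is Role.FOREGROUND and r.split is Split.TRAIN
        )
        log_lines.append(f"fg training items after augmentation: {n_fg}")
        save_manifest(train_ds, out / "train_manifest.csv")

    cache = SpectrogramCache()
    feature_space = "learned" if cfg.learned_features else "mel"
    model = train_model(
        train_ds,
        feature_space=feature_space,
        use_explicit_background=cfg.explicit_background,
        seed=cfg.training_seed,
        cache=cache,
        codebook_k=cfg.codebook_k,
        codebook_w=cfg.codebook_w,
    )
    model.save(out / "model.joblib")
    log_lines.append(
        f"trained {feature_space} model with {len(model.class_labels)} classes "
        f"(seed {cfg.training_seed})"
    )

    flags = {
        "augmented": bool(cfg.augmentation),
        "hybrid": bool(cfg.hybrid),
        "learned_features": bool(cfg.learned_features),
        "explicit_background": bool(cfg.explicit_background),
    }
    results = [foreground_auc(model, ds, cache, scenario=cfg.scenario, flags=flags)]
    if cfg.background_only_eval:
        res = background_only_probe(
            model, ds.subset(role=Role.BACKGROUND, split=Split.EVAL), cache, cfg.scenario
        )
        res.flags.update(flags)
        results.append(res)
    if cfg.adversarial_eval:
        res = adversarial_probe(
            model, ds, cfg.augmentation_seed, out / "adversarial", cache, cfg.scenario
        )
        res.flags.update(flags)
        results.append(res)

    payload = {
        "config": _config_dict(cfg),
        "results": [r.to_dict() for r in results],
    }
    with open(out / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for r in results:
        log_lines.append(f"result: {json.dumps(r.to_dict(), sort_keys=True)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    if d.get("synth") is not None:
        d["synth"]["years"] = list(d["synth"]["years"])
    return d
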