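"""Clip metadata model, manifest CSV I/O, temporal splitting and item restriction.

A *manifest* is the flat inventory of a recording dataset: one row per audio
clip, tying a WAV file to the individual it belongs to, its role (foreground =
the focal individual is vocalizing, background = it is silent), the recording
date, the train/eval assignment, and — for clips produced by augmentation —
provenance metadata saying which individual's background was mixed in.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Reserved individual label for the explicit-background ("wastebasket") class.
BACKGROUND_LABEL = "__background__"

MANIFEST_COLUMNS = (
    "path",
    "individual",
    "role",
    "date",
    "split",
    "provenance",
    "mixed_with_individual",
)


class Role(str, Enum):
    FOREGROUND = "foreground"
    BACKGROUND = "background"


class Split(str, Enum):
    TRAIN = "train"
    EVAL = "eval"
    UNASSIGNED = "unassigned"


class Provenance(str, Enum):
    ORIGINAL = "original"
    STRATIFIED_MIX = "stratified_mix"
    ADVERSARIAL_MIX = "adversarial_mix"


class ManifestError(ValueError):
    """Raised for schema or row-level manifest problems."""


@dataclass(frozen=True)
class ClipRecord:
    """One audio clip and its metadata.

    ``mixed_with_individual`` names the individual whose background recording
    was additively mixed into this clip; it is set exactly when the clip is an
    augmentation product rather than an original recording.
    """

    path: str
    individual: str
    role: Role
    date: _dt.date
    split: Split = Split.UNASSIGNED
    provenance: Provenance = Provenance.ORIGINAL
    mixed_with_individual: str | None = None

    def __post_init__(self) -> None:
        if not self.path:
            raise ManifestError("record path must be non-empty")
        if self.role is Role.BACKGROUND and self.provenance is not Provenance.ORIGINAL:
            raise ManifestError(
                "background records cannot carry mixed provenance "
                f"(got {self.provenance.value} for {self.path})"
            )
        has_mix = self.mixed_with_individual is not None
        if has_mix != (self.provenance is not Provenance.ORIGINAL):
            raise ManifestError(
                "mixed_with_individual must be set iff provenance is not original "
                f"({self.path})"
            )
        if has_mix and self.mixed_with_individual == self.individual:
            raise ManifestError(
                f"clip of {self.individual!r} cannot be mixed with its own background"
            )

    @property
    def year(self) -> int:
        return self.date.year


@dataclass
class Dataset:
    """An ordered collection of :class:`ClipRecord` with identity bookkeeping.

    ``individuals`` lists the distinct foreground individual IDs in first-seen
    order; ``K`` is their count — the number of classes an identifier of this
    dataset must distinguish.
    """

    records: list[ClipRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str | None]] = set()
        for rec in self.records:
            key = (rec.path, rec.provenance.value, rec.mixed_with_individual)
            if key in seen:
                raise ManifestError(f"duplicate record {key}")
            seen.add(key)

    @property
    def individuals(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.role is Role.FOREGROUND and rec.individual not in out:
                out.append(rec.individual)
        return out

    @property
    def K(self) -> int:
        return len(self.individuals)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(
        self,
        role: Role | None = None,
        split: Split | None = None,
        individual: str | None = None,
    ) -> "Dataset":
        recs = [
            r
            for r in self.records
            if (role is None or r.role is role)
            and (split is None or r.split is split)
            and (individual is None or r.individual == individual)
        ]
        return Dataset(recs)


def load_manifest(path: str | Path) -> Dataset:
    """Read a manifest CSV into a :class:`Dataset`, preserving file order."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestError(f"empty manifest file: {path}")
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        extra = [c for c in header if c not in MANIFEST_COLUMNS]
        if missing or extra:
            raise ManifestError(
                f"manifest schema mismatch in {path}: "
                f"missing columns {missing}, unexpected columns {extra}"
            )
        idx = {c: header.index(c) for c in MANIFEST_COLUMNS}
        records = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell for cell in row):
                continue
            try:
                d = _dt.date.fromisoformat(row[idx["date"]])
            except ValueError as exc:
                raise ManifestError(
                    f"row {rownum} of {path}: unparseable date "
                    f"{row[idx['date']]!r} ({exc})"
                ) from None
            mixed = row[idx["mixed_with_individual"]] or None
            try:
                records.append(
                    ClipRecord(
                        path=row[idx["path"]],
                        individual=row[idx["individual"]],
                        role=Role(row[idx["role"]]),
                        date=d,
                        split=Split(row[idx["split"]]),
                        provenance=Provenance(row[idx["provenance"]]),
                        mixed_with_individual=mixed,
                    )
                )
            except ValueError as exc:
                raise ManifestError(f"row {rownum} of {path}: {exc}") from None
    return Dataset(records)


def save_manifest(ds: Dataset, path: str | Path) -> Path:
    """Write ``ds`` as a manifest CSV; returns the path written."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in ds.records:
            writer.writerow(
                [
                    rec.path,
                    rec.individual,
                    rec.role.value,
                    rec.date.isoformat(),
                    rec.split.value,
                    rec.provenance.value,
                    rec.mixed_with_individual or "",
                ]
            )
    return path


def temporal_split(
    ds: Dataset,
    mode: str,
    boundary: _dt.date | int,
) -> Dataset:
    """Partition records into train and eval along time.

    ``within_year``: ``boundary`` is a date; records dated strictly before it
    go to train, the rest to eval (half-open convention, so the boundary day
    itself is evaluation data).  ``across_year``: ``boundary`` is a year;
    records from that year or earlier train, later years evaluate.  Every
    record is assigned to exactly one side.
    """
    if mode == "within_year":
        if not isinstance(boundary, _dt.date):
            raise ValueError("within_year split requires a date boundary")
        assigner = lambda r: Split.TRAIN if r.date < boundary else Split.EVAL
    elif mode == "across_year":
        if isinstance(boundary, _dt.date) or not isinstance(boundary, int):
            raise ValueError("across_year split requires an integer year boundary")
        assigner = lambda r: Split.TRAIN if r.year <= boundary else Split.EVAL
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    out = Dataset([replace(r, split=assigner(r)) for r in ds.records])
    for ind in out.individuals:
        n_train = sum(
            1
            for r in out.records
            if r.individual == ind and r.role is Role.FOREGROUND and r.split is Split.TRAIN
        )
        if n_train == 0:
            logger.warning("individual %s has no foreground training items after split", ind)
    return out


def restrict_per_individual(ds: Dataset, n: int) -> Dataset:
    """Keep only the ``n`` chronologically earliest foreground training clips
    per individual (ties broken by path); all other records pass through."""
    if n <= 0:
        raise ValueError("n must be a positive integer")
    keep_paths: set[tuple[str, str, str | None]] = set()
    for ind in ds.individuals:
        cands = [
            r
            for r in ds.records
            if r.individual == ind and r.role is Role.FOREGROUND and r.split is Split.TRAIN
        ]
        cands.sort(key=lambda r: (r.date, r.path))
        for r in cands[:n]:
            keep_paths.add((r.path, r.provenance.value, r.mixed_with_individual))
    out = []
    for r in ds.records:
        if r.role is Role.FOREGROUND and r.split is Split.TRAIN:
            if (r.path, r.provenance.value, r.mixed_with_individual) in keep_paths:
                out.append(r)
        else:
            out.append(r)
    return Dataset(out)
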