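"""Data model and I/O for the labelled face-image database ("facebase").

A facebase is an ordered collection of labelled image records — each
carrying an image id, an individual id, a cohort label (a syndrome name or
the reserved ``CONTROL``) and the analysis stage at which the image entered
the database — optionally paired with one unit-norm embedding row per
record.

The manifest is a plain CSV with header
``image_id,individual_id,cohort,stage,image_path``.  Embeddings are stored
either as a CSV (``image_id`` column followed by the vector components) or
as a ``.npy`` dense matrix in manifest row order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DimensionError, ManifestError

#: Reserved cohort label for unaffected distractor images.
CONTROL = "CONTROL"

MANIFEST_COLUMNS = ("image_id", "individual_id", "cohort", "stage", "image_path")

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class ImageRecord:
    """One labelled image.

    Multiple images of the same person (e.g. at different ages) are distinct
    records sharing ``individual_id``; identity is carried solely by that
    field, never parsed out of ``image_id``.
    """

    image_id: str
    individual_id: str
    cohort: str
    stage: int = 1
    image_path: str | None = None

    @property
    def is_control(self) -> bool:
        return self.cohort == CONTROL


@dataclass(frozen=True)
class CohortSummary:
    """Image and individual counts for one cohort."""

    cohort: str
    n_images: int
    n_individuals: int


class Facebase:
    """Validated collection of :class:`ImageRecord` plus optional embeddings.

    Parameters
    ----------
    records:
        Ordered image records.  ``image_id`` must be unique and every
        ``individual_id`` must map to a single cohort.
    embeddings:
        Optional dense ``(n_records, d)`` float matrix, one row per record in
        order.  Rows are renormalised to unit L2 norm on construction.
    """

    def __init__(
        self,
        records: Iterable[ImageRecord],
        embeddings: np.ndarray | None = None,
    ) -> None:
        self.records: tuple[ImageRecord, ...] = tuple(records)
        self._validate_records()
        self._index = {r.image_id: i for i, r in enumerate(self.records)}
        if embeddings is not None:
            embeddings = np.asarray(embeddings, dtype=np.float64)
            if embeddings.ndim != 2 or embeddings.shape[0] != len(self.records):
                raise DimensionError(
                    f"embedding matrix has {embeddings.shape[0] if embeddings.ndim == 2 else 'bad'}"
                    f" rows for {len(self.records)} records"
                )
            norms = np.linalg.norm(embeddings, axis=1)
            if np.any(norms < _NORM_TOL):
                raise DimensionError("zero-norm embedding row cannot be normalised")
            embeddings = embeddings / norms[:, None]
        self.embeddings = embeddings

    # -- construction helpers ------------------------------------------------

    def _validate_records(self) -> None:
        seen_ids: set[str] = set()
        individual_cohort: dict[str, str] = {}
        for rec in self.records:
            if rec.image_id in seen_ids:
                raise ManifestError(f"duplicate image_id {rec.image_id!r}")
            seen_ids.add(rec.image_id)
            prev = individual_cohort.setdefault(rec.individual_id, rec.cohort)
            if prev != rec.cohort:
                raise ManifestError(
                    f"individual {rec.individual_id!r} appears under two cohorts"
                    f" ({prev!r} and {rec.cohort!r})"
                )

    # -- basic queries -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        """Total number of images N."""
        return len(self.records)

    @property
    def image_ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    def index_of(self, image_id: str) -> int:
        try:
            return self._index[image_id]
        except KeyError:
            raise KeyError(f"unknown image_id {image_id!r}") from None

    def record(self, image_id: str) -> ImageRecord:
        return self.records[self.index_of(image_id)]

    def embedding(self, image_id: str) -> np.ndarray:
        if self.embeddings is None:
            raise DimensionError("facebase carries no embeddings")
        return self.embeddings[self.index_of(image_id)]

    @property
    def cohorts(self) -> list[str]:
        """Cohort names in first-appearance order, controls included."""
        out: list[str] = []
        for rec in self.records:
            if rec.cohort not in out:
                out.append(rec.cohort)
        return out

    @property
    def syndrome_cohorts(self) -> list[str]:
        return [c for c in self.cohorts if c != CONTROL]

    def cohort_image_ids(self, cohort: str) -> list[str]:
        ids = [r.image_id for r in self.records if r.cohort == cohort]
        if not ids:
            raise KeyError(f"unknown cohort {cohort!r}")
        return ids

    def individual_image_indices(self, individual_id: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.records) if r.individual_id == individual_id],
            dtype=np.intp,
        )

    def at_stage(self, stage: int) -> "Facebase":
        """Sub-facebase of records whose entry stage is ``<= stage``."""
        keep = [i for i, r in enumerate(self.records) if r.stage <= stage]
        emb = self.embeddings[keep] if self.embeddings is not None else None
        return Facebase([self.records[i] for i in keep], emb)

    # -- I/O -----------------------------------------------------------------

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_COLUMNS)
            for r in self.records:
                writer.writerow(
                    [r.image_id, r.individual_id, r.cohort, r.stage, r.image_path or ""]
                )

    def write_embeddings(self, path: str | Path) -> None:
        if self.embeddings is None:
            raise DimensionError("facebase carries no embeddings")
        path = Path(path)
        if path.suffix == ".npy":
            np.save(path, self.embeddings)
            return
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            d = self.embeddings.shape[1]
            writer.writerow(["image_id"] + [f"e{j}" for j in range(d)])
            for r, row in zip(self.records, self.embeddings):
                writer.writerow([r.image_id] + [repr(float(v)) for v in row])


def cohort_sizes(fb: Facebase) -> list[CohortSummary]:
    """Per-cohort image and individual counts; totals conserve N."""
    summaries: list[CohortSummary] = []
    for cohort in fb.cohorts:
        recs = [r for r in fb.records if r.cohort == cohort]
        summaries.append(
            CohortSummary(
                cohort=cohort,
                n_images=len(recs),
                n_individuals=len({r.individual_id for r in recs}),
            )
        )
    return summaries


def load_manifest(
    path: str | Path, embeddings_path: str | Path | None = None
) -> Facebase:
    """Read a manifest CSV (and optional embedding store) into a Facebase.

    Raises
    ------
    ManifestError
        On a missing/short header, duplicate ``image_id`` or an individual
        appearing under two cohorts.
    DimensionError
        When the embedding row count does not match the record count or an
        embedding id column disagrees with the manifest order.
    """
    path = Path(path)
    records: list[ImageRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestError(f"{path}: empty manifest, header row required")
        if tuple(h.strip() for h in header) != MANIFEST_COLUMNS:
            raise ManifestError(
                f"{path}: bad header {header!r}, expected {list(MANIFEST_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(MANIFEST_COLUMNS):
                raise ManifestError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            image_id, individual_id, cohort, stage, image_path = (c.strip() for c in row)
            try:
                stage_i = int(stage)
            except ValueError:
                raise ManifestError(f"{path}:{lineno}: stage must be an integer")
            records.append(
                ImageRecord(image_id, individual_id, cohort, stage_i, image_path or None)
            )
    embeddings = None
    if embeddings_path is not None:
        embeddings = load_embeddings(embeddings_path, [r.image_id for r in records])
    return Facebase(records, embeddings)


def load_embeddings(
    path: str | Path, expected_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Load a dense embedding matrix from ``.npy`` or id-keyed CSV."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if not row:
                continue
            ids.append(row[0])
            rows.append([float(v) for v in row[1:]])
    if expected_ids is not None and ids != list(expected_ids):
        raise DimensionError("embedding ids do not match manifest row order")
    return np.array(rows, dtype=np.float64)
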