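"""Clinician rating table: three scores per syndrome image.

Score semantics: 1 = definitely would have considered the diagnosis from
the photograph alone, 2 = unlikely, 3 = possibly.  Control images carry no
ratings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ManifestError

VALID_SCORES = frozenset({1, 2, 3})


@dataclass
class RatingTable:
    """Mapping of image_id to an ordered triple of rater scores."""

    scores: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for image_id, triple in self.scores.items():
            if len(triple) != 3 or any(s not in VALID_SCORES for s in triple):
                raise ManifestError(
                    f"image {image_id!r}: scores must be a triple from {{1,2,3}},"
                    f" got {triple!r}"
                )

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, image_id: str) -> bool:
        return image_id in self.scores

    def __getitem__(self, image_id: str) -> tuple[int, int, int]:
        return self.scores[image_id]

    def items(self):
        return self.scores.items()

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "rater1", "rater2", "rater3"])
            for image_id, (s1, s2, s3) in self.scores.items():
                writer.writerow([image_id, s1, s2, s3])

    @classmethod
    def read_csv(cls, path: str | Path) -> "RatingTable":
        scores: dict[str, tuple[int, int, int]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header[:4]] != [
                "image_id",
                "rater1",
                "rater2",
                "rater3",
            ]:
                raise ManifestError(f"{path}: bad ratings header {header!r}")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                image_id = row[0].strip()
                if image_id in scores:
                    raise ManifestError(f"{path}:{lineno}: duplicate image_id {image_id!r}")
                try:
                    triple = tuple(int(v) for v in row[1:4])
                except ValueError:
                    raise ManifestError(f"{path}:{lineno}: non-integer score")
                scores[image_id] = triple  # validated in __post_init__
        return cls(scores)
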