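"""Leave-one-out ranking and top-k same-cohort match extraction.

Every syndrome image in turn becomes the test case; it and *all other
images of the same individual* are withheld from the candidate pool, and
the remaining database is ranked by cosine similarity (descending, ties
broken by ascending image_id).  A top-k match means at least one candidate
of the test image's cohort — necessarily a different individual — within
the first k ranks.  Controls serve as distractors only, never as test
cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DimensionError
from .facebase import Facebase

__all__ = [
    "RankConfig",
    "RankedResult",
    "rank_candidates",
    "topk_flags",
    "evaluate_cohort",
    "evaluate_all",
]

DEFAULT_K_SET = (1, 5, 10)


@dataclass(frozen=True)
class RankConfig:
    """Ordered rank cutoffs at which a same-cohort match is scored."""

    k_set: tuple[int, ...] = DEFAULT_K_SET

    def __post_init__(self) -> None:
        ks = tuple(self.k_set)
        object.__setattr__(self, "k_set", ks)
        if not ks or any(k <= 0 for k in ks) or any(
            b <= a for a, b in zip(ks, ks[1:])
        ):
            raise ConfigError("k_set must be strictly increasing positive integers")


@dataclass(frozen=True)
class RankedResult:
    test_image_id: str
    ranked_candidate_ids: tuple[str, ...]
    flags: dict[int, bool]

    def flag(self, k: int) -> bool:
        try:
            return self.flags[k]
        except KeyError:
            raise KeyError(f"k={k} not in configured cutoffs {sorted(self.flags)}")


def _candidate_order(fb: Facebase, test_idx: int) -> np.ndarray:
    """Indices of all candidates for one test image, best match first."""
    if fb.embeddings is None:
        raise DimensionError("facebase carries no embeddings")
    rec = fb.records[test_idx]
    sims = fb.embeddings @ fb.embeddings[test_idx]
    excluded = fb.individual_image_indices(rec.individual_id)
    mask = np.ones(len(fb), dtype=bool)
    mask[excluded] = False
    candidates = np.nonzero(mask)[0]
    ids = _ids_array(fb)[candidates]
    # primary key: similarity descending; secondary: image_id ascending
    order = np.lexsort((ids, -sims[candidates]))
    return candidates[order]


def _ids_array(fb: Facebase) -> np.ndarray:
    cached = getattr(fb, "_ids_array_cache", None)
    if cached is None or len(cached) != len(fb):
        cached = np.array(fb.image_ids)
        fb._ids_array_cache = cached
    return cached


def rank_candidates(fb: Facebase, test_image_id: str) -> list[str]:
    """Full leave-one-out candidate ranking for one syndrome test image.

    The test image and every image sharing its individual_id are excluded,
    so the list has length ``N - (#images of that individual)``.
    """
    idx = fb.index_of(test_image_id)
    rec = fb.records[idx]
    if rec.is_control:
        raise ConfigError("controls are not test cases")
    order = _candidate_order(fb, idx)
    return [fb.records[i].image_id for i in order]


def topk_flags(
    ranked: list[str],
    cohort_of_test: str,
    fb: Facebase,
    cfg: RankConfig = RankConfig(),
) -> dict[int, bool]:
    """Same-cohort-within-top-k indicator for each configured cutoff.

    Monotone non-decreasing in k.  A cutoff beyond the candidate list is
    evaluated over what is available, with a warning.
    """
    if not ranked:
        raise ConfigError("ranked candidate list is empty")
    match_positions = [
        pos
        for pos, image_id in enumerate(ranked, start=1)
        if fb.record(image_id).cohort == cohort_of_test
    ]
    first = match_positions[0] if match_positions else None
    flags: dict[int, bool] = {}
    for k in cfg.k_set:
        if k > len(ranked):
            warnings.warn(
                f"k={k} exceeds candidate count {len(ranked)}; evaluating over"
                " available candidates",
                stacklevel=2,
            )
        flags[k] = first is not None and first <= k
    return flags


def _evaluate_indices(
    fb: Facebase, test_indices: np.ndarray, cfg: RankConfig
) -> list[RankedResult]:
    all_ids = np.array(fb.image_ids)
    cohorts = np.array([r.cohort for r in fb.records])
    results = []
    for idx in test_indices:
        rec = fb.records[idx]
        order = _candidate_order(fb, idx)
        same = cohorts[order] == rec.cohort
        hits = np.nonzero(same)[0]
        first = int(hits[0]) + 1 if hits.size else None
        flags = {k: first is not None and first <= k for k in cfg.k_set}
        results.append(
            RankedResult(
                test_image_id=rec.image_id,
                ranked_candidate_ids=tuple(all_ids[order]),
                flags=flags,
            )
        )
    return results


def evaluate_cohort(
    fb: Facebase, cohort: str, cfg: RankConfig = RankConfig()
) -> dict[int, tuple[int, int]]:
    """Observed (match, no-match) counts at each k over a cohort's test images."""
    results = evaluate_cohort_results(fb, cohort, cfg)
    n = len(results)
    return {
        k: (sum(r.flags[k] for r in results), n - sum(r.flags[k] for r in results))
        for k in cfg.k_set
    }


def evaluate_cohort_results(
    fb: Facebase, cohort: str, cfg: RankConfig = RankConfig()
) -> list[RankedResult]:
    """Per-test-image ranked results for every image of one syndrome cohort."""
    if cohort not in fb.cohorts:
        raise KeyError(f"unknown cohort {cohort!r}")
    if cohort == "CONTROL":
        raise ConfigError("controls are not test cases")
    test_indices = np.array(
        [i for i, r in enumerate(fb.records) if r.cohort == cohort], dtype=np.intp
    )
    return _evaluate_indices(fb, test_indices, cfg)


def evaluate_all(
    fb: Facebase, cfg: RankConfig = RankConfig()
) -> dict[str, list[RankedResult]]:
    """Ranked results for every syndrome cohort, keyed by cohort name."""
    return {c: evaluate_cohort_results(fb, c, cfg) for c in fb.syndrome_cohorts}
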