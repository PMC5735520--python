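"""Expected top-k match counts under a random-ranking null.

If candidate order is uniformly random, the top-k set is a uniform random
k-subset of the M candidates, so the probability that it contains at least
one of the m same-cohort candidates is the hypergeometric tail

    P(match) = 1 - C(M-m, k) / C(M, k)

which reduces to ``m/M`` at k=1.  The analytic form is primary; a
Monte-Carlo simulation of the same null is kept as an independent
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import ConfigError
from .facebase import Facebase

__all__ = [
    "NullSpec",
    "match_probability",
    "null_specs_for_cohort",
    "expected_counts",
    "simulate_expected_counts",
]


@dataclass(frozen=True)
class NullSpec:
    """Per-test-image null parameters: m successes among M candidates at cutoff k."""

    m: int
    M: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.m <= self.M:
            raise ConfigError(f"need 0 <= m <= M, got m={self.m}, M={self.M}")
        if not 1 <= self.k <= self.M:
            raise ConfigError(f"need 1 <= k <= M, got k={self.k}, M={self.M}")


def match_probability(m: int, M: int, k: int) -> float:
    """P(at least one of m successes in a uniform top-k of M candidates).

    Computed in log space as ``1 - exp(log C(M-m,k) - log C(M,k))`` for
    stability at database scale.  Equals ``m/M`` when k=1 and 1 when
    ``k > M - m``.
    """
    NullSpec(m, M, k)  # validate
    if m == 0:
        return 0.0
    if k > M - m:
        return 1.0
    if k == 1:
        return m / M
    log_tail = (
        _log_comb(M - m, k) - _log_comb(M, k)
    )
    return float(-np.expm1(log_tail))


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def null_specs_for_cohort(fb: Facebase, cohort: str, k: int) -> list[NullSpec]:
    """One NullSpec per test image of the cohort, honouring the rule that a
    test image's same-individual images are withheld from its candidate pool."""
    if cohort not in fb.cohorts:
        raise KeyError(f"unknown cohort {cohort!r}")
    n_total = len(fb)
    cohort_records = [r for r in fb.records if r.cohort == cohort]
    cohort_n = len(cohort_records)
    individual_counts: dict[str, int] = {}
    for r in cohort_records:
        individual_counts[r.individual_id] = individual_counts.get(r.individual_id, 0) + 1
    specs = []
    for r in cohort_records:
        own = individual_counts[r.individual_id]
        specs.append(NullSpec(m=cohort_n - own, M=n_total - own, k=k))
    return specs


def expected_counts(
    fb: Facebase, cohort: str, k: int
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Expected (match, no-match) for one cohort at cutoff k.

    Returns the real-valued pair (summing exactly to the cohort size) and
    the paper-style rounded pair (nearest-integer match count, complement
    as no-match).
    """
    specs = null_specs_for_cohort(fb, cohort, k)
    n_s = len(specs)
    expected = float(sum(match_probability(s.m, s.M, s.k) for s in specs))
    rounded = int(round(expected))
    return (expected, n_s - expected), (rounded, n_s - rounded)


def simulate_expected_counts(
    fb: Facebase,
    cohort: str,
    k: int,
    n_reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo expected match count under uniformly random rankings.

    Each replicate draws, for every test image, a uniform random ranking of
    its candidates (realised as a hypergeometric draw of same-cohort
    candidates into the top-k set) and counts test images with at least one
    success.  Returns (mean, standard error) over replicates; deterministic
    per seed.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    specs = null_specs_for_cohort(fb, cohort, k)
    rng = np.random.default_rng(seed)
    if not specs:
        return 0.0, 0.0
    m = np.array([s.m for s in specs])
    M = np.array([s.M for s in specs])
    if np.all(m == 0):
        return 0.0, 0.0
    # hypergeometric: ngood=m, nbad=M-m, nsample=k
    draws = rng.hypergeometric(m, M - m, np.minimum(k, M), size=(n_reps, len(specs)))
    per_rep = (draws > 0).sum(axis=1).astype(np.float64)
    mean = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return mean, se
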