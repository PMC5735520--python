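"""Goodness-of-fit of observed vs expected top-k match counts.

The statistic is a 1-df chi-square over the (match, no-match) pair with
Yates' continuity correction, the correction clamped at zero when
|O - E| <= 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import ConfigError
from .facebase import Facebase
from .null_model import expected_counts, simulate_expected_counts
from .retrieval import RankConfig, evaluate_cohort

__all__ = [
    "GofResult",
    "MatchCountRow",
    "yates_chi_square",
    "chi2_sf_1df",
    "build_match_table",
    "format_p",
]


@dataclass(frozen=True)
class GofResult:
    chi_square: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class MatchCountRow:
    """One table row; ``gof`` is None when an expected cell is zero
    (statistic undefined, e.g. rounded expectations at an extreme)."""

    cohort: str
    n_images: int
    k: int
    observed: tuple[int, int]
    expected: tuple[float, float]
    gof: GofResult | None


def gof_or_none(
    observed: tuple[float, float], expected: tuple[float, float]
) -> GofResult | None:
    if any(e <= 0 for e in expected):
        return None
    return yates_chi_square(observed, expected)


def chi2_sf_1df(x: float) -> float:
    """Upper-tail probability of a 1-df chi-square: erfc(sqrt(x/2))."""
    if x < 0:
        raise ConfigError("chi-square statistic must be >= 0")
    return math.erfc(math.sqrt(x / 2.0))


def yates_chi_square(
    observed: tuple[float, float], expected: tuple[float, float]
) -> GofResult:
    """Yates-corrected goodness-of-fit over the two (match, no-match) cells."""
    if any(e <= 0 for e in expected):
        raise ConfigError("undefined statistic: expected cell is zero")
    stat = sum(
        max(abs(o - e) - 0.5, 0.0) ** 2 / e for o, e in zip(observed, expected)
    )
    return GofResult(chi_square=stat, p_value=chi2_sf_1df(stat))


def format_p(p: float, threshold: float = 1e-5) -> str:
    """Display convention: five decimals, '<.00001' below the threshold."""
    if p < threshold:
        return "<.00001"
    return f"{p:.5f}"


def build_match_table(
    fb: Facebase,
    cfg: RankConfig = RankConfig(),
    null_mode: Literal["analytic-rounded", "analytic", "simulation"] = "analytic-rounded",
    n_reps: int = 10_000,
    seed: int = 0,
) -> list[MatchCountRow]:
    """Observed/expected match counts and GoF for every (cohort, k).

    ``analytic-rounded`` mirrors published-table arithmetic (integer
    expected cells); ``analytic`` keeps real-valued expectations;
    ``simulation`` estimates them by Monte-Carlo.
    """
    rows: list[MatchCountRow] = []
    for cohort in fb.syndrome_cohorts:
        observed_by_k = evaluate_cohort(fb, cohort, cfg)
        n_s = sum(observed_by_k[cfg.k_set[0]])
        for k in cfg.k_set:
            observed = observed_by_k[k]
            if null_mode == "simulation":
                est, _se = simulate_expected_counts(fb, cohort, k, n_reps, seed)
                expected: tuple[float, float] = (est, n_s - est)
            else:
                real, rounded = expected_counts(fb, cohort, k)
                expected = tuple(map(float, rounded)) if null_mode == "analytic-rounded" else real
            rows.append(
                MatchCountRow(
                    cohort=cohort,
                    n_images=n_s,
                    k=k,
                    observed=observed,
                    expected=expected,
                    gof=gof_or_none(observed, expected),
                )
            )
    return rows
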