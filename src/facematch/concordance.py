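"""Software-vs-clinician diagnostic concordance.

For each syndrome image two binary calls are paired: whether the software
placed a same-cohort image in the top k, and whether the clinician panel
"would have considered" the diagnosis under one of two rules
(at least two of three raters scoring 1, or all three scoring 1).  The
paired calls feed a 2x2 table whose discordant cells drive McNemar's test
(no continuity correction) and whose agreement is summarised by Cohen's
kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import ConfigError, ManifestError
from .facebase import Facebase
from .match_stats import chi2_sf_1df
from .ratings import VALID_SCORES, RatingTable
from .retrieval import RankedResult

__all__ = [
    "PairedTable",
    "ConcordanceResult",
    "ClinicianRule",
    "clinician_call",
    "software_call",
    "paired_table",
    "mcnemar_stat",
    "cohen_kappa",
    "concordance_table",
]

ClinicianRule = Literal["two_of_three_definite", "all_three_definite"]
RULES: tuple[str, ...] = ("two_of_three_definite", "all_three_definite")


@dataclass(frozen=True)
class PairedTable:
    """2x2 paired-outcome cells: correct by neither / both / one side only."""

    a_neither: int
    d_both: int
    b_software_only: int
    c_clinician_only: int

    def __post_init__(self) -> None:
        if min(self.a_neither, self.d_both, self.b_software_only, self.c_clinician_only) < 0:
            raise ConfigError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a_neither + self.d_both + self.b_software_only + self.c_clinician_only


@dataclass(frozen=True)
class ConcordanceResult:
    """McNemar statistic/p (None when undefined, i.e. b+c=0) and kappa."""

    mcnemar_stat: float | None
    p_value: float | None
    kappa: float


def clinician_call(
    scores: Sequence[int],
    rule: ClinicianRule = "two_of_three_definite",
    count_possible: bool = False,
) -> bool:
    """Panel-level call from the three rater scores.

    'Considered' means a score of 1 (definitely); with ``count_possible``
    a score of 3 (possibly) also counts — an alternative reading of
    'would have considered' kept behind this switch.
    """
    if len(scores) != 3 or any(s not in VALID_SCORES for s in scores):
        raise ConfigError(f"scores must be a triple from {{1,2,3}}, got {scores!r}")
    considered = {1, 3} if count_possible else {1}
    n_considered = sum(s in considered for s in scores)
    if rule == "two_of_three_definite":
        return n_considered >= 2
    if rule == "all_three_definite":
        return n_considered == 3
    raise ConfigError(f"unknown rule {rule!r}")


def software_call(result: RankedResult, k: int) -> bool:
    """The software 'made a diagnosis' iff the top-k same-cohort flag is set."""
    return result.flag(k)


def paired_table(
    software_calls: Sequence[bool], clinician_calls: Sequence[bool]
) -> PairedTable:
    """Tally aligned boolean call vectors into the four paired cells."""
    if len(software_calls) != len(clinician_calls):
        raise ConfigError(
            f"call vectors differ in length: {len(software_calls)} vs {len(clinician_calls)}"
        )
    a = d = b = c = 0
    for sw, cl in zip(software_calls, clinician_calls):
        if sw and cl:
            d += 1
        elif sw:
            b += 1
        elif cl:
            c += 1
        else:
            a += 1
    return PairedTable(a, d, b, c)


def mcnemar_stat(t: PairedTable) -> ConcordanceResult:
    """McNemar's test on the discordant cells, without continuity correction.

    Undefined (statistic and p reported as None, not an error) when both
    discordant cells are zero.
    """
    b, c = t.b_software_only, t.c_clinician_only
    if b + c == 0:
        return ConcordanceResult(None, None, cohen_kappa(t))
    stat = (b - c) ** 2 / (b + c)
    return ConcordanceResult(stat, chi2_sf_1df(stat), cohen_kappa(t))


def cohen_kappa(t: PairedTable) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) for the 2x2 table.

    When chance agreement is exactly 1 (both marginals fully degenerate in
    the same direction) observed agreement is also 1 and 0.0 is returned.
    """
    n = t.n
    if n == 0:
        raise ConfigError("empty table")
    p_o = (t.a_neither + t.d_both) / n
    p_sw = (t.b_software_only + t.d_both) / n
    p_cl = (t.c_clinician_only + t.d_both) / n
    p_e = p_sw * p_cl + (1 - p_sw) * (1 - p_cl)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1 - p_e)


def concordance_table(
    fb: Facebase,
    results_by_cohort: dict[str, list[RankedResult]],
    ratings: RatingTable,
    rule: ClinicianRule,
    k: int,
) -> dict[str, tuple[PairedTable, ConcordanceResult]]:
    """Per-cohort paired tables and concordance statistics for one (rule, k)."""
    out: dict[str, tuple[PairedTable, ConcordanceResult]] = {}
    for cohort, results in results_by_cohort.items():
        sw_calls: list[bool] = []
        cl_calls: list[bool] = []
        for res in results:
            if res.test_image_id not in ratings:
                raise ManifestError(
                    f"image {res.test_image_id!r} ({cohort}) has no clinician ratings"
                )
            sw_calls.append(software_call(res, k))
            cl_calls.append(clinician_call(ratings[res.test_image_id], rule))
        t = paired_table(sw_calls, cl_calls)
        out[cohort] = (t, mcnemar_stat(t))
    return out
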