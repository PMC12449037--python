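"""Disproportionality analysis: per-drug 2x2 tables and ROR-based signals.

For each suspected-drug ingredient, a 2x2 contingency table is built
against the whole report database:

    a = target-event reports with the target drug
    b = other-event reports with the target drug
    c = target-event reports with other drugs
    d = other-event reports with other drugs

The reporting odds ratio is ROR = (a/b)/(c/d) = ad/bc, with a 95%
confidence interval on the log scale,

    exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)),   z = 1.959964.

If any cell is zero the Haldane–Anscombe correction adds 0.5 to all four
cells before both the estimate and the interval are computed.  A safety
signal is declared when the lower CI bound exceeds 1.  Fisher's exact
two-sided p-value (point-probability rule) accompanies each signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .dictionary import TermDictionary, resolve_ingredient
from .errors import InconsistentTableError
from .report_io import ReportDatabase

Z95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cell counts of a drug-by-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InconsistentTableError(f"negative cell in {self.cells()}")
        if self.n == 0:
            raise InconsistentTableError("empty table")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.cells()) == 0


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool


@dataclass(frozen=True)
class SignalResult:
    """Per-ingredient disproportionality result."""

    atc5: str
    ingredient: str
    n_cases: int
    ror: float
    ci_low: float
    ci_high: float
    p_fisher: float
    corrected: bool
    signal: bool


def build_table(
    event_case_ids: set[str] | frozenset[str],
    drug_case_ids: set[str] | frozenset[str],
    total_n: int,
) -> ContingencyTable:
    """Cross-classify case-ID sets into the 2x2 cells.

    Each case counts once per (drug, event) pair regardless of how many
    drug or reaction records it carries — the inputs are sets of case IDs.
    """
    a = len(event_case_ids & drug_case_ids)
    b = len(drug_case_ids) - a
    c = len(event_case_ids) - a
    d = total_n - a - b - c
    if d < 0:
        raise InconsistentTableError(
            f"total_n={total_n} smaller than the union of the ID sets"
        )
    return ContingencyTable(a, b, c, d)


def ror_estimate(t: ContingencyTable) -> RorEstimate:
    """Reporting odds ratio with a log-scale Wald 95% CI.

    The Haldane–Anscombe correction (add 0.5 to every cell) is applied
    only when at least one cell is zero, and then both the estimate and
    the interval use the corrected cells — so no zero-cell table is ever a
    divide-by-zero.
    """
    corrected = t.has_zero_cell
    a, b, c, d = (x + 0.5 for x in t.cells()) if corrected else t.cells()
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = Z95 * se
    return RorEstimate(
        ror=ror,
        ci_low=math.exp(math.log(ror) - half),
        ci_high=math.exp(math.log(ror) + half),
        corrected=corrected,
    )


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value.

    Uses the point-probability rule: with margins fixed, sum the
    hypergeometric probabilities of every table whose point probability
    does not exceed that of the observed table (to within a small relative
    slack for floating-point ties).
    """
    p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    return min(float(p), 1.0)


def detect_signals(
    cohort_event_ids: set[str] | frozenset[str],
    db: ReportDatabase,
    dictionary: TermDictionary,
) -> list[SignalResult]:
    """ROR-based safety signals for every suspected drug in a cohort.

    Exposure means the case carries the ingredient with involvement
    ``suspected``; ingredients that resolve to no ATC 5th-level code are
    excluded from the tally.  The comparator (cells c/d) is the entire
    report database.  One result per ingredient with at least one exposed
    case inside the event cohort, sorted by case count descending then
    ingredient name.
    """
    event_ids = frozenset(cohort_event_ids)
    exposure: dict[str, set[str]] = {}
    for case in db.cases:
        for ing in case.suspected_ingredients():
            if resolve_ingredient(dictionary, ing):
                exposure.setdefault(ing, set()).add(case.case_id)

    results = []
    for ing in sorted(exposure):
        ids = exposure[ing]
        a = len(ids & event_ids)
        if a == 0:
            continue
        table = build_table(event_ids, ids, db.total_count)
        est = ror_estimate(table)
        results.append(
            SignalResult(
                atc5=", ".join(sorted(resolve_ingredient(dictionary, ing))),
                ingredient=ing,
                n_cases=a,
                ror=est.ror,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                p_fisher=fisher_exact_two_sided(table),
                corrected=est.corrected,
                signal=est.ci_low > 1.0,
            )
        )
    results.sort(key=lambda r: (-r.n_cases, r.ingredient))
    return results
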