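"""Group-contrast statistics between the KS and non-KS cohorts.

Three tabulations feed the univariate comparisons: the seven underlying-
disease flags plus fatal outcome; drug use aggregated at the ATC 2nd
level (suspected and concomitant drugs together); and the frequencies of
allergic/coronary PTs co-reported with the Kounis-syndrome PT.

Each feature is tested on its 2x2 group-by-feature table with Pearson's
chi-squared test without continuity correction, or with Fisher's exact
test when any expected cell count falls below 5.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .cohort import KS_PT, DEFAULT_SMQ_A, DEFAULT_SMQ_B, CohortLabel, included_cases
from .dictionary import (
    DiseaseFlagSet,
    TermDictionary,
    atc_truncate,
    classify_underlying_diseases,
    resolve_ingredient,
    smq_pts,
)
from .errors import DegenerateTableError
from .report_io import CaseReport
from .signals import ContingencyTable, fisher_exact_two_sided

ANY_LISTED_FEATURE = "any_listed_pt"


@dataclass(frozen=True)
class GroupCounts:
    """Numerator/denominator of one feature in each group."""

    feature: str
    x_ks: int
    n_ks: int
    x_nonks: int
    n_nonks: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_ks <= self.n_ks and 0 <= self.x_nonks <= self.n_nonks):
            raise ValueError(f"counts out of range for {self.feature!r}")

    def table(self) -> ContingencyTable:
        return ContingencyTable(
            self.x_ks, self.n_ks - self.x_ks, self.x_nonks, self.n_nonks - self.x_nonks
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Test choice and p-value for one feature."""

    feature: str
    test_used: str  # 'chi2' | 'fisher'
    statistic: float | None
    df: int | None
    p: float


def pearson_chi2(t: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1, upper-tail p.
    """
    a, b, c, d = t.cells()
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError(f"zero margin in {t.cells()}")
    n = t.n
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), 1, float(stats.chi2.sf(stat, 1))


def expected_cells(t: ContingencyTable) -> tuple[float, float, float, float]:
    a, b, c, d = t.cells()
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = t.n
    if n == 0:
        raise DegenerateTableError("empty table")
    return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


def choose_test(t: ContingencyTable, feature: str = "") -> ComparisonResult:
    """Chi-squared, or Fisher's exact test when any expected cell is < 5.

    The expected-count rule is evaluated on all four expected cells of the
    2x2 table.  Fisher results carry no statistic or df.
    """
    exp = expected_cells(t)
    if min(exp) < 5.0:
        return ComparisonResult(feature, "fisher", None, None, fisher_exact_two_sided(t))
    stat, df, p = pearson_chi2(t)
    return ComparisonResult(feature, "chi2", stat, df, p)


def compare_counts(gc: GroupCounts) -> ComparisonResult:
    """Test one feature's group contrast from its counts."""
    return choose_test(gc.table(), gc.feature)


def _split_groups(
    labelled: list[tuple[CaseReport, CohortLabel]],
) -> tuple[list[CaseReport], list[CaseReport]]:
    included = included_cases(labelled)
    ks = [case for case, lab in included if lab.group == "KS"]
    nonks = [case for case, lab in included if lab.group == "nonKS"]
    return ks, nonks


def tabulate_disease_and_death(
    labelled: list[tuple[CaseReport, CohortLabel]],
    dictionary: TermDictionary,
) -> list[GroupCounts]:
    """Seven underlying-disease prevalences plus fatal outcome, per group.

    Included cases always have a recorded history (missing histories are
    excluded upstream), so the flags are defined for every row.
    """
    ks, nonks = _split_groups(labelled)

    def flags_of(case: CaseReport) -> DiseaseFlagSet:
        return classify_underlying_diseases(dictionary, case.history or frozenset())

    ks_flags = [flags_of(c) for c in ks]
    nonks_flags = [flags_of(c) for c in nonks]
    rows = [
        GroupCounts(
            feature=f"disease_{name}",
            x_ks=sum(getattr(f, name) for f in ks_flags),
            n_ks=len(ks),
            x_nonks=sum(getattr(f, name) for f in nonks_flags),
            n_nonks=len(nonks),
        )
        for name in DiseaseFlagSet.FLAGS
    ]
    rows.append(
        GroupCounts(
            feature="death",
            x_ks=sum(c.died for c in ks),
            n_ks=len(ks),
            x_nonks=sum(c.died for c in nonks),
            n_nonks=len(nonks),
        )
    )
    return rows


def tabulate_atc2_use(
    labelled: list[tuple[CaseReport, CohortLabel]],
    dictionary: TermDictionary,
) -> list[GroupCounts]:
    """Medication use per ATC 2nd-level class, per group.

    Both suspected and concomitant drugs count; a case contributes at most
    once to a class however many of its members it took.  Ingredients with
    no ATC 5th-level code are excluded.
    """
    ks, nonks = _split_groups(labelled)

    def classes_of(case: CaseReport) -> frozenset[str]:
        out: set[str] = set()
        for ing in case.all_ingredients():
            for code in resolve_ingredient(dictionary, ing):
                out.add(atc_truncate(code, 2))
        return frozenset(out)

    ks_classes = [classes_of(c) for c in ks]
    nonks_classes = [classes_of(c) for c in nonks]
    present = sorted(set().union(*ks_classes, *nonks_classes, set()))
    return [
        GroupCounts(
            feature=f"atc2_{cls}",
            x_ks=sum(cls in s for s in ks_classes),
            n_ks=len(ks),
            x_nonks=sum(cls in s for s in nonks_classes),
            n_nonks=len(nonks),
        )
        for cls in present
    ]


def tabulate_copt_frequencies(
    labelled: list[tuple[CaseReport, CohortLabel]],
    dictionary: TermDictionary,
    *,
    smq_a: tuple[int, ...] = DEFAULT_SMQ_A,
    smq_b: tuple[int, ...] = DEFAULT_SMQ_B,
    ks_pt: int = KS_PT,
) -> list[GroupCounts]:
    """Frequencies of allergic/coronary PTs co-reported with the KS term.

    The candidate list is seeded from the KS group: an SMQ member PT
    (other than the KS term itself) qualifies when it co-occurs with the
    KS PT in at least one KS case.  Counts are cases reporting each PT,
    per group; a final row counts cases reporting at least one listed PT.
    """
    ks, nonks = _split_groups(labelled)
    smq_union = frozenset().union(
        *(smq_pts(dictionary, code) for code in (*smq_a, *smq_b))
    )
    candidates = sorted(
        set().union(*(c.reactions for c in ks), set()) & smq_union - {ks_pt}
    )
    rows = [
        GroupCounts(
            feature=f"pt_{pt}",
            x_ks=sum(pt in c.reactions for c in ks),
            n_ks=len(ks),
            x_nonks=sum(pt in c.reactions for c in nonks),
            n_nonks=len(nonks),
        )
        for pt in candidates
    ]
    listed = frozenset(candidates)
    rows.append(
        GroupCounts(
            feature=ANY_LISTED_FEATURE,
            x_ks=sum(bool(c.reactions & listed) for c in ks),
            n_ks=len(ks),
            x_nonks=sum(bool(c.reactions & listed) for c in nonks),
            n_nonks=len(nonks),
        )
    )
    return rows
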