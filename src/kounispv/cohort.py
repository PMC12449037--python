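"""Cohort selection: SMQ inclusion criteria, missing-data exclusion, and
KS / non-KS classification.

A case enters the cohort when it (a) reports at least one PT under the
anaphylactic-reaction or hypersensitivity SMQs and (b) reports at least one
PT under the myocardial-infarction SMQ, and is not excluded for missing
outcome or history data.  Included cases split on the presence of the
Kounis-syndrome PT — a term that belongs to all three SMQs, so it alone
satisfies both criteria.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .dictionary import TermDictionary, smq_pts
from .errors import FormatError
from .report_io import CaseReport, ReportDatabase

KS_PT = 10069167
DEFAULT_SMQ_A = (20000021, 20000214)  # anaphylactic reaction, hypersensitivity
DEFAULT_SMQ_B = (20000047,)  # myocardial infarction


@dataclass(frozen=True)
class CohortLabel:
    """Selection outcome for one case."""

    eligible_a: bool
    eligible_b: bool
    excluded_missing: bool
    group: str  # 'KS' | 'nonKS' | 'none'

    @property
    def included(self) -> bool:
        return self.group != "none"


@dataclass(frozen=True)
class AttritionTable:
    """Case counts at each step of the selection flow."""

    total: int
    n_criterion_a: int
    n_criterion_b: int
    n_both: int
    n_excluded: int
    n_final: int
    n_ks: int
    n_nonks: int

    def __post_init__(self) -> None:
        assert self.n_final == self.n_both - self.n_excluded
        assert self.n_final == self.n_ks + self.n_nonks


def label_case(
    case: CaseReport,
    dictionary: TermDictionary,
    *,
    smq_a: tuple[int, ...] = DEFAULT_SMQ_A,
    smq_b: tuple[int, ...] = DEFAULT_SMQ_B,
    ks_pt: int = KS_PT,
) -> CohortLabel:
    """Label one case against the inclusion/exclusion criteria.

    Depends only on the case's reaction set and its missingness flags, so
    labelling is idempotent.  Exclusion uses the four-table missing-data
    rule: outcome field empty or no history row at all.
    """
    pts_a = frozenset().union(*(smq_pts(dictionary, code) for code in smq_a))
    pts_b = frozenset().union(*(smq_pts(dictionary, code) for code in smq_b))
    eligible_a = bool(case.reactions & pts_a)
    eligible_b = bool(case.reactions & pts_b)
    excluded = case.outcome_missing or case.history_missing
    if eligible_a and eligible_b and not excluded:
        group = "KS" if ks_pt in case.reactions else "nonKS"
    else:
        group = "none"
    return CohortLabel(eligible_a, eligible_b, excluded, group)


def build_cohort(
    db: ReportDatabase,
    dictionary: TermDictionary,
    *,
    smq_a: tuple[int, ...] = DEFAULT_SMQ_A,
    smq_b: tuple[int, ...] = DEFAULT_SMQ_B,
    ks_pt: int = KS_PT,
) -> tuple[list[tuple[CaseReport, CohortLabel]], AttritionTable]:
    """Label every case and tally the attrition flow.

    Returns all cases (sorted by ``case_id``) with their labels; downstream
    stages filter on ``label.group``.  ``n_excluded`` counts cases meeting
    both criteria that fail the missing-data rule.
    """
    labelled = [
        (case, label_case(case, dictionary, smq_a=smq_a, smq_b=smq_b, ks_pt=ks_pt))
        for case in sorted(db.cases, key=lambda c: c.case_id)
    ]
    n_a = sum(1 for _, lab in labelled if lab.eligible_a)
    n_b = sum(1 for _, lab in labelled if lab.eligible_b)
    both = [lab for _, lab in labelled if lab.eligible_a and lab.eligible_b]
    n_both = len(both)
    n_excluded = sum(1 for lab in both if lab.excluded_missing)
    n_ks = sum(1 for _, lab in labelled if lab.group == "KS")
    n_nonks = sum(1 for _, lab in labelled if lab.group == "nonKS")
    attrition = AttritionTable(
        total=db.total_count,
        n_criterion_a=n_a,
        n_criterion_b=n_b,
        n_both=n_both,
        n_excluded=n_excluded,
        n_final=n_both - n_excluded,
        n_ks=n_ks,
        n_nonks=n_nonks,
    )
    return labelled, attrition


def included_cases(
    labelled: list[tuple[CaseReport, CohortLabel]],
) -> list[tuple[CaseReport, CohortLabel]]:
    """The final analytical cohort (both criteria met, nothing missing)."""
    return [(case, lab) for case, lab in labelled if lab.included]


_BAND_RE = re.compile(r"^(\d+)–(\d+) years$")
_OPEN_BAND_RE = re.compile(r"^≥(\d+) years$")


def dichotomize_age(age_band: str | None) -> tuple[bool | None, bool | None]:
    """Dichotomise a 10-year age band at 60 and at 70 years.

    Returns ``(age >= 60, age >= 70)``; missing bands propagate as
    ``(None, None)``.  Accepts an en dash or plain hyphen in the label.
    """
    if age_band is None:
        return (None, None)
    band = age_band.replace("-", "–")
    m = _BAND_RE.match(band)
    if m:
        lo = int(m.group(1))
    else:
        m = _OPEN_BAND_RE.match(band)
        if not m:
            raise FormatError(f"unrecognised age band {age_band!r}")
        lo = int(m.group(1))
    return (lo >= 60, lo >= 70)
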