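"""Read and write the four-table spontaneous-report database.

The layout mirrors the JADER structure: a demographics table (``demo``) with
one row per case, and three detail tables (``drug``, ``reac``, ``hist``)
linked to it by a shared ``case_id`` column.  Files are delimited text with
one header row; delimiter and encoding are configurable (the real PMDA
export is Shift-JIS CSV, the synthetic fixtures are UTF-8).

Missingness conventions
-----------------------
* ``outcomes`` empty  <=> clinical outcome not recorded.
* ``history is None`` <=> no ``hist`` row at all (history marked absent) —
  distinct from a recorded-but-empty history, which is encoded as a single
  ``hist`` row with a blank ``pt_code``.

Cases with either form of missing data are *kept* by the reader; exclusion
is a cohort-selection decision (see :mod:`kounispv.cohort`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DuplicateCaseError, FormatError

logger = logging.getLogger(__name__)

INVOLVEMENT_ROLES = ("suspected", "concomitant", "interaction")
SEXES = ("male", "female", "unknown")
DEATH_OUTCOME = "death"

_DEMO_COLS = ["case_id", "sex", "age_band", "height_band", "weight_band", "outcomes"]
_DRUG_COLS = ["case_id", "ingredient", "involvement"]
_REAC_COLS = ["case_id", "pt_code"]
_HIST_COLS = ["case_id", "pt_code"]


@dataclass(frozen=True)
class DrugRecord:
    """One per-case drug record: active ingredient plus involvement role."""

    ingredient: str
    involvement: str

    def __post_init__(self) -> None:
        if self.involvement not in INVOLVEMENT_ROLES:
            raise FormatError(
                f"involvement {self.involvement!r} not in {INVOLVEMENT_ROLES}"
            )


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous report, assembled from its four-table rows."""

    case_id: str
    sex: str = "unknown"
    age_band: str | None = None
    height_band: str | None = None
    weight_band: str | None = None
    outcomes: frozenset[str] = frozenset()
    drugs: tuple[DrugRecord, ...] = ()
    reactions: frozenset[int] = frozenset()
    history: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise FormatError("empty case_id")
        if self.sex not in SEXES:
            raise FormatError(f"sex {self.sex!r} not in {SEXES}")

    @property
    def died(self) -> bool:
        return DEATH_OUTCOME in self.outcomes

    @property
    def outcome_missing(self) -> bool:
        return len(self.outcomes) == 0

    @property
    def history_missing(self) -> bool:
        return self.history is None

    def suspected_ingredients(self) -> frozenset[str]:
        return frozenset(
            d.ingredient for d in self.drugs if d.involvement == "suspected"
        )

    def all_ingredients(self) -> frozenset[str]:
        return frozenset(d.ingredient for d in self.drugs)


@dataclass
class ReportDatabase:
    """A list of case reports with unique identifiers."""

    cases: list[CaseReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for cid in ids:
                if cid in seen:
                    raise DuplicateCaseError(f"duplicate case_id {cid!r}")
                seen.add(cid)

    @property
    def total_count(self) -> int:
        return len(self.cases)

    def by_id(self) -> dict[str, CaseReport]:
        return {c.case_id: c for c in self.cases}


def _read_table(path: str | Path, columns: list[str], delimiter: str, encoding: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=delimiter, encoding=encoding, dtype=str, keep_default_na=False
    )
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_database(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path,
    *,
    delimiter: str = ",",
    encoding: str = "utf-8",
) -> ReportDatabase:
    """Link the four tables into one :class:`ReportDatabase`.

    One case per ``demo`` row; detail rows attach by ``case_id``.  Detail
    rows whose ID is absent from ``demo`` are orphans: they are logged and
    dropped, and never change the number of cases.
    """
    demo = _read_table(demo_path, _DEMO_COLS, delimiter, encoding)
    drug = _read_table(drug_path, _DRUG_COLS, delimiter, encoding)
    reac = _read_table(reac_path, _REAC_COLS, delimiter, encoding)
    hist = _read_table(hist_path, _HIST_COLS, delimiter, encoding)

    dup = demo["case_id"][demo["case_id"].duplicated()]
    if len(dup):
        raise DuplicateCaseError(f"duplicate case_id in demo table: {dup.iloc[0]!r}")
    known = set(demo["case_id"])

    def _attach(df: pd.DataFrame, label: str) -> dict[str, list]:
        orphans = ~df["case_id"].isin(known)
        if orphans.any():
            logger.warning(
                "%s: dropped %d orphan row(s) with unknown case_id", label, int(orphans.sum())
            )
            df = df[~orphans]
        grouped: dict[str, list] = {}
        for row in df.itertuples(index=False):
            grouped.setdefault(row.case_id, []).append(row)
        return grouped

    drug_rows = _attach(drug, "drug")
    reac_rows = _attach(reac, "reac")
    hist_rows = _attach(hist, "hist")

    cases = []
    for row in demo.itertuples(index=False):
        cid = row.case_id
        outcomes = frozenset(x for x in row.outcomes.split(";") if x)
        drugs = tuple(
            DrugRecord(r.ingredient, r.involvement) for r in drug_rows.get(cid, [])
        )
        reactions = frozenset(
            int(r.pt_code) for r in reac_rows.get(cid, []) if r.pt_code
        )
        if cid in hist_rows:
            history: frozenset[int] | None = frozenset(
                int(r.pt_code) for r in hist_rows[cid] if r.pt_code
            )
        else:
            history = None
        cases.append(
            CaseReport(
                case_id=cid,
                sex=row.sex or "unknown",
                age_band=row.age_band or None,
                height_band=row.height_band or None,
                weight_band=row.weight_band or None,
                outcomes=outcomes,
                drugs=drugs,
                reactions=reactions,
                history=history,
            )
        )
    return ReportDatabase(cases)


def write_database(
    db: ReportDatabase,
    out_dir: str | Path,
    *,
    delimiter: str = ",",
    encoding: str = "utf-8",
) -> dict[str, Path]:
    """Emit the four-table layout the reader consumes.

    Row order is deterministic: cases sorted by ``case_id``; within a case,
    drug records keep their original order and PT codes are sorted.  A
    recorded-but-empty history becomes one ``hist`` row with a blank
    ``pt_code``; an absent history writes no row.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    for case in sorted(db.cases, key=lambda c: c.case_id):
        demo_rows.append(
            (
                case.case_id,
                case.sex,
                case.age_band or "",
                case.height_band or "",
                case.weight_band or "",
                ";".join(sorted(case.outcomes)),
            )
        )
        for d in case.drugs:
            drug_rows.append((case.case_id, d.ingredient, d.involvement))
        for pt in sorted(case.reactions):
            reac_rows.append((case.case_id, pt))
        if case.history is not None:
            if case.history:
                for pt in sorted(case.history):
                    hist_rows.append((case.case_id, pt))
            else:
                hist_rows.append((case.case_id, ""))
    paths = {
        "demo": out / "demo.csv",
        "drug": out / "drug.csv",
        "reac": out / "reac.csv",
        "hist": out / "hist.csv",
    }
    for key, rows, cols in (
        ("demo", demo_rows, _DEMO_COLS),
        ("drug", drug_rows, _DRUG_COLS),
        ("reac", reac_rows, _REAC_COLS),
        ("hist", hist_rows, _HIST_COLS),
    ):
        pd.DataFrame(rows, columns=cols).to_csv(
            paths[key], sep=delimiter, encoding=encoding, index=False
        )
    return paths
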