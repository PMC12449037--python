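"""Terminology layer: SMQ membership, a MedDRA-like term hierarchy, and ATC codes.

Every selection and classification rule in the pipeline is written against
this layer.  A :class:`TermDictionary` holds

* per-PT hierarchy records (PT -> HLT -> HLGT -> SOC),
* flat SMQ membership sets (SMQ code -> set of PT codes), and
* an ingredient -> ATC 5th-level code mapping.

Licensed MedDRA/WHO-ATC distributions are deliberately out of scope: the
dictionary is loaded from a plain-text three-file bundle (``pt.tsv``,
``smq.tsv``, ``atc.tsv``) and the package ships only synthetic dictionaries
built in code (see :func:`kounispv.synthetic.default_dictionary`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, UnknownSMQError

logger = logging.getLogger(__name__)

ATC5_PATTERN = re.compile(r"^[A-Z]\d\d[A-Z][A-Z]\d\d$")

# MedDRA codes the disease-flag definitions are written against.
PT_HYPERTENSION = 10020772
PT_ESSENTIAL_HYPERTENSION = 10015488
SOC_NEOPLASMS = 10029104
HLGT_MALIGNANT_NEOPLASMS = 10010331
SOC_CARDIAC = 10007541
HLT_DIABETES = 10012602
HLT_RENAL_FAILURE = 10038443
SOC_IMMUNE = 10021428
HLGT_ALLERGIC_CONDITIONS = 10001708
SOC_METABOLISM = 10027433
HLGT_LIPID_DISORDERS = 10013317


@dataclass(frozen=True)
class PTRecord:
    """One preferred term with its position in the hierarchy."""

    code: int
    name: str
    hlt: int
    hlgt: int
    soc: int

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError(f"PT {self.code}: empty name")


@dataclass
class TermDictionary:
    """SMQ membership plus hierarchy and ingredient->ATC maps."""

    pt_records: dict[int, PTRecord]
    smq_members: dict[int, frozenset[int]]
    ingredient_atc: dict[str, frozenset[str]]
    hlt_names: dict[int, str] = field(default_factory=dict)
    hlgt_names: dict[int, str] = field(default_factory=dict)
    soc_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.smq_members = {k: frozenset(v) for k, v in self.smq_members.items()}
        self.ingredient_atc = {
            k: frozenset(v) for k, v in self.ingredient_atc.items()
        }
        for smq, members in self.smq_members.items():
            missing = members - self.pt_records.keys()
            if missing:
                raise FormatError(
                    f"SMQ {smq} references PTs absent from pt_records: "
                    f"{sorted(missing)}"
                )
        for ingredient, codes in self.ingredient_atc.items():
            for code in codes:
                if not ATC5_PATTERN.match(code):
                    raise FormatError(
                        f"ingredient {ingredient!r}: malformed ATC5 code {code!r}"
                    )

    def pt_name(self, code: int) -> str:
        return self.pt_records[code].name


@dataclass(frozen=True)
class DiseaseFlagSet:
    """The seven underlying-disease indicators used for group comparisons.

    Flags are independent: a single history may set several.
    """

    hypertension: bool = False
    malignancy: bool = False
    cardiac: bool = False
    diabetes: bool = False
    renal: bool = False
    allergy: bool = False
    lipid: bool = False

    FLAGS = (
        "hypertension",
        "malignancy",
        "cardiac",
        "diabetes",
        "renal",
        "allergy",
        "lipid",
    )

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in self.FLAGS}

    def __or__(self, other: "DiseaseFlagSet") -> "DiseaseFlagSet":
        return DiseaseFlagSet(
            **{k: getattr(self, k) or getattr(other, k) for k in self.FLAGS}
        )


def smq_pts(dictionary: TermDictionary, smq_code: int) -> frozenset[int]:
    """Full PT membership of one SMQ (flat, no narrow/broad scoping).

    Raises :class:`UnknownSMQError` for codes the dictionary does not define:
    a missing SMQ always signals a dictionary/fixture mismatch, never an
    empty query.
    """
    try:
        return dictionary.smq_members[smq_code]
    except KeyError:
        raise UnknownSMQError(
            f"SMQ {smq_code} not defined in dictionary "
            f"(known: {sorted(dictionary.smq_members)})"
        ) from None


def classify_underlying_diseases(
    dictionary: TermDictionary, history_pts: set[int] | frozenset[int]
) -> DiseaseFlagSet:
    """Map a case's history PTs onto the seven underlying-disease flags.

    Hypertension is keyed to two explicit PTs; the remaining six flags are
    membership tests on the hierarchy (SOC, HLT, or SOC+HLGT).  PTs that do
    not resolve in the dictionary are ignored — spontaneous-report histories
    are dirty and the selection rules are inclusion-based — but counted via
    :func:`count_unknown_pts` for pipeline logging.
    """
    flags = dict.fromkeys(DiseaseFlagSet.FLAGS, False)
    for pt in history_pts:
        if pt in (PT_HYPERTENSION, PT_ESSENTIAL_HYPERTENSION):
            flags["hypertension"] = True
        rec = dictionary.pt_records.get(pt)
        if rec is None:
            logger.debug("history PT %s not in dictionary; ignored", pt)
            continue
        if rec.soc == SOC_NEOPLASMS and rec.hlgt == HLGT_MALIGNANT_NEOPLASMS:
            flags["malignancy"] = True
        if rec.soc == SOC_CARDIAC:
            flags["cardiac"] = True
        if rec.hlt == HLT_DIABETES:
            flags["diabetes"] = True
        if rec.hlt == HLT_RENAL_FAILURE:
            flags["renal"] = True
        if rec.soc == SOC_IMMUNE and rec.hlgt == HLGT_ALLERGIC_CONDITIONS:
            flags["allergy"] = True
        if rec.soc == SOC_METABOLISM and rec.hlgt == HLGT_LIPID_DISORDERS:
            flags["lipid"] = True
    return DiseaseFlagSet(**flags)


def count_unknown_pts(
    dictionary: TermDictionary, pts: set[int] | frozenset[int]
) -> int:
    """Number of PTs in ``pts`` that the dictionary cannot resolve."""
    return sum(1 for pt in pts if pt not in dictionary.pt_records)


def atc_truncate(code: str, level: int) -> str:
    """Truncate an ATC 5th-level code to the requested classification level.

    Level 5 is the 7-character chemical-substance code (identity); level 2
    is the 3-character therapeutic class (e.g. ``B01AB01`` -> ``B01``).
    """
    if not ATC5_PATTERN.match(code):
        raise FormatError(f"malformed ATC5 code {code!r}")
    if level == 5:
        return code
    if level == 2:
        return code[:3]
    raise FormatError(f"unsupported ATC level {level!r}; use 2 or 5")


def resolve_ingredient(dictionary: TermDictionary, ingredient: str) -> frozenset[str]:
    """ATC 5th-level codes for an active ingredient.

    An empty set means the drug is not classifiable at the 5th level and is
    excluded from ATC-level tallies.  Ingredients with several codes (e.g.
    epinephrine) keep the ingredient name as the aggregation key.
    """
    return dictionary.ingredient_atc.get(ingredient, frozenset())


# ---------------------------------------------------------------------------
# plain-text bundle I/O


def load_dictionary(
    pt_path: str | Path, smq_path: str | Path, atc_path: str | Path
) -> TermDictionary:
    """Load a dictionary bundle from its three tab-separated files.

    ``pt.tsv``: pt_code, pt_name, hlt_code, hlgt_code, soc_code;
    ``smq.tsv``: smq_code, pt_code; ``atc.tsv``: ingredient, atc5_code.
    """
    pt_df = pd.read_csv(pt_path, sep="\t", dtype=str, keep_default_na=False)
    smq_df = pd.read_csv(smq_path, sep="\t", dtype=str, keep_default_na=False)
    atc_df = pd.read_csv(atc_path, sep="\t", dtype=str, keep_default_na=False)
    for df, cols, path in (
        (pt_df, ["pt_code", "pt_name", "hlt_code", "hlgt_code", "soc_code"], pt_path),
        (smq_df, ["smq_code", "pt_code"], smq_path),
        (atc_df, ["ingredient", "atc5_code"], atc_path),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")

    pt_records: dict[int, PTRecord] = {}
    for row in pt_df.itertuples(index=False):
        code = int(row.pt_code)
        if code in pt_records:
            raise FormatError(f"duplicate PT code {code} in {pt_path}")
        pt_records[code] = PTRecord(
            code, row.pt_name, int(row.hlt_code), int(row.hlgt_code), int(row.soc_code)
        )
    smq_members: dict[int, set[int]] = {}
    for row in smq_df.itertuples(index=False):
        smq_members.setdefault(int(row.smq_code), set()).add(int(row.pt_code))
    ingredient_atc: dict[str, set[str]] = {}
    for row in atc_df.itertuples(index=False):
        ingredient_atc.setdefault(row.ingredient, set()).add(row.atc5_code)
    return TermDictionary(
        pt_records,
        {k: frozenset(v) for k, v in smq_members.items()},
        {k: frozenset(v) for k, v in ingredient_atc.items()},
    )


def write_dictionary(dictionary: TermDictionary, out_dir: str | Path) -> dict[str, Path]:
    """Write the three-file bundle consumed by :func:`load_dictionary`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pt": out / "pt.tsv",
        "smq": out / "smq.tsv",
        "atc": out / "atc.tsv",
    }
    pd.DataFrame(
        [
            (r.code, r.name, r.hlt, r.hlgt, r.soc)
            for r in sorted(dictionary.pt_records.values(), key=lambda r: r.code)
        ],
        columns=["pt_code", "pt_name", "hlt_code", "hlgt_code", "soc_code"],
    ).to_csv(paths["pt"], sep="\t", index=False)
    pd.DataFrame(
        [
            (smq, pt)
            for smq in sorted(dictionary.smq_members)
            for pt in sorted(dictionary.smq_members[smq])
        ],
        columns=["smq_code", "pt_code"],
    ).to_csv(paths["smq"], sep="\t", index=False)
    pd.DataFrame(
        [
            (ing, code)
            for ing in sorted(dictionary.ingredient_atc)
            for code in sorted(dictionary.ingredient_atc[ing])
        ],
        columns=["ingredient", "atc5_code"],
    ).to_csv(paths["atc"], sep="\t", index=False)
    return paths
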