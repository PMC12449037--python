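"""Synthetic JADER-shaped databases with known ground truth.

The generator emulates the features of a spontaneous-report database that
the downstream stages depend on: the case-linked four-table structure,
multi-PT and multi-drug cases, suspected vs concomitant involvement,
categorical age/height/weight bands with heavy missingness, a binary fatal
outcome, and drug–event pairs with a configurable planted reporting odds
ratio.  Default condition values (group sizes, prevalences, death rates,
band distributions) mirror the published cohort structure of allergy-
associated coronary events: ~53% of eligible cases carry the Kounis-
syndrome PT, the non-KS group has markedly higher mortality (32% vs 5%)
and distinct drug-class use, and roughly a third of eligible cases have
missing outcome or history data.

It does *not* emulate reporting bias, duplicate reports, or temporal
(quarterly) structure.

The planting scheme samples each drug–event pair from the unique 2x2 joint
distribution with the requested margins and odds ratio
(:func:`solve_joint`); non-signal pairs are independent (true ROR 1).  All
randomness flows through one ``numpy`` generator keyed by the seed, with
draws made in a fixed order, so identical configurations give byte-
identical databases.

All dictionary entries built here reuse the genuine MedDRA/ATC codes that
appear in published tables where available; codes at or above 90000000 are
synthetic stand-ins for terms whose real codes are licensed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dictionary import (
    HLGT_ALLERGIC_CONDITIONS,
    HLGT_LIPID_DISORDERS,
    HLGT_MALIGNANT_NEOPLASMS,
    HLT_DIABETES,
    HLT_RENAL_FAILURE,
    PT_ESSENTIAL_HYPERTENSION,
    PT_HYPERTENSION,
    SOC_CARDIAC,
    SOC_IMMUNE,
    SOC_METABOLISM,
    SOC_NEOPLASMS,
    DiseaseFlagSet,
    PTRecord,
    TermDictionary,
)
from .errors import InfeasibleConfigError
from .report_io import CaseReport, DrugRecord, ReportDatabase

# Cohort-defining codes.
KS_PT = 10069167
SMQ_ANAPHYLACTIC = 20000021
SMQ_HYPERSENSITIVITY = 20000214
SMQ_MI = 20000047

# Synthetic generic qualifying PTs for eligible non-KS cases.
PT_ALLERGIC_REACTION_SYN = 90000101
PT_MI = 10028596

# Synthetic event PTs reserved for planted drug–event signals (not in any SMQ).
SIGNAL_EVENT_PTS = (93000001, 93000002, 93000003, 93000004)

AGE_BANDS = (
    "0–9 years",
    "10–19 years",
    "20–29 years",
    "30–39 years",
    "40–49 years",
    "50–59 years",
    "60–69 years",
    "70–79 years",
    "80–89 years",
    "≥90 years",
)
# Pooled cohort age distribution over the ten bands.
AGE_PROBS = (0.004, 0.033, 0.016, 0.004, 0.045, 0.152, 0.274, 0.315, 0.127, 0.030)

HEIGHT_BANDS = tuple(f"{lo}–{lo + 9}cm" for lo in range(130, 190, 10))
HEIGHT_PROBS = (0.021, 0.064, 0.309, 0.404, 0.191, 0.011)
WEIGHT_BANDS = tuple(f"{lo}–{lo + 9}kg" for lo in range(30, 110, 10))
WEIGHT_PROBS = (0.060, 0.140, 0.280, 0.300, 0.160, 0.030, 0.010, 0.020)

# Co-reported allergic/coronary PTs and their per-group carriage
# probabilities (KS group of 130, non-KS group of 115).
COPT_PROBS: dict[int, tuple[float, float]] = {
    10002388: (1 / 130, 3 / 115),  # Angina unstable
    10051592: (5 / 130, 15 / 115),  # Acute coronary syndrome
    10016029: (1 / 130, 2 / 115),  # Face oedema
    10058269: (1 / 130, 2 / 115),  # Troponin T increased
    10020751: (2 / 130, 5 / 115),  # Hypersensitivity
    10046735: (2 / 130, 0.0),  # Urticaria
    10013700: (1 / 130, 1 / 115),  # Drug hypersensitivity
    10037844: (2 / 130, 11 / 115),  # Rash
    10066973: (2 / 130, 0.0),  # Contrast media allergy
    10055048: (1 / 130, 0.0),  # Allergy to vaccine
    10062506: (1 / 130, 41 / 115),  # Heparin-induced thrombocytopenia
    10040560: (2 / 130, 17 / 115),  # Shock
    10002199: (32 / 130, 18 / 115),  # Anaphylactic shock
    10002198: (17 / 130, 5 / 115),  # Anaphylactic reaction
    10045240: (1 / 130, 0.0),  # Type I hypersensitivity
}

DISEASE_PREVALENCE: dict[str, dict[str, float]] = {
    "KS": {
        "hypertension": 31 / 130,
        "malignancy": 32 / 130,
        "cardiac": 41 / 130,
        "diabetes": 12 / 130,
        "renal": 5 / 130,
        "allergy": 14 / 130,
        "lipid": 12 / 130,
    },
    "nonKS": {
        "hypertension": 38 / 115,
        "malignancy": 31 / 115,
        "cardiac": 54 / 115,
        "diabetes": 24 / 115,
        "renal": 7 / 115,
        "allergy": 2 / 115,
        "lipid": 17 / 115,
    },
    "background": {
        "hypertension": 0.15,
        "malignancy": 0.08,
        "cardiac": 0.10,
        "diabetes": 0.08,
        "renal": 0.03,
        "allergy": 0.03,
        "lipid": 0.08,
    },
}

ATC2_USE: dict[str, dict[str, float]] = {
    "KS": {
        "B01": 19 / 130,
        "C01": 16 / 130,
        "C07": 6 / 130,
        "C09": 1 / 130,
        "J01": 34 / 130,
        "L01": 4 / 130,
        "L04": 2 / 130,
        "M01": 12 / 130,
        "N01": 27 / 130,
        "N02": 11 / 130,
        "V08": 34 / 130,
    },
    "nonKS": {
        "B01": 57 / 115,
        "C01": 3 / 115,
        "C07": 2 / 115,
        "C09": 5 / 115,
        "J01": 6 / 115,
        "L01": 22 / 115,
        "L04": 0.0,
        "M01": 4 / 115,
        "N01": 2 / 115,
        "N02": 3 / 115,
        "V08": 7 / 115,
    },
}

# One representative ingredient list per therapeutic class used above.
CLASS_INGREDIENTS: dict[str, tuple[str, ...]] = {
    "B01": ("Heparin",),
    "C01": ("Lidocaine", "Nicorandil"),
    "C07": ("Propranolol",),
    "C09": ("Candesartan",),
    "J01": ("Cefazolin", "Clarithromycin"),
    "L01": ("Ipilimumab", "Regorafenib"),
    "L04": ("Pomalidomide",),
    "M01": ("Ibuprofen",),
    "N01": ("Propofol", "Sevoflurane"),
    "N02": ("Morphine",),
    "V08": ("Iopamidol", "Iohexol"),
}

DEATH_PROB = {"KS": 7 / 130, "nonKS": 37 / 115, "background": 0.05}

BACKGROUND_PTS = tuple(range(92000001, 92000013))


def default_dictionary() -> TermDictionary:
    """The synthetic terminology bundle used by the generator.

    SMQ membership is flat (no narrow/broad scope) and restricted to the
    PTs a published cohort of this kind names, plus two generic qualifying
    terms; hierarchy placements are faithful where the real SOC/HLGT/HLT
    codes are known and synthetic (>= 90000000) otherwise.
    """
    hlt_allergic, hlgt_skin, soc_skin = 90001001, 91000002, 91000001
    hlt_skin = 91000003
    hlgt_cardiac, hlt_coronary, hlt_cardiac_hist = 90002001, 90002002, 90002003
    soc_invest, hlgt_invest, hlt_invest = 91000010, 91000011, 91000012
    soc_blood, hlgt_blood, hlt_blood = 91000020, 91000021, 91000022
    soc_general, hlgt_general, hlt_general = 91000030, 91000031, 91000032
    hlt_background = 91000033
    soc_vascular, hlgt_vascular, hlt_vascular = 91000040, 91000041, 91000042
    soc_renal_syn = 91000050

    def _pt(code, name, hlt, hlgt, soc):
        return PTRecord(code, name, hlt, hlgt, soc)

    records = [
        # allergic / immune reaction terms
        _pt(10002198, "Anaphylactic reaction", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(10002199, "Anaphylactic shock", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(10045240, "Type I hypersensitivity", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(10020751, "Hypersensitivity", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(10013700, "Drug hypersensitivity", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(10066973, "Contrast media allergy", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(10055048, "Allergy to vaccine", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(PT_ALLERGIC_REACTION_SYN, "Allergic reaction (synthetic)", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        # skin terms
        _pt(10037844, "Rash", hlt_skin, hlgt_skin, soc_skin),
        _pt(10046735, "Urticaria", hlt_skin, hlgt_skin, soc_skin),
        _pt(10016029, "Face oedema", hlt_skin, hlgt_skin, soc_skin),
        # coronary terms
        _pt(KS_PT, "Kounis syndrome", hlt_coronary, hlgt_cardiac, SOC_CARDIAC),
        _pt(10051592, "Acute coronary syndrome", hlt_coronary, hlgt_cardiac, SOC_CARDIAC),
        _pt(10002388, "Angina unstable", hlt_coronary, hlgt_cardiac, SOC_CARDIAC),
        _pt(PT_MI, "Myocardial infarction", hlt_coronary, hlgt_cardiac, SOC_CARDIAC),
        _pt(10058269, "Troponin T increased", hlt_invest, hlgt_invest, soc_invest),
        _pt(10062506, "Heparin-induced thrombocytopenia", hlt_blood, hlgt_blood, soc_blood),
        _pt(10040560, "Shock", hlt_general, hlgt_general, soc_general),
        # history terms driving the seven disease flags
        _pt(PT_HYPERTENSION, "Hypertension", hlt_vascular, hlgt_vascular, soc_vascular),
        _pt(PT_ESSENTIAL_HYPERTENSION, "Essential hypertension", hlt_vascular, hlgt_vascular, soc_vascular),
        _pt(90000011, "Malignant neoplasm (synthetic)", 90000021, HLGT_MALIGNANT_NEOPLASMS, SOC_NEOPLASMS),
        _pt(90000012, "Cardiac disorder (synthetic)", hlt_cardiac_hist, hlgt_cardiac, SOC_CARDIAC),
        _pt(90000013, "Diabetes mellitus (synthetic)", HLT_DIABETES, 90000022, SOC_METABOLISM),
        _pt(90000014, "Renal failure (synthetic)", HLT_RENAL_FAILURE, 90000023, soc_renal_syn),
        _pt(90000015, "Allergic condition history (synthetic)", hlt_allergic, HLGT_ALLERGIC_CONDITIONS, SOC_IMMUNE),
        _pt(90000016, "Lipid metabolism disorder (synthetic)", 90000024, HLGT_LIPID_DISORDERS, SOC_METABOLISM),
        # planted-signal event terms (outside every SMQ)
        _pt(SIGNAL_EVENT_PTS[0], "Coronary vasospasm (synthetic)", hlt_coronary, hlgt_cardiac, SOC_CARDIAC),
        _pt(SIGNAL_EVENT_PTS[1], "Palpitations (synthetic)", hlt_cardiac_hist, hlgt_cardiac, SOC_CARDIAC),
        _pt(SIGNAL_EVENT_PTS[2], "Dizziness (synthetic)", hlt_general, hlgt_general, soc_general),
        _pt(SIGNAL_EVENT_PTS[3], "Nausea (synthetic)", hlt_general, hlgt_general, soc_general),
    ]
    records += [
        _pt(code, f"Background event {i:02d} (synthetic)", hlt_background, hlgt_general, soc_general)
        for i, code in enumerate(BACKGROUND_PTS, start=1)
    ]

    smq_members = {
        SMQ_ANAPHYLACTIC: frozenset({KS_PT, 10002198, 10002199, 10045240}),
        SMQ_HYPERSENSITIVITY: frozenset(
            {
                KS_PT,
                10020751,
                10013700,
                10046735,
                10037844,
                10016029,
                10066973,
                10055048,
                10040560,
                PT_ALLERGIC_REACTION_SYN,
            }
        ),
        SMQ_MI: frozenset({KS_PT, 10051592, 10002388, 10058269, 10062506, PT_MI}),
    }

    ingredient_atc = {
        "Iopamidol": {"V08AB04"},
        "Iohexol": {"V08AB02"},
        "Sugammadex": {"V03AB35"},
        "Propofol": {"N01AX10"},
        "Sevoflurane": {"N01AB08"},
        "Rocuronium bromide": {"M03AC09"},
        "Fentanyl": {"N01AH01", "N02AB03"},
        "Morphine": {"N02AA01"},
        "Cefazolin": {"J01DB04"},
        "Clarithromycin": {"J01FA09"},
        "Heparin": {"B01AB01"},
        "Covid-19 RNA vaccine": {"J07BN01"},
        "Ipilimumab": {"L01FX04"},
        "Regorafenib": {"L01EX05"},
        "Pomalidomide": {"L04AX06"},
        "Eltrombopag": {"B02BX05"},
        "Lidocaine": {"C01BB01"},
        "Nicorandil": {"C01DX16"},
        "Epinephrine": {
            "A01AD01",
            "B02BC09",
            "C01CA24",
            "R01AA14",
            "R03AA01",
            "S01EA01",
        },
        "Propranolol": {"C07AA05"},
        "Candesartan": {"C09CA06"},
        "Ibuprofen": {"M01AE01"},
        # deliberately unmapped: exercises the ATC-exclusion rule
        # (an empty mapping would be rejected; absence from the map is the rule)
    }

    return TermDictionary(
        pt_records={r.code: r for r in records},
        smq_members=smq_members,
        ingredient_atc={k: frozenset(v) for k, v in ingredient_atc.items()},
    )


# ---------------------------------------------------------------------------
# 2x2 joint distribution with fixed margins and odds ratio


def solve_joint(
    p_drug: float, p_event: float, odds_ratio: float
) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of the unique 2x2 joint
    distribution with margins ``p_drug``, ``p_event`` and the requested
    odds ratio.

    The odds-ratio constraint ``p11*p00 = OR * p10*p01`` reduces to a
    quadratic in ``p11``; exactly one root lies in the Frechet interval
    ``[max(0, p1+p2-1), min(p1, p2)]`` for OR > 0.
    """
    if not (0.0 < p_drug < 1.0 and 0.0 < p_event < 1.0):
        raise InfeasibleConfigError(
            f"margins must lie strictly in (0,1); got ({p_drug}, {p_event})"
        )
    if not odds_ratio > 0.0:
        raise InfeasibleConfigError(f"odds ratio must be positive; got {odds_ratio}")
    p1, p2, theta = p_drug, p_event, odds_ratio
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if abs(theta - 1.0) < 1e-12:
        p11 = p1 * p2
    else:
        a = 1.0 - theta
        b = 1.0 + (theta - 1.0) * (p1 + p2)
        c = -theta * p1 * p2
        disc = math.sqrt(b * b - 4.0 * a * c)
        roots = [(-b + disc) / (2.0 * a), (-b - disc) / (2.0 * a)]
        feasible = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
        if not feasible:  # pragma: no cover - cannot occur for valid input
            raise InfeasibleConfigError(
                f"no feasible joint for margins ({p1}, {p2}) and OR {theta}"
            )
        p11 = min(max(feasible[0], lo), hi)
    p10, p01 = p1 - p11, p2 - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = (p11, p10, p01, p00)
    if any(p < -1e-12 for p in cells):  # pragma: no cover
        raise InfeasibleConfigError(f"negative cell in solved joint: {cells}")
    return tuple(max(p, 0.0) for p in cells)  # type: ignore[return-value]


def sample_signal_counts(
    p_drug: float,
    p_event: float,
    target_ror: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Realised (a, b, c, d) counts for one planted drug–event pair.

    Multinomial sampling over the :func:`solve_joint` cells — exactly the
    per-case planting distribution, aggregated to counts.  Used for large
    repeated-seed recovery studies where the full database is not needed.
    """
    cells = solve_joint(p_drug, p_event, target_ror)
    a, b, c, d = rng.multinomial(n, cells)
    return int(a), int(b), int(c), int(d)


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass(frozen=True)
class PlantedSignal:
    """One drug–event pair with a known reporting odds ratio."""

    ingredient: str
    event_pts: frozenset[int]
    target_ror: float
    p_drug: float = 0.02
    p_event: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_pts", frozenset(self.event_pts))
        if self.target_ror <= 0:
            raise InfeasibleConfigError("target ROR must be positive")


def _default_signals() -> tuple[PlantedSignal, ...]:
    return (
        PlantedSignal("Sugammadex", frozenset({SIGNAL_EVENT_PTS[0]}), 4.0),
        PlantedSignal("Eltrombopag", frozenset({SIGNAL_EVENT_PTS[1]}), 1.0),
    )


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic database.

    Probabilities are per case; ``cohort_fraction`` is the probability a
    case qualifies for the allergy+coronary cohort, and ``ks_fraction`` the
    probability an eligible case carries the Kounis-syndrome PT.
    """

    n_cases: int = 20000
    seed: int = 0
    cohort_fraction: float = 0.02
    ks_fraction: float = 0.53
    death_prob: dict[str, float] = field(default_factory=lambda: dict(DEATH_PROB))
    disease_prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DISEASE_PREVALENCE.items()}
    )
    atc2_use: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in ATC2_USE.items()}
    )
    copt_prob: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(COPT_PROBS)
    )
    planted_signals: tuple[PlantedSignal, ...] = field(default_factory=_default_signals)
    missing_age: float = 1 / 245
    missing_height: float = 0.60
    missing_weight: float = 0.58
    missing_history: float = 0.20
    missing_outcome: float = 0.15
    background_drug_prob: float = 0.30

    def validate(self) -> None:
        if self.n_cases < 1:
            raise InfeasibleConfigError("n_cases must be >= 1")
        probs = [
            self.cohort_fraction,
            self.ks_fraction,
            self.missing_age,
            self.missing_height,
            self.missing_weight,
            self.missing_history,
            self.missing_outcome,
            self.background_drug_prob,
            *self.death_prob.values(),
        ]
        probs += [p for g in self.disease_prevalence.values() for p in g.values()]
        probs += [p for g in self.atc2_use.values() for p in g.values()]
        probs += [p for pair in self.copt_prob.values() for p in pair]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise InfeasibleConfigError("all probabilities must lie in [0, 1]")
        cohort_ings = {i for members in CLASS_INGREDIENTS.values() for i in members}
        for s in self.planted_signals:
            solve_joint(s.p_drug, s.p_event, s.target_ror)  # raises if infeasible
            if s.ingredient in cohort_ings:
                raise InfeasibleConfigError(
                    f"planted ingredient {s.ingredient!r} collides with the "
                    "cohort drug catalogue; exposure counts would be confounded"
                )


@dataclass(frozen=True)
class SignalTruth:
    """Realised cells and odds ratio of one planted drug–event pair."""

    ingredient: str
    event_pts: frozenset[int]
    target_ror: float
    a: int
    b: int
    c: int
    d: int

    @property
    def realized_ror(self) -> float:
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


@dataclass(frozen=True)
class CaseTruth:
    """Generative labels for one case."""

    eligible: bool
    ks: bool
    excluded_missing: bool
    group: str  # 'KS' | 'nonKS' | 'none'
    flags: DiseaseFlagSet
    died: bool


@dataclass
class GroundTruth:
    signals: list[SignalTruth]
    cases: dict[str, CaseTruth]

    @property
    def n_ks(self) -> int:
        return sum(1 for t in self.cases.values() if t.group == "KS")

    @property
    def n_nonks(self) -> int:
        return sum(1 for t in self.cases.values() if t.group == "nonKS")


# ---------------------------------------------------------------------------
# generation


def generate(
    config: GeneratorConfig, dictionary: TermDictionary | None = None
) -> tuple[ReportDatabase, GroundTruth]:
    """Generate one database and its ground truth.

    Deterministic given ``config.seed``: every random quantity is drawn
    from a single stream in a fixed vectorised order before cases are
    assembled.
    """
    config.validate()
    d = dictionary if dictionary is not None else default_dictionary()
    n = config.n_cases
    rng = np.random.default_rng(config.seed)

    # --- fixed-order vectorised draws -------------------------------------
    eligible = rng.random(n) < config.cohort_fraction
    ks_draw = rng.random(n) < config.ks_fraction
    sex = rng.choice(np.array(["male", "female", "unknown"]), n, p=[0.69, 0.30, 0.01])
    age_idx = rng.choice(len(AGE_BANDS), n, p=AGE_PROBS)
    height_idx = rng.choice(len(HEIGHT_BANDS), n, p=HEIGHT_PROBS)
    weight_idx = rng.choice(len(WEIGHT_BANDS), n, p=WEIGHT_PROBS)
    miss_age = rng.random(n) < config.missing_age
    miss_height = rng.random(n) < config.missing_height
    miss_weight = rng.random(n) < config.missing_weight
    miss_hist = rng.random(n) < config.missing_history
    miss_outcome = rng.random(n) < config.missing_outcome
    death_u = rng.random(n)
    disease_u = rng.random((n, len(DiseaseFlagSet.FLAGS)))
    copt_codes = sorted(config.copt_prob)
    copt_u = rng.random((n, len(copt_codes)))
    atc2_classes = sorted(set(config.atc2_use.get("KS", {})) | set(config.atc2_use.get("nonKS", {})))
    atc2_u = rng.random((n, len(atc2_classes)))
    atc2_pick = rng.integers(0, 1 << 16, size=(n, len(atc2_classes)))
    atc2_suspected = rng.random((n, len(atc2_classes))) < 0.5
    n_bg_reac = 1 + rng.poisson(0.5, n)
    bg_reac_pick = rng.integers(0, len(BACKGROUND_PTS), size=(n, int(n_bg_reac.max())))
    bg_drug = rng.random(n) < config.background_drug_prob
    # planted ingredients are reserved for the planting scheme: keeping them
    # out of the background catalogue keeps GroundTruth exposure exact
    planted_ings = {s.ingredient for s in config.planted_signals}
    catalogue = sorted(set(d.ingredient_atc) - planted_ings)
    bg_drug_pick = rng.integers(0, len(catalogue), n)
    bg_drug_suspected = rng.random(n) < 0.5
    signal_cells = []
    for s in config.planted_signals:
        cells = np.cumsum(solve_joint(s.p_drug, s.p_event, s.target_ror))
        signal_cells.append(np.searchsorted(cells, rng.random(n), side="right"))

    # --- per-case assembly -------------------------------------------------
    flag_pt = {
        "hypertension": PT_HYPERTENSION,
        "malignancy": 90000011,
        "cardiac": 90000012,
        "diabetes": 90000013,
        "renal": 90000014,
        "allergy": 90000015,
        "lipid": 90000016,
    }
    cases: list[CaseReport] = []
    truths: dict[str, CaseTruth] = {}
    sig_cells_count = [np.zeros(4, dtype=int) for _ in config.planted_signals]

    for i in range(n):
        cid = f"C{i:07d}"
        is_elig = bool(eligible[i])
        is_ks = is_elig and bool(ks_draw[i])
        group = "KS" if is_ks else ("nonKS" if is_elig else "background")

        reactions: set[int] = {
            BACKGROUND_PTS[bg_reac_pick[i, j]] for j in range(n_bg_reac[i])
        }
        drugs: list[DrugRecord] = []
        if is_elig:
            gi = 0 if is_ks else 1
            if is_ks:
                reactions.add(KS_PT)
            else:
                reactions.update((PT_ALLERGIC_REACTION_SYN, PT_MI))
            for j, pt in enumerate(copt_codes):
                if copt_u[i, j] < config.copt_prob[pt][gi]:
                    reactions.add(pt)
            use = config.atc2_use[group]
            for j, cls in enumerate(atc2_classes):
                if atc2_u[i, j] < use.get(cls, 0.0):
                    members = CLASS_INGREDIENTS[cls]
                    ing = members[atc2_pick[i, j] % len(members)]
                    role = "suspected" if atc2_suspected[i, j] else "concomitant"
                    drugs.append(DrugRecord(ing, role))
        elif bg_drug[i]:
            role = "suspected" if bg_drug_suspected[i] else "concomitant"
            drugs.append(DrugRecord(catalogue[bg_drug_pick[i]], role))

        for k, s in enumerate(config.planted_signals):
            cell = int(signal_cells[k][i])
            sig_cells_count[k][cell] += 1
            if cell in (0, 1):  # exposed
                drugs.append(DrugRecord(s.ingredient, "suspected"))
            if cell in (0, 2):  # event
                reactions.update(s.event_pts)

        flags = dict.fromkeys(DiseaseFlagSet.FLAGS, False)
        prev = config.disease_prevalence[group]
        history: set[int] = set()
        for j, name in enumerate(DiseaseFlagSet.FLAGS):
            if disease_u[i, j] < prev.get(name, 0.0):
                flags[name] = True
                history.add(flag_pt[name])
        flagset = DiseaseFlagSet(**flags)

        died = death_u[i] < config.death_prob[group]
        outcomes: frozenset[str] = (
            frozenset()
            if miss_outcome[i]
            else frozenset({"death"} if died else {"recovered"})
        )
        hist: frozenset[int] | None = None if miss_hist[i] else frozenset(history)

        excluded = is_elig and (miss_outcome[i] or miss_hist[i])
        final_group = group if (is_elig and not excluded) else "none"
        if not is_elig:
            final_group = "none"

        cases.append(
            CaseReport(
                case_id=cid,
                sex=str(sex[i]),
                age_band=None if miss_age[i] else AGE_BANDS[age_idx[i]],
                height_band=None if miss_height[i] else HEIGHT_BANDS[height_idx[i]],
                weight_band=None if miss_weight[i] else WEIGHT_BANDS[weight_idx[i]],
                outcomes=outcomes,
                drugs=tuple(drugs),
                reactions=frozenset(reactions),
                history=hist,
            )
        )
        truths[cid] = CaseTruth(
            eligible=is_elig,
            ks=is_ks,
            excluded_missing=excluded,
            group=final_group,
            flags=flagset,
            died=died,
        )

    signal_truths = [
        SignalTruth(
            s.ingredient,
            s.event_pts,
            s.target_ror,
            a=int(counts[0]),
            b=int(counts[1]),
            c=int(counts[2]),
            d=int(counts[3]),
        )
        for s, counts in zip(config.planted_signals, sig_cells_count)
    ]
    return ReportDatabase(cases), GroundTruth(signal_truths, truths)


def null_config(n_cases: int = 5000, seed: int = 0) -> GeneratorConfig:
    """A configuration whose planted pairs all have true ROR 1."""
    base = GeneratorConfig(n_cases=n_cases, seed=seed)
    return replace(
        base,
        planted_signals=tuple(
            replace(s, target_ror=1.0) for s in base.planted_signals
        ),
    )
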