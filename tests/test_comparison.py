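"""Group contrasts: chi-squared/Fisher choice and the three tabulations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kounispv.cohort import build_cohort
from kounispv.comparison import (
    ANY_LISTED_FEATURE,
    GroupCounts,
    choose_test,
    compare_counts,
    expected_cells,
    pearson_chi2,
    tabulate_atc2_use,
    tabulate_copt_frequencies,
    tabulate_disease_and_death,
)
from kounispv.dictionary import TermDictionary
from kounispv.errors import DegenerateTableError, InconsistentTableError
from kounispv.report_io import CaseReport, DrugRecord, ReportDatabase
from kounispv.signals import ContingencyTable, fisher_exact_two_sided
from kounispv.synthetic import KS_PT, PT_ALLERGIC_REACTION_SYN, PT_MI


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((41, 89, 54, 61), 6.11),  # cardiac disorders
            ((5, 125, 15, 100), 6.88),  # acute coronary syndrome PT
            ((10, 10, 10, 10), 0.0),
        ],
    )
    def test_statistic(self, table, expected):
        stat, df, p = pearson_chi2(ContingencyTable(*table))
        assert df == 1
        assert stat == pytest.approx(expected, abs=0.01)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2(ContingencyTable(0, 0, 5, 5))

    @given(
        a=st.integers(1, 40), b=st.integers(1, 40),
        c=st.integers(1, 40), d=st.integers(1, 40),
    )
    def test_invariant_under_transposition(self, a, b, c, d):
        s1 = pearson_chi2(ContingencyTable(a, b, c, d))[0]
        s2 = pearson_chi2(ContingencyTable(a, c, b, d))[0]  # transpose
        s3 = pearson_chi2(ContingencyTable(c, d, a, b))[0]  # row swap
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert s1 == pytest.approx(s3, rel=1e-12)


class TestChooseTest:
    def test_small_expected_count_uses_fisher(self):
        res = choose_test(ContingencyTable(1, 129, 3, 112))
        assert res.test_used == "fisher"
        assert res.statistic is None and res.df is None
        assert min(expected_cells(ContingencyTable(1, 129, 3, 112))) < 5

    def test_large_expected_counts_use_chi2(self):
        res = choose_test(ContingencyTable(41, 89, 54, 61))
        assert res.test_used == "chi2" and res.df == 1
        assert res.statistic == pytest.approx(6.11, abs=0.01)

    def test_empty_table_is_an_error(self):
        with pytest.raises(InconsistentTableError):
            ContingencyTable(0, 0, 0, 0)

    def test_chi2_and_fisher_usually_agree_when_expected_large(self):
        """With all expected counts >= 5 and N >= 200, accept/reject at
        alpha=0.05 agrees on at least 95% of random tables."""
        rng = np.random.default_rng(12)
        agree = total = 0
        while total < 200:
            a, b, c, d = rng.integers(10, 80, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            if t.n < 200 or min(expected_cells(t)) < 5:
                continue
            total += 1
            p_chi = pearson_chi2(t)[2]
            p_f = fisher_exact_two_sided(t)
            agree += (p_chi < 0.05) == (p_f < 0.05)
        assert agree / total >= 0.95


def _cohort(cases, meddra):
    labelled, _ = build_cohort(ReportDatabase(cases), meddra)
    return labelled


def _case(cid, group, *, drugs=(), extra_reactions=(), history=frozenset(),
          outcomes=("recovered",)):
    reactions = {KS_PT} if group == "KS" else {PT_ALLERGIC_REACTION_SYN, PT_MI}
    reactions |= set(extra_reactions)
    return CaseReport(
        case_id=cid,
        outcomes=frozenset(outcomes),
        drugs=tuple(drugs),
        reactions=frozenset(reactions),
        history=history,
    )


class TestTabulations:
    def test_disease_and_death_by_hand(self, meddra):
        cases = [
            _case("A", "KS", history=frozenset({10020772}), outcomes=("death",)),
            _case("B", "KS"),
            _case("C", "nonKS", history=frozenset({90000012})),
            _case("D", "nonKS", history=frozenset({10020772, 90000013})),
        ]
        rows = {r.feature: r for r in tabulate_disease_and_death(_cohort(cases, meddra), meddra)}
        assert rows["disease_hypertension"].x_ks == 1
        assert rows["disease_hypertension"].x_nonks == 1
        assert rows["disease_cardiac"].x_nonks == 1
        assert rows["disease_diabetes"].x_nonks == 1
        assert rows["death"].x_ks == 1 and rows["death"].x_nonks == 0
        assert rows["death"].n_ks == 2 and rows["death"].n_nonks == 2

    def test_atc2_case_counts_once_per_class(self, meddra):
        """Two same-class drugs contribute a single count to that class."""
        toy = TermDictionary(
            pt_records=dict(meddra.pt_records),
            smq_members=dict(meddra.smq_members),
            ingredient_atc={
                "Heparin": frozenset({"B01AB01"}),
                "Aspirin": frozenset({"B01AC06"}),
            },
        )
        cases = [
            _case(
                "A", "KS",
                drugs=(
                    DrugRecord("Heparin", "suspected"),
                    DrugRecord("Aspirin", "concomitant"),
                ),
            ),
            _case("B", "nonKS", drugs=(DrugRecord("Unmapped drug", "suspected"),)),
        ]
        rows = {r.feature: r for r in tabulate_atc2_use(_cohort(cases, toy), toy)}
        assert rows["atc2_B01"].x_ks == 1
        assert rows["atc2_B01"].x_nonks == 0
        assert set(rows) == {"atc2_B01"}  # unmapped drug contributes nothing

    def test_copt_candidates_seeded_from_ks_group(self, meddra):
        cases = [
            _case("A", "KS", extra_reactions={10002199}),
            _case("B", "nonKS", extra_reactions={10037844}),
        ]
        rows = {r.feature: r for r in tabulate_copt_frequencies(_cohort(cases, meddra), meddra)}
        assert "pt_10002199" in rows  # co-occurs with the KS PT in a KS case
        assert "pt_10037844" not in rows  # appears only in the non-KS group
        assert rows[ANY_LISTED_FEATURE].x_ks == 1
        assert rows[ANY_LISTED_FEATURE].x_nonks == 0

    def test_copt_empty_ks_group(self, meddra):
        cases = [_case("B", "nonKS", extra_reactions={10037844})]
        rows = tabulate_copt_frequencies(_cohort(cases, meddra), meddra)
        assert [r.feature for r in rows] == [ANY_LISTED_FEATURE]
        assert rows[0].x_nonks == 0

    def test_counts_match_ground_truth(self, small_sim, meddra):
        _, db, truth = small_sim
        labelled, _ = build_cohort(db, meddra)
        rows = {r.feature: r for r in tabulate_disease_and_death(labelled, meddra)}
        for name in ("hypertension", "cardiac", "diabetes"):
            expected_ks = sum(
                getattr(t.flags, name)
                for t in truth.cases.values()
                if t.group == "KS"
            )
            assert rows[f"disease_{name}"].x_ks == expected_ks
        assert rows["death"].x_nonks == sum(
            t.died for t in truth.cases.values() if t.group == "nonKS"
        )

    def test_atc2_matches_brute_force_recount(self, small_sim, meddra):
        _, db, _ = small_sim
        labelled, _ = build_cohort(db, meddra)
        rows = {r.feature: r for r in tabulate_atc2_use(labelled, meddra)}
        ks_cases = [c for c, lab in labelled if lab.group == "KS"]
        for feature, row in rows.items():
            cls = feature.removeprefix("atc2_")
            recount = sum(
                any(
                    code.startswith(cls)
                    for ing in case.all_ingredients()
                    for code in meddra.ingredient_atc.get(ing, frozenset())
                )
                for case in ks_cases
            )
            assert row.x_ks == recount


class TestGroupCounts:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GroupCounts("f", 5, 4, 0, 10)

    def test_compare_counts_orientation(self):
        gc = GroupCounts("cardiac", 41, 130, 54, 115)
        res = compare_counts(gc)
        assert res.test_used == "chi2"
        assert res.statistic == pytest.approx(6.11, abs=0.01)
        assert res.p == pytest.approx(0.013, abs=0.001)
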