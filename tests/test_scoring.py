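"""Evidence counting, the concordance score, forcing rules and routing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemcurate import scoring
from chemcurate.resolvers import PRIMARY_SLOTS

CIR_NAME, CIR_CAS, COMPTOX_NAME, COMPTOX_CAS = PRIMARY_SLOTS


def keys(cir_name=None, cir_cas=None, comptox_name=None, comptox_cas=None):
    return {
        CIR_NAME: cir_name,
        CIR_CAS: cir_cas,
        COMPTOX_NAME: comptox_name,
        COMPTOX_CAS: comptox_cas,
    }


class TestCountEvidence:
    def test_all_concordant(self):
        p = scoring.count_evidence(keys("A", "A", "A", "A"))
        assert (p.E, p.D, p.M) == (4, 0, 0)
        assert p.cas_pair == scoring.CAS_AGREE
        assert p.majority_key == "A"

    def test_majority_with_one_discordant_one_missing(self):
        p = scoring.count_evidence(keys("A", "A", "B", None))
        assert (p.E, p.D, p.M) == (2, 1, 1)
        assert p.cas_pair == scoring.CAS_INCOMPARABLE

    def test_two_vs_two_with_cas_disagreement(self):
        p = scoring.count_evidence(keys("A", "A", "B", "B"))
        assert (p.E, p.D, p.M) == (2, 2, 0)
        assert p.cas_pair == scoring.CAS_DISAGREE

    def test_single_retrieval_counts_as_consistent(self):
        p = scoring.count_evidence(keys(None, "A", None, None))
        assert (p.E, p.D, p.M) == (1, 0, 3)

    def test_mutually_discordant_retrievals_count_as_different(self):
        p = scoring.count_evidence(keys("A", "B", None, None))
        assert (p.E, p.D, p.M) == (0, 2, 2)
        p = scoring.count_evidence(keys("A", "B", "C", "D"))
        assert (p.E, p.D, p.M) == (0, 4, 0)

    def test_tie_break_prefers_cas_pair_class(self):
        p = scoring.count_evidence(keys("A", "B", "A", "B"))
        assert p.majority_key == "B"  # class holding both CAS-derived slots
        assert (p.E, p.D) == (2, 2)

    def test_requires_exactly_four_slots(self):
        with pytest.raises(ValueError):
            scoring.count_evidence({CIR_NAME: "A"})


class TestRawScore:
    @pytest.mark.parametrize(
        ("e", "d", "expected"),
        [(4, 0, 4.0), (3, 1, 2.8), (2, 1, 1.8), (2, 2, 1.6), (1, 0, 1.0),
         (0, 3, -0.6), (0, 4, -0.8), (0, 2, -0.4)],
    )
    def test_spot_values(self, e, d, expected):
        assert scoring.raw_score(e, d) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 4), st.integers(0, 4), st.integers(0, 4))
    @settings(derandomize=True, max_examples=100)
    def test_monotonic_in_e_and_d(self, e, d, other):
        if e + d > 4:
            return
        if e + 1 + d <= 4:
            assert scoring.raw_score(e + 1, d) > scoring.raw_score(e, d)
        if e + d + 1 <= 4:
            assert scoring.raw_score(e, d + 1) < scoring.raw_score(e, d)


class TestForcing:
    def test_tie_between_e_and_d_forces_zero(self):
        profile = scoring.count_evidence(keys("A", "A", "B", "C"))
        assert (profile.E, profile.D) == (2, 2)
        assert scoring.apply_forcing(1.6, profile) == 0.0

    def test_cas_disagreement_forces_zero(self):
        profile = scoring.count_evidence(keys("A", "A", "A", "B"))
        assert (profile.E, profile.D) == (3, 1)
        assert profile.cas_pair == scoring.CAS_DISAGREE
        assert scoring.apply_forcing(2.8, profile) == 0.0

    def test_name_discordance_with_cas_agreement_not_forced(self):
        profile = scoring.count_evidence(keys("B", "A", "A", "A"))
        assert profile.cas_pair == scoring.CAS_AGREE
        assert scoring.apply_forcing(2.8, profile) == pytest.approx(2.8)

    def test_no_consistent_evidence_forces_zero(self):
        profile = scoring.count_evidence(keys(None, None, None, None))
        assert scoring.apply_forcing(0.0, profile) == 0.0


def route(**kwargs):
    profile = scoring.count_evidence(keys(**kwargs))
    final = scoring.apply_forcing(scoring.raw_score(profile.E, profile.D), profile)
    return scoring.classify(final, profile)


class TestClassify:
    def test_four_concordant_is_high_reliability_maintain(self):
        result = route(cir_name="A", cir_cas="A", comptox_name="A", comptox_cas="A")
        assert result.category == scoring.MAINTAIN
        assert result.reliability == scoring.RELIABILITY_HIGH
        assert result.final_score == 4.0

    def test_three_concordant_one_missing_is_medium_maintain(self):
        result = route(cir_name=None, cir_cas="A", comptox_name="A", comptox_cas="A")
        assert result.category == scoring.MAINTAIN
        assert result.reliability == scoring.RELIABILITY_MEDIUM
        assert result.final_score == 3.0

    def test_all_missing_is_reject(self):
        result = route()
        assert result.category == scoring.REJECT
        assert result.final_score == 0.0

    @pytest.mark.parametrize(
        ("slot_kwargs", "reason"),
        [
            # both name slots missing -> name may hold a typo
            (dict(cir_cas="A", comptox_cas="A"), scoring.REASON_VERIFY_NAME),
            # one source entirely missing
            (dict(comptox_name="A", comptox_cas="A"), scoring.REASON_NEED_ONE),
            # one CAS + one name missing, different sources
            (dict(cir_cas="A", comptox_name="A"), scoring.REASON_NEED_ONE),
            # both CAS slots missing
            (dict(cir_name="A", comptox_name="A"),
             scoring.REASON_VERIFY_CAS_NEED_ONE),
            # single retrieval
            (dict(cir_cas="A"), scoring.REASON_NEED_TWO),
            # 2 concordant + 1 discordant name, CAS agreeing
            (dict(cir_name="B", cir_cas="A", comptox_cas="A"),
             scoring.REASON_VERIFY_NAME),
            # 3 concordant + 1 discordant name, CAS agreeing (score 2.8)
            (dict(cir_name="B", cir_cas="A", comptox_name="A", comptox_cas="A"),
             scoring.REASON_VERIFY_NAME),
        ],
    )
    def test_check_reasons(self, slot_kwargs, reason):
        result = route(**slot_kwargs)
        assert result.category == scoring.CHECK
        assert result.check_reason == reason


class TestEnumeration:
    def test_every_profile_gets_exactly_one_category(self):
        rows = scoring.enumerate_decision_matrix()
        assert len(rows) == 3**4
        for row in rows:
            assert row["category"] in (
                scoring.MAINTAIN, scoring.CHECK, scoring.REJECT
            )
            assert row["E"] + row["D"] + row["M"] == 4

    def test_maintain_iff_score_at_least_three(self):
        for row in scoring.enumerate_decision_matrix():
            assert (row["category"] == scoring.MAINTAIN) == (
                row["final_score"] >= 3
            )
            assert (row["category"] == scoring.REJECT) == (
                row["final_score"] == 0
            )

    def test_shipped_matrix_tsv_matches_computation(self):
        from pathlib import Path

        import pandas as pd

        path = Path(__file__).resolve().parents[1] / "docs" / "decision_matrix.tsv"
        shipped = pd.read_csv(path, sep="\t")
        computed = scoring.decision_matrix_table()
        pd.testing.assert_frame_equal(
            shipped.reset_index(drop=True), computed.reset_index(drop=True),
            check_dtype=False,
        )

    def test_reliability_grades(self):
        for row in scoring.enumerate_decision_matrix():
            if row["final_score"] == 4.0:
                assert row["reliability"] == scoring.RELIABILITY_HIGH
            elif row["category"] == scoring.MAINTAIN:
                assert row["reliability"] == scoring.RELIABILITY_MEDIUM
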