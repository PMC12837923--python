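"""Ordinal discretisation, signatures, frequencies and matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catpattern.exceptions import AlignmentError, ConfigurationError
from catpattern.patterns import (
    EQUIV,
    GREATER,
    LESS,
    DiscretisationCriterion,
    OrdinalPattern,
    discretise,
    match_model_to_human,
    modal_pattern,
    pattern_frequencies,
    pattern_signature,
    session_consistency,
    signature_to_pattern,
)

TAU = DiscretisationCriterion(mode="threshold", tolerance=0.1)


def _pat(signature, k=3):
    cats = tuple(f"C{i}" for i in range(k))
    return signature_to_pattern(signature, cats)


class TestDiscretise:
    def test_equal_proportions_give_all_equiv(self):
        counts = [(24, 30)] * 9
        pat = discretise(counts, TAU)
        assert set(pat.cells) == {EQUIV}

    def test_threshold_worked_example(self):
        # (30/30, 27/30, 15/30), tau = 0.1:
        # |1.0-0.9| <= 0.1 -> EQUIV; 1.0 vs 0.5 and 0.9 vs 0.5 -> GREATER
        pat = discretise([(30, 30), (27, 30), (15, 30)], TAU)
        assert pat.relation(0, 1) == EQUIV
        assert pat.relation(0, 2) == GREATER
        assert pat.relation(1, 2) == GREATER
        # stored lower-triangular cells read row-vs-column
        assert pat.cells == (EQUIV, LESS, LESS)

    def test_swapping_two_categories_inverts_their_cell(self):
        counts = {"A": (30, 30), "B": (15, 30)}
        fwd = discretise(counts, TAU, categories=("A", "B"))
        rev = discretise(counts, TAU, categories=("B", "A"))
        assert fwd.cells == (LESS,)
        assert rev.cells == (GREATER,)

    def test_zero_trial_category_rejected(self):
        with pytest.raises(ConfigurationError, match="zero-trial"):
            discretise([(0, 0), (5, 10)], TAU)

    def test_ci_overlap_mode(self):
        crit = DiscretisationCriterion(mode="ci_overlap", ci_level=0.95)
        # identical counts: intervals coincide -> EQUIV
        assert set(discretise([(20, 30), (20, 30)], crit).cells) == {EQUIV}
        # extreme separation: 30/30 vs 3/30 cannot overlap
        assert discretise([(30, 30), (3, 30)], crit).cells == (LESS,)
        # moderate separation overlapping at n = 30: 24/30 vs 19/30
        assert discretise([(24, 30), (19, 30)], crit).cells == (EQUIV,)

    @given(
        ps=st.lists(st.integers(0, 30), min_size=2, max_size=9),
        seed=st.integers(0, 10_000),
    )
    def test_antisymmetry_and_equiv_on_equal(self, ps, seed):
        counts = [(p, 30) for p in ps]
        pat = discretise(counts, TAU)
        k = len(ps)
        inverse = {LESS: GREATER, GREATER: LESS, EQUIV: EQUIV}
        for i in range(k):
            for j in range(k):
                if i != j:
                    assert pat.relation(i, j) == inverse[pat.relation(j, i)]
                    if ps[i] == ps[j]:
                        assert pat.relation(i, j) == EQUIV

    def test_tau_zero_is_strict_equality(self):
        crit = DiscretisationCriterion(mode="threshold", tolerance=0.0)
        pat = discretise([(10, 30), (10, 30), (11, 30)], crit)
        assert pat.relation(0, 1) == EQUIV
        assert pat.relation(2, 0) == GREATER

    @given(ps=st.lists(st.integers(0, 30), min_size=2, max_size=6))
    def test_monotone_coarsening_in_tau(self, ps):
        counts = [(p, 30) for p in ps]
        taus = [0.0, 0.05, 0.1, 0.3, 0.6, 1.0]
        previous_equiv: set = set()
        for tau in taus:
            pat = discretise(counts, DiscretisationCriterion("threshold", tau))
            equiv = {i for i, c in enumerate(pat.cells) if c == EQUIV}
            assert previous_equiv <= equiv  # raising tau never removes EQUIV
            previous_equiv = equiv
        assert previous_equiv == set(range(len(pat.cells)))  # tau = 1: all EQUIV

    def test_depends_only_on_counts_not_trial_order(self):
        # same aggregated counts via different splits produce the same input,
        # so the pattern is a pure function of (n_correct, n_trials)
        a = discretise([(12, 30), (20, 30)], TAU)
        b = discretise([(12, 30), (20, 30)], TAU)
        assert a == b


class TestSignatures:
    def test_all_equiv_three_categories(self):
        pat = discretise([(10, 10)] * 3, TAU)
        assert pattern_signature(pat) == "==="

    def test_signature_length_is_k_choose_2(self):
        for k in (2, 5, 9):
            pat = discretise([(10, 10)] * k, TAU)
            assert len(pat.signature) == k * (k - 1) // 2

    @given(
        cells_a=st.lists(st.sampled_from("<>="), min_size=3, max_size=3),
        cells_b=st.lists(st.sampled_from("<>="), min_size=3, max_size=3),
    )
    def test_signature_equality_iff_structural_equality(self, cells_a, cells_b):
        pa = _pat("".join(cells_a))
        pb = _pat("".join(cells_b))
        assert (pa.signature == pb.signature) == (pa == pb)

    def test_signature_round_trips(self):
        sig = "<>=<>="
        assert signature_to_pattern(sig, tuple("ABCD")).signature == sig

    def test_wrong_cell_count_rejected(self):
        with pytest.raises(ConfigurationError):
            OrdinalPattern(categories=("A", "B", "C"), cells=("<",))


class TestFrequencies:
    def test_identical_cohort_single_row(self):
        pats = [_pat("===")] * 7
        freq = pattern_frequencies(pats)
        assert len(freq) == 1
        assert freq["proportion"].tolist() == [1.0]

    def test_counts_match_brute_force_tally(self):
        sigs = ["===", "<<<", "===", ">>>", "<<<", "===", "=<>", ">>>", "===", "<<<"]
        pats = [_pat(s) for s in sigs]
        freq = pattern_frequencies(pats)
        expected = {s: sigs.count(s) for s in set(sigs)}
        assert dict(zip(freq["signature"], freq["count"])) == expected
        assert freq["count"].is_monotonic_decreasing
        assert int(freq["count"].sum()) == len(sigs)

    def test_unique_count_bounded(self):
        rng = np.random.default_rng(0)
        pats = [
            _pat("".join(rng.choice(list("<>="), 3))) for _ in range(200)
        ]
        freq = pattern_frequencies(pats)
        assert len(freq) <= min(200, 3**3)

    def test_mixed_category_orders_rejected(self):
        a = signature_to_pattern("=", ("A", "B"))
        b = signature_to_pattern("=", ("B", "A"))
        with pytest.raises(AlignmentError):
            pattern_frequencies([a, b])


class TestModal:
    def test_single_participant(self):
        winners, prop = modal_pattern([_pat("<=>")])
        assert [w.signature for w in winners] == ["<=>"]
        assert prop == 1.0

    def test_ties_returned_lexicographically(self):
        pats = [_pat("<<<")] * 2 + [_pat(">>>")] * 2 + [_pat("===")]
        winners, prop = modal_pattern(pats)
        assert [w.signature for w in winners] == ["<<<", ">>>"]
        assert prop == pytest.approx(0.4)


class TestConsistency:
    def test_identical_sessions(self):
        pats = {f"p{i}": _pat("===") for i in range(5)}
        prop, indicator, excl = session_consistency(pats, dict(pats))
        assert prop == 1.0 and excl == []

    def test_three_of_five_match(self):
        test = {f"p{i}": _pat("===") for i in range(5)}
        retest = dict(test)
        retest["p3"] = _pat("<<<")
        retest["p4"] = _pat(">>>")
        prop, indicator, _ = session_consistency(test, retest)
        assert prop == pytest.approx(0.6)
        assert not indicator["p3"] and indicator["p0"]

    def test_disjoint_patterns_give_zero(self):
        test = {f"p{i}": _pat("<<<") for i in range(4)}
        retest = {f"p{i}": _pat(">>>") for i in range(4)}
        prop, _, _ = session_consistency(test, retest)
        assert prop == 0.0

    def test_missing_participant_excluded_not_dropped(self):
        test = {"p1": _pat("==="), "p2": _pat("<<<")}
        retest = {"p1": _pat("===")}
        prop, indicator, excl = session_consistency(test, retest)
        assert excl == ["p2"]
        assert prop == 1.0


class TestModelMatch:
    def test_all_equiv_model_matches_all_equiv_modal(self):
        humans = [_pat("===")] * 6 + [_pat("<<<")] * 3
        out = match_model_to_human(_pat("==="), humans)
        assert out["exact_match_to_modal"]
        assert out["cell_overlap_with_modal"] == 1.0
        assert out["rank_of_model_signature"] == 1

    def test_overlap_fraction_counts_matching_cells(self):
        # k = 9 -> 36 cells; differ in exactly 9 -> overlap 0.75
        k = 9
        n_cells = k * (k - 1) // 2
        cats = tuple(f"C{i}" for i in range(k))
        base = signature_to_pattern("=" * n_cells, cats)
        cells = ["="] * n_cells
        for i in range(9):
            cells[i] = "<"
        other = OrdinalPattern(categories=cats, cells=tuple(cells))
        out = match_model_to_human(other, [base] * 5)
        assert out["cell_overlap_with_modal"] == pytest.approx(0.75)
        assert not out["exact_match_to_modal"]

    def test_absent_signature_has_no_rank(self):
        humans = [_pat("===")] * 4
        out = match_model_to_human(_pat("<><"), humans)
        assert out["rank_of_model_signature"] is None
        assert not out["exact_match_to_modal"]

    def test_category_order_mismatch_rejected(self):
        humans = [signature_to_pattern("=", ("A", "B"))]
        model = signature_to_pattern("=", ("B", "A"))
        with pytest.raises(AlignmentError):
            match_model_to_human(model, humans)
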