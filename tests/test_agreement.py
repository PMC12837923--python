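"""Cohen's kappa: worked examples, oracle equivalence, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from catpattern.agreement import (
    align_rater_sequences,
    cohen_kappa,
    intra_rater_reliability,
    kappa_band,
    kappa_matrix_values,
    pairwise_agreement_matrix,
    pooled_pairwise_kappa,
)
from catpattern.exceptions import AlignmentError
from oracles import brute_force_kappa


class TestCohenKappa:
    def test_identical_nonconstant_sequences(self):
        res = cohen_kappa(list("aabbc"), list("aabbc"))
        assert res.kappa == 1.0
        assert not res.degenerate_marginals

    def test_symmetric_chance_fixture(self):
        res = cohen_kappa([1, 1, 2, 2], [1, 2, 1, 2])
        assert res.observed_agreement == 0.5
        assert res.expected_agreement == 0.5
        assert res.kappa == 0.0

    def test_2x2_counts_20_5_5_20(self):
        # contingency (20,5;5,20): p_o = 0.8, p_e = 0.5, kappa = 0.6
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 5 + ["y"] * 20
        res = cohen_kappa(a, b)
        assert res.kappa == pytest.approx(0.6, abs=1e-12)
        assert res.observed_agreement == pytest.approx(0.8)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.band == "moderate"

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            cohen_kappa([1, 2], [1, 2, 3])

    def test_single_item_rejected(self):
        with pytest.raises(AlignmentError):
            cohen_kappa([1], [1])

    def test_constant_identical_sequences_flagged_kappa_one(self):
        res = cohen_kappa(["a"] * 5, ["a"] * 5)
        assert res.kappa == 1.0
        assert res.degenerate_marginals

    def test_constant_different_sequences_flagged_kappa_zero(self):
        res = cohen_kappa(["a"] * 5, ["b"] * 5)
        assert res.kappa == 0.0
        assert res.degenerate_marginals

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 40)
        b = np.where(rng.random(40) < 0.7, a, rng.integers(0, 3, 40))
        res = cohen_kappa(a.tolist(), b.tolist())
        assert res.ci_low <= res.kappa <= res.ci_high
        assert res.standard_error > 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = int(rng.integers(2, 51))
            k = int(rng.integers(2, 11))
            a = rng.integers(0, k, n).tolist()
            b = rng.integers(0, k, n).tolist()
            po, pe, kap = brute_force_kappa(a, b)
            res = cohen_kappa(a, b)
            assert res.observed_agreement == pytest.approx(po, abs=1e-12)
            assert res.expected_agreement == pytest.approx(pe, abs=1e-12)
            assert res.kappa == pytest.approx(kap, abs=1e-12)

    def test_se_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 60))
            a = rng.integers(0, k, n)
            b = rng.integers(0, k, n)
            table = np.zeros((k, k))
            np.add.at(table, (a, b), 1)
            sm = sm_kappa(table, return_results=True)
            res = cohen_kappa(a.tolist(), b.tolist())
            assert res.kappa == pytest.approx(sm.kappa, abs=1e-12)
            assert res.standard_error == pytest.approx(
                float(np.sqrt(sm.var_kappa)), abs=1e-12
            )

    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=2, max_size=40
        ),
        perm_seed=st.integers(0, 1000),
    )
    def test_item_order_invariance(self, pairs, perm_seed):
        a, b = zip(*pairs)
        rng = np.random.default_rng(perm_seed)
        idx = rng.permutation(len(a))
        base = cohen_kappa(a, b)
        perm = cohen_kappa(np.asarray(a)[idx], np.asarray(b)[idx])
        assert perm.kappa == pytest.approx(base.kappa, abs=1e-12)

    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=2, max_size=40
        )
    )
    def test_bijective_relabelling_invariance(self, pairs):
        a, b = zip(*pairs)
        relabel = {0: "v", 1: "w", 2: "x", 3: "y", 4: "z"}
        base = cohen_kappa(a, b)
        mapped = cohen_kappa([relabel[x] for x in a], [relabel[x] for x in b])
        assert mapped.kappa == pytest.approx(base.kappa, abs=1e-12)


class TestKappaBand:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.79, "substantial"),
            (0.88, "almost_perfect"),
            (-0.2, "no"),
            (0.0, "no"),
            (0.1, "slight"),
            (0.3, "fair"),
            (0.5, "moderate"),
            (1.0, "almost_perfect"),
        ],
    )
    def test_bands(self, value, band):
        assert kappa_band(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.5)


class TestMatrices:
    def test_identical_raters_off_diagonal_one(self):
        seq = list("abcab")
        mat = pairwise_agreement_matrix([("r1", seq), ("r2", seq)])
        assert mat.loc["r1", "r2"].kappa == 1.0
        assert mat.loc["r1", "r1"].kappa == 1.0

    def test_entries_equal_individual_calls_and_symmetry(self):
        rng = np.random.default_rng(3)
        raters = [
            (f"r{i}", rng.integers(0, 4, 30).tolist()) for i in range(3)
        ]
        mat = pairwise_agreement_matrix(raters)
        for i, (ra, sa) in enumerate(raters):
            for rb, sb in raters[i + 1:]:
                solo = cohen_kappa(sa, sb)
                assert mat.loc[ra, rb].kappa == solo.kappa
                assert mat.loc[rb, ra].kappa == mat.loc[ra, rb].kappa

    def test_vectorised_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(9)
        wide = pd.DataFrame(
            {f"r{i}": rng.choice(list("abcd"), 40) for i in range(5)},
            index=[f"s{j}" for j in range(40)],
        )
        fast = kappa_matrix_values(wide)
        for i in range(5):
            for j in range(i + 1, 5):
                slow = cohen_kappa(wide.iloc[:, i].tolist(), wide.iloc[:, j].tolist())
                assert fast.iloc[i, j] == pytest.approx(slow.kappa, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            pairwise_agreement_matrix([("a", [1, 2, 3]), ("b", [1, 2])])

    def test_pooled_kappa_two_rater_case_is_symmetrised_table(self):
        # with exactly two raters, pooling over unordered pairs equals kappa
        # of the symmetrised contingency table, and p_o equals plain p_o
        rng = np.random.default_rng(4)
        a = rng.choice(list("ab"), 30)
        b = rng.choice(list("ab"), 30)
        wide = pd.DataFrame({"r1": a, "r2": b})
        pooled = pooled_pairwise_kappa(wide)
        solo = cohen_kappa(a.tolist(), b.tolist())
        assert pooled.observed_agreement == pytest.approx(
            solo.observed_agreement, abs=1e-12
        )
        # oracle: symmetrised table kappa
        labels = sorted(set(a) | set(b))
        idx = {lab: i for i, lab in enumerate(labels)}
        table = np.zeros((len(labels), len(labels)))
        for x, y in zip(a, b):
            table[idx[x], idx[y]] += 0.5
            table[idx[y], idx[x]] += 0.5
        n = table.sum()
        po = np.trace(table) / n
        pe = (table.sum(1) / n) @ (table.sum(0) / n)
        assert pooled.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)

    def test_pooled_kappa_invariant_to_rater_order(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(
            {f"r{i}": rng.choice(list("abc"), 25) for i in range(4)}
        )
        shuffled = wide[["r2", "r0", "r3", "r1"]]
        assert pooled_pairwise_kappa(wide).kappa == pytest.approx(
            pooled_pairwise_kappa(shuffled).kappa, abs=1e-12
        )


class TestIntraRater:
    def test_identical_sessions_give_kappa_one(self, small_cohort):
        table, _ = small_cohort
        test = table[table["session"] == "test"]
        retest = test.assign(session="retest")
        per, median, excl = intra_rater_reliability(test, retest)
        assert (per["kappa"] == 1.0).all()
        assert median == 1.0
        assert excl == []

    def test_chance_relabelling_gives_near_zero_median(self):
        rng = np.random.default_rng(12)
        cats = list("abcd")
        rows = []
        for p in range(30):
            for session in ("test", "retest"):
                for i in range(60):
                    rows.append(
                        dict(
                            rater_id=f"p{p}", rater_kind="human", session=session,
                            presentation="ms50", image_condition="full", block=1,
                            trial_index=i + 1, stimulus_id=f"s{i}",
                            true_category="Mug",
                            response_label="x",
                            response_category=rng.choice(cats),
                        )
                    )
        df = pd.DataFrame(rows)
        _, median, _ = intra_rater_reliability(
            df[df["session"] == "test"], df[df["session"] == "retest"]
        )
        # independent uniform relabelling: median kappa ~ 0 up to MC noise
        assert abs(median) < 0.1

    def test_matches_per_participant_brute_force(self, small_cohort):
        table, _ = small_cohort
        test = table[table["session"] == "test"]
        retest = table[table["session"] == "retest"]
        per, median, excl = intra_rater_reliability(test, retest)
        assert excl == []
        for row in per.itertuples(index=False):
            t = test[test["rater_id"] == row.rater_id].set_index("stimulus_id")
            r = retest[retest["rater_id"] == row.rater_id].set_index("stimulus_id")
            r = r.reindex(t.index)
            _, _, kap = brute_force_kappa(
                t["response_category"].tolist(), r["response_category"].tolist()
            )
            assert row.kappa == pytest.approx(kap, abs=1e-12)
        assert median == pytest.approx(float(per["kappa"].median()))

    def test_missing_session_listed_not_dropped(self, small_cohort):
        table, _ = small_cohort
        test = table[table["session"] == "test"]
        retest = table[table["session"] == "retest"]
        drop = retest["rater_id"].iloc[0]
        per, _, excl = intra_rater_reliability(
            test, retest[retest["rater_id"] != drop]
        )
        assert drop in excl
        assert drop not in set(per["rater_id"])


class TestAlignment:
    def test_align_pivots_by_stimulus(self, tiny_table):
        wide = align_rater_sequences(tiny_table)
        assert wide.shape == (3, 2)
        assert wide.loc["vase_001", "r1"] == "Vase"
        assert wide.loc["vase_001", "r2"] == "Plate"

    def test_incomplete_coverage_rejected(self, tiny_table):
        with pytest.raises(AlignmentError, match="incomplete"):
            align_rater_sequences(tiny_table.iloc[:-1])
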