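"""ICA decomposition: centering, planted-signal recovery, membership,
enrichment against a brute-force hypergeometric oracle, and activity tests."""

import math

import numpy as np
import pandas as pd
import pytest

import oxyr_adapt as oa


def _best_abs_corr(vec, candidates: pd.DataFrame) -> float:
    return max(
        abs(np.corrcoef(vec, candidates[c])[0, 1]) for c in candidates.columns
    )


def _match_component(true_vec, S: pd.DataFrame) -> str:
    return max(
        S.columns, key=lambda c: abs(np.corrcoef(true_vec, S[c])[0, 1])
    )


class TestCenterToReference:
    def test_identical_columns_center_to_zero(self):
        vals = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [1.0, 2.0], "s3": [1.0, 2.0]},
            index=["g1", "g2"],
        )
        em = oa.ExpressionMatrix(
            vals,
            pd.Series({"s1": "ref", "s2": "ref", "s3": "other"}),
            pd.Series({"s1": 1, "s2": 2, "s3": 1}),
            reference_condition="ref",
        )
        assert (oa.center_to_reference(em).to_numpy() == 0).all()

    def test_single_reference_sample_becomes_zero(self):
        vals = pd.DataFrame({"s1": [3.0], "s2": [5.0]}, index=["g"])
        em = oa.ExpressionMatrix(
            vals, pd.Series({"s1": "ref", "s2": "o"}),
            pd.Series({"s1": 1, "s2": 1}), "ref",
        )
        out = oa.center_to_reference(em)
        assert out["s1"].iloc[0] == 0.0
        assert out["s2"].iloc[0] == 2.0

    def test_reference_replicates_average_to_zero(self):
        vals = pd.DataFrame(
            {"r1": [1.0], "r2": [2.0], "r3": [3.0], "x": [10.0]}, index=["g"]
        )
        em = oa.ExpressionMatrix(
            vals,
            pd.Series({"r1": "ref", "r2": "ref", "r3": "ref", "x": "o"}),
            pd.Series({"r1": 1, "r2": 2, "r3": 3, "x": 1}),
            "ref",
        )
        out = oa.center_to_reference(em)
        np.testing.assert_allclose(out.loc["g", ["r1", "r2", "r3"]], [-1, 0, 1])

    def test_missing_reference_condition_rejected(self):
        vals = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        em = oa.ExpressionMatrix(
            vals, pd.Series({"s1": "a", "s2": "b"}),
            pd.Series({"s1": 1, "s2": 1}), "missing",
        )
        with pytest.raises(ValueError, match="reference"):
            oa.center_to_reference(em)


class TestRobustICA:
    def test_zero_noise_planted_components_recovered(self, modulons, conditions):
        em, S_true, A_true = oa.simulate_expression(
            modulons, conditions, noise_sd=0.0, seed=0, n_genes=300
        )
        Xc = oa.center_to_reference(em)
        model = oa.robust_ica(Xc, n_components=2, n_restarts=5, seed=0)
        assert model.n_components == 2
        for name in S_true.columns:
            assert _best_abs_corr(S_true[name], model.S) > 0.99
            comp = _match_component(S_true[name], model.S)
            r = abs(np.corrcoef(A_true.loc[name], model.A.loc[comp])[0, 1])
            assert r > 0.99

    def test_all_zero_matrix_flagged_degenerate(self):
        Xc = pd.DataFrame(
            np.zeros((20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        model = oa.robust_ica(Xc, n_components=2, n_restarts=3, seed=0)
        assert model.n_components == 0
        assert any("degenerate" in f for f in model.flags)

    def test_same_seed_reproduces_decomposition(self, modulons, conditions):
        em, *_ = oa.simulate_expression(
            modulons, conditions, noise_sd=0.2, seed=1, n_genes=200
        )
        Xc = oa.center_to_reference(em)
        m1 = oa.robust_ica(Xc, 2, n_restarts=4, seed=5)
        m2 = oa.robust_ica(Xc, 2, n_restarts=4, seed=5)
        pd.testing.assert_frame_equal(m1.S, m2.S)
        pd.testing.assert_frame_equal(m1.A, m2.A)

    def test_different_seed_matches_components_at_default_noise(
        self, modulons, conditions
    ):
        em, *_ = oa.simulate_expression(
            modulons, conditions, noise_sd=0.25, seed=1, n_genes=300
        )
        Xc = oa.center_to_reference(em)
        m1 = oa.robust_ica(Xc, 2, n_restarts=5, seed=5)
        m2 = oa.robust_ica(Xc, 2, n_restarts=5, seed=99)
        for c in m1.S.columns:
            assert _best_abs_corr(m1.S[c], m2.S) > 0.95

    def test_reconstruction_close_to_rank_k_svd_baseline(self, modulons, conditions):
        em, *_ = oa.simulate_expression(
            modulons, conditions, noise_sd=0.25, seed=2, n_genes=300
        )
        Xc = oa.center_to_reference(em).to_numpy()
        model = oa.robust_ica(oa.center_to_reference(em), 2, n_restarts=5, seed=0)
        resid_ica = np.linalg.norm(Xc - model.S.to_numpy() @ model.A.to_numpy())
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        best = (u[:, :2] * s[:2]) @ vt[:2]
        resid_svd = np.linalg.norm(Xc - best)
        assert resid_ica <= resid_svd + 0.05 * np.linalg.norm(Xc)

    def test_unit_norm_and_sign_convention(self, modulons, conditions):
        em, *_ = oa.simulate_expression(
            modulons, conditions, noise_sd=0.1, seed=3, n_genes=200
        )
        model = oa.robust_ica(oa.center_to_reference(em), 2, n_restarts=3, seed=0)
        for c in model.S.columns:
            w = model.S[c].to_numpy()
            assert np.linalg.norm(w) == pytest.approx(1.0)
            assert w[np.argmax(np.abs(w))] > 0

    def test_too_many_components_rejected(self):
        Xc = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="n_components"):
            oa.robust_ica(Xc, n_components=4, n_restarts=2, seed=0)


class TestDefineMembership:
    def test_planted_members_recovered_at_zero_noise(self, modulons, conditions):
        em, S_true, _ = oa.simulate_expression(
            modulons, conditions, noise_sd=0.0, seed=0, n_genes=300
        )
        model = oa.robust_ica(oa.center_to_reference(em), 2, n_restarts=3, seed=0)
        planted = {m.name: m.member_genes for m in modulons}
        for name in planted:
            comp = _match_component(S_true[name], model.S)
            im = oa.define_membership(model.S[comp], k=5.0)
            assert im.members == planted[name]

    def test_huge_k_empties_membership(self):
        rng = np.random.default_rng(0)
        w = pd.Series(rng.normal(size=100), name="c")
        im = oa.define_membership(w, k=1e9)
        assert im.members == set()

    def test_single_outlier_is_sole_member(self):
        w = pd.Series([0.01] * 50 + [5.0], index=[f"g{i}" for i in range(51)],
                      name="c")
        # equal-weight background with one large entry: MAD reflects background
        im = oa.define_membership(w + pd.Series(
            np.random.default_rng(1).normal(0, 1e-3, 51), index=w.index))
        assert im.members == {"g50"}

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            oa.define_membership(pd.Series([1.0, 1.0, 1.0], name="c"))


def hypergeom_tail_oracle(overlap, universe, regulon_size, members_size):
    """Exhaustive tail sum of the hypergeometric pmf."""
    total = 0.0
    for k in range(overlap, min(regulon_size, members_size) + 1):
        total += (
            math.comb(regulon_size, k)
            * math.comb(universe - regulon_size, members_size - k)
            / math.comb(universe, members_size)
        )
    return total


class TestMatchRegulon:
    def test_exact_p_against_combinatorial_oracle(self):
        regulon = {f"g{i}" for i in range(20)}
        members = set(regulon)
        match = oa.match_regulon(members, {"R": regulon}, universe_size=1000)
        assert match.regulator == "R"
        expected = hypergeom_tail_oracle(20, 1000, 20, 20)
        assert match.p_value == pytest.approx(expected, rel=1e-9)

    def test_full_overlap_ten_of_ten_in_universe_100(self):
        regulon = {f"g{i}" for i in range(10)}
        match = oa.match_regulon(regulon, {"R": regulon}, universe_size=100)
        assert match.p_value == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_zero_overlap_gives_p_one_for_all(self):
        members = {"a", "b", "c"}
        regulons = {"R1": {"x", "y"}, "R2": {"z"}}
        match = oa.match_regulon(members, regulons, universe_size=100)
        assert all(p == pytest.approx(1.0) for p in match.all_p_values.values())

    def test_bonferroni_scales_with_number_of_regulons(self):
        regulon = {f"g{i}" for i in range(10)}
        decoys = {f"D{j}": {f"d{j}_{i}" for i in range(10)} for j in range(9)}
        single = oa.match_regulon(regulon, {"R": regulon}, 1000)
        multi = oa.match_regulon(regulon, {"R": regulon, **decoys}, 1000)
        assert multi.p_value == pytest.approx(10 * single.p_value, rel=1e-9)

    def test_empty_member_set_flagged(self):
        match = oa.match_regulon(set(), {"R": {"a"}}, 10)
        assert match.regulator is None
        assert math.isnan(match.p_value)


class TestActivities:
    def _model(self):
        A = pd.DataFrame(
            [[4.0, 6.0, 1.0, 1.0, 9.0]],
            index=["ic1"],
            columns=["s1", "s2", "s3", "s4", "s5"],
        )
        grouping = pd.Series(
            {"s1": "wt", "s2": "wt", "s3": "ev", "s4": "ev", "s5": "solo"}
        )
        return A, grouping

    def test_mean_and_sd_of_replicates(self):
        A, grouping = self._model()
        summary = oa.activity_summary(A, "ic1", grouping)
        assert summary.loc["wt", "mean"] == pytest.approx(5.0)
        assert summary.loc["wt", "sd"] == pytest.approx(np.sqrt(2))
        assert summary.loc["wt", "n"] == 2

    def test_single_replicate_omits_sd(self):
        A, grouping = self._model()
        summary = oa.activity_summary(A, "ic1", grouping)
        assert summary.loc["solo", "mean"] == 9.0
        assert np.isnan(summary.loc["solo", "sd"])

    def test_unknown_component_rejected(self):
        A, grouping = self._model()
        with pytest.raises(KeyError):
            oa.activity_summary(A, "nope", grouping)

    def test_planted_ordering_preserved(self, modulons, conditions):
        em, S_true, _ = oa.simulate_expression(
            modulons, conditions, noise_sd=0.25, seed=6, n_genes=300
        )
        model = oa.robust_ica(oa.center_to_reference(em), 2, n_restarts=3, seed=0)
        comp = _match_component(S_true["OxyR"], model.S)
        summary = oa.activity_summary(
            model.A, comp, em.sample_conditions
        )
        evolved = abs(summary.loc[["evolved1", "evolved2"], "mean"]).min()
        wt = abs(summary.loc["wt", "mean"])
        assert evolved > wt


class TestDifferentialActivity:
    def _make(self, vals1, vals2):
        cols = [f"a{i}" for i in range(len(vals1))] + [
            f"b{i}" for i in range(len(vals2))
        ]
        A = pd.DataFrame([list(vals1) + list(vals2)], index=["ic1"], columns=cols)
        grouping = pd.Series(
            {c: ("g1" if c.startswith("a") else "g2") for c in cols}
        )
        return A, grouping

    def test_identical_groups_give_zero_and_p_one(self):
        A, g = self._make([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        diff, p = oa.differential_activity(A, "ic1", {"g1"}, {"g2"}, g)
        assert diff == 0.0
        assert p == pytest.approx(1.0)

    def test_label_swap_negates_difference_same_p(self):
        A, g = self._make([1.0, 2.0, 4.0], [5.0, 7.0, 6.0])
        d1, p1 = oa.differential_activity(A, "ic1", {"g1"}, {"g2"}, g)
        d2, p2 = oa.differential_activity(A, "ic1", {"g2"}, {"g1"}, g)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_undersized_group_rejected_with_descriptive_diff(self):
        A, g = self._make([1.0, 2.0], [5.0])
        with pytest.raises(ValueError, match="descriptive difference"):
            oa.differential_activity(A, "ic1", {"g1"}, {"g2"}, g)

    def test_power_at_five_sd_matches_simulated_oracle(self):
        # Welch t, n=3 vs 3, 5 SD shift: true power at alpha=0.01 is ~0.62
        # (simulated independently at 20k reps); 200 reps stay within a
        # 3-sigma binomial band around it.
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            vals1 = rng.normal(0, 1, 3)
            vals2 = rng.normal(5, 1, 3)
            A, g = self._make(vals1, vals2)
            _, p = oa.differential_activity(A, "ic1", {"g1"}, {"g2"}, g)
            hits += p < 0.01
        rate = hits / n_sim
        assert 0.62 - 3 * np.sqrt(0.62 * 0.38 / n_sim) < rate < 0.62 + 3 * np.sqrt(
            0.62 * 0.38 / n_sim
        )
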