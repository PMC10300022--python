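"""Cognitive-score standardisation, lesion statistics, univariate screening,
feature clustering and stepwise regression."""

import numpy as np
import pandas as pd
import pytest

from dynstates import (cluster_reduce_features, correlate_lesion_fo,
                       lesion_frequency_map, stepwise_regression,
                       univariate_group_tests, zscore_tests)


class TestZscore:
    def _norms(self, tests, mean, sd):
        return pd.DataFrame({"mean": mean, "sd": sd}, index=tests)

    def test_raw_equal_to_norm_mean_gives_zero(self):
        raw = pd.DataFrame({"a": [10.0, 10.0], "b": [5.0, 5.0]})
        norms = self._norms(["a", "b"], [10.0, 5.0], [2.0, 1.0])
        assert (zscore_tests(raw, norms) == 0).all().all()

    def test_one_sd_above_gives_one(self):
        raw = pd.DataFrame({"a": [12.0]})
        norms = self._norms(["a"], [10.0], [2.0])
        assert zscore_tests(raw, norms).iloc[0, 0] == 1.0

    def test_identity_norms_no_op(self, rng):
        raw = pd.DataFrame(rng.normal(size=(5, 3)), columns=["a", "b", "c"])
        norms = self._norms(["a", "b", "c"], [0, 0, 0], [1, 1, 1])
        pd.testing.assert_frame_equal(zscore_tests(raw, norms), raw)

    def test_missing_norm_named(self):
        raw = pd.DataFrame({"a": [1.0], "b": [2.0]})
        norms = self._norms(["a"], [0.0], [1.0])
        with pytest.raises(KeyError, match="b"):
            zscore_tests(raw, norms)


class TestLesionCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate_lesion_fo(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = correlate_lesion_fo(x, -x)
        assert r == pytest.approx(-1.0)

    def test_null_p_uniform(self, rng):
        # permutation null: p-values should look uniform
        x = rng.normal(size=25)
        ps = []
        for _ in range(200):
            y = rng.permutation(x)
            ps.append(correlate_lesion_fo(x, y)[1])
        ps = np.asarray(ps)
        assert 0.01 < (ps < 0.05).mean() < 0.12
        assert abs(ps.mean() - 0.5) < 0.08

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_lesion_fo(np.ones(5), np.arange(5.0))


class TestFrequencyMap:
    def test_single_mask_identity(self):
        m = np.zeros((4, 4, 4))
        m[1, 2, 3] = 1
        np.testing.assert_array_equal(lesion_frequency_map([m]), m)

    def test_overlap_fractions(self):
        a = np.zeros((3, 3, 3))
        b = np.zeros((3, 3, 3))
        a[0, 0, 0] = a[1, 1, 1] = 1
        b[1, 1, 1] = b[2, 2, 2] = 1
        freq = lesion_frequency_map([a, b])
        assert freq[1, 1, 1] == 1.0
        assert freq[0, 0, 0] == freq[2, 2, 2] == 0.5

    def test_empty_stack_and_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lesion_frequency_map([np.zeros((3, 3, 3))])
        with pytest.raises(ValueError):
            lesion_frequency_map([np.ones((3, 3, 3)), np.ones((4, 3, 3))])


class TestUnivariate:
    def test_identical_subgroups_nothing_significant(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        X = pd.concat([X, X], ignore_index=True)
        out = univariate_group_tests(X, [0] * 10 + [1] * 10)
        assert not out["significant"].any()

    def test_planted_shift_detected_with_unbalanced_subgroups(self, rng):
        # 2-SD shift in one test, subgroup sizes 8 vs 23
        hits = 0
        for _ in range(100):
            labels = np.array([0] * 8 + [1] * 23)
            col = rng.normal(size=31)
            col[labels == 0] += 2.0
            table = pd.DataFrame({"planted": col,
                                  "noise": rng.normal(size=31)})
            out = univariate_group_tests(table, labels).set_index("test")
            hits += bool(out.loc["planted", "significant"])
        assert hits > 90

    def test_invariant_to_column_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        labels = [0] * 10 + [1] * 10
        out1 = univariate_group_tests(X, labels).set_index("test")
        out2 = univariate_group_tests(X[["c", "a", "b"]], labels).set_index("test")
        for t in "abc":
            assert out1.loc[t, "p_raw"] == out2.loc[t, "p_raw"]


class TestClusterReduce:
    def test_identical_pair_collapses(self, rng):
        z = rng.normal(size=30)
        table = pd.DataFrame({"a": z, "b": z, "c": rng.normal(size=30)})
        target = z + rng.normal(0, 0.1, size=30)
        sel = cluster_reduce_features(table, target)
        assert len(sel) == 2
        assert "c" in sel and ("a" in sel or "b" in sel)

    def test_redundant_battery_reduced_but_not_collapsed(self, rng):
        from dynstates import CognitiveSimConfig, simulate_cognitive_scores
        fo = rng.uniform(0, 1, size=33)
        cfg = CognitiveSimConfig()  # 24 tests, 7 latent factors, 2 planted
        table = simulate_cognitive_scores(fo, cfg, rng)
        sel = cluster_reduce_features(table, fo)
        assert cfg.n_latent <= len(sel) < cfg.n_tests

    def test_invariant_to_subject_order(self, rng):
        table = pd.DataFrame(rng.normal(size=(25, 6)),
                             columns=list("abcdef"))
        target = rng.normal(size=25)
        sel1 = cluster_reduce_features(table, target)
        order = rng.permutation(25)
        sel2 = cluster_reduce_features(table.iloc[order].reset_index(drop=True),
                                       target[order])
        assert sel1 == sel2


class TestStepwise:
    def test_exact_single_predictor_recovery(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"x{j}" for j in range(5)])
        y = X["x2"].to_numpy().copy()
        res = stepwise_regression(X, y)
        assert res.selected == ["x2"]
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.beta["x2"] == pytest.approx(y.std(), rel=1e-6)

    def test_null_false_entry_control(self, rng):
        # under the null, more than one retained term should be rare
        few = 0
        for _ in range(200):
            X = pd.DataFrame(rng.normal(size=(30, 10)))
            X.columns = [f"x{j}" for j in range(10)]
            res = stepwise_regression(X, rng.normal(size=30))
            few += len(res.selected) <= 1
        assert few >= 160  # >= 80% of nulls

    def test_planted_signed_recovery_and_antisymmetry(self, rng):
        # two-state toy: FO6 = 1 - FO5, so the two models must mirror
        n = 33
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"x{j}" for j in range(6)])
        fo5 = 0.5 + 0.2 * X["x0"].to_numpy() - 0.2 * X["x1"].to_numpy() \
            + rng.normal(0, 0.05, size=n)
        fo6 = 1.0 - fo5
        m5 = stepwise_regression(X, fo5)
        m6 = stepwise_regression(X, fo6)
        assert {"x0", "x1"} <= set(m5.selected)
        assert m5.beta["x0"] > 0 > m5.beta["x1"]
        for term in m5.selected:
            assert m6.beta[term] == pytest.approx(-m5.beta[term], abs=1e-10)
        assert m5.r_squared > 0.8

    def test_r_squared_equals_one_minus_sse_over_sst(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + 0.5 * X["b"].to_numpy() + rng.normal(size=50)
        res = stepwise_regression(X, y)
        sse = ((y - res.fitted) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert res.r_squared == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_aliased_column_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X["c"] = X["a"]  # exact alias
        y = X["a"].to_numpy() + rng.normal(0, 0.1, size=30)
        res = stepwise_regression(X, y)
        assert not {"a", "c"} <= set(res.selected)
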