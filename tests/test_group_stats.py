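import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uapipe.errors import ConfigurationError
from uapipe.group_stats import (cluster_permutation_test, linear_load_slope,
                                mad_winsorize, random_intercept_model,
                                slope_group_tests, within_subject_center)


def long_table(values_by_subject, group="young"):
    rows = []
    for subj, vals in values_by_subject.items():
        for load, v in zip((1, 2, 3, 4), vals):
            rows.append({"subject": subj, "group": group, "load": load, "value": v})
    return pd.DataFrame(rows)


class TestLinearLoadSlope:
    def test_exact_line(self):
        table = long_table({"s1": [2, 4, 6, 8]})
        out = linear_load_slope(table)
        assert out.loc[0, "beta"] == pytest.approx(2.0)
        assert out.loc[0, "intercept"] == pytest.approx(0.0)

    def test_constant_values(self):
        out = linear_load_slope(long_table({"s1": [5, 5, 5, 5]}))
        assert out.loc[0, "beta"] == pytest.approx(0.0)

    def test_matches_normal_equations(self, rng):
        table = long_table({f"s{i}": rng.standard_normal(4) for i in range(6)})
        out = linear_load_slope(table).set_index("subject")
        for subj, sub in table.groupby("subject"):
            x = sub["load"].to_numpy(float)
            y = sub["value"].to_numpy(float)
            X = np.column_stack([x, np.ones_like(x)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)  # brute-force OLS oracle
            assert out.loc[subj, "beta"] == pytest.approx(beta[0])
            assert out.loc[subj, "intercept"] == pytest.approx(beta[1])

    def test_single_load_level_raises(self):
        table = pd.DataFrame({"subject": ["s1", "s1"], "group": ["g", "g"],
                              "load": [2, 2], "value": [1.0, 2.0]})
        with pytest.raises(ConfigurationError, match="single load"):
            linear_load_slope(table)

    def test_group_tests(self, rng):
        young = {f"y{i}": [0, -1, -2, -3] + rng.standard_normal(4) * 0.1
                 for i in range(5)}
        old = {f"o{i}": [0, -0.2, -0.4, -0.6] + rng.standard_normal(4) * 0.1
               for i in range(5)}
        table = pd.concat([long_table(young, "young"), long_table(old, "old")])
        tests = slope_group_tests(linear_load_slope(table))
        assert tests["within"]["young"]["p"] < 0.01
        assert tests["between"]["p"] < 0.01


class TestMadWinsorize:
    def test_hand_computed_example(self):
        # median 3, scaled MAD = 1.4826, bound 3 + 3*1.4826 = 7.4478
        vals, flags = mad_winsorize(np.array([1.0, 2.0, 3.0, 4.0, 100.0]), k=3)
        assert vals[-1] == pytest.approx(7.4478, abs=1e-4)
        assert list(flags) == [False, False, False, False, True]
        assert np.array_equal(vals[:4], [1, 2, 3, 4])

    def test_no_outliers_identity(self, rng):
        x = rng.standard_normal(20)
        vals, flags = mad_winsorize(x)
        if not flags.any():
            assert np.array_equal(vals, x)

    def test_all_equal_no_flags(self):
        vals, flags = mad_winsorize(np.full(6, 2.5))
        assert not flags.any()
        assert np.array_equal(vals, np.full(6, 2.5))

    def test_degenerate_mad_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mad_winsorize(np.array([1.0, 1.0, 1.0, 1.0, 9.0]))

    def test_too_few_values(self):
        with pytest.raises(ConfigurationError):
            mad_winsorize(np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=4, max_size=40))
    def test_idempotent(self, values):
        x = np.asarray(values)
        once, _ = mad_winsorize(x)
        twice, _ = mad_winsorize(once)
        assert np.allclose(once, twice)


class TestWithinSubjectCenter:
    def test_hand_computed_example(self):
        table = pd.DataFrame({
            "subject": ["a", "a", "b", "b"], "group": ["g"] * 4,
            "load": [1, 2, 1, 2], "value": [1.0, 3.0, 5.0, 7.0]})
        out = within_subject_center(table)
        assert out["value"].tolist() == [3.0, 5.0, 3.0, 5.0]
        before = table.groupby("load")["value"].mean()
        after = out.groupby("load")["value"].mean()
        pd.testing.assert_series_equal(before, after)

    def test_single_subject_unchanged(self):
        table = long_table({"s1": [1, 2, 3, 4]})
        out = within_subject_center(table)
        assert np.allclose(out["value"], table["value"])

    def test_subject_shift_invariance(self):
        base = long_table({"s1": [1, 2, 3, 4], "s2": [2, 3, 4, 5]})
        shifted = base.copy()
        shifted.loc[shifted["subject"] == "s1", "value"] += 17.5
        a = within_subject_center(base)["value"].to_numpy()
        b = within_subject_center(shifted)["value"].to_numpy()
        # the restored group mean absorbs the shift; the within-subject
        # pattern (deviations from the grand mean) is invariant
        assert np.allclose(a - a.mean(), b - b.mean())

    def test_condition_means_preserved_exactly(self, rng):
        table = long_table({f"s{i}": rng.standard_normal(4) for i in range(5)})
        out = within_subject_center(table)
        before = table.groupby("load")["value"].mean().to_numpy()
        after = out.groupby("load")["value"].mean().to_numpy()
        assert np.allclose(before, after, atol=1e-12)

    def test_missing_cells_raise(self):
        table = long_table({"s1": [1, 2, 3, 4]})
        table = pd.concat([table, pd.DataFrame([{"subject": "s2", "group": "young",
                                                 "load": 1, "value": 0.0}])])
        with pytest.raises(ConfigurationError, match="incomplete"):
            within_subject_center(table)


class TestClusterPermutation:
    def test_null_calibration(self, rng):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            data = rng.standard_normal((12, 30))
            res = cluster_permutation_test(data, n_perm=150, seed=rep)
            hits += len(res.significant()) > 0
        assert hits / n_rep <= 0.08

    def test_planted_window_detected(self, rng):
        data = rng.standard_normal((14, 60))
        data[:, 25:35] += 1.5
        res = cluster_permutation_test(data, n_perm=300, seed=1)
        sig = res.significant()
        assert sig
        covered = {t for _, t in sig[0].points}
        assert len(covered & set(range(25, 35))) >= 8

    def test_min_channel_rule(self, rng):
        # strong effect on 2 channels only -> no spatial cluster under min-3
        n_sub, n_ch, n_t = 14, 6, 20
        data = rng.standard_normal((n_sub, n_ch, n_t))
        data[:, :2, 5:15] += 2.5
        # channels 0-1 form an island: a cluster there can never reach 3
        adjacency = np.zeros((n_ch, n_ch), dtype=bool)
        adjacency[0, 1] = adjacency[1, 0] = True
        for i in range(2, n_ch - 1):
            adjacency[i, i + 1] = adjacency[i + 1, i] = True
        res = cluster_permutation_test(data, adjacency=adjacency, n_perm=100,
                                       seed=2)
        assert all(len(c.channels) >= 3 for c in res.clusters)
        assert not res.significant()

    def test_spatial_cluster_detected_with_three_channels(self, rng):
        n_sub, n_ch, n_t = 14, 6, 20
        data = rng.standard_normal((n_sub, n_ch, n_t))
        data[:, :3, 5:15] += 2.0
        adjacency = np.zeros((n_ch, n_ch), dtype=bool)
        for i in range(n_ch - 1):
            adjacency[i, i + 1] = adjacency[i + 1, i] = True
        res = cluster_permutation_test(data, adjacency=adjacency, n_perm=300,
                                       seed=3)
        assert res.significant()

    def test_no_suprathreshold_points_empty(self):
        data = np.zeros((10, 20))
        res = cluster_permutation_test(data, n_perm=50, seed=4)
        assert res.clusters == []

    def test_p_bounds(self, rng):
        data = rng.standard_normal((12, 30)) + 0.8
        res = cluster_permutation_test(data, n_perm=100, seed=5)
        for c in res.clusters:
            assert 1 / 101 <= c.p <= 1.0


class TestRandomInterceptModel:
    def _simulate(self, rng, load_beta=-0.18, age_beta=-0.86, n_per_group=12,
                  noise=0.3):
        rows = []
        for g, age in (("young", 0), ("old", 1)):
            for i in range(n_per_group):
                intercept = 3.0 + 0.5 * rng.standard_normal() + age_beta * age
                for load in (1, 2, 3, 4):
                    rows.append({"subject": f"{g}{i}", "group": g, "load": load,
                                 "value": intercept + load_beta * load
                                 + noise * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_fixed_effect_signs_recovered(self, rng):
        # reference level is 'old' (alphabetical); the planted old deficit
        # of -0.86 appears as a positive 'young' coefficient
        hits_load = hits_age = 0
        n_rep = 10
        for rep in range(n_rep):
            table = self._simulate(np.random.default_rng(rep))
            res = random_intercept_model(table)
            hits_load += res.fixed_effects["load"]["estimate"] < 0
            hits_age += res.fixed_effects["group"]["estimate"] > 0
        assert hits_load == n_rep
        assert hits_age == n_rep

    def test_interaction_dropped_when_absent(self, rng):
        table = self._simulate(rng)
        res = random_intercept_model(table, interaction=True)
        assert res.method == "mixed"
        assert res.interaction_dropped
        assert "interaction" not in res.fixed_effects

    def test_null_effects_type_i_error(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            table = self._simulate(np.random.default_rng(1000 + rep),
                                   load_beta=0.0, age_beta=0.0)
            res = random_intercept_model(table)
            hits += res.fixed_effects["load"]["p"] < 0.05
        assert hits <= 0.05 * n_rep + 2

    def test_two_stage_agrees_on_balanced_design(self, rng):
        table = self._simulate(rng)
        mixed = random_intercept_model(table)
        from uapipe.group_stats import _two_stage
        two = _two_stage(table, "value")
        assert mixed.fixed_effects["load"]["estimate"] == pytest.approx(
            two.fixed_effects["load"]["estimate"], abs=1e-6)

    def test_min_observations_enforced(self):
        table = pd.DataFrame({"subject": ["a"], "group": ["g"], "load": [1],
                              "value": [1.0]})
        with pytest.raises(ConfigurationError):
            random_intercept_model(table)
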