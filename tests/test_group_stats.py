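import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milletsoil import table1
from milletsoil.group_stats import (anova_duncan, duncan_critical_range,
                                    fold_change_report, hellinger,
                                    orthogonal_contrast, spearman_matrix,
                                    variance_partition, _round2)


class TestDuncan:
    def test_critical_values_match_published_table(self):
        # Duncan 5 % significant ranges for error df = 8 (classic tables):
        # p = 2: 3.26, p = 3: 3.40, p = 4: 3.47
        published = {2: 3.26, 3: 3.40, 4: 3.47}
        for p, q_pub in published.items():
            q = duncan_critical_range(0.05, p, 8, mse=1.0, n=1.0)
            assert q == pytest.approx(q_pub, abs=0.02)

    def test_identical_groups_share_letter(self):
        vals = [5.0, 5.1, 4.9] * 2
        groups = ["A"] * 3 + ["B"] * 3
        res = anova_duncan(vals, groups)
        assert res.letters["A"] == res.letters["B"] == "a"

    def test_extreme_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(0)
        vals = np.r_[rng.normal(0, 0.1, 3), rng.normal(100, 0.1, 3)]
        res = anova_duncan(vals, ["lo"] * 3 + ["hi"] * 3)
        assert res.letters["hi"] == "a"
        assert res.letters["lo"] == "b"
        assert res.p_value < 1e-6

    def test_four_group_toy_matches_pairwise_range_oracle(self):
        rng = np.random.default_rng(7)
        means = {"A": 10.0, "B": 9.6, "C": 8.0, "D": 7.9}
        vals, groups = [], []
        for g, m in means.items():
            vals.extend(m + rng.normal(0, 0.3, 3))
            groups.extend([g] * 3)
        res = anova_duncan(vals, groups, alpha=0.05)
        # oracle: exhaustive pairwise sweep with its own LSR computation
        df = pd.DataFrame({"y": vals, "g": groups})
        gm = df.groupby("g")["y"].mean().sort_values(ascending=False)
        mse = res.mse
        dferr = res.df_error
        sig = {}
        names = list(gm.index)
        for i, j in itertools.combinations(range(4), 2):
            span = j - i + 1
            q = stats.studentized_range.ppf(0.95 ** (span - 1), span,
                                            dferr)
            lsr = q * np.sqrt(mse / 3)
            sig[(names[i], names[j])] = gm.iloc[i] - gm.iloc[j] > lsr
        # groups sharing a letter must not be significantly different
        for (a, b), is_sig in sig.items():
            shared = set(res.letters[a]) & set(res.letters[b])
            assert bool(shared) == (not is_sig)

    def test_letters_order_consistent(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            k = 4
            means = rng.uniform(0, 10, k)
            vals, groups = [], []
            for gi in range(k):
                vals.extend(means[gi] + rng.normal(0, 1.0, 3))
                groups.extend([f"g{gi}" for _ in range(3)])
            res = anova_duncan(vals, groups)
            gm = pd.Series(res.means).sort_values(ascending=False)
            letter_rank = {g: min(ord(c) for c in res.letters[g])
                           for g in gm.index}
            ranks = [letter_rank[g] for g in gm.index]
            assert ranks == sorted(ranks)

    def test_zero_variance_everywhere_letters_by_equality(self):
        vals = [1.0, 1.0, 2.0, 2.0, 1.0, 1.0]
        groups = ["a", "a", "b", "b", "c", "c"]
        res = anova_duncan(vals, groups)
        assert res.letters["a"] == res.letters["c"]
        assert res.letters["b"] != res.letters["a"]

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_duncan([1, 2], ["a", "b"])


class TestContrast:
    def test_equal_means_give_null_result(self):
        vals = [10.0, 10.1, 9.9] * 4
        groups = sum([[g] * 3 for g in table1.TREATMENTS], [])
        res = orthogonal_contrast(vals, groups,
                                  {"NPK": 3, "CM": -1, "PM": -1, "SM": -1})
        assert res.estimate == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_closed_form_t(self):
        rng = np.random.default_rng(1)
        data = {"NPK": 10 + rng.normal(0, 0.01, 3)}
        for g in ("CM", "PM", "SM"):
            data[g] = 12 + rng.normal(0, 0.01, 3)
        vals = np.concatenate(list(data.values()))
        groups = sum([[g] * 3 for g in data], [])
        res = orthogonal_contrast(vals, groups,
                                  {"NPK": 3, "CM": -1, "PM": -1, "SM": -1})
        assert res.estimate == pytest.approx(-6.0, abs=0.05)
        assert res.p_value < 0.01
        # closed form: t = estimate / sqrt(MSE * sum(c^2)/n)
        df = pd.DataFrame({"y": vals, "g": groups})
        mse = df.groupby("g")["y"].apply(
            lambda s: ((s - s.mean()) ** 2).sum()).sum() / (12 - 4)
        t_exp = res.estimate / np.sqrt(mse * 12 / 3)
        assert res.t_statistic == pytest.approx(t_exp)

    def test_scale_invariance_of_t(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(10, 1, 12)
        groups = sum([[g] * 3 for g in table1.TREATMENTS], [])
        c = {"NPK": 3, "CM": -1, "PM": -1, "SM": -1}
        a = orthogonal_contrast(vals, groups, c)
        b = orthogonal_contrast(vals * 2, groups, c)
        assert b.estimate == pytest.approx(2 * a.estimate)
        assert b.t_statistic == pytest.approx(a.t_statistic)
        assert b.p_value == pytest.approx(a.p_value)

    def test_nonzero_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 0"):
            orthogonal_contrast([1, 2, 3, 4], ["a", "a", "b", "b"],
                                {"a": 1, "b": 1})


class TestSpearmanGrid:
    def _blocks(self, xs, ys):
        a = pd.DataFrame([xs], index=["x"], columns=list(range(len(xs))))
        b = pd.DataFrame([ys], index=["y"], columns=list(range(len(ys))))
        return a, b

    def test_monotone_cube(self):
        x = np.array([1.0, 2, 3, 4, 5])
        a, b = self._blocks(x, x ** 3)
        out = spearman_matrix(a, b)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_negation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        a, b = self._blocks(x, -x)
        out = spearman_matrix(a, b)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        a, b = self._blocks([1, 2, 2, 3], [1, 3, 2, 4])
        out = spearman_matrix(a, b)
        # average ranks: x -> [1, 2.5, 2.5, 4], y -> [1, 3, 2, 4]
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([1, 3, 2, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.loc[0, "rho"] == pytest.approx(expected)

    def test_constant_variable_flagged(self):
        a, b = self._blocks([1, 1, 1, 1], [1, 2, 3, 4])
        out = spearman_matrix(a, b)
        assert np.isnan(out.loc[0, "rho"])
        assert out.loc[0, "stars"] == ""

    def test_bh_adjustment_is_monotone(self, rng):
        a = pd.DataFrame(rng.random((5, 10)),
                         index=[f"a{i}" for i in range(5)])
        b = pd.DataFrame(rng.random((4, 10)),
                         index=[f"b{i}" for i in range(4)])
        out = spearman_matrix(a, b)
        srt = out.sort_values("p_raw")
        assert srt["p_adj"].is_monotonic_increasing


class TestVPA:
    def test_orthogonal_groups_have_zero_shared_fraction(self):
        rng = np.random.default_rng(0)
        n = 32
        xa = np.tile([1.0, -1.0], n // 2).reshape(-1, 1)
        xb = np.repeat([1.0, -1.0], n // 2).reshape(-1, 1)
        y = 2 * xa + 3 * xb + rng.normal(0, 0.01, (n, 1))
        y = np.hstack([y, -y]) + 10  # positive 2-feature response
        res = variance_partition(y, {"A": xa, "B": xb},
                                 hellinger_transform=False, adjust=False)
        shared = res.fractions[frozenset({"A", "B"})]
        assert shared == pytest.approx(0.0, abs=1e-4)
        # the Ezekiel adjustment shifts shared fractions slightly
        # negative even under exact orthogonality
        adj = variance_partition(y, {"A": xa, "B": xb},
                                 hellinger_transform=False)
        assert adj.fractions[frozenset({"A", "B"})] == pytest.approx(
            -1 / (n - 2), abs=0.01)

    def test_pure_group_a_response(self):
        rng = np.random.default_rng(1)
        n = 24
        xa = rng.normal(size=(n, 2))
        xb = rng.normal(size=(n, 2))
        y = xa @ np.array([[1.0, -2.0], [0.5, 1.0]])
        res = variance_partition(y, {"A": xa, "B": xb},
                                 hellinger_transform=False)
        assert res.unique["A"] == pytest.approx(1.0, abs=0.1)
        assert abs(res.unique["B"]) < 0.1
        assert res.residual == pytest.approx(0.0, abs=0.02)

    def test_three_groups_match_inclusion_exclusion_oracle(self):
        rng = np.random.default_rng(2)
        n = 40
        mats = {k: rng.normal(size=(n, 2)) for k in ("A", "B", "C")}
        y = (mats["A"] @ rng.normal(size=(2, 3))
             + mats["B"] @ rng.normal(size=(2, 3))
             + rng.normal(0, 0.5, (n, 3)))
        res = variance_partition(y, mats, hellinger_transform=False)

        def adj_r2(keys):
            x = np.hstack([mats[k] for k in keys])
            xc = x - x.mean(0)
            yc = y - y.mean(0)
            beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
            r2 = ((xc @ beta) ** 2).sum() / (yc ** 2).sum()
            m = x.shape[1]
            return 1 - (1 - r2) * (n - 1) / (n - m - 1)

        full = adj_r2(["A", "B", "C"])
        # oracle fractions by direct inclusion-exclusion over the 7 fits
        names = ["A", "B", "C"]
        r2 = {frozenset(c): adj_r2(list(c))
              for r in range(1, 4) for c in itertools.combinations(names, r)}
        r2[frozenset()] = 0.0
        F = frozenset(names)
        for t_set, got in res.fractions.items():
            val = 0.0
            for r in range(len(t_set) + 1):
                for sub in itertools.combinations(sorted(t_set), r):
                    u = frozenset(sub)
                    val += (-1) ** (len(t_set) - len(u)) * (
                        r2[F] - r2[F - u])
            assert got == pytest.approx(val, abs=1e-10)
        total = sum(res.fractions.values()) + res.residual
        assert total == pytest.approx(1.0, abs=1e-9)
        assert res.adjusted_r2_full == pytest.approx(full)

    def test_fraction_sum_identity(self):
        rng = np.random.default_rng(3)
        n = 20
        mats = {"A": rng.normal(size=(n, 2)), "B": rng.normal(size=(n, 1))}
        y = rng.random((n, 4)) + 0.5
        res = variance_partition(y, mats)  # hellinger on
        assert sum(res.fractions.values()) + res.residual == pytest.approx(
            1.0, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 20
        a, b = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        y = rng.random((n, 3)) + 0.5
        r1 = variance_partition(y, {"A": a, "B": b})
        r2 = variance_partition(y, {"B": b, "A": a})
        for key in r1.fractions:
            assert r1.fractions[key] == pytest.approx(r2.fractions[key])

    def test_collinear_group_rejected(self):
        rng = np.random.default_rng(5)
        n = 20
        x = rng.normal(size=(n, 1))
        bad = np.hstack([x, 2 * x])
        y = rng.random((n, 3)) + 0.5
        with pytest.raises(ValueError, match="collinear"):
            variance_partition(y, {"A": bad, "B": rng.normal(size=(n, 1))})

    def test_hellinger_rows_are_unit_sum_of_squares(self, rng):
        x = rng.random((5, 8)) + 0.01
        h = hellinger(x)
        np.testing.assert_allclose((h ** 2).sum(axis=1), 1.0)


class TestFoldChangeReport:
    def test_published_summary_reproduces_printed_contrasts(self):
        rep = fold_change_report(table1.summary_frame())
        assert rep["SQI"]["ratio_min"] == 2.85
        assert rep["SQI"]["ratio_max"] == 4.73
        assert rep["pH"]["difference_min"] == 0.05
        assert rep["pH"]["difference_max"] == 0.26
        assert rep["TC"]["ratios"][("SM", 2022)] == 1.11
        assert rep["TP"]["ratios"][("SM", 2022)] == 1.26
        ap_pm = max(v for (t, y), v in rep["AP"]["ratios"].items()
                    if t == "PM")
        assert ap_pm == 1.58

    def test_all_equal_means_give_unit_ratios(self):
        df = pd.DataFrame([
            {"variable": "TC", "year": 2022, "treatment": t, "mean": 5.0}
            for t in table1.TREATMENTS])
        rep = fold_change_report(df)
        assert all(v == 1.0 for v in rep["TC"]["ratios"].values())

    def test_missing_control_mean_raises(self):
        df = pd.DataFrame([
            {"variable": "TC", "year": 2022, "treatment": "CM",
             "mean": 5.0}])
        with pytest.raises(ValueError, match="NPK"):
            fold_change_report(df)

    def test_half_away_from_zero_rounding(self):
        assert _round2(1.125) == 1.13
        assert _round2(-1.125) == -1.13
        assert _round2(0.5649) == 0.56
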