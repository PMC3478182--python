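"""Statistical machinery: intervals, correlations, U tests, ICC, ROC."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluoroquant import (
    PopulationSpec,
    WaterIntervalScheme,
    assign_interval,
    dose_response_report,
    icc_repeatability,
    interval_separation,
    make_population,
    mann_whitney,
    roc_analysis,
    spearman_table,
    subject_level,
)


class TestAssignInterval:
    @pytest.mark.parametrize(
        "ppm,expected",
        [(0.0, 0), (0.15, 0), (0.20, 1), (0.59, 1), (0.595, 1), (0.60, 2),
         (0.89, 2), (0.90, 3), (1.59, 3), (1.60, 4), (2.5, 4), (100.0, 4)],
    )
    def test_boundaries(self, ppm, expected):
        assert assign_interval(ppm) == expected

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            assign_interval(-0.1)

    def test_partition(self, rng):
        scheme = WaterIntervalScheme()
        for ppm in rng.uniform(0, 5, 200):
            assert 0 <= assign_interval(ppm, scheme) <= 4

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            WaterIntervalScheme(boundaries=(0.2, 0.2, 0.9, 1.6))


def _tooth_rows(subject, tf_pair, dq_pair, capture=1):
    rows = []
    for tooth, tf, dq in zip(("UR1", "UL1"), tf_pair, dq_pair):
        rows.append(
            {
                "subject_id": subject, "capture_index": capture, "tooth": tooth,
                "tf": tf, "water_interval": 0, "water_ppm": 0.1,
                "area_ch": dq * 2, "delta_f_ch": 0.5, "delta_q_ch": dq,
                "area_blur": dq * 100, "delta_f_blur": 1.0, "delta_q_blur": dq * 100,
            }
        )
    return rows


class TestSubjectLevel:
    def test_max_tf_rule(self):
        df = pd.DataFrame(_tooth_rows("a", (2, 3), (0.1, 0.2)) + _tooth_rows("b", (0, 0), (0.0, 0.0)))
        subj = subject_level(df).set_index("subject_id")
        assert subj.loc["a", "tf_subject"] == 3
        assert subj.loc["b", "tf_subject"] == 0

    def test_metrics_from_larger_delta_q_tooth(self):
        df = pd.DataFrame(_tooth_rows("a", (1, 1), (0.30, 0.10)))
        subj = subject_level(df).iloc[0]
        assert subj["delta_q_ch"] == 0.30
        assert subj["area_ch"] == 0.60  # companion metric from the same tooth

    def test_excluded_rows_skipped(self):
        rows = _tooth_rows("a", (1, 1), (0.1, 0.1))
        for r in rows:
            r["excluded"] = True
        df = pd.DataFrame(rows + [dict(r, subject_id="b", excluded=False) for r in _tooth_rows("b", (2, 2), (0.2, 0.2))])
        subj = subject_level(df)
        assert subj["subject_id"].tolist() == ["b"]


class TestSpearman:
    def test_monotone_extremes(self):
        df = pd.DataFrame(
            {"tf_subject": [0, 1, 2, 3, 4], "up": [0.1, 0.2, 0.3, 0.4, 0.5],
             "down": [5.0, 4.0, 3.0, 2.0, 1.0]}
        )
        tab = spearman_table(df, metrics=("up", "down")).set_index("metric")
        assert tab.loc["up", "rho"] == pytest.approx(1.0)
        assert tab.loc["down", "rho"] == pytest.approx(-1.0)

    def test_tied_fixture_matches_hand_ranks(self):
        # x: [1, 2, 2, 3, 4, 5] -> ranks [1, 2.5, 2.5, 4, 5, 6]
        # y: [10, 20, 25, 30, 40, 50] -> ranks [1..6]
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([10.0, 20.0, 25.0, 30.0, 40.0, 50.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        ry = np.arange(1.0, 7.0)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on average ranks
        df = pd.DataFrame({"tf_subject": y, "m": x})
        tab = spearman_table(df, metrics=("m",))
        assert tab["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        df = pd.DataFrame({"tf_subject": [1, 1, 1], "m": [0.1, 0.2, 0.3]})
        tab = spearman_table(df, metrics=("m",))
        assert np.isnan(tab["rho"].iloc[0])


class TestMannWhitney:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        u, p = mann_whitney(x, x.copy())
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_fully_separated_4v4_exact(self):
        u, p = mann_whitney(np.array([10.0, 11, 12, 13]), np.array([1.0, 2, 3, 4]))
        assert u == 16.0
        assert p == pytest.approx(2 / 70)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, int(rng.integers(3, 8)))
            y = rng.normal(0.5, 1, int(rng.integers(3, 8)))
            _, p = mann_whitney(x, y)
            p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(p_scipy, abs=1e-12)


class TestIntervalSeparation:
    def _records(self, shift_per_interval, n=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(5):
            for i in range(n):
                rows.append(
                    {"subject_id": f"s{k}_{i}", "water_interval": k,
                     "m": rng.normal(k * shift_per_interval, 1.0)}
                )
        return pd.DataFrame(rows)

    def test_bonferroni_is_tenfold_capped(self):
        sep = interval_separation(self._records(0.8, seed=1), "m")
        raw = sep["p_raw"].to_numpy()
        adj = sep["p_adjusted"].to_numpy()
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(adj[iu], np.minimum(1.0, 10 * raw[iu]))
        assert (adj[iu] >= raw[iu]).all()

    def test_identical_distributions_not_significant(self):
        sep = interval_separation(self._records(0.0, seed=2), "m")
        assert sep["p_adjusted"].loc[0, 4] > 0.05

    def test_empty_interval_not_computable(self):
        df = self._records(1.0, seed=3)
        df = df[df.water_interval != 2]
        sep = interval_separation(df, "m")
        assert np.isnan(sep["p_adjusted"].loc[1, 2])
        assert not np.isnan(sep["p_adjusted"].loc[0, 4])

    def test_path_reported(self):
        sep = interval_separation(self._records(0.5, seed=4), "m")
        assert sep["path"] in ("nonparametric", "anova")
        assert np.isfinite(sep["levene_p"]) and np.isfinite(sep["anova_p"])


def _icc_oracle_2_1(pairs: np.ndarray) -> float:
    """Closed-form two-way random-effects absolute-agreement single-measure ICC."""
    n, k = pairs.shape
    grand = pairs.mean()
    row_means = pairs.mean(axis=1)
    col_means = pairs.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((pairs - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def _frame(self, c1, c2):
        rows = []
        for i, (a, b) in enumerate(zip(c1, c2)):
            rows.append({"subject_id": f"s{i}", "capture_index": 1, "m": a})
            rows.append({"subject_id": f"s{i}", "capture_index": 2, "m": b})
        return pd.DataFrame(rows)

    def test_identical_repeats_icc_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        icc = icc_repeatability(self._frame(vals, vals), metrics=("m",))
        assert icc["icc2_1"].iloc[0] == pytest.approx(1.0)
        assert icc["n_pairs"].iloc[0] == 6

    def test_permuted_repeats_icc_near_zero(self, rng):
        vals = rng.normal(0, 1, 200)
        perm = rng.permutation(vals)
        icc = icc_repeatability(self._frame(vals, perm), metrics=("m",))
        assert icc["icc2_1"].iloc[0] == pytest.approx(0.0, abs=0.1)

    def test_offset_lowers_absolute_agreement(self, rng):
        vals = rng.normal(10, 2, 30)
        shifted = vals + 1.5
        icc = icc_repeatability(self._frame(vals, shifted), metrics=("m",))
        assert icc["icc2_1"].iloc[0] < icc["icc3_1"].iloc[0]
        assert icc["icc3_1"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_closed_form_oracle(self, rng):
        c1 = rng.normal(5, 2, 12)
        c2 = c1 + rng.normal(0, 0.7, 12)
        icc = icc_repeatability(self._frame(c1, c2), metrics=("m",))
        expected = _icc_oracle_2_1(np.column_stack([c1, c2]))
        assert icc["icc2_1"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_too_few_pairs_undefined(self):
        icc = icc_repeatability(self._frame([1.0, 2.0], [1.0, 2.0]), metrics=("m",))
        assert np.isnan(icc["icc2_1"].iloc[0])


class TestRoc:
    def _frame(self, values, tf):
        return pd.DataFrame({"m": values, "tf_subject": tf})

    def test_perfect_separation(self):
        df = self._frame([0.1, 0.2, 0.3, 0.8, 0.9], [0, 1, 2, 3, 4])
        roc = roc_analysis(df, "m")
        assert roc.auc == pytest.approx(1.0)
        thr, sens, spec = roc.operating_point
        assert sens == 1.0 and spec == 1.0

    def test_uninformative_metric(self):
        df = self._frame([0.5] * 8, [0, 0, 1, 2, 3, 3, 4, 4])
        roc = roc_analysis(df, "m")
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_u_statistic(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 30))
            values = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
            tf = rng.integers(0, 6, n)
            if (tf >= 3).all() or (tf < 3).all():
                continue
            df = self._frame(values, tf)
            roc = roc_analysis(df, "m")
            pos = values[tf >= 3]
            neg = values[tf < 3]
            u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert roc.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.normal(0, 1, 40)
        tf = rng.integers(0, 6, 40)
        if (tf >= 3).any() and (tf < 3).any():
            df = self._frame(values, tf)
            roc = roc_analysis(df, "m")
            assert roc.auc == pytest.approx(roc_auc_score(tf >= 3, values), abs=1e-10)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis(self._frame([0.1, 0.2], [0, 1]), "m")


class TestDoseResponseReport:
    def test_mean_delta_q_increases_across_intervals(self):
        df = make_population(PopulationSpec(n_per_interval=60, seed=31))
        report = dose_response_report(df)
        means = report["descriptives"]["delta_q_ch_mean"]
        assert (means.diff().dropna() > 0).all()

    def test_single_interval_degrades_gracefully(self):
        df = make_population(PopulationSpec(n_per_interval=10, seed=32))
        df = df[df.water_interval == 2]
        report = dose_response_report(df)
        assert report["separation"] == {}
        assert any("single interval" in n for n in report["notices"])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            dose_response_report(pd.DataFrame())

    def test_tf_distribution_groups_four_plus(self):
        df = make_population(PopulationSpec(n_per_interval=60, seed=33))
        report = dose_response_report(df)
        tab = report["tf_distribution"]
        assert list(tab.columns) == ["0", "1", "2", "3", "4+"]
        assert tab.to_numpy().sum() == report["subject_table"].shape[0]
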