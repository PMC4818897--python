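import numpy as np
import pytest

from elbow4d import (
    DegenerateTestError,
    ICCResult,
    RatingsMatrix,
    UndefinedICCError,
    cohort_summary,
    icc_oneway_random,
    icc_twoway_random,
    interpret_icc,
    load_rom_table,
    paired_t,
    rom_report,
    round_half_away,
    welch_t,
)


def icc_brute_force(values):
    """From-definitions ANOVA oracle with explicit loops (no vectorization)."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(values[i]) / k for i in range(n)]
    col = [sum(values[:, j]) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_total = sum((values[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    wms = (ss_total - ss_rows) / (n * (k - 1))
    icc1 = (bms - wms) / (bms + (k - 1) * wms)
    icc2 = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    return icc1, icc2


EXAMPLE = np.array(
    [
        [9.0, 2.0, 5.0, 8.0],
        [6.0, 1.0, 3.0, 2.0],
        [8.0, 4.0, 6.0, 8.0],
        [7.0, 1.0, 2.0, 6.0],
        [10.0, 5.0, 6.0, 9.0],
        [6.0, 2.0, 4.0, 7.0],
    ]
)


class TestICC:
    def test_perfect_agreement(self):
        m = RatingsMatrix(np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 3)))
        for fn in (icc_oneway_random, icc_twoway_random):
            res = fn(m)
            assert res.estimate == pytest.approx(1.0)
            assert res.interpretation == "excellent"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = rng.integers(4, 12)
            k = rng.integers(2, 5)
            vals = rng.normal(5, 2, size=(n, k)) + rng.normal(0, 3, size=(n, 1))
            icc1, icc2 = icc_brute_force(vals)
            m = RatingsMatrix(vals)
            assert icc_oneway_random(m).estimate == pytest.approx(icc1, abs=1e-12)
            assert icc_twoway_random(m).estimate == pytest.approx(icc2, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = EXAMPLE.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": EXAMPLE.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
        m = RatingsMatrix(EXAMPLE)
        one = icc_oneway_random(m)
        two = icc_twoway_random(m)
        assert one.estimate == pytest.approx(table.loc["ICC(1,1)", "ICC"], abs=1e-9)
        assert two.estimate == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        # pingouin prints the CI rounded to 2 decimals
        ci1 = np.asarray(table.loc["ICC(1,1)", "CI95"], float)
        np.testing.assert_allclose(one.ci95, ci1, atol=0.0051)
        ci2 = np.asarray(table.loc["ICC(A,1)", "CI95"], float)
        np.testing.assert_allclose(two.ci95, ci2, atol=0.0051)

    def test_affine_invariance(self):
        m = RatingsMatrix(EXAMPLE)
        m2 = RatingsMatrix(3.5 * EXAMPLE + 11.0)
        assert icc_oneway_random(m2).estimate == pytest.approx(
            icc_oneway_random(m).estimate, abs=1e-12
        )
        assert icc_twoway_random(m2).estimate == pytest.approx(
            icc_twoway_random(m).estimate, abs=1e-12
        )

    def test_rater_bias_lowers_absolute_agreement(self):
        # a constant offset on one rater is "error" for ICC(2,1) but not
        # for consistency-style agreement; the estimate must drop
        base = RatingsMatrix(EXAMPLE)
        biased_vals = EXAMPLE.copy()
        biased_vals[:, 0] += 10.0
        biased = RatingsMatrix(biased_vals)
        assert (
            icc_twoway_random(biased).estimate < icc_twoway_random(base).estimate
        )

    def test_constant_matrix_is_undefined(self):
        m = RatingsMatrix(np.full((5, 3), 7.0))
        with pytest.raises(UndefinedICCError):
            icc_oneway_random(m)
        with pytest.raises(UndefinedICCError):
            icc_twoway_random(m)

    def test_result_serializes(self):
        res = icc_twoway_random(RatingsMatrix(EXAMPLE))
        d = res.to_dict()
        assert isinstance(res, ICCResult)
        assert set(d) >= {"model", "estimate", "ci95_lower", "ci95_upper",
                          "interpretation"}

    def test_ratings_matrix_validation(self):
        with pytest.raises(ValueError, match="2 subjects"):
            RatingsMatrix(np.ones((1, 3)))
        bad = EXAMPLE.copy()
        bad[2, 1] = np.nan
        with pytest.raises(ValueError, match=r"\(2, 1\)"):
            RatingsMatrix(bad)


class TestInterpretation:
    @pytest.mark.parametrize(
        "value,label",
        [(0.9, "excellent"), (0.76, "excellent"), (0.75, "fair to good"),
         (0.4, "fair to good"), (0.39, "poor"), (-0.2, "poor")],
    )
    def test_thresholds(self, value, label):
        assert interpret_icc(value) == label


class TestCohortStats:
    def test_summary_mean_and_sample_sd(self):
        mean, sd, n = cohort_summary([2.0, 4.0, 6.0])
        assert (mean, n) == (4.0, 3)
        assert sd == pytest.approx(2.0)

    def test_summary_rejects_empty(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    @pytest.mark.parametrize("x,expected", [(100.7, 101), (-17.3, -17),
                                            (2.5, 3), (-2.5, -3), (0.4, 0)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected

    def test_paired_t_hand_computed(self):
        pre = np.array([30.0, 31.0, 34.0, 40.0])
        post = np.array([45.0, 39.0, 47.0, 58.0])
        t, df, p = paired_t(pre, post)
        assert df == 3
        # diffs 15, 8, 13, 18: mean 13.5, sample SD sqrt(53/3)
        expected_t = 13.5 / (np.sqrt(53.0 / 3.0) / np.sqrt(4.0))
        assert t == pytest.approx(expected_t, rel=1e-12)
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(expected_t, 3), rel=1e-12)
        t_rev, _, p_rev = paired_t(post, pre)
        assert t_rev == pytest.approx(-t)
        assert p_rev == pytest.approx(p)

    def test_paired_t_degenerate_cases(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)
        with pytest.raises(DegenerateTestError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_welch_matches_scipy_equal_var_false(self):
        from scipy import stats as sps

        a = [1.0, 2.0, 4.0, 7.0]
        b = [5.0, 9.0, 10.0, 12.0, 15.0]
        t, df, p = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestRomTable:
    def test_bundled_cohort_means(self):
        df = load_rom_table()
        assert len(df) == 11
        assert round_half_away(df["arc_pre"].mean()) == 101
        assert round_half_away(df["extension_pre"].mean()) == -17

    def test_arc_consistency_enforced(self, tmp_path):
        df = load_rom_table()
        df.loc[0, "arc_pre"] += 5
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="arc != flexion"):
            load_rom_table(bad)

    def test_report_contains_paired_tests_and_groups(self):
        report = rom_report(load_rom_table())
        arc = report["arc"]
        assert arc["n"] == 11 and arc["df"] == 10
        assert arc["post_mean"] > arc["pre_mean"]
        assert 0.0 <= arc["p"] <= 1.0
        assert set(report["groups"]) == {"arthroscopic", "open"}
        assert sum(g["n"] for g in report["groups"].values()) == 11

    def test_from_csv_roundtrip(self, tmp_path):
        path = tmp_path / "ratings.csv"
        path.write_text(
            "subject,s1,s2\nA,1.0,1.1\nB,2.0,2.2\nC,3.0,2.9\n"
        )
        m = RatingsMatrix.from_csv(path)
        assert m.values.shape == (3, 2)
        assert m.row_labels == ["A", "B", "C"]
        assert m.col_labels == ["s1", "s2"]
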