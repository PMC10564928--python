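import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onhpulse.cohort_stats import (
    anova_oneway,
    build_report,
    compute_opp,
    paired_t,
    pearson_r,
    percent_difference,
)

# ---- independent brute-force oracles -------------------------------------


def pearson_brute(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


def paired_t_brute(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    return d.mean() / (d.std(ddof=1) / np.sqrt(n))


def anova_brute(*groups):
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


# ---- unit tests -----------------------------------------------------------


class TestOpp:
    def test_worked_example(self):
        assert compute_opp(99.0, 15.0) == pytest.approx(56.0)

    def test_group_mean_formula_evaluation(self):
        assert compute_opp(98.7, 13.7) == pytest.approx(56.67, abs=0.005)

    def test_map_not_above_iop_rejected(self):
        with pytest.raises(ValueError):
            compute_opp(90.0, 90.0)

    def test_linear_in_both_arguments(self):
        a = compute_opp(100.0, 10.0)
        assert compute_opp(103.0, 10.0) - a == pytest.approx(2.0)
        assert compute_opp(100.0, 13.0) - a == pytest.approx(-2.0)


class TestPercentDifference:
    def test_identical_is_zero(self):
        assert percent_difference(10.0, 10.0) == 0.0

    def test_worked_example(self):
        assert percent_difference(9.0, 11.0) == pytest.approx(20.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 0.0)

    def test_first_denominator_option(self):
        assert percent_difference(10.0, 11.0, denominator="first") \
            == pytest.approx(10.0)

    @given(x=st.floats(0.1, 1e3), y=st.floats(0.1, 1e3),
           k=st.floats(0.01, 100.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetric_and_scale_invariant(self, x, y, k):
        assert percent_difference(x, y) == pytest.approx(
            percent_difference(y, x))
        assert percent_difference(k * x, k * y) == pytest.approx(
            percent_difference(x, y), rel=1e-9)


class TestPearson:
    def test_perfect_positive(self):
        r, p, n = pearson_r([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0) and n == 4

    def test_perfect_negative_affine(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        r, _, _ = pearson_r(x, -2.0 * x + 7.0)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, _, _ = pearson_r(x, y)
            assert r == pytest.approx(pearson_brute(x, y), abs=1e-12)


class TestPairedT:
    def test_identical_vectors_convention(self):
        t, p, n = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_convention(self):
        with pytest.warns(UserWarning, match="infinite"):
            t, p, _ = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            t, _, _ = paired_t(x, y)
            assert t == pytest.approx(paired_t_brute(x, y), abs=1e-10)

    def test_null_type_one_error_rate(self):
        # paired samples drawn from the same law: p should rarely be small
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(200):
            base = rng.normal(size=10)
            x = base + rng.normal(0, 0.5, 10)
            y = base + rng.normal(0, 0.5, 10)
            _, p, _ = paired_t(x, y)
            rejections += p <= 0.05
        assert rejections <= 0.10 * 200


class TestAnova:
    def test_identical_groups_f_zero(self):
        f, p = anova_oneway([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                            [1.0, 2.0, 3.0])
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(0.0, 1e-3, 5)
        g2 = 10.0 + rng.normal(0.0, 1e-3, 5)
        _, p = anova_oneway(g1, g2)
        assert p < 1e-10

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0], [3.0])

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(4, 9)) for _ in range(3)]
            f, _ = anova_oneway(*groups)
            assert f == pytest.approx(anova_brute(*groups), abs=1e-10)


# ---- report ---------------------------------------------------------------


def synthetic_cohort(n=24, seed=0, groups=("ND", "NDR", "NPDR")):
    rng = np.random.default_rng(seed)
    hr = rng.uniform(55, 90, n)
    pa = np.clip(rng.normal(1.8, 1.0, n), 0.2, None)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "group": [groups[i % len(groups)] for i in range(n)],
        "age": rng.normal(60, 12, n),
        "HR": hr,
        "MAP": rng.normal(100, 13, n),
        "IOP": rng.uniform(10, 20, n),
        "HbA1c": rng.normal(7, 1.2, n),
        "PA_RV": pa,
        "PF_RV": hr + rng.normal(0, 0.5, n),
        "r2_RV": rng.uniform(0.4, 0.99, n),
        "PA_ONHT": pa * rng.normal(1.0, 0.1, n),
        "PF_ONHT": hr + rng.normal(0, 0.5, n),
        "r2_ONHT": rng.uniform(0.4, 0.99, n),
        "D_A_R": 1.0 + 0.03 * (pa / pa.max()) + rng.normal(0, 0.005, n),
        "D_V_R": rng.normal(1.04, 0.02, n),
    })


class TestBuildReport:
    def test_constructed_pf_hr_dependency_is_significant(self):
        rep = build_report(synthetic_cohort())
        for roi in ("RV", "ONHT"):
            cell = rep["correlations"][roi][f"PF_{roi}~HR"]["all"]
            assert cell["r"] >= 0.95
            assert cell["p"] < 1e-6

    def test_missing_column_named_in_error(self):
        df = synthetic_cohort().drop(columns=["D_V_R"])
        with pytest.raises(KeyError, match="D_V_R"):
            build_report(df)

    def test_single_group_anova_not_applicable(self):
        rep = build_report(synthetic_cohort(groups=("ND",)))
        assert all(row["anova_p"] is None
                   for row in rep["group_table"].values())

    def test_shuffled_pa_kills_correlation(self):
        df = synthetic_cohort(n=25)
        rng = np.random.default_rng(5)
        near_zero = 0
        n_shuffles = 30
        for _ in range(n_shuffles):
            shuffled = df.copy()
            shuffled["PA_RV"] = rng.permutation(df["PA_RV"].to_numpy())
            rep = build_report(shuffled)
            cell = rep["correlations"]["RV"]["PA_RV~D_A_R"]["all"]
            near_zero += abs(cell["r"]) < 0.3
        assert near_zero >= 0.9 * n_shuffles

    def test_report_deterministic(self):
        df = synthetic_cohort()
        assert build_report(df) == build_report(df)

    def test_qc_exclusion_bookkeeping(self):
        df = synthetic_cohort()
        df.loc[0, "r2_RV"] = 0.05
        rep = build_report(df, qc_mode="fixed", qc_value=0.23)
        assert rep["n_excluded"] == 1
        assert rep["excluded_subjects"] == ["S0"]

    def test_opp_derived_when_absent(self):
        rep = build_report(synthetic_cohort())
        assert "OPP" in rep["group_table"]

    def test_report_writer_outputs(self, tmp_path):
        from onhpulse.cohort_stats import write_report

        rep = build_report(synthetic_cohort())
        write_report(rep, tmp_path)
        assert (tmp_path / "report.json").exists()
        text = (tmp_path / "report.md").read_text()
        assert "PF_RV~HR" in text
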