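import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import studentized_range

from memphys.stats import (
    StudyTable,
    _balanced_anova_arrays,
    normalize_table,
    normalize_to_control,
    stars,
    studentized_range_cdf,
    tukey_hsd,
    two_way_anova,
)


def _table(values: np.ndarray, mems=None, concs=None) -> StudyTable:
    a, b, n = values.shape
    mems = mems or [f"M{i}" for i in range(a)]
    concs = concs or list(range(b))
    rows = [
        {"membrane": mems[i], "conc": concs[j], "replicate": k, "value": values[i, j, k]}
        for i in range(a)
        for j in range(b)
        for k in range(n)
    ]
    return StudyTable(data=pd.DataFrame(rows))


class TestNormalize:
    def test_arithmetic(self):
        assert normalize_to_control([83.0], 73.0)[0] == pytest.approx(1.137, abs=1e-3)
        assert normalize_to_control([73.0], 73.0)[0] == pytest.approx(1.0)
        assert normalize_to_control([0.0], 73.0)[0] == 0.0

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_to_control([1.0], 0.0)

    def test_table_normalization_and_control_error_bars(self):
        rng = np.random.default_rng(3)
        vals = 73.0 + rng.standard_normal((1, 2, 5))
        tbl = _table(vals, mems=["DOPC"], concs=[0, 10])
        norm = normalize_table(tbl)
        ctrl = norm[norm["conc"] == 0].iloc[0]
        raw = vals[0, 0]
        assert ctrl["mean_rel"] == pytest.approx(1.0)
        # control error bar = relative SD of raw control measurements
        assert ctrl["sd_rel"] == pytest.approx(np.std(raw, ddof=1) / raw.mean())


class TestTwoWayAnova:
    def test_matches_brute_force_on_toy_table(self):
        """2x2 balanced table: the SS decomposition equals sums of squares
        computed by direct enumeration over cells."""
        vals = np.array([[[1.0, 2.0], [3.0, 4.0]], [[2.0, 4.0], [6.0, 8.0]]])
        res = two_way_anova(_table(vals))

        # brute force from first principles
        grand = vals.mean()
        ss_a = sum(
            vals.shape[1] * vals.shape[2] * (vals[i].mean() - grand) ** 2
            for i in range(2)
        )
        ss_b = sum(
            vals.shape[0] * vals.shape[2] * (vals[:, j].mean() - grand) ** 2
            for j in range(2)
        )
        ss_cells = sum(
            vals.shape[2] * (vals[i, j].mean() - grand) ** 2
            for i, j in itertools.product(range(2), range(2))
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_res = sum(
            (vals[i, j, k] - vals[i, j].mean()) ** 2
            for i, j, k in itertools.product(range(2), range(2), range(2))
        )
        assert res["membrane"]["sum_sq"] == pytest.approx(ss_a, abs=1e-12)
        assert res["conc"]["sum_sq"] == pytest.approx(ss_b, abs=1e-12)
        assert res["interaction"]["sum_sq"] == pytest.approx(ss_ab, abs=1e-12)
        assert res["residual"]["sum_sq"] == pytest.approx(ss_res, abs=1e-12)
        # df sum to N - 1 and SS sum to total SS
        assert res.table["df"].sum() == vals.size - 1
        assert res.table["sum_sq"].sum() == pytest.approx(
            ((vals - grand) ** 2).sum(), rel=1e-12
        )

    def test_matches_statsmodels_on_random_balanced_table(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(8)
        tbl = _table(rng.normal(10, 2, (3, 6, 3)))
        res = two_way_anova(tbl)
        d = tbl.data.rename(columns={"membrane": "mem"})
        ref = anova_lm(smf.ols("value ~ C(mem) * C(conc)", data=d).fit(), typ=2)
        assert res["membrane"]["F"] == pytest.approx(ref.loc["C(mem)", "F"], rel=1e-9)
        assert res["conc"]["F"] == pytest.approx(ref.loc["C(conc)", "F"], rel=1e-9)
        assert res["interaction"]["p"] == pytest.approx(
            ref.loc["C(mem):C(conc)", "PR(>F)"], rel=1e-9, abs=1e-12
        )

    def test_identical_values_zero_effect_ss(self):
        vals = np.full((2, 3, 2), 5.0)
        vals += np.random.default_rng(0).standard_normal(vals.shape) * 0  # exact
        res = two_way_anova(_table(vals))
        assert res["membrane"]["sum_sq"] == 0.0
        assert res["conc"]["sum_sq"] == 0.0

    def test_single_replicate_rejected(self):
        vals = np.ones((2, 2, 1))
        with pytest.raises(ValueError):
            two_way_anova(_table(vals))

    def test_unbalanced_uses_type2_with_warning(self):
        rng = np.random.default_rng(1)
        tbl = _table(rng.normal(0, 1, (2, 2, 3)))
        tbl.data.drop(index=tbl.data.index[-1], inplace=True)
        with pytest.warns(UserWarning, match="unbalanced"):
            res = two_way_anova(tbl)
        assert not res.balanced
        assert res.df_resid == 2 * 2 * 3 - 1 - 1 - 1 - 1 - 1

    def test_power_against_monte_carlo(self):
        """A concentration shift of one noise SD per rank is detected in
        >90% of simulated 3x6x3 tables (alpha = 0.05, 1000 runs)."""
        rej = 0
        n_sim = 1000
        shift = np.arange(6)[None, :, None] * 1.0
        for i in range(n_sim):
            r = np.random.default_rng(20_000 + i)
            arr = r.standard_normal((3, 6, 3)) + shift
            parts = _balanced_anova_arrays(arr)
            ss, df = parts["conc"]
            ss_r, df_r = parts["residual"]
            F = (ss / df) / (ss_r / df_r)
            if sps.f.sf(F, df, df_r) < 0.05:
                rej += 1
        assert rej / n_sim > 0.90


class TestStudentizedRange:
    @pytest.mark.parametrize(
        "q,k,df",
        [(3.5, 3, 12), (2.0, 6, 45), (5.0, 4, 8), (1.0, 3, 30), (3.0, 2, 10)],
    )
    def test_cdf_matches_scipy(self, q, k, df):
        assert studentized_range_cdf(q, k, df) == pytest.approx(
            studentized_range.cdf(q, k, df), abs=1e-6
        )

    def test_monotone_in_q(self):
        vals = [studentized_range_cdf(q, 4, 20) for q in (1.0, 2.0, 3.0, 4.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestTukey:
    def test_identical_means_p_near_one(self):
        vals = np.tile(np.array([5.0, 5.1, 4.9]), (1, 3, 1)).reshape(1, 3, 3)
        vals = np.stack([vals[0]] * 2)  # 2 membranes, identical groups
        tbl = _table(vals)
        res = tukey_hsd(tbl, "conc-within-membrane")
        assert (res["p"] > 0.99).all()

    def test_two_groups_equals_pooled_t_test(self):
        """With k = 2 the Tukey p equals the two-sided pooled-variance t
        test via q = |t| * sqrt(2)."""
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 6)
        rows = [
            {"membrane": "M", "conc": c, "replicate": i, "value": v}
            for c, arr in [(0, x), (1, y)]
            for i, v in enumerate(arr)
        ]
        tbl = StudyTable(data=pd.DataFrame(rows))
        sp2 = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        df = len(x) + len(y) - 2
        mse = sp2 / df
        res = tukey_hsd(tbl, "conc-within-membrane", mse=mse, df_resid=df)
        t_p = sps.ttest_ind(x, y, equal_var=True).pvalue
        assert res["p"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_three_groups_against_scipy_oracle(self):
        """Known toy data: p within 1e-3 of the studentized-range oracle."""
        rows = []
        data = {0: [1.1, 0.9, 1.0], 10: [1.6, 1.5, 1.7], 40: [2.2, 2.0, 2.1]}
        for c, arr in data.items():
            for i, v in enumerate(arr):
                rows.append({"membrane": "M", "conc": c, "replicate": i, "value": v})
        tbl = StudyTable(data=pd.DataFrame(rows))
        groups = [np.array(v) for v in data.values()]
        sp2 = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df = sum(len(g) - 1 for g in groups)
        mse = sp2 / df
        res = tukey_hsd(tbl, "conc-within-membrane", mse=mse, df_resid=df)
        for _, row in res.iterrows():
            q = row["q"]
            p_ref = float(studentized_range.sf(q, 3, df))
            assert row["p"] == pytest.approx(p_ref, abs=1e-3)

    def test_p_monotone_in_mean_difference(self):
        base = np.array([[[0.0, 0.1, -0.1]], [[0.0, 0.1, -0.1]]])
        ps = []
        for d in (0.5, 1.0, 2.0):
            vals = np.concatenate([base, base + d], axis=1)  # 2 mem x 2 conc
            tbl = _table(vals)
            res = tukey_hsd(tbl, "conc-within-membrane", mse=0.01, df_resid=8)
            ps.append(res["p"].iloc[0])
        assert ps[0] > ps[1] > ps[2]

    def test_membrane_within_conc_family(self):
        rng = np.random.default_rng(9)
        tbl = _table(rng.normal(0, 1, (3, 2, 3)))
        res = tukey_hsd(tbl, "membrane-within-conc")
        # 3 membranes -> 3 pairs per concentration, 2 concentrations
        assert len(res) == 6

    def test_star_annotation_thresholds(self):
        assert stars(0.2) == "ns"
        assert stars(0.03) == "*"
        assert stars(0.004) == "**"
        assert stars(5e-4) == "***"
        assert stars(5e-5) == "****"


def test_null_type_one_error_calibration():
    """Under a simulated null the 5% test rejects ~5% of the time
    (10,000 seeded 3x6x3 tables, tolerance +/-0.01)."""
    rej = 0
    n_sim = 10_000
    for i in range(n_sim):
        arr = np.random.default_rng(50_000 + i).standard_normal((3, 6, 3))
        parts = _balanced_anova_arrays(arr)
        ss, df = parts["conc"]
        ss_r, df_r = parts["residual"]
        F = (ss / df) / (ss_r / df_r)
        if sps.f.sf(F, df, df_r) < 0.05:
            rej += 1
    assert rej / n_sim == pytest.approx(0.05, abs=0.01)
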