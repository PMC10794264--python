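"""Outlier screening, diet x time ANOVA, Shapiro-gated one-way tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from palmtrace.stats import (
    AnovaResult,
    one_way_gate,
    rout_screen,
    two_way_anova,
)


def make_design(effects=None, sd=1.0, n=6, rng=None):
    """Balanced 3-diet x 4-timepoint Gaussian dataset."""
    rng = rng or np.random.default_rng(0)
    effects = effects or {}
    rows = []
    for diet in ("LP", "MP", "HP"):
        for tp in ("P0", "P10", "P21", "P35"):
            mu = effects.get((diet, tp), effects.get(diet, 0.0))
            for _ in range(n):
                rows.append({"diet": diet, "timepoint": tp,
                             "y": mu + rng.normal(0.0, sd)})
    return pd.DataFrame(rows)


class TestRout:
    def test_tight_cluster_untouched(self):
        res = rout_screen([5.0, 5.1, 4.9, 5.05])
        assert res.outliers.size == 0
        assert res.retained.size == 4

    def test_gross_deviate_flagged(self):
        res = rout_screen([5.0, 5.1, 4.9, 5.05, 50.0])
        assert list(res.outliers) == [50.0]
        assert 50.0 not in res.retained

    def test_matches_leave_one_out_robust_z_oracle(self):
        """Any value with a huge leave-one-out robust z must be flagged."""
        rng = np.random.default_rng(5)
        x = np.append(rng.normal(10.0, 0.5, 9), 110.0)
        flagged = set(rout_screen(x).outliers)
        for i, v in enumerate(x):
            rest = np.delete(x, i)
            mad = sps.median_abs_deviation(rest, scale="normal")
            z = abs(v - np.median(rest)) / mad
            if z > 50:
                assert v in flagged
            if z < 2:
                assert v not in flagged

    def test_identical_values_degenerate_scale(self):
        res = rout_screen([7.0] * 6)
        assert res.outliers.size == 0

    def test_degenerate_scale_still_catches_deviate(self):
        res = rout_screen([7.0, 7.0, 7.0, 7.0, 70.0])
        assert list(res.outliers) == [70.0]

    def test_small_samples_skipped(self):
        res = rout_screen([1.0, 2.0])
        assert res.skipped
        assert res.retained.size == 2

    def test_q_validation(self):
        with pytest.raises(ValueError):
            rout_screen([1.0, 2.0, 3.0], q=0.5)

    def test_spares_pure_gaussian_samples(self):
        """Q = 1% removes nothing from clean n=8 samples >=98% of the time."""
        rng = np.random.default_rng(20240117)
        clean = 0
        reps = 1000
        for _ in range(reps):
            clean += rout_screen(rng.normal(0.0, 1.0, 8)).outliers.size == 0
        assert clean / reps >= 0.98


class TestTwoWayAnova:
    def test_parity_with_statsmodels_type3(self):
        """F and p agree with statsmodels anova_lm(typ=3) to 1e-8."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        df = make_design(effects={"LP": 1.0, ("HP", "P35"): -1.5},
                         sd=1.0, n=5, rng=rng)
        # mild imbalance: drop a few rows (no cell emptied)
        df = df.drop(index=[0, 7, 30]).reset_index(drop=True)

        ours = {r.effect: r for r in two_way_anova(df, "y", tukey=False)}
        fit = smf.ols(
            "y ~ C(diet, Sum) * C(timepoint, Sum)", data=df
        ).fit()
        ref = sm.stats.anova_lm(fit, typ=3)
        pairs = {
            "diet": "C(diet, Sum)",
            "timepoint": "C(timepoint, Sum)",
            "diet:timepoint": "C(diet, Sum):C(timepoint, Sum)",
        }
        for name, ref_name in pairs.items():
            assert ours[name].f == pytest.approx(ref.loc[ref_name, "F"], abs=1e-8)
            assert ours[name].p == pytest.approx(ref.loc[ref_name, "PR(>F)"],
                                                 abs=1e-8)

    def test_constant_response_gives_p_one(self):
        df = make_design(sd=0.0)
        df["y"] = 3.14
        for res in two_way_anova(df, "y"):
            assert res.p == 1.0
            assert res.f == 0.0

    def test_empty_cell_raises_with_cells_listed(self):
        df = make_design()
        df = df[~((df["diet"] == "LP") & (df["timepoint"] == "P0"))]
        with pytest.raises(ValueError, match=r"\('LP', 'P0'\)"):
            two_way_anova(df, "y")

    def test_strong_diet_shift_always_detected(self):
        """+4 mUr LP shift at sd 0.5, n=6: diet effect p < 1e-4 in 100/100."""
        rng = np.random.default_rng(20240117)
        for _ in range(100):
            df = make_design(effects={"LP": 4.0}, sd=0.5, n=6, rng=rng)
            res = {r.effect: r for r in two_way_anova(df, "y", tukey=False)}
            assert res["diet"].p < 1e-4

    def test_tukey_only_on_significant_interaction(self):
        rng = np.random.default_rng(1)
        null = make_design(rng=rng)
        res_null = {r.effect: r for r in two_way_anova(null, "y")}
        if res_null["diet:timepoint"].p >= 0.05:
            assert res_null["diet:timepoint"].posthoc == ()

        crossed = make_design(
            effects={("LP", "P0"): 5.0, ("HP", "P35"): 5.0}, sd=0.5, rng=rng
        )
        res = {r.effect: r for r in two_way_anova(crossed, "y")}
        assert res["diet:timepoint"].p < 0.05
        assert len(res["diet:timepoint"].posthoc) == 66  # C(12, 2) cell pairs

    def test_tukey_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(3)
        df = make_design(effects={("LP", "P0"): 3.0}, sd=1.0, rng=rng)
        res = {r.effect: r for r in two_way_anova(df, "y")}
        cells = {
            f"{d}/{t}": g["y"].to_numpy()
            for (d, t), g in df.groupby(["diet", "timepoint"])
        }
        for pair, _, p_adj in res["diet:timepoint"].posthoc:
            g1, g2 = pair.split(" vs ")
            p_raw = sps.ttest_ind(cells[g1], cells[g2]).pvalue
            assert p_adj >= p_raw - 1e-10

    def test_label_permutation_destroys_significance(self):
        """Shuffled labels on a strong-effect dataset: median p > 0.3."""
        rng = np.random.default_rng(20240117)
        df = make_design(effects={"LP": 4.0}, sd=0.5, n=6, rng=rng)
        ps = []
        for _ in range(200):
            shuffled = df.copy()
            idx = rng.permutation(len(df))
            shuffled["diet"] = df["diet"].to_numpy()[idx]
            shuffled["timepoint"] = df["timepoint"].to_numpy()[idx]
            try:
                res = {r.effect: r
                       for r in two_way_anova(shuffled, "y", tukey=False)}
            except ValueError:  # permutation emptied a cell
                continue
            ps.append(res["diet"].p)
        assert np.median(ps) > 0.3


class TestOneWayGate:
    def test_gaussian_groups_take_parametric_route(self):
        rng = np.random.default_rng(20240117)
        groups = [rng.normal(0, 1, 8) for _ in range(3)]
        res = one_way_gate(groups)
        assert res.route == "anova"
        f, p = sps.f_oneway(*groups)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_heavy_tailed_group_routes_nonparametric_in_majority(self):
        rng = np.random.default_rng(20240117)
        n_kruskal = 0
        reps = 100
        for _ in range(reps):
            groups = [rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                      rng.standard_cauchy(10)]
            n_kruskal += one_way_gate(groups).route == "kruskal"
        assert n_kruskal / reps > 0.5

    def test_identical_groups_not_significant(self):
        res = one_way_gate([[5.0] * 6, [5.0] * 6, [5.0] * 6])
        assert res.p == pytest.approx(1.0)

    def test_tiny_group_routes_nonparametric(self):
        res = one_way_gate([[1.0, 2.0], [1.5, 2.5, 3.0], [2.0, 3.0, 4.0]])
        assert res.route == "kruskal"

    def test_dict_input_and_group_count_validation(self):
        rng = np.random.default_rng(0)
        res = one_way_gate({"a": rng.normal(size=6), "b": rng.normal(size=6)})
        assert res.route in ("anova", "kruskal")
        with pytest.raises(ValueError):
            one_way_gate([[1.0, 2.0, 3.0]])
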