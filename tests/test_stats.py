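import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskychoice import (
    bootstrap_median_se,
    correlation,
    correlation_p_from_r,
    drug_effect_table,
    fisher_rz_compare,
    mann_whitney_u,
    mixed_anova,
    route_by_normality,
    wilcoxon_signed_rank,
)


class TestNormalityRouting:
    def test_heavy_tailed_routed_nonparametric(self):
        hits = sum(
            route_by_normality(np.random.default_rng(s).standard_cauchy(200)) == "nonparametric"
            for s in range(40)
        )
        assert hits >= 38

    def test_normal_routed_parametric_at_test_level(self):
        hits = sum(
            route_by_normality(np.random.default_rng(s).standard_normal(200)) == "parametric"
            for s in range(40)
        )
        # Shapiro-Wilk rejects ~5% of truly normal samples
        assert hits >= 33

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            route_by_normality(np.ones(10))
        with pytest.raises(ValueError):
            route_by_normality([1.0, 2.0])


class TestWilcoxon:
    def test_deterministic_shift_is_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=22)
        res = wilcoxon_signed_rank(x + 1.0, x)
        assert res.p < 0.001

    def test_all_zero_differences_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x)

    def test_exact_branch_matches_enumeration(self):
        d = np.array([1.2, -0.7, 2.3, 0.4, -1.9, 3.1])
        res = wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        ws = np.array(
            [sum(r for r, s in zip(ranks, signs) if s > 0)
             for signs in itertools.product([-1, 1], repeat=len(d))]
        )
        w_pos = sum(r for r, x in zip(ranks, d) if x > 0)
        p_exact = min(1.0, 2 * min((ws <= w_pos).mean(), (ws >= w_pos).mean()))
        assert res.extra["method"] == "exact"
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        res = wilcoxon_signed_rank(x + 0.3, x)
        assert res.extra["method"] == "approx"
        assert "z" in res.extra


class TestMannWhitney:
    def test_fully_separated_groups(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0

    def test_identical_groups_midpoint_u(self):
        res = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 0.5])
        assert abs(res.statistic - 8.0) <= 4  # near n_a*n_b/2

    def test_exact_branch_matches_enumeration(self):
        a = np.array([1.1, 3.4, 0.2, 5.6, 2.2])
        b = np.array([4.1, 6.5, 2.9, 7.7, 5.1])
        res = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        us = []
        for idx in itertools.combinations(range(10), 5):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(10) if i not in idx]]
            us.append(sum((x > yv) + 0.5 * (x == yv) for x in ga for yv in gb))
        us = np.array(us)
        u_obs = sum((x > yv) for x in a for yv in b)
        p_exact = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert res.extra["method"] == "exact"
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


def _balanced_table(rng, a=2, b=2, n=8, effect=None):
    rows = []
    for gi in range(a):
        for si in range(n):
            subj = f"g{gi}s{si}"
            for wi in range(b):
                y = rng.normal()
                if effect is not None:
                    y += effect(gi, wi)
                rows.append({"subj": subj, "grp": f"G{gi}", "sess": f"W{wi}", "y": y})
    return pd.DataFrame(rows)


def _splitplot_oracle(df):
    """From-scratch split-plot sums of squares for a balanced 2x2 design."""
    a = df["grp"].nunique()
    b = df["sess"].nunique()
    n = df["subj"].nunique() // a
    grand = df["y"].mean()
    gm = df.groupby("grp")["y"].mean()
    wm = df.groupby("sess")["y"].mean()
    cm = df.groupby(["grp", "sess"])["y"].mean()
    sm = df.groupby(["subj", "grp"])["y"].mean()
    ss_group = b * n * ((gm - grand) ** 2).sum()
    ss_subj = b * ((sm - gm.reindex(sm.index.get_level_values("grp")).to_numpy()) ** 2).sum()
    ss_within = a * n * ((wm - grand) ** 2).sum()
    ss_int = n * sum(
        (cm[g, s] - gm[g] - wm[s] + grand) ** 2 for g in gm.index for s in wm.index
    )
    ss_tot = ((df["y"] - grand) ** 2).sum()
    ss_err = ss_tot - ss_group - ss_subj - ss_within - ss_int
    df_group, df_subj = a - 1, a * (n - 1)
    df_w, df_err = b - 1, a * (n - 1) * (b - 1)
    return {
        "between": (ss_group / df_group) / (ss_subj / df_subj),
        "within": (ss_within / df_w) / (ss_err / df_err),
        "interaction": (ss_int / ((a - 1) * (b - 1))) / (ss_err / df_err),
    }


class TestMixedAnova:
    def test_constant_outcome_gives_zero_f(self):
        df = _balanced_table(np.random.default_rng(0))
        df["y"] = 5.0
        res = mixed_anova(df, "y", "sess", "grp", "subj")
        assert all(r.statistic == 0.0 and r.p == 1.0 for r in res.values())

    def test_pure_interaction_dominates(self):
        # crossed cell means +/-1 (zero main effects) plus tiny noise
        rng = np.random.default_rng(1)
        df = _balanced_table(rng)
        df["y"] = np.where(df["grp"].str[-1] == df["sess"].str[-1], 1.0, -1.0)
        df["y"] += rng.normal(scale=1e-6, size=len(df))
        res = mixed_anova(df, "y", "sess", "grp", "subj")
        assert res["interaction"].statistic > 1e8
        # main-effect F are noise-over-noise ratios, O(1) against the interaction
        assert res["between"].statistic < 100
        assert res["within"].statistic < 100

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        df = _balanced_table(rng, effect=lambda g, w: 0.4 * g + 0.2 * w + 0.3 * g * w)
        res = mixed_anova(df, "y", "sess", "grp", "subj")
        oracle = _splitplot_oracle(df)
        for key in ("between", "within", "interaction"):
            assert res[key].statistic == pytest.approx(oracle[key], abs=1e-8)

    def test_missing_cell_rejected(self):
        df = _balanced_table(np.random.default_rng(3)).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(df, "y", "sess", "grp", "subj")


class TestCorrelation:
    @pytest.mark.parametrize(
        "r,n,expected_p",
        [(-0.384, 43, 0.011), (-0.348, 43, 0.022), (-0.592, 21, 0.005)],
    )
    def test_p_from_printed_rho_and_df(self, r, n, expected_p):
        assert correlation_p_from_r(r, n) == pytest.approx(expected_p, abs=5e-4)

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = correlation(x, 2 * x + 1, "pearson")
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_spearman_uses_midranks(self):
        x = [1, 2, 2, 3, 4, 5]
        y = [2, 1, 3, 5, 4, 6]
        res = correlation(x, y, "spearman")
        assert res.statistic == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.ones(10), np.arange(10.0))


class TestFisherRz:
    def test_printed_group_comparison(self):
        res = fisher_rz_compare(-0.592, 21, -0.021, 22)
        assert round(res.statistic, 2) == -2.01

    def test_equal_correlations_give_zero(self):
        res = fisher_rz_compare(0.4, 30, 0.4, 50)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetric_in_arguments(self):
        a = fisher_rz_compare(0.6, 25, 0.1, 30)
        b = fisher_rz_compare(0.1, 30, 0.6, 25)
        assert a.statistic == pytest.approx(-b.statistic)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_rz_compare(1.0, 10, 0.5, 10)


class TestBootstrapMedianSe:
    def test_constant_vector_gives_zero(self):
        assert bootstrap_median_se(np.full(20, 3.0), n_boot=1000, seed=0) == 0.0

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(0).normal(size=30)
        a = bootstrap_median_se(x, n_boot=5000, seed=42)
        b = bootstrap_median_se(x, n_boot=5000, seed=42)
        assert a == b

    def test_tracks_asymptotic_formula(self):
        # SE of the median of n normals ~ 1.2533 sigma / sqrt(n)
        ses = [
            bootstrap_median_se(np.random.default_rng(s).normal(size=100), n_boot=20_000, seed=s)
            for s in range(5)
        ]
        assert np.mean(ses) == pytest.approx(1.2533 / 10, rel=0.25)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median_se([1.0])


class TestDrugEffectTable:
    def _params(self):
        rows = []
        for sid, lam_off, lam_on in [("a", 1.0, 1.0), ("b", 2.0, 1.5)]:
            for sess, lam in [("OFF", lam_off), ("ON", lam_on)]:
                rows.append({"subject_id": sid, "group": "PD_dep_hist", "session": sess,
                             "lam": lam, "mu": 1.0, "c": -1.0 if sess == "OFF" else 0.0})
        return pd.DataFrame(rows)

    def _clinical(self):
        return pd.DataFrame(
            {"subject_id": ["a", "b"], "group": ["PD_dep_hist"] * 2,
             "bdi_off": [10, 6], "bdi_on": [6, 6], "led": [500.0, 600.0],
             "icd_flag": [False, True]}
        )

    def test_sign_conventions(self):
        out = drug_effect_table(self._params(), self._clinical())
        a = out[out["subject_id"] == "a"].iloc[0]
        assert a["d_lam"] == 0.0
        assert a["d_c"] == 1.0
        assert a["d_bdi"] == 4.0  # BDI_OFF - BDI_ON: positive = improvement ON

    def test_unmatched_subject_rejected(self):
        params = self._params().iloc[:-1]  # subject b missing its ON session
        with pytest.raises(ValueError, match="missing a session"):
            drug_effect_table(params, self._clinical())
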