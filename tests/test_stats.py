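"""Statistical battery: printed-summary t-tests, chi-square and U
oracles, log screening, the mixed ANCOVA against an independent GLM
route, and partial correlations against the closed form and pingouin."""

import math

import numpy as np
import pandas as pd
import pytest

from leukozone.stats import (
    StatResult,
    UnbalancedDesignError,
    analysis_report,
    chi_square_counts,
    log_screen,
    mann_whitney_u,
    mixed_ancova,
    partial_correlation,
    two_sample_t,
    two_sample_t_from_vectors,
)


class TestTwoSampleT:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (408015.7, 60602.5, 432537.5, 39577.2, 1.397),  # white matter volume
            (1615269.0, 178016.0, 1605508.0, 137530.0, 0.179),  # TICV
        ],
    )
    def test_printed_summary_values(self, m1, s1, m2, s2, expected):
        res = two_sample_t(m1, s1, 17, m2, s2, 17)
        assert abs(res.value) == pytest.approx(expected, abs=5e-4)
        assert res.df == 32.0

    def test_equal_moments_give_zero(self):
        assert two_sample_t(5.0, 2.0, 10, 5.0, 2.0, 10).value == 0.0

    def test_zero_variance_equal_means_convention(self):
        res = two_sample_t(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert res.value == 0.0 and res.p == 1.0

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t(3.0, 0.0, 5, 4.0, 0.0, 5)

    def test_summary_equals_raw_vectors_to_ten_digits(self, rng):
        for _ in range(5):
            x = rng.normal(3.0, 2.0, size=17)
            y = rng.normal(2.0, 1.5, size=17)
            from_raw = two_sample_t_from_vectors(x, y)
            from_stats = two_sample_t(
                float(x.mean()), float(x.std(ddof=1)), 17,
                float(y.mean()), float(y.std(ddof=1)), 17,
            )
            assert from_raw.value == pytest.approx(from_stats.value, rel=1e-10)

    def test_welch_df_formula(self):
        res = two_sample_t(1.0, 1.0, 10, 0.0, 3.0, 20, pooled=False)
        v1, v2 = 1.0 / 10, 9.0 / 20
        expected_df = (v1 + v2) ** 2 / (v1**2 / 9 + v2**2 / 19)
        assert res.df == pytest.approx(expected_df)


class TestChiSquare:
    def test_identical_rows_are_zero(self):
        assert chi_square_counts([[11, 6], [11, 6]]).value == 0.0

    def test_textbook_expected_count_oracle(self):
        table = np.array([[10, 5], [3, 12]], float)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert chi_square_counts(table).value == pytest.approx(by_hand, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_counts([[0, 0], [3, 4]])


class TestMannWhitney:
    def test_identical_vectors_full_tie(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney_u(x, x).value == pytest.approx(len(x) ** 2 / 2)

    def test_complete_separation_gives_zero(self):
        assert mann_whitney_u([1, 2, 3], [10, 11, 12]).value == 0.0

    def test_matches_all_pairs_win_count(self, rng):
        x = rng.integers(0, 6, size=12).astype(float)
        y = rng.integers(0, 6, size=9).astype(float)
        wins = sum(1.0 for a in x for b in y if a > b)
        ties = sum(0.5 for a in x for b in y if a == b)
        assert mann_whitney_u(x, y).value == pytest.approx(wins + ties)


class TestLogScreen:
    def test_zeros_map_to_zeros(self):
        s = log_screen(np.zeros(10), offset=1.0)
        assert (s.transformed == 0.0).all()

    def test_monotone(self, rng):
        x = rng.gamma(2.0, 3.0, size=50)
        s = log_screen(x)
        assert (np.argsort(s.transformed) == np.argsort(x)).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_screen([-1.0, 2.0])

    def test_lognormal_sample_normalizes_and_matches_moment_formula(self, rng):
        x = rng.lognormal(0.0, 0.8, size=200)
        s = log_screen(x, offset=0.0)
        t = np.log(x)
        m2 = ((t - t.mean()) ** 2).mean()
        m3 = ((t - t.mean()) ** 3).mean()
        assert s.skewness == pytest.approx(m3 / m2**1.5, rel=1e-10)
        assert -1.0 <= s.skewness <= 1.0


def small_mixed_dataset(seed=0, n_per_group=4, k=3):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    rows = []
    cov = rng.normal(size=n)
    for i in range(n):
        grp = "A" if i < n_per_group else "B"
        base = rng.normal()
        for lev in range(k):
            rows.append(
                dict(subject=f"s{i}", group=grp, level=f"L{lev}",
                     value=base + 0.5 * lev + 0.3 * cov[i] + rng.normal(scale=0.5),
                     covariate=cov[i])
            )
    return pd.DataFrame(rows)


class TestMixedAncova:
    def test_matches_independent_glm_route(self):
        """Pool Type-III SS from per-contrast statsmodels OLS fits, using
        a different contrast basis, and compare every effect."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = small_mixed_dataset(seed=5)
        got = mixed_ancova(df)

        wide = df.pivot(index="subject", columns="level", values="value")
        per = df.drop_duplicates("subject").set_index("subject")
        meta = per.loc[wide.index]
        Y = wide.to_numpy()
        k = Y.shape[1]
        # polynomial (not QR-derived) orthonormal contrasts
        lin = np.array([-1.0, 0.0, 1.0]) / math.sqrt(2.0)
        quad = np.array([1.0, -2.0, 1.0]) / math.sqrt(6.0)
        contrasts = np.column_stack([lin, quad])
        Z = Y @ contrasts
        ss = {"Intercept": 0.0, "cov": 0.0, "grp": 0.0, "err": 0.0}
        for j in range(k - 1):
            d = pd.DataFrame({
                "z": Z[:, j],
                "cov": meta["covariate"].to_numpy() - meta["covariate"].mean(),
                "grp": meta["group"].to_numpy(),
            })
            fit = smf.ols("z ~ cov + C(grp, Sum)", data=d).fit()
            tab = anova_lm(fit, typ=3)
            ss["Intercept"] += tab.loc["Intercept", "sum_sq"]
            ss["cov"] += tab.loc["cov", "sum_sq"]
            ss["grp"] += tab.loc["C(grp, Sum)", "sum_sq"]
            ss["err"] += tab.loc["Residual", "sum_sq"]
        n, g = Y.shape[0], 2
        df_err = (k - 1) * (n - 1 - g)
        for effect, key, df_eff in (
            ("region", "Intercept", k - 1),
            ("region_x_covariate", "cov", k - 1),
            ("region_x_group", "grp", k - 1),
        ):
            f_expected = (ss[key] / df_eff) / (ss["err"] / df_err)
            assert got[effect].value == pytest.approx(f_expected, rel=1e-9)
            assert got[effect].effect_size == pytest.approx(
                ss[key] / (ss[key] + ss["err"]), rel=1e-9)
            assert got[effect].df == (df_eff, df_err)

        # between-subject effect: ANCOVA on subject means
        d = pd.DataFrame({
            "m": Y.mean(axis=1),
            "cov": meta["covariate"].to_numpy() - meta["covariate"].mean(),
            "grp": meta["group"].to_numpy(),
        })
        tab = anova_lm(smf.ols("m ~ cov + C(grp, Sum)", data=d).fit(), typ=3)
        f_grp = (tab.loc["C(grp, Sum)", "sum_sq"] / 1) / (
            tab.loc["Residual", "sum_sq"] / (n - 3))
        assert got["group"].value == pytest.approx(f_grp, rel=1e-9)

    def test_df_convention_at_cohort_size(self):
        df = small_mixed_dataset(seed=1, n_per_group=17, k=3)
        got = mixed_ancova(df)
        assert got["region"].df == (2.0, 62.0)
        assert got["region_x_group"].df == (2.0, 62.0)
        assert got["group"].df == (1.0, 31.0)

    def test_two_level_factor_df(self):
        df = small_mixed_dataset(seed=2, n_per_group=17, k=2)
        got = mixed_ancova(df)
        assert got["region"].df == (1.0, 31.0)

    def test_partial_eta_squared_bounds(self):
        got = mixed_ancova(small_mixed_dataset(seed=3))
        for res in got.values():
            assert 0.0 <= res.effect_size <= 1.0

    def test_unbalanced_design_names_subjects(self):
        df = small_mixed_dataset(seed=4)
        df = df[~((df.subject == "s1") & (df.level == "L2"))]
        with pytest.raises(UnbalancedDesignError, match="s1"):
            mixed_ancova(df)

    def test_varying_covariate_rejected(self):
        df = small_mixed_dataset(seed=4)
        df.loc[df.index[0], "covariate"] += 1.0
        with pytest.raises(ValueError, match="covariate varies"):
            mixed_ancova(df)

    def test_effect_size_monotone_in_planted_interaction(self):
        """Mean partial eta squared for the interaction grows with the
        planted group-by-region effect."""
        means = []
        rng = np.random.default_rng(99)
        for effect in (0.0, 0.4, 0.8):
            etas = []
            for _ in range(40):
                n, k = 17, 3
                rows = []
                for i in range(2 * n):
                    grp = "A" if i < n else "B"
                    cov = rng.normal()
                    base = rng.normal()
                    for lev in range(k):
                        bump = effect * lev if grp == "A" else 0.0
                        rows.append(dict(subject=i, group=grp, level=lev,
                                         value=base + bump + rng.normal(),
                                         covariate=cov))
                etas.append(mixed_ancova(pd.DataFrame(rows))["region_x_group"].effect_size)
            means.append(np.mean(etas))
        assert means[0] < means[1] < means[2]


class TestPartialCorrelation:
    def test_self_correlation_near_one(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        res = partial_correlation(x, x, z)
        assert res.value == pytest.approx(1.0)

    def test_closed_form_identity(self, rng):
        for _ in range(5):
            x = rng.normal(size=25)
            z = rng.normal(size=25)
            y = 0.4 * x - 0.3 * z + rng.normal(size=25)
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            closed = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            assert partial_correlation(x, y, z).value == pytest.approx(closed, rel=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = -0.5 * x + 0.2 * z + rng.normal(size=40)
        ours = partial_correlation(x, y, z)
        theirs = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                                 x="x", y="y", covar="z")
        assert ours.value == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation([1.0] * 10, list(range(10)), list(range(10)))


@pytest.fixture(scope="module")
def cohort():
    from leukozone.cohort import simulate_cohort

    return simulate_cohort(seed=21)


class TestAnalysisReport:
    def test_report_complete_with_finite_statistics(self, cohort):
        report = analysis_report(cohort)
        assert report["n"] == 34 and report["groups"] == {"AF": 17, "non-AF": 17}
        for block in ("depth_ancova", "anterior_posterior_ancova"):
            for eff in report[block].values():
                assert np.isfinite(eff["value"]) and 0.0 <= eff["p"] <= 1.0
        assert len(report["thickness_partial_correlations"]) == 8
        for d in report["group_comparisons"].values():
            assert np.isfinite(d["value"])

    def test_identical_groups_mostly_nonsignificant(self):
        from leukozone.cohort import pilot_preset, simulate_cohort
        import dataclasses

        spec = pilot_preset()
        af = spec.groups[0]
        twin = dataclasses.replace(af, name="non-AF")
        spec = dataclasses.replace(spec, groups=(af, twin))
        report = analysis_report(simulate_cohort(spec, seed=8))
        ps = [d["p"] for d in report["group_comparisons"].values() if d.get("p") is not None]
        assert np.mean([p > 0.05 for p in ps]) >= 0.8

    def test_report_is_deterministic(self, cohort):
        import json

        a = json.dumps(analysis_report(cohort), sort_keys=True)
        b = json.dumps(analysis_report(cohort), sort_keys=True)
        assert a == b
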