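"""Spearman, ICC, GEE group tests and the cross-sectional report."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from izmap.stats import (
    cross_sectional_report,
    gee_group_test,
    icc_agreement,
    pool_stage,
    spearman,
)


class TestPoolStage:
    @pytest.mark.parametrize(
        "stage,group",
        [(0, "early"), (1, "early"), (2, "early"), (3, "moderate"), (4, "moderate"),
         (5, "moderate"), (6, "advanced")],
    )
    def test_mapping(self, stage, group):
        assert pool_stage(stage) == group

    @pytest.mark.parametrize("stage", [-1, 7, 3.5])
    def test_out_of_range_raises(self, stage):
        with pytest.raises(ValueError):
            pool_stage(stage)


class TestSpearman:
    def test_perfect_concordance(self):
        r = spearman(np.arange(1, 11), np.arange(1, 11))
        assert r.rho == pytest.approx(1.0)
        # exact permutation p: only the 2 fully concordant/discordant
        # pairings of 10 distinct ranks reach |rho| = 1
        assert r.p_value == pytest.approx(2 / math.factorial(10))

    def test_perfect_reversal(self):
        r = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)
        assert r.p_value == pytest.approx(2 / math.factorial(5))

    def test_tied_vector_matches_enumeration_oracle(self):
        from scipy import stats as sps

        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 2.0, 4.0, 3.0, 5.0, 5.0, 6.0])
        res = spearman(x, y)
        # midrank rho by brute force
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_expected = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(rho_expected)
        # p by full 8! enumeration (independent loop)
        a = (rx - rx.mean()) / np.linalg.norm(rx - rx.mean())
        b = (ry - ry.mean()) / np.linalg.norm(ry - ry.mean())
        count = sum(
            abs(float(a @ b[list(perm)])) >= abs(rho_expected) - 1e-12
            for perm in itertools.permutations(range(8))
        )
        assert res.p_value == pytest.approx(count / math.factorial(8))

    def test_large_n_matches_scipy_t_approximation(self, rng):
        from scipy import stats as sps

        x = rng.integers(0, 7, 30).astype(float)
        y = x + rng.normal(0, 2, 30)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y)
        trans = spearman(np.exp(x), y**3)
        assert trans.rho == pytest.approx(base.rho)
        assert trans.p_value == pytest.approx(base.p_value)

    def test_constant_vector_is_undefined(self):
        res = spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert math.isnan(res.rho)


class TestICC:
    FIXTURE = np.array([[1, 1.1], [2, 2.2], [3, 2.9], [4, 4.3], [5, 4.8], [6, 6.1]])

    def test_duplicated_grader_gives_one(self):
        m = np.column_stack([self.FIXTURE[:, 0], self.FIXTURE[:, 0]])
        assert icc_agreement(m).icc == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self, rng):
        m = rng.normal(size=(300, 2))
        assert abs(icc_agreement(m).icc) < 0.15

    def test_fixture_matches_anova_by_hand(self):
        # hand-computed two-way ANOVA mean squares for the 6x2 fixture,
        # cross-checked against pingouin's ICC2 (absolute agreement)
        res = icc_agreement(self.FIXTURE)
        assert res.icc == pytest.approx(0.995150, abs=1e-6)
        assert res.p_value == pytest.approx(1.729421e-06, rel=1e-4)

    def test_agrees_with_pingouin_on_random_tables(self, rng):
        import pingouin as pg

        for _ in range(3):
            m = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1)) * 2
            res = icc_agreement(m)
            df = pd.DataFrame(
                {
                    "subj": np.repeat(np.arange(12), 2),
                    "rater": np.tile([0, 1], 12),
                    "y": m.ravel(),
                }
            )
            tbl = pg.intraclass_corr(df, "subj", "rater", "y")
            ref = tbl.loc[tbl["Type"] == "ICC(A,1)", "ICC"].iloc[0]
            assert res.icc == pytest.approx(float(ref), abs=1e-9)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            icc_agreement(np.ones((3, 2)))


def make_cohort(rng, n_clusters=60, means=(0.0, 1.0, 2.0), icc_rho=0.5, sigma=1.0):
    groups = ["early", "moderate", "advanced"]
    rows = []
    sd_b = sigma * math.sqrt(icc_rho)
    sd_w = sigma * math.sqrt(1 - icc_rho)
    for c in range(n_clusters):
        g = groups[c % 3]
        mu = means[c % 3]
        b = rng.normal(0, sd_b)
        for _ in range(2):
            rows.append(
                {"patient_id": f"P{c:03d}", "pooled_group": g, "y": mu + b + rng.normal(0, sd_w)}
            )
    return pd.DataFrame(rows)


class TestGEE:
    def test_recovers_group_means_with_clustered_data(self, rng):
        df = make_cohort(rng, n_clusters=200)
        res = gee_group_test(df, "y")
        for g, mu in zip(("early", "moderate", "advanced"), (0.0, 1.0, 2.0)):
            assert abs(res.group_means[g] - mu) < 2 * res.group_se[g]
        assert res.p_value < 1e-3
        assert res.df == 2

    def test_bonferroni_adjustment_is_three_times_raw_capped(self, rng):
        df = make_cohort(rng, n_clusters=30, means=(0.0, 0.1, 0.2))
        res = gee_group_test(df, "y")
        assert all(0 <= p <= 1 for p in res.pairwise.values())
        assert len(res.pairwise) == 3

    def test_singleton_clusters_match_independence_gee(self, rng):
        import statsmodels.api as sm

        df = make_cohort(rng, n_clusters=90)
        df = df.groupby("patient_id", as_index=False).first()  # one eye per patient
        res = gee_group_test(df, "y")
        X = pd.get_dummies(
            pd.Categorical(df["pooled_group"], categories=["early", "moderate", "advanced"]),
            drop_first=True,
            dtype=float,
        )
        X.insert(0, "const", 1.0)
        ind = sm.GEE(
            df["y"].to_numpy(),
            X.to_numpy(),
            groups=df["patient_id"].to_numpy(),
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
        means_ind = {
            "early": ind.params[0],
            "moderate": ind.params[0] + ind.params[1],
            "advanced": ind.params[0] + ind.params[2],
        }
        for g in means_ind:
            assert res.group_means[g] == pytest.approx(means_ind[g], abs=1e-8)

    def test_missing_outcomes_are_dropped(self, rng):
        df = make_cohort(rng, n_clusters=30)
        df.loc[df.index[:5], "y"] = np.nan
        res = gee_group_test(df, "y")
        assert res.n_obs == len(df) - 5

    def test_single_cluster_group_raises(self, rng):
        df = make_cohort(rng, n_clusters=30)
        df = df[(df.pooled_group != "early") | (df.patient_id == "P000")]
        with pytest.raises(ValueError, match="cluster"):
            gee_group_test(df, "y")


class TestCrossSectionalReport:
    def make_records(self, rng, n=24):
        rows = []
        for i in range(n):
            stage = int(rng.integers(0, 7))
            rows.append(
                {
                    "patient_id": f"P{i // 2:03d}",
                    "stage": stage,
                    "pooled_group": pool_stage(stage),
                    "tel_area_mm2": 0.1 + 0.08 * stage + rng.normal(0, 0.02),
                    "attn_area_mm2": 0.8 + rng.normal(0, 0.2),
                    "izloss_area_mm2": 0.1 * stage + rng.normal(0, 0.05),
                    "ezloss_area_mm2": 0.15 * stage + abs(rng.normal(0, 0.05)),
                    "overlap_attn_pct": 50 - 6 * stage + rng.normal(0, 5),
                    "overlap_izloss_pct": 15 + rng.normal(0, 5),
                    "overlap_ezloss_pct": 10 * stage + rng.normal(0, 5),
                }
            )
        return pd.DataFrame(rows)

    def test_tables_have_expected_structure(self, rng):
        tables = cross_sectional_report(self.make_records(rng))
        corr = tables["correlations"]
        assert len(corr) == 7
        assert {"parameter", "rho", "p_value", "n"} <= set(corr.columns)
        grp = tables["by_group"]
        assert "gee_p" in grp.columns
        assert {"early_mean", "moderate_mean", "advanced_mean"} <= set(grp.columns)

    def test_monotone_parameters_get_expected_correlation_sign(self, rng):
        corr = cross_sectional_report(self.make_records(rng, n=30))["correlations"]
        corr = corr.set_index("parameter")
        assert corr.loc["tel_area_mm2", "rho"] > 0.5
        assert corr.loc["overlap_attn_pct", "rho"] < -0.5

    def test_single_group_omits_gee(self, rng, caplog):
        df = self.make_records(rng, n=12)
        df["pooled_group"] = "early"
        df["stage"] = 1
        tables = cross_sectional_report(df)
        assert "gee_p" not in tables["by_group"].columns

    def test_missing_overlaps_handled_pairwise(self, rng):
        df = self.make_records(rng, n=20)
        df.loc[df.index[:4], "overlap_ezloss_pct"] = np.nan
        corr = cross_sectional_report(df)["correlations"].set_index("parameter")
        assert corr.loc["overlap_ezloss_pct", "n"] == 16
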