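import numpy as np
import pytest

import hemiconn as hc
from hemiconn.asymmetry import AsymmetryProfile
from hemiconn.exceptions import StatsError
from hemiconn.montage import AREAS
from hemiconn.stats import (
    anova_tukey,
    cross_subject_correlation,
    pls_fit,
    run_cohort_analysis,
    shapiro_wilk,
)


class TestShapiroWilk:
    def test_normal_sample(self):
        x = np.random.default_rng(0).standard_normal(100)
        w, p = shapiro_wilk(x)
        assert w > 0.95

    def test_skewed_sample_rejected(self):
        x = np.random.default_rng(1).exponential(size=100)
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_constant_sample_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            w, p = shapiro_wilk(np.ones(10))
        assert np.isnan(w) and np.isnan(p)

    @pytest.mark.parametrize("n", [2, 5001])
    def test_sample_size_bounds(self, n):
        with pytest.raises(StatsError, match="n="):
            shapiro_wilk(np.zeros(n))


class TestCrossSubjectCorrelation:
    def test_identity_and_negation(self):
        x = np.random.default_rng(2).standard_normal(20)
        assert cross_subject_correlation(x, x)[0] == pytest.approx(1.0)
        assert cross_subject_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            cross_subject_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch(self):
        with pytest.raises(StatsError, match="length"):
            cross_subject_correlation([1, 2, 3], [1, 2])

    def test_matches_scipy_p(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 30))
        r, p = cross_subject_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestPLS:
    def test_univariate_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.standard_normal(25)
            y = 0.5 * x + rng.standard_normal(25)
            r2, _ = pls_fit(x, y, n_perm=0)
            r = np.corrcoef(x, y)[0, 1]
            assert r2 == pytest.approx(r**2, abs=1e-10)

    def test_matches_sklearn_pls_regression(self):
        # independent oracle: scikit-learn's NIPALS PLS with one component
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        for p in (1, 3):
            x = rng.standard_normal((30, p))
            y = x @ rng.standard_normal(p) + rng.standard_normal(30)
            r2, _ = pls_fit(x, y, n_perm=0)
            ref = PLSRegression(n_components=1, scale=False).fit(x, y[:, None])
            assert r2 == pytest.approx(ref.score(x, y[:, None]), abs=1e-10)

    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r2, _ = pls_fit(x, 2 * x, n_perm=0)
        assert r2 == pytest.approx(1.0)

    def test_permutation_p_significant_for_strong_signal(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        y = x + 0.2 * rng.standard_normal(40)
        _, p = pls_fit(x, y, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_permutation_p_uniform_under_null(self):
        rng = np.random.default_rng(7)
        ps = []
        for k in range(40):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            ps.append(pls_fit(x, y, n_perm=99, seed=k)[1])
        assert 0.3 < np.mean(ps) < 0.7

    def test_degenerate_variance(self):
        with pytest.raises(StatsError, match="degenerate"):
            pls_fit(np.ones(10), np.arange(10.0))


class TestAnovaTukey:
    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = {g: rng.standard_normal(10) for g in ("a", "b", "c")}
            if anova_tukey(groups).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_detects_shifted_group(self):
        rng = np.random.default_rng(9)
        groups = {
            "a": rng.standard_normal(30),
            "b": rng.standard_normal(30),
            "c": rng.standard_normal(30) + 2.0,
        }
        res = anova_tukey(groups)
        assert res.p < 1e-6
        assert res.pairwise[("a", "c")] < 0.001
        assert res.pairwise[("a", "b")] > 0.05

    def test_degenerate_zero_within_variance(self):
        res = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.degenerate
        assert np.isnan(res.f)

    def test_small_group_rejected(self):
        with pytest.raises(StatsError, match="n="):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


def synthetic_profiles(n, seed, coupled_cells=(), coupling=0.9):
    """AI profiles with optional latent coupling in selected (band, area) cells."""
    rng = np.random.default_rng(seed)
    bands = ["delta", "theta", "alpha", "beta"]
    profiles = []
    latent = rng.standard_normal(n)
    for i in range(n):
        prof = AsymmetryProfile(f"sub-{i:03d}")
        for area in AREAS:
            cell_fc = ("FC-fMRI", "none", area)
            prof.entries[cell_fc] = latent[i] + 0.3 * rng.standard_normal()
            prof.entries[("FC-EEG", "none", area)] = rng.standard_normal()
            for band in bands:
                if (band, area) in coupled_cells:
                    v = coupling * latent[i] + np.sqrt(1 - coupling**2) * rng.standard_normal()
                else:
                    v = rng.standard_normal()
                prof.entries[("powerEEG", band, area)] = v
        prof.entries[("FC-fMRI", "none", "whole")] = 0.0
        prof.entries[("FC-EEG", "none", "whole")] = 0.0
        for band in bands:
            prof.entries[("powerEEG", band, "whole")] = float(
                np.mean([prof.entries[("powerEEG", band, a)] for a in AREAS])
            )
        profiles.append(prof)
    return profiles


class TestRunCohortAnalysis:
    def test_cell_grid_shape(self):
        profiles = synthetic_profiles(19, seed=10)
        stats = run_cohort_analysis(profiles, {}, n_perm=0)
        # 5 areas x 4 bands for the single group
        assert len(stats.correlations) == 20
        assert set(stats.correlations["area"]) == set(AREAS)
        assert "q" in stats.correlations.columns

    def test_coupled_cells_localize(self):
        coupled = {("theta", "frontal"), ("theta", "temporal")}
        profiles = synthetic_profiles(40, seed=11, coupled_cells=coupled)
        stats = run_cohort_analysis(profiles, {}, n_perm=0)
        corr = stats.correlations
        hits = corr[corr["q"] < 0.05]
        got = {(r.band, r.area) for r in hits.itertuples(index=False)}
        assert coupled <= got
        assert len(got - coupled) <= 2

    def test_groups_and_anova(self):
        profiles = synthetic_profiles(30, seed=12)
        groups = {
            p.subject_id: g
            for p, g in zip(profiles, ["inattention"] * 10 + ["motion"] * 10 + ["mixed"] * 10)
        }
        stats = run_cohort_analysis(profiles, groups, n_perm=0)
        assert set(stats.correlations["group"]) == {"inattention", "motion", "mixed", "all"}
        assert not stats.anova.empty
        # matched groups: no wholesale group differences
        assert (stats.anova["p"] < 0.05).mean() < 0.25
        assert not stats.shapiro.empty

    def test_small_group_skipped_with_warning(self):
        profiles = synthetic_profiles(6, seed=13)
        groups = {p.subject_id: ("tiny" if i < 2 else "rest") for i, p in enumerate(profiles)}
        with pytest.warns(UserWarning, match="tiny"):
            stats = run_cohort_analysis(profiles, groups, n_perm=0)
        assert "tiny" not in set(stats.correlations["group"])
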