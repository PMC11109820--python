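import numpy as np
import pandas as pd
import pytest

from parcelmeg import (
    CohortTable,
    build_design,
    fit_glm,
    max_stat_pvalues,
    permutation_maxt,
)
from parcelmeg.glm import _t_stats, format_t
from conftest import small_cohort_config
from parcelmeg import generate_cohort


def _cohort(n_als=36, n_control=51, alsfrs=None, seed=0):
    rng = np.random.default_rng(seed)
    n = n_als + n_control
    alsfrs_vals = np.full(n, np.nan)
    alsfrs_vals[:n_als] = alsfrs if alsfrs is not None else rng.integers(15, 48, n_als)
    umn = np.full(n, np.nan)
    umn[:n_als] = rng.integers(0, 20, n_als)
    onset = np.full(n, np.nan)
    onset[:n_als] = rng.uniform(0.5, 6, n_als)
    return CohortTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["ALS"] * n_als + ["control"] * n_control,
        "age": rng.normal(61, 11, n),
        "sex": rng.choice(["M", "F"], n),
        "handedness": rng.choice(["right", "left"], n, p=[0.9, 0.1]),
        "alsfrs_r": alsfrs_vals,
        "umn_score": umn,
        "years_from_onset": onset,
    }))


class TestBuildDesign:
    def test_group_design_shape_and_contrast(self):
        design = build_design(_cohort(), "group")
        assert design.X.shape == (87, 5)
        assert design.columns[:2] == ("ALS", "control")
        assert design.contrast[:2].tolist() == [1.0, -1.0]
        assert all(design.contrast[2:] == 0)
        # confounds are mean-centered
        assert np.allclose(design.X[:, 2:].mean(axis=0), 0, atol=1e-10)

    def test_full_scale_alsfrs_matches_controls(self):
        cohort = _cohort(n_als=3, n_control=4, alsfrs=[48, 38, 28])
        design = build_design(cohort, "alsfrs_change")
        score = design.X[:, 0]
        assert score[0] == 0.0  # 48 - 48, same as every control
        assert score[1] == 10.0
        assert score[2] == 20.0
        assert all(score[3:] == 0.0)

    def test_delta_alsfrs_value(self):
        cohort = _cohort(n_als=2, n_control=3, alsfrs=[38, 30])
        cohort.df.loc[0, "years_from_onset"] = 2.0
        design = build_design(cohort, "delta_alsfrs")
        assert design.X[0, 0] == pytest.approx((48 - 38) / 2.0)

    def test_missing_covariate_lists_subjects(self):
        cohort = _cohort(n_als=3, n_control=3)
        cohort.df.loc[1, "age"] = np.nan
        with pytest.raises(ValueError, match="s1"):
            build_design(cohort, "group")

    def test_all_zero_scores_degenerate(self):
        cohort = _cohort(n_als=3, n_control=4, alsfrs=[48, 48, 48])
        with pytest.raises(ValueError, match="degenerate"):
            build_design(cohort, "alsfrs_change")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            build_design(_cohort(n_als=3, n_control=3), "bonferroni")


class TestFitGlm:
    def test_null_t_matches_student_distribution(self):
        """On independent Gaussian outcomes the contrast t follows
        Student-t(n - rank); its SD over many draws matches the closed form
        within 3%."""
        design = build_design(_cohort(), "group")
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((87, 10000))
        t, dof = _t_stats(Y, design.X, design.contrast)
        assert dof == 87 - design.X.shape[1]
        expected_sd = np.sqrt(dof / (dof - 2))
        assert abs(t.std() - expected_sd) / expected_sd < 0.03

    def test_perfect_fit_flagged_infinite(self):
        design = build_design(_cohort(n_als=5, n_control=5), "group")
        y = design.X @ np.array([1.0, -1.0, 0, 0, 0])
        t, _ = fit_glm(y, design)
        assert np.isinf(t)

    def test_confound_only_outcome_gives_zero_t(self):
        design = build_design(_cohort(), "group")
        y = 2.0 * design.X[:, 2]  # pure age effect
        t, _ = fit_glm(y, design)
        assert abs(t) < 1e-8

    def test_dof_reporting_convention(self):
        assert format_t(3.729, 82) == "t(82) = 3.729"


@pytest.fixture(scope="module")
def data():
    design = build_design(_cohort(), "group")
    rng = np.random.default_rng(2)
    Y = rng.standard_normal((87, 4, 3))
    return design, Y


class TestPermutationMaxT:

    def test_deterministic_under_seed(self, data):
        design, Y = data
        r1 = permutation_maxt(Y, design, n_perm=200, seed=7)
        r2 = permutation_maxt(Y, design, n_perm=200, seed=7)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)

    def test_p_formula_and_monotonicity(self, data):
        design, Y = data
        res = permutation_maxt(Y, design, n_perm=200, seed=3)
        expected = (1 + (res.null_max[None, :] >=
                         np.abs(res.t_obs).ravel()[:, None]).sum(1)) / 201
        np.testing.assert_allclose(res.p_fwe.ravel(), expected)
        order = np.argsort(np.abs(res.t_obs).ravel())
        assert (np.diff(res.p_fwe.ravel()[order]) <= 1e-12).all()
        assert res.p_fwe.min() >= 1 / 201
        assert res.p_fwe.max() <= 1.0

    def test_coarse_n_perm_rejected(self, data):
        design, Y = data
        with pytest.raises(ValueError, match="n_perm"):
            permutation_maxt(Y, design, n_perm=50, seed=0)

    def test_planted_group_shift_detected(self):
        cohort = _cohort(seed=5)
        design = build_design(cohort, "group")
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((87, 3, 2))
        Y[cohort.is_als, 1, 0] += 1.5
        res = permutation_maxt(Y, design, n_perm=500, seed=1)
        assert res.p_fwe[1, 0] < 0.05
        assert res.p_fwe[0, 0] > 0.05


class TestMaxStatPvalues:
    def test_worked_example(self):
        null = np.arange(1.0, 101.0)
        p = max_stat_pvalues(np.array([50.5]), null)
        assert p[0] == pytest.approx((1 + 50) / 101)

    def test_ties_count_toward_null(self):
        null = np.array([1.0, 2.0, 3.0, 4.0])
        assert max_stat_pvalues(np.array([3.0]), null)[0] == pytest.approx(3 / 5)

    def test_sign_irrelevant(self):
        null = np.arange(1.0, 101.0)
        p_pos = max_stat_pvalues(np.array([80.0]), null)
        p_neg = max_stat_pvalues(np.array([-80.0]), null)
        assert p_pos == p_neg
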