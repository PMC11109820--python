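import numpy as np
import pandas as pd
import pytest

from parcelmeg import (
    CohortTable,
    FeatureTable,
    RandomForestParams,
    build_features,
    nested_loocv,
    stepwise_select,
)

FAST = RandomForestParams(n_estimators=20, pool_size=4, selection_estimators=10)


def _cohort(n_als, alsfrs):
    return CohortTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n_als)],
        "group": ["ALS"] * n_als,
        "age": 60.0,
        "sex": "M",
        "handedness": "right",
        "alsfrs_r": alsfrs,
        "umn_score": 5.0,
        "years_from_onset": 2.0,
    }))


def _metrics(subjects, P, B, seed=0):
    rng = np.random.default_rng(seed)
    power = {s: rng.uniform(0.1, 1, (P, B)) for s in subjects}
    expo = {s: rng.uniform(1, 2, P) for s in subjects}
    a = {}
    for s in subjects:
        m = rng.uniform(0, 0.5, (B, P, P))
        a[s] = (m + m.transpose(0, 2, 1)) / 2
    return power, expo, a


class TestBuildFeatures:
    @pytest.mark.parametrize("P,B,expected", [(52, 6, 8320), (4, 2, 24)])
    def test_column_count(self, P, B, expected):
        """bands*(P*(P-1)/2) AEC pairs + bands*P powers + P exponents."""
        cohort = _cohort(3, [37.0, 30.0, 45.0])
        bands = tuple(f"b{i}" for i in range(B))
        parcels = tuple(f"p{i}" for i in range(P))
        table = build_features(*_metrics(cohort.subject_ids, P, B),
                               cohort, bands, parcels)
        assert table.X.shape == (3, expected)
        assert table.y.tolist() == [11.0, 18.0, 3.0]

    def test_missing_subject_rejected(self):
        cohort = _cohort(3, [37.0, 30.0, 45.0])
        power, expo, a = _metrics(cohort.subject_ids, 4, 2)
        del power["s1"]
        with pytest.raises(ValueError, match="s1"):
            build_features(power, expo, a, cohort, ("b0", "b1"),
                           tuple(f"p{i}" for i in range(4)))


class TestStepwiseSelect:
    def test_target_feature_found(self, rng):
        n = 20
        X = pd.DataFrame(rng.standard_normal((n, 10)),
                         columns=[f"f{i}" for i in range(10)])
        y = X["f3"].to_numpy()
        selected = stepwise_select(X, y, FAST, seed=0)
        assert selected[0] == "f3"

    def test_duplicate_informative_feature_selected_once(self, rng):
        n = 20
        f = rng.standard_normal(n)
        X = pd.DataFrame({"dup_a": f, "dup_b": f,
                          "noise": rng.standard_normal(n)})
        y = f + 0.05 * rng.standard_normal(n)
        selected = stepwise_select(X, y, FAST, seed=1)
        assert sum(c.startswith("dup") for c in selected) == 1

    def test_pure_noise_selects_little(self, rng):
        """On independent noise, greedy selection stops after at most a
        couple of features and never reports a strong CV fit."""
        sizes = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.standard_normal((15, 12)),
                             columns=[f"f{i}" for i in range(12)])
            y = r.standard_normal(15)
            sizes.append(len(stepwise_select(X, y, FAST, seed=seed)))
        assert np.mean(sizes) <= 3.0
        assert max(sizes) <= 4

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((3, 5)))
        with pytest.raises(ValueError, match="k = 5"):
            stepwise_select(X, rng.standard_normal(3), FAST, seed=0)


def _table(n=14, p=30, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if informative:
        y = 4 * X[:, 0] + 2 * X[:, 1] + 0.3 * rng.standard_normal(n)
    else:
        y = rng.standard_normal(n)
    y = (y - y.min()) / (np.ptp(y) + 1e-9) * 30 + 5
    return FeatureTable(
        X=pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                       columns=[f"f{i}" for i in range(p)]),
        y=pd.Series(y, index=[f"s{i}" for i in range(n)]),
    )


class TestNestedLoocv:
    def test_one_prediction_per_subject_and_determinism(self):
        table = _table()
        r1 = nested_loocv(table, FAST, seed=3)
        r2 = nested_loocv(table, FAST, seed=3)
        assert len(r1.y_pred) == table.n_subjects
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)
        assert len(r1.selected) == table.n_subjects

    def test_r2_equals_squared_pearson(self):
        res = nested_loocv(_table(), FAST, seed=4)
        r = np.corrcoef(res.y_true, res.y_pred)[0, 1]
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_heldout_target_cannot_leak(self):
        """A subject's out-of-fold prediction never depends on its own
        target: changing y_i leaves prediction_i untouched (it changes only
        the folds where subject i is a training row)."""
        table = _table()
        base = nested_loocv(table, FAST, seed=5)
        y2 = table.y.copy()
        y2.iloc[0] = 48.0 - y2.iloc[0]
        poked = nested_loocv(FeatureTable(X=table.X, y=y2), FAST, seed=5)
        assert poked.y_pred[0] == base.y_pred[0]

    def test_informative_signal_predicts(self):
        res = nested_loocv(_table(n=20, informative=True, seed=8), FAST, seed=8)
        assert res.r_squared > 0.3
        assert res.p_value < 0.05

    def test_constant_target_rejected(self):
        table = _table()
        const = FeatureTable(X=table.X, y=pd.Series(10.0, index=table.X.index))
        with pytest.raises(ValueError, match="constant"):
            nested_loocv(const, FAST, seed=0)

    def test_too_few_subjects_rejected(self):
        t = _table(n=8)
        with pytest.raises(ValueError, match="10 subjects"):
            nested_loocv(t, FAST, seed=0)
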