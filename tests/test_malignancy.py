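import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwqus.cohort import sample_cohort
from pwqus.malignancy import (
    LesionMeasurement,
    QUSMalignancyClassifier,
    clopper_pearson,
    default_model,
    fit_logistic,
    log_odds,
    mann_whitney,
    odds_ratio_table,
    probability,
    roc_auc,
    table5_lesions,
)


class TestLogOdds:
    def test_zero_measurement_returns_intercept(self):
        assert log_odds(np.zeros(4)) == pytest.approx(-31.7558)

    def test_published_case_lesion6(self):
        # AC 0.8061, SoS 1590, ESD 89.88, ESC 1.976 -> ~1.607 -> p ~0.833
        m = LesionMeasurement(ac=0.8061, sos=1590, esd=89.88, esc=1.976)
        lo = log_odds(m)
        assert lo == pytest.approx(1.607, abs=5e-4)
        assert probability(lo) == pytest.approx(0.833, abs=5e-4)

    def test_published_case_lesion1(self):
        m = LesionMeasurement(ac=0.39, sos=1508, esd=86.67, esc=2.4)
        assert log_odds(m) == pytest.approx(-4.195, abs=5e-4)

    def test_invalid_measurement_rejected(self):
        with pytest.raises(ValueError):
            LesionMeasurement(ac=np.nan, sos=1540, esd=80, esc=2)
        with pytest.raises(ValueError):
            LesionMeasurement(ac=0.5, sos=-10, esd=80, esc=2)


class TestProbability:
    def test_zero_maps_to_half(self):
        assert probability(0.0) == 0.5

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, x):
        assert probability(x) + probability(-x) == pytest.approx(1.0, abs=1e-12)


class TestOddsRatios:
    def test_matches_published_inference_table(self):
        table = odds_ratio_table(default_model()).set_index("parameter")
        published = {"ac": 41734.12, "sos": 1.02, "esd": 0.91, "esc": 1.08}
        for name, ref in published.items():
            assert table.loc[name, "odds_ratio"] == pytest.approx(ref, rel=5e-3)

    def test_zero_coefficient_gives_unit_odds(self):
        from pwqus.malignancy import LogisticModel

        m = LogisticModel(0, 0, 0, 0, 0)
        assert (odds_ratio_table(m)["odds_ratio"] == 1).all()


def _brute_force_u(a, b):
    """Exhaustive rank count: wins + half-ties for group a."""
    return sum(
        1.0 if x > y else 0.5 if x == y else 0.0
        for x, y in itertools.product(a, b)
    )


class TestMannWhitney:
    def test_identical_groups_do_not_reject(self):
        u, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_all_values_identical_is_degenerate(self):
        u, p = mann_whitney([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_complete_separation_small_sample(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, rng.integers(3, 9)).astype(float)
        b = rng.integers(0, 8, rng.integers(3, 9)).astype(float)
        u, _ = mann_whitney(a, b)
        assert u == pytest.approx(_brute_force_u(a, b))

    def test_large_shift_rejects(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        _, p = mann_whitney(a, b)
        assert p < 1e-3


class TestROC:
    def test_perfect_separation_gives_unit_auc(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=100, seed=0)
        assert res.auc == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        a1 = roc_auc(s, y, n_boot=10, seed=0).auc
        a2 = roc_auc(-s, y, n_boot=10, seed=0).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 1, 500)
        y = rng.integers(0, 2, 500)
        assert roc_auc(s, y, n_boot=50, seed=0).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_bootstrap_ci_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        s = rng.normal(0, 1, 80)
        y = (s + rng.normal(0, 1, 80) > 0).astype(int)
        r1 = roc_auc(s, y, n_boot=200, seed=9)
        r2 = roc_auc(s, y, n_boot=200, seed=9)
        assert r1.ci == r2.ci
        assert r1.ci[0] <= r1.auc <= r1.ci[1]


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-10)

    def test_all_successes_hits_one(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-10)

    def test_symmetric_at_half(self):
        lo, hi = clopper_pearson(5, 10)
        assert lo == pytest.approx(1 - hi, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)


class TestFitLogistic:
    def test_recovers_signs_and_or_consistency(self):
        cohort = sample_cohort(2500, 2500, seed=42)
        model = fit_logistic(cohort)
        ref = default_model()
        assert np.all(np.sign(model.coefficients) == np.sign(ref.coefficients))
        inf = model.inference
        np.testing.assert_allclose(
            inf["odds_ratio"], np.exp(inf["coef"]), rtol=1e-12
        )

    def test_perfect_separation_is_flagged(self):
        rng = np.random.default_rng(0)
        n = 30
        ac = np.concatenate([rng.uniform(0.2, 0.4, n), rng.uniform(0.8, 1.0, n)])
        cohort = pd.DataFrame(
            {
                "ac": ac,
                "sos": rng.normal(1540, 10, 2 * n),
                "esd": rng.normal(85, 5, 2 * n),
                "esc": rng.normal(2.5, 0.3, 2 * n),
                "label": ["benign"] * n + ["malignant"] * n,
            }
        )
        model = fit_logistic(cohort)
        assert model.separation_warning

    def test_requires_both_labels(self):
        cohort = sample_cohort(20, 0, seed=1)
        with pytest.raises(ValueError):
            fit_logistic(cohort)


class TestSklearnWrapper:
    def test_default_model_predicts_table5(self):
        clf = QUSMalignancyClassifier(use_default_model=True).fit(None)
        t5 = table5_lesions()
        proba = clf.predict_proba(t5[["ac", "sos", "esd", "esc"]].to_numpy())
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        calls = clf.predict(t5[["ac", "sos", "esd", "esc"]].to_numpy())
        # the one clearly malignant case in the packaged worked examples
        assert calls[5] == "malignant"

    def test_clonable(self):
        from sklearn.base import clone

        clf = QUSMalignancyClassifier(use_default_model=True, threshold=0.4)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()
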