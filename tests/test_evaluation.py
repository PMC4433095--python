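"""Allocation, DGV prediction, accuracy standardization, model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from bayesalphabet.evaluation import (
    AccuracyWarning,
    allocate,
    paired_model_ttest,
    per_breed_accuracy,
    predict_dgv,
    realized_accuracy,
    replicate_summary,
    select_best_fit,
    validation_correlation,
)
from bayesalphabet.genotypes import GenotypeMatrix


class TestAllocate:
    def test_study_sizes(self):
        tr, va = allocate(3240, 0.70, seed=1)
        assert (len(tr), len(va)) == (2268, 972)

    def test_even_split(self):
        tr, va = allocate(10, 0.5, seed=2)
        assert (len(tr), len(va)) == (5, 5)

    def test_disjoint_exhaustive_and_deterministic(self):
        a = allocate(101, 0.66, seed=9)
        b = allocate(101, 0.66, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        union = np.concatenate(a)
        assert len(np.intersect1d(a[0], a[1])) == 0
        assert np.array_equal(np.sort(union), np.arange(101))

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_bad_fraction(self, fraction):
        with pytest.raises(ValueError):
            allocate(100, fraction, seed=1)


class TestPredictDGV:
    def test_hand_arithmetic(self):
        u = pd.Series([0.1, -0.2], index=["s1", "s2"])
        z = np.array([[10.0, -10.0]])
        assert predict_dgv(z, u)[0] == pytest.approx(3.0)

    def test_zero_effects(self):
        u = pd.Series(np.zeros(3), index=list("abc"))
        assert not predict_dgv(np.full((4, 3), 10.0), u).any()

    def test_permutation_invariance(self, rng):
        k = 8
        ids = np.array([f"s{i}" for i in range(k)], dtype=object)
        Z = 10.0 * (rng.binomial(2, 0.5, size=(5, k)) - 1.0)
        u = pd.Series(rng.normal(size=k), index=ids)
        perm = rng.permutation(k)
        a = predict_dgv(Z, u)
        b = predict_dgv(Z[:, perm], u.iloc[perm])
        assert np.allclose(a, b)

    def test_snp_mismatch_reported(self):
        gm = GenotypeMatrix(np.zeros((3, 2)), snp_ids=["a", "b"],
                            coding="centered-ten")
        u = pd.Series([0.1, 0.2], index=["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            predict_dgv(gm, u)


class TestCorrelationAndAccuracy:
    def test_perfect_correlations(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        assert validation_correlation(y, y) == pytest.approx(1.0)
        assert validation_correlation(-y, y) == pytest.approx(-1.0)

    def test_four_point_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0])
        expected = sp_stats.pearsonr(x, y).statistic
        assert validation_correlation(x, y) == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            validation_correlation(np.ones(5), np.arange(5.0))

    def test_study_worked_example(self):
        assert realized_accuracy(0.276, 0.26) == pytest.approx(0.541, abs=5e-4)

    def test_above_one_warns_not_clamps(self):
        with pytest.warns(AccuracyWarning, match="outside the parameter space"):
            acc = realized_accuracy(0.267, 0.06)
        assert acc == pytest.approx(1.090, abs=5e-4)

    def test_zero_correlation(self):
        assert realized_accuracy(0.0, 0.5) == 0.0

    def test_monotone_decreasing_in_h2(self):
        accs = [realized_accuracy(0.3, h2) for h2 in (0.1, 0.2, 0.4, 0.8)]
        assert all(a > b for a, b in zip(accs, accs[1:]))

    def test_bad_h2(self):
        with pytest.raises(ValueError):
            realized_accuracy(0.3, 0.0)


class TestReplicateSummary:
    def test_equal_values_zero_cv(self):
        mean, sd, cv = replicate_summary([0.5, 0.5, 0.5])
        assert (mean, sd, cv) == (0.5, 0.0, 0.0)

    def test_two_values(self):
        mean, sd, cv = replicate_summary([0.4, 0.6])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.1414, abs=1e-4)
        assert cv == pytest.approx(0.2828, abs=1e-4)

    def test_matches_direct_computation(self, rng):
        x = rng.normal(0.5, 0.05, 20)
        mean, sd, cv = replicate_summary(x)
        assert mean == pytest.approx(x.mean())
        assert sd == pytest.approx(x.std(ddof=1))
        assert cv == pytest.approx(x.std(ddof=1) / x.mean())

    def test_zero_mean_flagged(self):
        with pytest.raises(ValueError, match="CV undefined"):
            replicate_summary([-0.1, 0.1])


class TestBestFit:
    def test_small_fractions_ineligible(self):
        assert select_best_fit({0.6: 0.05, 0.7: 0.04, 0.3: 0.01}) == 0.7

    def test_tie_goes_to_larger_fraction(self):
        assert select_best_fit({0.6: 0.04, 0.7: 0.04, 0.8: 0.04}) == 0.8

    def test_no_eligible_fraction(self):
        with pytest.raises(ValueError):
            select_best_fit({0.3: 0.01, 0.5: 0.02})


class TestPerBreed:
    def test_single_breed_reduces_to_overall(self, rng):
        dgv = rng.normal(size=50)
        y = dgv + rng.normal(size=50)
        tab = per_breed_accuracy(dgv, y, ["Angus"] * 50, {"Angus": 0.25})
        assert len(tab) == 1
        r = validation_correlation(dgv, y)
        assert tab["accuracy"].iloc[0] == pytest.approx(r / np.sqrt(0.25))

    def test_small_breed_skipped_with_notice(self, rng):
        dgv = rng.normal(size=13)
        y = dgv + rng.normal(size=13)
        breeds = ["Angus"] * 11 + ["Limousin"] * 2
        with pytest.warns(AccuracyWarning, match="Limousin"):
            tab = per_breed_accuracy(dgv, y, breeds, {"Angus": 0.3, "Limousin": 0.3})
        assert list(tab["breed"]) == ["Angus"]

    def test_missing_h2_entry(self, rng):
        dgv = rng.normal(size=10)
        with pytest.raises(KeyError, match="h2"):
            per_breed_accuracy(dgv, dgv + 1e-3 * rng.normal(size=10),
                               ["Angus"] * 10, {})


class TestPairedTTest:
    def test_hand_example(self):
        res = paired_model_ttest([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res["mean_diff"] == pytest.approx(2.0)
        assert res["t"] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-3)
        assert res["df"] == 2

    def test_identical_vectors_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_model_ttest([0.1, 0.2], [0.1, 0.2])

    def test_matches_scipy_reference(self, rng):
        a = rng.normal(0.5, 0.05, 20)
        b = a + rng.normal(0.01, 0.02, 20)
        mine = paired_model_ttest(a, b)
        ref = sp_stats.ttest_rel(a, b)
        assert mine["t"] == pytest.approx(ref.statistic)
        assert mine["p"] == pytest.approx(ref.pvalue)

    def test_bonferroni_threshold(self):
        res = paired_model_ttest([1.0, 2.0, 3.0], [0.0, 0.0, 0.1], family_size=36)
        assert res["bonferroni_alpha"] == pytest.approx(0.05 / 36, abs=1e-6)
        assert 0.05 / 36 == pytest.approx(0.0014, abs=1e-4)
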