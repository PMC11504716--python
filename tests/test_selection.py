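import itertools

import numpy as np
import pandas as pd
import pytest

from cranangles.selection import (CfsModel, best_first_search, build_cfs_model,
                                  cfs_merit, repeated_selection,
                                  symmetrical_uncertainty, threshold_mask)


def random_model(rng, n):
    rcf = rng.uniform(0, 0.6, n)
    a = rng.uniform(0, 0.4, (n, n))
    rff = (a + a.T) / 2
    np.fill_diagonal(rff, 0.0)
    return CfsModel([f"a{i}" for i in range(n)], rcf, rff)


def exhaustive_best_merit(model):
    """Independent oracle: enumerate every non-empty subset directly."""
    n = len(model.attributes)
    best = -np.inf
    for k in range(1, n + 1):
        for combo in itertools.combinations(range(n), k):
            rcf = model.feature_class[list(combo)].mean()
            if k == 1:
                merit = rcf
            else:
                pairs = [model.feature_feature[i, j]
                         for i, j in itertools.combinations(combo, 2)]
                merit = k * rcf / np.sqrt(k + k * (k - 1) * np.mean(pairs))
            best = max(best, merit)
    return best


class TestMerit:
    def test_singleton_reduces_to_rcf(self):
        model = CfsModel(["a"], np.array([0.4]), np.zeros((1, 1)))
        assert cfs_merit(["a"], model) == pytest.approx(0.4)

    def test_two_uncorrelated_closed_form(self):
        model = CfsModel(["a", "b"], np.array([0.5, 0.5]), np.zeros((2, 2)))
        assert cfs_merit(["a", "b"], model) == pytest.approx(2 * 0.5 / np.sqrt(2))

    def test_matches_direct_formula_on_all_subsets(self, rng):
        model = random_model(rng, 5)
        for k in range(1, 6):
            for combo in itertools.combinations(range(5), k):
                rcf = model.feature_class[list(combo)].mean()
                if k == 1:
                    expected = rcf
                else:
                    pairs = [model.feature_feature[i, j]
                             for i, j in itertools.combinations(combo, 2)]
                    expected = k * rcf / np.sqrt(k + k * (k - 1) * np.mean(pairs))
                assert cfs_merit(combo, model) == pytest.approx(expected, abs=1e-12)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            cfs_merit([], random_model(rng, 3))


class TestSymmetricalUncertainty:
    def test_hand_worked_2x2(self):
        # joint counts (0,0)=2, (0,1)=1, (1,1)=1
        x = np.array([0, 0, 0, 1])
        y = np.array([0, 0, 1, 1])
        hx = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        hy = 1.0
        hxy = -(0.5 * np.log2(0.5) + 0.25 * np.log2(0.25) * 2)
        expected = 2 * (hx + hy - hxy) / (hx + hy)
        assert symmetrical_uncertainty(x, y) == pytest.approx(expected, abs=1e-12)

    def test_identity_and_independence(self):
        x = np.array([0, 1, 0, 1, 0, 1])
        assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)
        y = np.array([0, 0, 1, 1, 0, 0])
        z = np.array([0, 1] * 3)
        # constructed independent pair
        assert symmetrical_uncertainty(np.array([0, 0, 1, 1]),
                                       np.array([0, 1, 0, 1])) == pytest.approx(0.0)

    def test_missing_codes_skipped(self):
        x = np.array([0, 1, -1, 0])
        y = np.array([0, 1, 1, -1])
        assert symmetrical_uncertainty(x, y) == pytest.approx(1.0)


class TestBuildModel:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(1)
        y = np.array(["male"] * 30 + ["female"] * 30)
        frame = pd.DataFrame({"x": np.where(y == "male", 1.0, 2.0),
                              "noise": rng.normal(size=60)})
        model = build_cfs_model(frame, y)
        assert model.feature_class[0] == pytest.approx(1.0)

    def test_independent_attribute_near_zero(self):
        rng = np.random.default_rng(2)
        y = np.array(["male", "female"] * 40)
        frame = pd.DataFrame({"x": rng.normal(size=80)})
        with pytest.warns(UserWarning, match="no MDL split"):
            model = build_cfs_model(frame, y)
        assert model.feature_class[0] < 0.1

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            build_cfs_model(frame, np.array(["male", "male"]))


class TestBestFirst:
    def test_dominant_attribute_selected(self):
        rcf = np.array([0.01, 0.9, 0.01])
        model = CfsModel(["a", "b", "c"], rcf, np.zeros((3, 3)))
        subset, merit = best_first_search(model)
        assert 1 in subset
        assert merit >= 0.9

    def test_equals_exhaustive_on_random_models(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 10))
            model = random_model(rng, n)
            _, merit = best_first_search(model)
            assert merit == pytest.approx(exhaustive_best_merit(model), abs=1e-9)

    def test_redundant_attribute_excluded(self):
        # two perfectly correlated attributes with equal relevance: adding the
        # twin never improves the merit (k=2, r_ff=1 gives 2*0.5/sqrt(4) = 0.5,
        # the singleton value), so exactly one survives
        rcf = np.array([0.5, 0.5])
        rff = np.array([[0.0, 1.0], [1.0, 0.0]])
        model = CfsModel(["a", "b"], rcf, rff)
        subset, merit = best_first_search(model)
        assert len(subset) == 1
        assert merit == pytest.approx(0.5)

    def test_deterministic(self, rng):
        model = random_model(rng, 8)
        assert best_first_search(model) == best_first_search(model)


def signal_noise_table(seed, n=160, n_signal=3, n_noise=7, shift=2.0):
    rng = np.random.default_rng(seed)
    y = np.array(["male", "female"] * (n // 2))
    cols = {}
    for i in range(n_signal):
        cols[f"sig{i}"] = rng.normal(0, 1, n) + np.where(y == "male", shift, 0.0)
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols), y


class TestRepeatedSelection:
    def test_signal_attributes_rank_high(self):
        freqs = []
        for seed in range(5):
            frame, y = signal_noise_table(seed)
            ai = repeated_selection(frame, y, seed=seed)
            freqs.append(ai.frequencies)
        mean_freq = pd.concat(freqs, axis=1).mean(axis=1)
        assert (mean_freq[[f"sig{i}" for i in range(3)]] >= 0.9).all()
        assert (mean_freq[[f"noise{i}" for i in range(7)]] <= 0.2).all()

    def test_frequencies_are_multiples_of_runs(self):
        frame, y = signal_noise_table(11, n=80)
        ai = repeated_selection(frame, y, folds=5, repeats=4, seed=0)
        assert ai.total_runs == 20
        counts = ai.frequencies * 20
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_subsets_nested(self):
        frame, y = signal_noise_table(3, n=120)
        ai = repeated_selection(frame, y, seed=1)
        labels = list(ai.subsets)
        for tighter, looser in zip(labels[1:], labels[:-1]):
            assert set(ai.subsets[tighter]) <= set(ai.subsets[looser])

    def test_extreme_frequencies(self):
        frame, y = signal_noise_table(9, n=200, n_signal=1, n_noise=2, shift=6.0)
        ai = repeated_selection(frame, y, seed=2)
        assert ai.frequencies["sig0"] == 1.0
        assert "sig0" in ai.subsets["=1"] and "sig0" in ai.subsets[">0"]
        never = ai.frequencies[ai.frequencies == 0.0].index
        for attr in never:
            assert all(attr not in subset for subset in ai.subsets.values())

    def test_deterministic_given_seed(self):
        frame, y = signal_noise_table(4, n=80)
        a1 = repeated_selection(frame, y, seed=7)
        a2 = repeated_selection(frame, y, seed=7)
        pd.testing.assert_series_equal(a1.frequencies, a2.frequencies)
        assert a1.subsets == a2.subsets


def test_threshold_mask_labels():
    freq = pd.Series({"a": 1.0, "b": 0.4, "c": 0.0})
    assert list(freq.index[threshold_mask(freq, ">0")]) == ["a", "b"]
    assert list(freq.index[threshold_mask(freq, ">=0.4")]) == ["a", "b"]
    assert list(freq.index[threshold_mask(freq, "=1")]) == ["a"]
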