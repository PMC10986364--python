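import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import p3dseize as pz
from p3dseize.selection import (FeatureMatrix, feature_count_sweep,
                                mrmr_rank, mutual_information)
import oracles


class TestMutualInformation:
    def test_identical_balanced_binary_is_ln2(self):
        a = np.tile([0, 1], 500)
        assert mutual_information(a, a) == pytest.approx(np.log(2), abs=1e-12)

    def test_self_information_is_entropy(self):
        rng = np.random.default_rng(0)
        a = rng.choice([0, 1, 2], size=600, p=[0.5, 0.3, 0.2])
        _, counts = np.unique(a, return_counts=True)
        p = counts / counts.sum()
        entropy = -(p * np.log(p)).sum()
        assert mutual_information(a, a) == pytest.approx(entropy, abs=1e-12)

    def test_independent_discrete_near_zero(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.integers(0, 4, size=10_000)
            b = rng.integers(0, 4, size=10_000)
            assert mutual_information(a, b) <= 0.01

    def test_printed_2x2_joint_table(self):
        # joint counts [[40, 10], [10, 40]]
        a = np.r_[np.zeros(50), np.ones(50)]
        b = np.r_[np.zeros(40), np.ones(10), np.zeros(10), np.ones(40)]
        pj = np.array([[0.4, 0.1], [0.1, 0.4]])
        expected = sum(
            pj[i, j] * np.log(pj[i, j] / (pj[i].sum() * pj[:, j].sum()))
            for i in range(2) for j in range(2)
        )
        assert mutual_information(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 300))
    def test_symmetric_and_nonnegative(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n) + 0.5 * a
        mi = mutual_information(a, b)
        assert mi >= 0
        assert mi == pytest.approx(mutual_information(b, a), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2, 3], [1, 2])


def _fm(columns: dict, y) -> FeatureMatrix:
    names = tuple(columns)
    X = np.column_stack([columns[n] for n in names])
    return FeatureMatrix(X, np.asarray(y), names)


class TestMrmrRank:
    def test_single_candidate(self):
        y = np.tile([0, 1], 50)
        fm = _fm({"only": y.astype(float)}, y)
        res = mrmr_rank(fm)
        assert res.ranked_names == ("only",)
        assert res.importance[0] == pytest.approx(np.log(2), abs=1e-9)

    def test_duplicate_of_strong_predictor_demoted(self):
        """An exact copy of the first pick has redundancy ~H(f1), pushing its
        criterion strongly negative, so a weak independent predictor wins
        the second slot."""
        rng = np.random.default_rng(1)
        y = np.tile([0, 1], 250)
        f1 = y ^ (rng.random(500) < 0.02)
        f3 = np.where(rng.random(500) < 0.7, y, rng.integers(0, 2, 500))
        fm = _fm({"f1": f1.astype(float), "f2": f1.astype(float),
                  "f3": f3.astype(float)}, y)
        res = mrmr_rank(fm)
        assert res.ranked_names == ("f1", "f3", "f2")

    def test_first_pick_is_max_relevance(self):
        rng = np.random.default_rng(2)
        y = np.tile([0, 1], 100)
        cols = {
            "noise": rng.standard_normal(200),
            "strong": y + 0.1 * rng.standard_normal(200),
            "weak": y + 2.0 * rng.standard_normal(200),
        }
        fm = _fm(cols, y)
        res = mrmr_rank(fm)
        rel = {n: mutual_information(cols[n], y) for n in cols}
        assert res.ranked_names[0] == max(sorted(rel), key=rel.get)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 120)
        cols = {f"v{i}": rng.standard_normal(120) + 0.8 * y * (i % 2)
                for i in range(4)}
        fm = _fm(cols, y)
        res = mrmr_rank(fm)
        order, scores = oracles.mrmr_exhaustive(cols, y, mutual_information)
        assert list(res.ranked_names) == order
        assert np.allclose(res.importance, scores, atol=1e-12)

    def test_duplicate_of_selected_never_changes_next_pick(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        cols = {"a": y + 0.2 * rng.standard_normal(200),
                "b": rng.standard_normal(200),
                "c": 0.5 * y + rng.standard_normal(200)}
        base = mrmr_rank(_fm(cols, y))
        first = base.ranked_names[0]
        cols2 = dict(cols)
        cols2["zz_dup"] = cols[first].copy()
        dup = mrmr_rank(_fm(cols2, y))
        assert dup.ranked_names[0] == first
        assert dup.ranked_names[1] == base.ranked_names[1]

    def test_constant_variable_still_rankable(self):
        y = np.tile([0, 1], 30)
        fm = _fm({"const": np.ones(60), "good": y.astype(float)}, y)
        res = mrmr_rank(fm)
        assert res.ranked_names[0] == "good"
        assert set(res.ranked_names) == {"const", "good"}

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            mrmr_rank(FeatureMatrix(np.empty((10, 0)), np.tile([0, 1], 5), ()))


class TestFeatureCountSweep:
    def _fm4(self):
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], 40)
        return _fm({f"v{i}": rng.standard_normal(80) for i in range(4)}, y)

    def _sweep(self, canned):
        fm = self._fm4()
        calls = iter(canned)
        return feature_count_sweep(fm, fm.variable_names,
                                   lambda X, y: next(calls), k_max=len(canned))

    def test_peak_in_middle(self):
        assert self._sweep([0.90, 0.94, 0.97, 0.95]).chosen_k == 3

    def test_all_equal_prefers_fewest(self):
        assert self._sweep([0.9, 0.9, 0.9, 0.9]).chosen_k == 1

    def test_monotone_increasing_takes_all(self):
        assert self._sweep([0.7, 0.8, 0.9, 0.95]).chosen_k == 4

    def test_invalid_k_max_rejected(self):
        fm = self._fm4()
        with pytest.raises(ValueError):
            feature_count_sweep(fm, fm.variable_names, lambda X, y: 1.0, k_max=0)

    def test_evaluator_sees_ranked_prefixes(self):
        fm = self._fm4()
        seen = []
        feature_count_sweep(fm, ("v2", "v0", "v1", "v3"),
                            lambda X, y: seen.append(X.shape[1]) or 0.5, k_max=3)
        assert seen == [1, 2, 3]


def test_build_feature_matrix_channel_average(small_block, small_windows):
    fm = pz.build_feature_matrix(small_block, small_windows.labels)
    assert fm.X.shape == (len(small_windows), 4)
    assert fm.variable_names == pz.FEATURE_NAMES
    expected = small_block.values[3].mean(axis=(0, 2))
    assert np.allclose(fm.X[3], expected)


def test_selection_result_json_round_trip(tmp_path):
    y = np.tile([0, 1], 50)
    fm = _fm({"a": y.astype(float), "b": np.random.default_rng(0).standard_normal(100)}, y)
    res = mrmr_rank(fm)
    res.chosen_k = 1
    path = tmp_path / "sel.json"
    res.to_json(path, seed=7)
    import json

    payload = json.loads(path.read_text())
    assert payload["ranked_names"] == list(res.ranked_names)
    assert payload["chosen_k"] == 1
    assert payload["seed"] == 7
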