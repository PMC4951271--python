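import math

import numpy as np
import pandas as pd
import pytest

from hotspotter.classifier import CvConfig
from hotspotter.errors import UsageError
from hotspotter.selection import (discretize, mrmr_rank, mutual_information,
                                  select_top_third, two_step_select,
                                  wrapper_search)
from hotspotter.synthetic_data import SyntheticSpec, generate_feature_table


def oracle_mi(x, y):
    """Brute-force plug-in MI in bits from the joint contingency table."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy == 0:
                continue
            px, py = np.mean(x == xv), np.mean(y == yv)
            mi += pxy * math.log2(pxy / (px * py))
    return mi


def oracle_mrmr(features: pd.DataFrame, y):
    """Independent greedy MID ordering using the oracle MI."""
    disc = {c: discretize(features[c].to_numpy()) for c in features.columns}
    remaining = list(features.columns)
    selected = []
    while remaining:
        def score(c):
            rel = oracle_mi(disc[c], y)
            if not selected:
                return rel
            red = np.mean([oracle_mi(disc[c], disc[s]) for s in selected])
            return rel - red
        scores = {c: score(c) for c in remaining}
        best = max(remaining, key=lambda c: (scores[c], -remaining.index(c)))
        selected.append(best)
        remaining.remove(best)
    return selected


class TestDiscretize:
    def test_gaussian_column_is_mostly_mid(self):
        rng = np.random.default_rng(0)
        codes = discretize(rng.standard_normal(1000))
        assert abs(np.mean(codes == 1) - 0.683) < 0.05

    def test_constant_column_all_mid(self):
        assert (discretize(np.full(10, 3.3)) == 1).all()

    def test_three_spread_values_map_to_three_states(self):
        x = np.array([-3.0, 0.0, 3.0] * 5)
        codes = discretize(x)
        assert set(codes[x == -3.0]) == {0}
        assert set(codes[x == 0.0]) == {1}
        assert set(codes[x == 3.0]) == {2}


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        y = np.array([0, 1] * 8)
        assert mutual_information(y, y) == pytest.approx(1.0)

    def test_constant_is_zero_bits(self):
        y = np.array([0, 1] * 8)
        assert mutual_information(np.zeros(16), y) == pytest.approx(0.0)

    def test_matches_hand_computed_joint_table(self):
        # joint counts: x in {0,1,2}, y in {0,1}
        x = np.array([0] * 4 + [1] * 6 + [2] * 2 + [0] * 2 + [1] * 1 + [2] * 5)
        y = np.array([0] * 12 + [1] * 8)
        assert mutual_information(x, y) == pytest.approx(oracle_mi(x, y))

    def test_symmetry_nonnegativity_self_entropy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 3, size=15)
            y = rng.integers(0, 2, size=15)
            mxy = mutual_information(x, y)
            assert mxy >= 0
            assert mxy == pytest.approx(mutual_information(y, x))
            # MI(x,x) = H(x)
            h = -sum(p * math.log2(p) for v in np.unique(x)
                     if (p := np.mean(x == v)) > 0)
            assert mutual_information(x, x) == pytest.approx(h)

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            mutual_information([0, 1], [0, 1, 2])


class TestMrmrRank:
    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 10)
        features = pd.DataFrame({
            "copy": y.astype(float) + 0.001 * rng.standard_normal(20),
            "noise1": rng.standard_normal(20),
            "noise2": rng.standard_normal(20),
        })
        ranked = mrmr_rank(features, y)
        assert ranked[0][0] == "copy"

    def test_duplicate_informative_feature_demoted_by_redundancy(self):
        y = np.array([0, 1] * 10)
        sig = np.where(y == 1, 2.0, -2.0)
        rng = np.random.default_rng(3)
        weak = sig * 0.6 + 1.6 * np.where(rng.standard_normal(20) > 0, 2.0, -2.0)
        features = pd.DataFrame({
            "dup_a": sig, "dup_b": sig,
            "weak": weak,
            "noise": rng.standard_normal(20),
        })
        ranked = [name for name, _ in mrmr_rank(features, y)]
        assert ranked == oracle_mrmr(features, y)
        # perfect duplicate has zero MID score once its twin is selected
        assert not (ranked[0].startswith("dup") and ranked[1].startswith("dup"))

    def test_output_is_permutation(self):
        rng = np.random.default_rng(4)
        features = pd.DataFrame(rng.standard_normal((12, 5)),
                                columns=list("abcde"))
        y = rng.integers(0, 2, 12)
        ranked = [name for name, _ in mrmr_rank(features, y)]
        assert sorted(ranked) == list("abcde")

    def test_agrees_with_exhaustive_oracle_on_random_toys(self):
        rng = np.random.default_rng(5)
        for n_feat in (2, 3, 4, 5):
            for n_samp in (8, 14, 20):
                features = pd.DataFrame(
                    rng.standard_normal((n_samp, n_feat)),
                    columns=[f"f{i}" for i in range(n_feat)])
                y = rng.integers(0, 2, n_samp)
                got = [name for name, _ in mrmr_rank(features, y)]
                assert got == oracle_mrmr(features, y)


class TestSelectTopThird:
    @pytest.mark.parametrize("size,expected",
                             [(17, 6), (55, 18), (33, 11), (3, 1), (1, 1)])
    def test_retention_counts(self, size, expected):
        assert select_top_third(size) == expected

    def test_invalid_size(self):
        with pytest.raises(UsageError):
            select_top_third(0)


def make_separable_dataset(seed=0, n=40):
    """One feature separates classes perfectly; the rest are noise."""
    from hotspotter.dataset import LabeledDataset
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    features = pd.DataFrame({
        "perfect": np.where(y == 1, 1.0, -1.0) + 0.01 * rng.standard_normal(n),
        **{f"noise{i}": rng.standard_normal(n) for i in range(4)},
    })
    labels = pd.Series(np.where(y == 1, "hot", "nonhot"), name="label")
    prov = pd.DataFrame({"structure_id": "syn", "chain": "A",
                         "resnum": range(n), "res_type": "ALA"})
    return LabeledDataset(features=features, labels=labels, provenance=prov)


class TestWrapperSearch:
    def test_perfect_separator_halts_at_best_pair(self):
        data = make_separable_dataset()
        subset, trace = wrapper_search(list(data.features.columns), data,
                                       cv=CvConfig(k=5, seed=0))
        assert "perfect" in subset
        assert len(subset) == 2
        assert trace["cv_f1"].iloc[0] == pytest.approx(1.0)

    def test_trace_f1_nondecreasing_on_accepted_steps(self):
        data = generate_feature_table(SyntheticSpec(seed=3, n_hot=20, n_nonhot=30))
        noise = [c for c in data.features.columns
                 if c not in data.metadata["planted"]][:8]
        candidates = noise + data.metadata["planted"]
        subset, trace = wrapper_search(candidates, data, cv=CvConfig(k=5, seed=0))
        accepted = trace[trace["accepted"]]["cv_f1"].to_numpy()
        assert (np.diff(accepted) >= 0).all()

    def test_deterministic_given_seed(self):
        data = generate_feature_table(SyntheticSpec(seed=4, n_hot=15, n_nonhot=20))
        noise = [c for c in data.features.columns
                 if c not in data.metadata["planted"]][:6]
        candidates = noise + data.metadata["planted"]
        s1, t1 = wrapper_search(candidates, data, cv=CvConfig(k=5, seed=7))
        s2, t2 = wrapper_search(candidates, data, cv=CvConfig(k=5, seed=7))
        assert s1 == s2
        pd.testing.assert_frame_equal(t1, t2)

    def test_needs_two_candidates(self):
        data = make_separable_dataset()
        with pytest.raises(UsageError):
            wrapper_search(["perfect"], data)


def test_two_step_select_retains_36_of_108():
    data = generate_feature_table(SyntheticSpec(seed=11))
    result = two_step_select(data, cv=CvConfig(k=5, seed=0))
    assert len(result.retained) == 36
    assert set(result.final_subset) <= set(result.retained)
    per_group = {name: len([c for c, _ in ranks])
                 for name, ranks in result.group_ranks.items()}
    assert per_group == {"physicochemical": 17, "structural": 55,
                         "neighborhood": 33, "other": 3}
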