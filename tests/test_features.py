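"""Feature reduction: Pearson gate, overlap integrals, chi2 ranking, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from asapml.features import (
    FeatureSelection,
    chi2_select,
    consensus_features,
    overlap_edges,
    overlap_integral,
    overlap_select,
    pearson_select,
    select_features,
)

groups = hnp.arrays(
    float, st.integers(3, 40), elements=st.floats(-50, 50, allow_nan=False)
)


class TestOverlapIntegral:
    def test_hand_computed_three_bin_example(self):
        # A = {0,0,1,1}, B = {1,1,2,2} on edges {-0.5, 0.5, 1.5, 2.5}:
        # normalised A = (0.5, 0.5, 0), B = (0, 0.5, 0.5) -> overlap 0.5
        a = np.array([0.0, 0.0, 1.0, 1.0])
        b = np.array([1.0, 1.0, 2.0, 2.0])
        edges = np.array([-0.5, 0.5, 1.5, 2.5])
        assert overlap_integral(a, b, edges) == pytest.approx(0.5)

    def test_identical_samples_give_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        edges = overlap_edges(np.concatenate([v, v]))
        assert overlap_integral(v, v, edges) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.linspace(0, 1, 20)
        b = np.linspace(10, 11, 20)
        edges = overlap_edges(np.concatenate([a, b]))
        assert overlap_integral(a, b, edges) == pytest.approx(0.0)

    @given(a=groups, b=groups)
    def test_symmetry_and_range(self, a, b):
        edges = overlap_edges(np.concatenate([a, b]))
        ab = overlap_integral(a, b, edges)
        ba = overlap_integral(b, a, edges)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0 + 1e-12

    @given(a=groups, b=groups,
           scale=st.floats(0.1, 10), shift=st.floats(-5, 5))
    def test_affine_invariance_with_transformed_edges(self, a, b, scale, shift):
        edges = overlap_edges(np.concatenate([a, b]))
        before = overlap_integral(a, b, edges)
        after = overlap_integral(
            scale * a + shift, scale * b + shift,
            None if edges is None else scale * edges + shift,
        )
        assert after == pytest.approx(before, abs=1e-9)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            overlap_integral(np.array([]), np.array([1.0]), np.array([0, 1.0]))

    def test_degenerate_pooled_range_counts_as_full_overlap(self):
        edges = overlap_edges(np.array([2.0, 2.0, 2.0]))
        assert edges is None
        assert overlap_integral([2.0], [2.0, 2.0], edges) == 1.0


class TestPearsonSelect:
    def test_feature_equal_to_label_is_selected(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 10)
        X = pd.DataFrame({100: y.astype(float),
                          101: rng.normal(size=20)})
        sel = pearson_select(X, y)
        assert 100 in sel.selected
        assert sel.scores[100] < 1e-10

    def test_constant_feature_never_selected(self):
        y = np.array([0, 1] * 10)
        X = pd.DataFrame({100: np.ones(20), 101: y.astype(float)})
        sel = pearson_select(X, y)
        assert 100 not in sel.selected
        assert sel.scores[100] == 1.0

    def test_null_selection_rate_approximates_alpha(self):
        # label permutations on independent features: the P < 0.05 gate
        # should fire on ~5% of bins
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.lognormal(0, 0.3, size=(50, 500)))
        y = np.array([0] * 25 + [1] * 25)
        rates = []
        for _ in range(40):
            sel = pearson_select(X, rng.permutation(y))
            rates.append(len(sel.selected) / X.shape[1])
        assert abs(np.mean(rates) - 0.05) < 0.015

    def test_fdr_gate_is_stricter(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 200)))
        y = np.array([0] * 20 + [1] * 20)
        plain = pearson_select(X, y)
        corrected = pearson_select(X, y, fdr=True)
        assert set(corrected.selected) <= set(plain.selected)

    def test_normality_diagnostic_reported(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 50)))
        y = np.array([0] * 15 + [1] * 15)
        sel = pearson_select(X, y, normality_diagnostic=True)
        assert 0.5 <= sel.normal_fraction <= 1.0

    def test_too_few_samples_per_class_is_error(self):
        X = pd.DataFrame(np.random.default_rng(5).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="3 samples"):
            pearson_select(X, np.array([0, 0, 1, 1]))


def _bruteforce_chi2(X, y):
    """Frequency-style chi2 ranking computed from first principles."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    stats = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        observed = np.array([X[y == 0, j].sum(), X[y == 1, j].sum()])
        prior = np.array([(y == 0).mean(), (y == 1).mean()])
        expected = prior * X[:, j].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (observed - expected) ** 2 / expected
        stats[j] = np.nansum(np.where(expected > 0, terms, 0.0))
    return stats


class TestChi2Select:
    def test_perfectly_informative_feature_ranks_first(self):
        y = np.array([0] * 10 + [1] * 10)
        rng = np.random.default_rng(6)
        X = pd.DataFrame({7: y.astype(float), 8: rng.uniform(1, 2, 20),
                          9: rng.uniform(1, 2, 20)})
        sel = chi2_select(X, y, k=1)
        assert list(sel.selected) == [7]

    def test_constant_across_classes_scores_zero(self):
        y = np.array([0] * 10 + [1] * 10)
        X = pd.DataFrame({5: np.ones(20)})
        sel = chi2_select(X, y, k=1)
        assert sel.scores[5] == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(60, 100))
        y = rng.integers(0, 2, 60)
        sel = chi2_select(pd.DataFrame(X), y, k=40)
        brute = _bruteforce_chi2(X, y)
        np.testing.assert_allclose(sel.scores.to_numpy(), brute, atol=1e-9)
        expected = set(np.lexsort((np.arange(100), -brute))[:40])
        assert set(sel.selected) == expected

    def test_negative_feature_directs_to_clip_step(self):
        X = pd.DataFrame({1: [-0.1, 0.2], 2: [0.1, 0.3]})
        with pytest.raises(ValueError, match="clip"):
            chi2_select(X, np.array([0, 1]), k=1)


class TestOverlapSelect:
    def test_planted_bins_all_selected(self, planted_dataset, planted_effect):
        sel = overlap_select(planted_dataset.spectra, planted_dataset.labels)
        assert set(planted_effect.effect_peaks) <= set(sel.selected.tolist())

    def test_k_equal_to_feature_count_is_identity(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.uniform(size=(20, 7)))
        y = np.array([0] * 10 + [1] * 10)
        sel = overlap_select(X, y, k=7)
        assert sorted(sel.selected) == list(range(7))

    def test_tie_at_cut_prefers_lower_bin_label(self):
        rng = np.random.default_rng(9)
        y = np.array([0] * 10 + [1] * 10)
        col = rng.uniform(size=20)
        # bins 200 and 300 are identical -> identical overlap; with k=1 the
        # lower label must win
        X = pd.DataFrame({300: col, 200: col})
        sel = overlap_select(X, y, k=1)
        assert list(sel.selected) == [200]

    def test_fewer_features_than_k_warns_and_selects_all(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.uniform(size=(20, 3)))
        y = np.array([0] * 10 + [1] * 10)
        with pytest.warns(UserWarning, match="selecting all"):
            sel = overlap_select(X, y, k=40)
        assert len(sel.selected) == 3

    @pytest.mark.parametrize("method", ["overlap", "chi2"])
    def test_selection_count_is_min_k_nfeatures(self, method, planted_dataset):
        sel = select_features(method, planted_dataset.spectra,
                              planted_dataset.labels, k=40)
        assert len(sel.selected) == 40


def _selection(method, bins, partition):
    all_bins = list(range(100, 110))
    return FeatureSelection(
        method=method,
        selected=np.asarray(bins),
        scores=pd.Series(np.zeros(len(all_bins)), index=all_bins),
        partition_id=partition,
    )


class TestConsensus:
    def test_bin_selected_everywhere_is_included(self):
        sels = [
            _selection(m, [100, 101], p)
            for m in ("pearson", "overlap", "chi2")
            for p in range(4)
        ]
        report = consensus_features(sels)
        assert 100 in report.consensus and 101 in report.consensus

    def test_exactly_75_percent_is_excluded(self):
        # bin 100: selected in 3 of 4 partitions by pearson (exactly 75%),
        # always by the others -> excluded by the strict inequality
        sels = []
        for p in range(4):
            sels.append(_selection("pearson", [100] if p < 3 else [], p))
            sels.append(_selection("overlap", [100], p))
            sels.append(_selection("chi2", [100], p))
        report = consensus_features(sels, fraction=0.75)
        assert 100 not in report.consensus
        assert report.fractions.loc[100, "pearson"] == pytest.approx(0.75)

    def test_consensus_monotone_in_fraction(self):
        rng = np.random.default_rng(11)
        sels = []
        for p in range(8):
            for m in ("pearson", "overlap", "chi2"):
                bins = rng.choice(range(100, 110), size=5, replace=False)
                sels.append(_selection(m, sorted(bins), p))
        sizes = [
            len(consensus_features(sels, fraction=f).consensus)
            for f in (0.0, 0.25, 0.5, 0.75)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_method_without_partitions_is_error(self):
        sels = [_selection("pearson", [100], 0), _selection("overlap", [100], 0)]
        with pytest.raises(ValueError, match="chi2"):
            consensus_features(sels)

    def test_consensus_subset_of_every_method(self):
        rng = np.random.default_rng(12)
        sels = []
        for p in range(6):
            for m in ("pearson", "overlap", "chi2"):
                bins = rng.choice(range(100, 106), size=3, replace=False)
                sels.append(_selection(m, sorted(bins), p))
        report = consensus_features(sels, fraction=0.5)
        for m in report.methods:
            qualifying = set(
                report.fractions.index[report.fractions[m] > 0.5]
            )
            assert set(report.consensus.tolist()) <= qualifying
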