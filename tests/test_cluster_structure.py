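import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunorank.cluster_structure import (
    SUBTYPES,
    genomic_dissimilarity,
    gradient_fractions,
    heatmap_split,
    hierarchical_order,
    hyperexpression_fractions,
    log_center,
    splitting_point,
    uncentered_correlation_matrix,
)

from conftest import make_matrix


class TestLogCenter:
    def test_mean_mode(self):
        cm = log_center(make_matrix([[1.0, 2.0, 4.0]]), mode="mean")
        assert np.allclose(cm.values.iloc[0], [-1.0, 0.0, 1.0])

    def test_zero_becomes_missing(self):
        cm = log_center(make_matrix([[0.0, 8.0, 8.0]]), mode="mean")
        row = cm.values.iloc[0]
        assert np.isnan(row.iloc[0]) and np.allclose(row.iloc[1:], 0.0)

    def test_all_zero_gene_flagged(self):
        cm = log_center(make_matrix([[0.0, 0.0], [1.0, 2.0]]))
        assert cm.all_missing_rows == [0]
        assert cm.values.iloc[0].isna().all()

    def test_centering_statistic_zero(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.gamma(2, 10, size=(20, 11)))
        for mode, stat in (("mean", np.nanmean), ("median", np.nanmedian)):
            cm = log_center(m, mode=mode)
            centers = stat(cm.values.to_numpy(), axis=1)
            assert np.allclose(centers, 0.0, atol=1e-9)

    def test_median_mode_odd_row_has_central_zero(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.gamma(2, 10, size=(10, 7)))
        cm = log_center(m, mode="median")
        zeros_per_row = (np.abs(cm.values.to_numpy()) < 1e-12).sum(axis=1)
        assert (zeros_per_row == 1).all()


def brute_average_linkage(sim: np.ndarray) -> list[frozenset]:
    """Naive O(n^3) average-linkage agglomeration; returns the merge partitions."""
    d = 1.0 - sim
    clusters = [[i] for i in range(sim.shape[0])]
    merges = []
    while len(clusters) > 1:
        best, pair = np.inf, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if dist < best - 1e-12:
                    best, pair = dist, (i, j)
        i, j = pair
        merged = clusters[i] + clusters[j]
        merges.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


class TestHierarchicalOrder:
    def test_identical_pair_merges_before_flipped_row(self):
        m = log_center(make_matrix([[1, 2, 4], [1, 2, 4], [4, 2, 1.0]]))
        ordered = hierarchical_order(m, axes="rows")
        order = ordered.row_order
        # the two identical rows are adjacent leaves
        assert abs(order.index(0) - order.index(1)) == 1

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(2)
        cm = log_center(make_matrix(rng.gamma(2, 10, size=(15, 8))))
        ordered = hierarchical_order(cm, axes="both")
        assert sorted(ordered.row_order) == list(range(15))
        assert sorted(ordered.col_order) == list(range(8))

    def test_merge_sequence_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        sim = uncentered_correlation_matrix(X)
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        d = 1.0 - sim
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform(d, checks=False), method="average")
        # reconstruct partitions from the scipy merge tree
        members = {i: frozenset([i]) for i in range(6)}
        merges = []
        for k, (a, b, _h, _n) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[6 + k] = merged
            merges.append(merged)
        assert merges == brute_average_linkage(sim)

    def test_row_with_no_overlap_placed_last(self):
        arr = np.array(
            [[1.0, 2.0, np.nan, np.nan],
             [2.0, 1.0, np.nan, np.nan],
             [1.5, 2.5, np.nan, np.nan],
             [np.nan, np.nan, 1.0, 2.0]]
        )
        cm = log_center(make_matrix(np.ones((4, 4))))
        cm.values = pd.DataFrame(arr, columns=cm.values.columns)
        with pytest.warns(UserWarning, match="no overlap"):
            ordered = hierarchical_order(cm, axes="rows")
        assert ordered.row_order[-1] == 3


class TestGenomicDissimilarity:
    @staticmethod
    def _labeled_matrix(seed=0, n_genes=10, n_per=4):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.gamma(2, 10, size=(n_genes, 4 * n_per)))
        labels = pd.Series(np.repeat(list(SUBTYPES), n_per), index=m.samples)
        return m, labels

    def test_identical_subtypes_distance_zero(self):
        m, labels = self._labeled_matrix()
        vals = m.values.copy()
        # make Primitive columns a copy of Classical columns
        c_cols = labels.index[labels == "Classical"]
        p_cols = labels.index[labels == "Primitive"]
        vals[p_cols] = vals[c_cols].to_numpy()
        m.values = vals
        res = genomic_dissimilarity(m, labels)
        assert res.distances.loc["Classical", "Primitive"] == 0.0

    def test_matches_naive_per_gene_summation(self):
        m, labels = self._labeled_matrix(seed=5)
        res = genomic_dissimilarity(m, labels)
        for a in SUBTYPES:
            for b in SUBTYPES:
                naive = sum(
                    abs(
                        m.values.loc[g, labels.index[labels == a]].mean()
                        - m.values.loc[g, labels.index[labels == b]].mean()
                    )
                    for g in m.values.index
                )
                assert res.distances.loc[a, b] == pytest.approx(naive)

    def test_metric_axioms(self):
        for seed in range(5):
            m, labels = self._labeled_matrix(seed=seed)
            d = genomic_dissimilarity(m, labels).distances
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert (d.to_numpy() >= 0).all()
            for a in SUBTYPES:
                for b in SUBTYPES:
                    for c in SUBTYPES:
                        assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-9

    def test_missing_subtype_errors(self):
        m, labels = self._labeled_matrix()
        with pytest.raises(ValueError):
            genomic_dissimilarity(m, labels.replace("Basal", "Classical"))


def planted_delta_matrix(n_genes=60, flip_at=30, n_per=6, violations=()):
    """Matrix whose Delta(CB, PS) is negative before ``flip_at`` and positive
    after, with optional violation indices (sign forced opposite)."""
    labels = pd.Series(
        np.repeat(list(SUBTYPES), n_per), index=[f"s{i}" for i in range(4 * n_per)]
    )
    arr = np.zeros((n_genes, 4 * n_per))
    for g in range(n_genes):
        ps_up = g < flip_at  # PS above gene mean => Delta < 0
        if g in violations:
            ps_up = not ps_up
        for j, s in enumerate(labels):
            hi = s in ("Primitive", "Secretory") if ps_up else s in ("Classical", "Basal")
            arr[g, j] = 4.0 if hi else 1.0
    m = make_matrix(arr, samples=list(labels.index))
    cm = log_center(m, mode="mean")
    cm.row_order = list(range(n_genes))
    return cm, labels


class TestHeatmapSplit:
    def test_clean_flip_splits_exactly_at_k(self):
        cm, labels = planted_delta_matrix(flip_at=30)
        res = heatmap_split(cm, labels, window=(10, 50), tolerance=3)
        assert res.split_index == 30
        assert res.upper == list(range(31))
        assert set(res.upper).isdisjoint(res.lower)
        assert sorted(res.upper + res.lower) == list(range(60))

    def test_short_violation_runs_tolerated(self):
        cm, labels = planted_delta_matrix(flip_at=30, violations=(20, 21, 22))
        res = heatmap_split(cm, labels, window=(10, 50), tolerance=3)
        assert res.split_index == 30

    def test_long_violation_run_moves_split_to_run_start(self):
        cm, labels = planted_delta_matrix(flip_at=30, violations=(20, 21, 22, 23))
        res = heatmap_split(cm, labels, window=(10, 50), tolerance=3)
        assert res.split_index == 20

    def test_no_sign_change_flagged(self):
        cm, labels = planted_delta_matrix(flip_at=60)  # all negative
        res = heatmap_split(cm, labels, window=(10, 50))
        assert res.no_split and res.split_index is None

    def test_agrees_with_exhaustive_scan(self):
        # oracle: try every candidate split; valid iff all violation runs on
        # the negative side are <= tolerance; take the largest prefix
        rng = np.random.default_rng(9)
        for trial in range(20):
            n = 40
            delta_sign = rng.random(n) < 0.5
            flip = rng.integers(5, 35)
            delta_sign[:flip] = rng.random(flip) < 0.15  # mostly negative
            delta_sign[flip:] = True
            viol = np.where(delta_sign[:flip])[0]
            cm, labels = planted_delta_matrix(
                n_genes=n, flip_at=flip, violations=tuple(viol)
            )
            res = heatmap_split(cm, labels, window=(0, n - 1), tolerance=3)
            d = (~delta_sign).astype(int)  # 1 where Delta < 0
            last_neg, run, oracle = None, 0, None
            for i in range(n):
                if d[i]:
                    last_neg, run = i, 0
                else:
                    run += 1
                    if run > 3:
                        break
            oracle = None if last_neg is None else last_neg + 1
            if res.no_split:
                assert oracle is None or not d.any() or d.all()
            else:
                assert res.split_index == oracle


class TestSplittingPoint:
    def test_single_sustained_flip(self):
        seq = [1, 1, 1, -1, -1, -1, -1, -1, -1]
        assert splitting_point(seq) == 2  # boundary between 3rd and 4th

    def test_reverting_flip_is_none(self):
        assert splitting_point([1, -1, 1, 1, 1, 1, 1, 1]) is None

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError):
            splitting_point([1, -1, -1, -1, -1, -1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from([1.0, -1.0]), min_size=7, max_size=30))
    def test_agrees_with_exhaustive_oracle(self, seq):
        def oracle(s):
            regime = np.sign(s[0])
            i = 1
            while i < len(s):
                if np.sign(s[i]) == regime:
                    i += 1
                    continue
                new = np.sign(s[i])
                if i + 5 < len(s) and all(np.sign(v) == new for v in s[i : i + 6]):
                    return i - 1
                while i < len(s) and np.sign(s[i]) != regime:
                    i += 1
            return None

        assert splitting_point(seq) == oracle(seq)


class TestGradientFractions:
    def test_planted_gradient_is_monotone(self):
        n_per = 6
        labels = pd.Series(
            np.repeat(list(SUBTYPES), n_per),
            index=[f"s{i}" for i in range(4 * n_per)],
        )
        arr = np.zeros((20, 24))
        # hyper-expressing sample counts rise across C < B < P < S for upper
        # genes and fall for lower genes
        n_above = {s: c for s, c in zip(SUBTYPES, (1, 2, 4, 5))}
        for g in range(20):
            for s in SUBTYPES:
                cols = np.where(labels.to_numpy() == s)[0]
                k = n_above[s] if g < 10 else n_per - n_above[s]
                arr[g, cols[:k]] = 16.0
                arr[g, cols[k:]] = 1.0
        m = make_matrix(arr, samples=list(labels.index))
        cm = log_center(m, mode="mean")
        out = gradient_fractions(cm, labels, split_index=9)
        assert out.loc["upper", "monotone"] and out.loc["lower", "monotone"]
        upper_vals = out.loc["upper", list(SUBTYPES)].to_numpy(dtype=float)
        assert (np.diff(upper_vals) > 0).all()

    def test_identical_distributions_near_half_not_monotone(self):
        rng = np.random.default_rng(4)
        n_per = 25
        labels = pd.Series(
            np.repeat(list(SUBTYPES), n_per),
            index=[f"s{i}" for i in range(4 * n_per)],
        )
        m = make_matrix(rng.gamma(5, 10, size=(30, 4 * n_per)),
                        samples=list(labels.index))
        cm = log_center(m, mode="mean")
        out = gradient_fractions(cm, labels, split_index=14)
        vals = out.loc[["upper", "lower"], list(SUBTYPES)].to_numpy(dtype=float)
        assert np.allclose(vals, 0.5, atol=0.15)

    def test_empty_half_errors(self):
        cm, labels = planted_delta_matrix(n_genes=10, flip_at=5)
        with pytest.raises(ValueError):
            gradient_fractions(cm, labels, split_index=9)
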