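import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from immunorank.gene_selection import (
    EPS,
    SelectionParams,
    bh_fdr,
    filter_enrichment_terms,
    go_variant_select,
    hybrid_select,
    storey_pi0,
    storey_q,
    strict_bottom_mask,
    strict_top_mask,
    trim_for_gene_set_export,
    wilcoxon_rank_sum_p,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent brute-force re-implementation of the cascade (naive loops)
# ---------------------------------------------------------------------------

def naive_cascade(arr, g1_idx, g2_idx, sd_top=0.5):
    n_genes, n_samples = arr.shape
    med1 = [float(np.median(arr[i, g1_idx])) for i in range(n_genes)]
    med2 = [float(np.median(arr[i, g2_idx])) for i in range(n_genes)]
    relvar, sds, meds, presence, pvals = [], [], [], [], []
    for i in range(n_genes):
        lo, hi = min(med1[i], med2[i]), max(med1[i], med2[i])
        relvar.append((hi - lo) / (lo + EPS))
        meds.append(float(np.median(arr[i])))
        sds.append(float(np.std(arr[i], ddof=1)))
        presence.append(int(sum(v >= 0.5 for v in arr[i])))
        a, b = arr[i, g1_idx], arr[i, g2_idx]
        if all(v == arr[i][0] for v in arr[i][list(g1_idx) + list(g2_idx)]):
            pvals.append(np.nan)
        else:
            method = (
                "exact"
                if len(a) <= 20 and len(b) <= 20
                and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
                else "asymptotic"
            )
            pvals.append(float(mannwhitneyu(a, b, alternative="two-sided",
                                            method=method).pvalue))

    def top_mask(vals, frac):
        m = len(vals)
        k = int(np.floor(frac * m))
        boundary = sorted(vals)[m - k - 1]
        return [v > boundary for v in vals]

    pass_a = top_mask(relvar, 0.5)
    relevant = [presence[i] > 0.6 * n_samples for i in range(n_genes)]
    calculable = [not np.isnan(p) for p in pvals]
    pass_b = [
        calculable[i] and relevant[i] and pvals[i] < 0.01 for i in range(n_genes)
    ]
    pool = [i for i in range(n_genes) if calculable[i] and relevant[i]]
    qs = {}
    if pool:
        qvals = storey_q([pvals[i] for i in pool])
        qs = dict(zip(pool, qvals))
    pass_c = [pass_b[i] and qs.get(i, 1.0) < 0.01 for i in range(n_genes)]
    octile = sorted(meds)[int(np.ceil(0.125 * n_genes)) - 1]
    pass_d = [m > octile for m in meds]
    pass_e = top_mask(sds, sd_top)
    return [
        all(f)
        for f in zip(pass_a, pass_b, pass_c, pass_d, pass_e)
    ], dict(pass_a=pass_a, pass_b=pass_b, pass_c=pass_c, pass_d=pass_d,
            pass_e=pass_e)


def planted_toy():
    """16 genes: 8 strongly shifted between groups (high SD, high median),
    8 flat low genes that fail every criterion by construction."""
    rng = np.random.default_rng(42)
    n1 = n2 = 15
    arr = np.zeros((16, n1 + n2))
    for g in range(8):  # shifted genes
        arr[g, :n1] = rng.normal(50, 6, n1)
        arr[g, n1:] = rng.normal(150, 6, n2)
    for g in range(8, 16):  # flat genes, identical narrow band
        arr[g] = rng.normal(10, 0.05, n1 + n2)
    arr = np.abs(arr)
    m = make_matrix(arr)
    return m, m.samples[:n1], m.samples[n1:]


class TestHybridSelect:
    def test_planted_toy_selects_exactly_the_shifted_genes(self):
        m, g1, g2 = planted_toy()
        rep = hybrid_select(m, g1, g2)
        assert rep.selected == m.gene_keys()[:8]
        # each flag verified against the naive oracle
        sel, flags = naive_cascade(m.values.to_numpy(), np.arange(15),
                                   np.arange(15, 30))
        for name in ("pass_a", "pass_b", "pass_c", "pass_d", "pass_e"):
            assert rep.table[name].tolist() == flags[name]

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        arr = rng.gamma(5, 10, size=(10, 20))
        arr[3] = 7.0
        m = make_matrix(arr)
        rep = hybrid_select(m, m.samples[:10], m.samples[10:])
        row = rep.table.iloc[3]
        assert row["relative_median_variation"] == 0.0
        assert np.isnan(row["wilcoxon_p"])
        assert not row["selected"]

    def test_agrees_with_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(7)
        arr = rng.gamma(2, 20, size=(50, 30))
        m = make_matrix(arr)
        rep = hybrid_select(m, m.samples[:15], m.samples[15:])
        sel, _flags = naive_cascade(arr, np.arange(15), np.arange(15, 30))
        assert rep.table["selected"].tolist() == sel

    def test_selection_invariant_to_gene_permutation(self):
        rng = np.random.default_rng(8)
        arr = rng.gamma(2, 20, size=(30, 20))
        m = make_matrix(arr)
        rep = hybrid_select(m, m.samples[:10], m.samples[10:])
        perm = rng.permutation(30)
        rep_p = hybrid_select(m.subset_genes(perm), m.samples[:10], m.samples[10:])
        assert set(rep.selected) == set(rep_p.selected)

    def test_overlapping_groups_error(self):
        m = make_matrix(np.ones((8, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            hybrid_select(m, m.samples[:3], m.samples[2:])

    def test_fewer_than_eight_genes_error(self):
        m = make_matrix(np.ones((5, 4)))
        with pytest.raises(ValueError, match="8 genes"):
            hybrid_select(m, m.samples[:2], m.samples[2:])


class TestGoVariant:
    def test_variant_subset_of_hybrid(self):
        rng = np.random.default_rng(9)
        arr = rng.gamma(2, 20, size=(40, 24))
        m = make_matrix(arr)
        g1, g2 = m.samples[:12], m.samples[12:]
        assert set(go_variant_select(m, g1, g2).selected) <= set(
            hybrid_select(m, g1, g2).selected
        )

    def test_sd_boundary_is_strict_top_third(self):
        # SDs straddling the 1/3 boundary: only strictly-above genes pass e'
        rng = np.random.default_rng(10)
        n_genes = 9
        arr = np.array(
            [rng.normal(100, sd, 30) for sd in (1, 2, 3, 4, 5, 6, 7, 8, 9)]
        )
        arr = np.abs(arr)
        m = make_matrix(arr)
        rep = go_variant_select(m, m.samples[:15], m.samples[15:])
        sds = rep.table["sd_value"].to_numpy()
        k = int(np.floor(n_genes / 3))
        boundary = np.sort(sds)[n_genes - k - 1]
        assert rep.table["pass_e"].tolist() == list(sds > boundary)
        assert rep.table["pass_e"].sum() == k


class TestTrim:
    def test_eight_increasing_genes_drop_the_bottom_one(self):
        # strictly increasing mean/SD/presence: the same bottom gene fails all
        spread = np.linspace(-1.0, 1.0, 16)
        arr = np.array([10.0 * (g + 1) + (g + 1) * spread for g in range(8)])
        arr[0] = 0.2 + 0.01 * spread  # lowest mean, SD, and presence (all < 0.5)
        m = make_matrix(arr)
        trimmed = trim_for_gene_set_export(m)
        assert trimmed.n_genes == 7
        assert trimmed.gene_keys() == m.gene_keys()[1:]

    def test_identical_genes_all_retained(self):
        m = make_matrix(np.ones((8, 5)))
        assert trim_for_gene_set_export(m).n_genes == 8


class TestStrictMasks:
    def test_top_mask_distinct_even(self):
        v = np.array([1.0, 2, 3, 4])
        assert strict_top_mask(v, 0.5).tolist() == [False, False, True, True]

    def test_top_mask_tie_at_boundary_fails(self):
        v = np.array([1.0, 2, 2, 3])
        # top half boundary value is 2; ties at 2 fail strictness
        assert strict_top_mask(v, 0.5).tolist() == [False, False, False, True]

    def test_bottom_mask_mirrors(self):
        v = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        assert strict_bottom_mask(v, 0.125).tolist() == [True] + [False] * 7


class TestFdr:
    def test_bh_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bh_monotone_and_bounded(self, ps):
        adj = bh_fdr(ps)
        assert ((0 <= adj) & (adj <= 1)).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_storey_all_ones(self):
        assert np.allclose(storey_q([1.0] * 10), 1.0)

    def test_storey_pi0_near_one_under_null(self):
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            pi0 = storey_pi0(rng.uniform(size=1000))
            hits += 0.8 <= pi0 <= 1.0
        assert hits >= 0.95 * n_sim

    def test_storey_never_exceeds_bh(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = rng.uniform(size=200) ** 2
            q = storey_q(p)
            bh = bh_fdr(p)
            pi0 = storey_pi0(p)
            if pi0 <= 1.0:
                assert (q <= bh + 1e-12).all()

    def test_storey_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = storey_q(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            storey_q([])


class TestWilcoxonHelper:
    def test_degenerate_identical_groups_nan(self):
        assert np.isnan(wilcoxon_rank_sum_p([5, 5, 5], [5, 5, 5]))

    def test_matches_scipy_on_clean_data(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        expected = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert wilcoxon_rank_sum_p(a, b) == pytest.approx(float(expected))


class TestEnrichmentFilter:
    @pytest.fixture()
    def terms(self):
        return pd.DataFrame(
            [
                ("BP", "t1", 1e-9, ["g1"]),  # 1 member: rejected
                ("BP", "t2", 5e-4, ["g%d" % i for i in range(11)]),  # kept
                ("BP", "t3", 5e-3, ["g1", "g2"]),  # p too big
                ("MF", "t4", 1e-9, ["g1", "g2"]),  # wrong ontology
                ("BP", "t5", 1e-4, ["g1", "g2", "g3"]),  # kept (>=2 rule)
                ("XX", "t6", 1e-9, ["g1", "g2"]),  # unknown tag: warned
            ],
            columns=["ontology", "term", "p", "members"],
        )

    def test_default_rule_set(self, terms):
        with pytest.warns(UserWarning, match="unknown ontology"):
            out = filter_enrichment_terms(terms, min_members=2, p_threshold=1e-3)
        assert sorted(out["term"]) == ["t2", "t5"]

    def test_min_ten_members_rule_set(self, terms):
        with pytest.warns(UserWarning):
            out = filter_enrichment_terms(terms, min_members=10, p_threshold=1e-3)
        assert sorted(out["term"]) == ["t2"]
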