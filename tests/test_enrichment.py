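import numpy as np
import pytest

from pea_augment.annotations import DatasetMembership
from pea_augment.enrichment import (
    EnrichmentConfig,
    RankedList,
    bh_adjust,
    enrich_dataset,
    gsea_es,
    gsea_exact_p,
    gsea_preranked,
    pca_select,
    prepare_log_matrix,
)

from conftest import make_dataset


class TestLogMatrix:
    def test_zeros_become_min_nonzero_over_ten(self):
        mat = np.array([[0.0, 2.0, 20.0]])
        out = prepare_log_matrix(mat)
        assert out[0, 0] == pytest.approx(np.log2(0.2))
        assert np.all(np.isfinite(out))

    def test_no_zeros_is_plain_log(self):
        mat = np.array([[1.0, 4.0], [2.0, 8.0]])
        np.testing.assert_allclose(prepare_log_matrix(mat), np.log2(mat))

    def test_replacement_preserves_order(self):
        mat = np.array([[0.0, 10.0]])
        out = prepare_log_matrix(mat)
        assert out[0, 0] == pytest.approx(0.0)  # log2(1.0)
        assert out[0, 0] < out[0, 1]

    def test_preserves_within_column_rank_order(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0, 30, size=(10, 6))
        mat[rng.random(mat.shape) < 0.3] = 0.0
        out = prepare_log_matrix(mat)
        for col in range(mat.shape[1]):
            assert np.array_equal(
                np.argsort(mat[:, col], kind="stable"),
                np.argsort(out[:, col], kind="stable"),
            )

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            prepare_log_matrix(np.zeros((3, 3)))


class TestPcaSelect:
    def test_minimal_prefix_rule(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(30, 8)) * np.array([5, 3, 2, 1, 1, 1, 1, 1])
        for thr in (0.5, 0.75, 0.9):
            sel = pca_select(mat, thr)
            cum = np.cumsum(sel.variance_fractions)
            assert cum[-1] >= thr - 1e-12
            if sel.n_selected > 1:
                assert cum[-2] < thr  # prefix is minimal

    def test_dominant_direction_selects_one_pc(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=(50, 1))
        mat = latent @ rng.normal(size=(1, 6)) + 0.01 * rng.normal(size=(50, 6))
        assert pca_select(mat, 0.75).n_selected == 1

    def test_loadings_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(4)
        direction = rng.normal(size=6)
        direction /= np.linalg.norm(direction)
        mat = rng.normal(size=(80, 1)) @ direction[None, :] + 0.01 * rng.normal(size=(80, 6))
        sel = pca_select(mat, 0.5)
        cov = np.cov(mat, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)
        top = eigvec[:, np.argmax(eigval)]
        cos = abs(np.dot(sel.loadings[0], top))
        assert cos == pytest.approx(1.0, abs=1e-9)  # up to sign
        assert abs(np.dot(sel.loadings[0], direction)) > 0.999

    def test_constant_matrix_raises(self):
        with pytest.raises(ValueError):
            pca_select(np.ones((5, 4)))


def ranked(scores, indices=None):
    idx = indices if indices is not None else list(range(len(scores)))
    return RankedList.from_scores(idx, scores)


class TestEnrichmentScore:
    def test_singleton_at_top_is_one(self):
        # hand-walk: single hit with weight 5/5 = 1 at position 1
        assert gsea_es(ranked([5, 4, 3, 2, 1]), {0}) == pytest.approx(1.0)

    def test_singleton_at_bottom_is_minus_one(self):
        assert gsea_es(ranked([5, 4, 3, 2, 1]), {4}) == pytest.approx(-1.0)

    def test_near_full_set_bounded(self):
        es = gsea_es(ranked([5, 4, 3, 2, 1]), {0, 1, 2, 3})
        assert abs(es) <= 1.0

    def test_bound_holds_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = rng.normal(size=n)
            k = int(rng.integers(1, n))
            members = set(rng.choice(n, size=k, replace=False).tolist())
            assert abs(gsea_es(ranked(scores), members)) <= 1.0 + 1e-12

    def test_antisymmetric_under_list_reversal(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(size=9))[::-1]  # distinct, descending
        members = {1, 4, 6}
        es_fwd = gsea_es(ranked(scores), members)
        rev = ranked(-scores[::-1], indices=list(range(8, -1, -1)))
        es_rev = gsea_es(rev, members)
        assert es_rev == pytest.approx(-es_fwd)

    def test_empty_and_full_sets_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(ranked([3, 2, 1]), set())
        with pytest.raises(ValueError):
            gsea_es(ranked([3, 2, 1]), {0, 1, 2})

    def test_ties_order_stably_by_local_index(self):
        r = ranked([1.0, 1.0, 2.0], indices=[7, 3, 5])
        assert r.indices.tolist() == [5, 3, 7]  # score 2 first, then ties by index


class TestExactP:
    # Enumerating the 5 singleton placements by hand (weight 1 each, miss
    # 1/4): ES = {+1, +0.75, +0.5, -0.75, -1} (the middle placement's
    # running-sum extremes tie at +/-0.5 and resolve positive). Same-sign
    # tail for the observed top placement: 1 of 3 positives.
    def test_singleton_at_top_conditional_tail(self):
        p = gsea_exact_p(ranked([5, 4, 3, 2, 1]), {0})
        assert p == pytest.approx(1 / 3)

    def test_complement_set_mirrors_opposite_tail(self):
        # Unweighted (exponent 0) running sums satisfy ES(S^c) = -ES(S)
        # pointwise, so the complement's opposite-tail p must agree. Even N
        # keeps every placement's extremes untied (the positive tie-break
        # would otherwise make a few placements change tail).
        scores = [9, 6, 4, 2, 1.5, 1]
        p_single = gsea_exact_p(ranked(scores), {5}, sign="neg", exponent=0)
        p_complement = gsea_exact_p(ranked(scores), {0, 1, 2, 3, 4}, sign="pos", exponent=0)
        assert p_single == pytest.approx(1 / 3)  # hand enumeration of 6 placements
        assert p_single == pytest.approx(p_complement)

    def test_threshold_below_minimum_gives_one(self):
        p = gsea_exact_p(ranked([5, 4, 3, 2, 1]), {1}, sign="pos", threshold=0.0)
        assert p == pytest.approx(1.0)

    def test_budget_guard(self):
        with pytest.raises(ValueError):
            gsea_exact_p(ranked(list(range(60, 0, -1))), set(range(25)), max_enumeration=100)


class TestPreranked:
    def test_matches_exact_enumeration_within_monte_carlo_error(self):
        rng = np.random.default_rng(8)
        scores = np.sort(rng.normal(size=10))[::-1]
        members = {0, 2, 5}
        r = ranked(scores)
        res = gsea_preranked(r, {"P": members}, n_perm=4000, seed=11, min_size=3)
        es, p = res["P"]
        p_exact = gsea_exact_p(r, members)
        sigma = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p - p_exact) <= 3 * sigma + 2 / 4000

    def test_sets_below_min_size_excluded(self):
        r = ranked(list(range(30, 0, -1)))
        out = gsea_preranked(r, {"small": {0, 1}, "ok": set(range(16))}, n_perm=50, seed=0)
        assert set(out) == {"ok"}

    def test_deterministic_for_fixed_seed(self):
        r = ranked(list(range(25, 0, -1)))
        sets = {"A": set(range(15)), "B": set(range(5, 21))}
        a = gsea_preranked(r, sets, n_perm=200, seed=42)
        b = gsea_preranked(r, sets, n_perm=200, seed=42)
        assert a == b

    def test_n_perm_must_be_positive(self):
        with pytest.raises(ValueError):
            gsea_preranked(ranked([3, 2, 1]), {"P": {0}}, n_perm=0, min_size=1)

    def test_calls_invariant_to_loading_sign_flip(self):
        # PC loading signs are arbitrary; negating every score mirrors the
        # list and flips ES, and with the sign-matched null the enrichment
        # calls must not change (exact p can shift by the tiny mass of
        # placements whose running-sum extremes tie, so the assertion is on
        # calls and on p agreement up to that tie mass).
        rng = np.random.default_rng(9)
        scores = np.sort(rng.normal(size=30))[::-1]
        members = {0, 1, 2, 3, 4, 5, 6, 8, 9, 10, 12, 13, 14, 15, 16}
        r_fwd = ranked(scores)
        r_flip = RankedList.from_scores(list(range(30)), -scores)
        res_fwd = gsea_preranked(r_fwd, {"P": members}, n_perm=999, seed=21)
        res_flip = gsea_preranked(r_flip, {"P": members}, n_perm=999, seed=21)
        es_f, p_f = res_fwd["P"]
        es_b, p_b = res_flip["P"]
        assert es_b == pytest.approx(-es_f)
        assert (p_f <= 0.01) == (p_b <= 0.01)
        assert p_f == pytest.approx(p_b, abs=0.05)


class TestBhAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 12)))
            adj = bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            # oracle: min over j >= i of (m/j) p_(j), clipped at 1
            expected = np.empty(m)
            for rank_pos, idx in enumerate(order):
                i = rank_pos + 1
                expected[idx] = min(
                    min((m / (jpos + 1)) * p[order[jpos]] for jpos in range(rank_pos, m)),
                    1.0,
                )
            np.testing.assert_allclose(adj, expected)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestEnrichDataset:
    def _planted_dataset(self, seed=0, effect=3.0, n_met=40, n_samp=16, members=range(15)):
        rng = np.random.default_rng(seed)
        group = np.r_[np.zeros(n_samp // 2), np.ones(n_samp // 2)]
        base = rng.normal(8, 1, size=n_met)
        shift = np.zeros(n_met)
        shift[list(members)] = effect
        log2 = base + np.outer(group - 0.5, shift) + rng.normal(0, 0.4, (n_samp, n_met))
        ds = make_dataset(
            n_samples=n_samp, n_metabolites=n_met, intensities=np.power(2.0, log2)
        )
        return ds

    def test_planted_pathway_is_enriched(self):
        ds = self._planted_dataset()
        mem = DatasetMembership("DS1", {"planted": set(range(15))})
        records, count = enrich_dataset(ds, mem, EnrichmentConfig(n_perm=999, seed=1))
        planted = [r for r in records if r.pathway_id == "planted" and r.enriched]
        assert planted, "planted pathway should be enriched on at least one PC"
        assert count >= 1

    def test_all_sets_below_min_size_yield_nothing(self):
        ds = self._planted_dataset()
        mem = DatasetMembership("DS1", {"small": set(range(5))})
        records, count = enrich_dataset(ds, mem, EnrichmentConfig(n_perm=99, seed=1))
        assert records == [] and count == 0

    def test_pathway_on_two_pcs_counts_twice(self):
        ds = self._planted_dataset()
        mem = DatasetMembership("DS1", {"planted": set(range(15))})
        records, count = enrich_dataset(ds, mem, EnrichmentConfig(n_perm=999, seed=1))
        assert count == sum(r.enriched for r in records)

    def test_enriched_flag_consistent_with_alpha(self):
        ds = self._planted_dataset()
        mem = DatasetMembership("DS1", {"planted": set(range(15))})
        cfg = EnrichmentConfig(n_perm=499, seed=2, alpha=0.01)
        records, _ = enrich_dataset(ds, mem, cfg)
        for r in records:
            assert r.enriched == (r.padj <= cfg.alpha)
            assert 0 < r.pvalue <= 1 and r.padj >= r.pvalue - 1e-12
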