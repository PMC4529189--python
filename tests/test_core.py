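import logging
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from clue.annotations import AnnotationDB
from clue.clustering import ClusterModel
from clue.core import (
    ContingencyCounts,
    cluster_min_p,
    combine_fisher,
    combine_fisher_from_logs,
    enriched_kinases,
    fisher_one_sided,
    log_fisher_one_sided,
    minmax_normalize,
    score_clustering,
)


def exact_upper_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """Oracle: exact-rational sum of hypergeometric probabilities over all
    tables with the same margins whose odds ratio is at least as large as
    observed (equivalently, whose top-left cell is >= a)."""
    N, K, n = a + b + c + d, a + b, a + c
    return sum(
        (Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
         for x in range(a, min(K, n) + 1)),
        Fraction(0),
    )


def _hard_model(assignment, k, site_ids=None):
    assignment = np.asarray(assignment)
    n = assignment.size
    membership = np.zeros((n, k))
    membership[np.arange(n), assignment] = 1.0
    return ClusterModel(
        k=k,
        site_ids=site_ids or [f"G{i};S1" for i in range(n)],
        centroids=np.zeros((k, 2)),
        membership=membership,
        hard_assignment=assignment,
    )


class TestFisherOneSided:
    def test_minimum_possible_overlap_gives_one(self):
        assert fisher_one_sided(ContingencyCounts(0, 10, 10, 80)) == pytest.approx(1.0)

    def test_two_table_margin_enumeration(self):
        # margins (1,1,1): only two tables, the observed one has prob 1/2
        assert fisher_one_sided(ContingencyCounts(1, 0, 0, 1)) == pytest.approx(0.5)

    def test_matches_exact_rational_oracle(self):
        p = fisher_one_sided(ContingencyCounts(5, 5, 5, 85))
        assert p == pytest.approx(float(exact_upper_tail(5, 5, 5, 85)), rel=1e-12)

    @pytest.mark.parametrize("counts", [ContingencyCounts(0, 0, 7, 13), ContingencyCounts(0, 20, 0, 30)])
    def test_degenerate_margins_return_one(self, counts):
        assert fisher_one_sided(counts) == 1.0

    def test_strictly_decreasing_in_overlap_for_fixed_margins(self):
        # margins: 10 substrates, cluster of 12, universe 60
        ps = []
        for a in range(0, 11):
            ps.append(fisher_one_sided(ContingencyCounts(a, 10 - a, 12 - a, 38 + a)))
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_log_variant_agrees_where_no_underflow(self):
        counts = ContingencyCounts(8, 2, 4, 46)
        assert log_fisher_one_sided(counts) == pytest.approx(
            np.log(fisher_one_sided(counts)), rel=1e-10
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(-1, 1, 1, 1)


class TestClusterMinP:
    def test_minimum(self):
        assert cluster_min_p([0.3, 0.01, 0.8]) == 0.01

    def test_empty_row_is_uninformative(self):
        assert cluster_min_p([]) == 1.0

    def test_all_ones(self):
        assert cluster_min_p([1.0, 1.0, 1.0]) == 1.0

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            cluster_min_p(bad)


class TestCombineFisher:
    def test_all_ones_gives_null_score(self):
        pk, ek = combine_fisher([1.0, 1.0, 1.0])
        assert pk == pytest.approx(1.0)
        assert ek == pytest.approx(0.0)

    def test_single_p_is_identity(self):
        # for 2 df the chi-squared upper tail at -2 ln p is exactly p
        pk, ek = combine_fisher([0.1])
        assert pk == pytest.approx(0.1, rel=1e-12)
        assert ek == pytest.approx(1.0, rel=1e-12)

    def test_two_cluster_closed_form(self):
        # X = -2 ln(0.01 * 0.5); P_2 = e^{-X/2} (1 + X/2) evaluated exactly
        x = -2.0 * (np.log(0.01) + np.log(0.5))
        expected = np.exp(-x / 2) * (1 + x / 2)
        pk, ek = combine_fisher([0.01, 0.5])
        assert x == pytest.approx(10.5966, abs=1e-4)
        assert pk == pytest.approx(expected, rel=1e-12)
        assert ek == pytest.approx(-np.log10(expected), rel=1e-12)

    def test_zero_p_floored_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            pk, ek = combine_fisher([0.0, 0.5])
        assert 0 < pk < 1e-100 and np.isfinite(ek)
        assert any("floored" in rec.message for rec in caplog.records)

    def test_monotone_decreasing_in_common_p(self):
        pks = [combine_fisher([p] * 4)[0] for p in (0.9, 0.5, 0.1, 0.01, 1e-6)]
        assert all(x > y for x, y in zip(pks, pks[1:]))

    def test_log_route_survives_extreme_scores(self):
        log_pk, pk, ek = combine_fisher_from_logs([-800.0] * 10)
        assert pk == 0.0  # underflows as a probability...
        assert np.isfinite(ek) and ek > 3000  # ...but the score does not
        assert log_pk == pytest.approx(-ek / np.log10(np.e), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_fisher([])


def _three_group_setup():
    """30 sites in 3 true groups of 10; 3 kinases each annotating 8 sites
    of one group."""
    site_ids = [f"G{i};S1" for i in range(30)]
    true = np.repeat([0, 1, 2], 10)
    db = AnnotationDB(
        {
            f"K{g}": frozenset(site_ids[i] for i in np.where(true == g)[0][:8])
            for g in range(3)
        }
    )
    return site_ids, true, db


class TestScoreClustering:
    @pytest.mark.parametrize("split_group,split_size", [(0, 5), (0, 3), (1, 5), (2, 4)])
    def test_coherent_partition_beats_split(self, split_group, split_size):
        site_ids, true, db = _three_group_setup()
        coherent = _hard_model(true, k=3, site_ids=site_ids)
        # carve `split_size` sites of one true group into a fourth cluster
        split_labels = true.copy()
        idx = np.where(true == split_group)[0][:split_size]
        split_labels[idx] = 3
        split = _hard_model(split_labels, k=4, site_ids=site_ids)
        assert score_clustering(coherent, db).score > score_clustering(split, db).score

    def test_no_eligible_kinase_scores_zero(self):
        model = _hard_model([0, 0, 1, 1], k=2)
        table = score_clustering(model, AnnotationDB({}))
        assert table.score == 0.0
        assert np.all(table.cluster_p == 1.0)

    def test_cluster_label_permutation_invariance(self):
        site_ids, true, db = _three_group_setup()
        model = _hard_model(true, k=3, site_ids=site_ids)
        permuted = model.relabel(np.array([1, 2, 0]))
        a = score_clustering(model, db)
        b = score_clustering(permuted, db)
        assert a.score == pytest.approx(b.score, rel=1e-12)
        np.testing.assert_allclose(sorted(a.cluster_p), sorted(b.cluster_p))

    def test_site_order_invariance(self):
        site_ids, true, db = _three_group_setup()
        rng = np.random.default_rng(0)
        order = rng.permutation(30)
        a = score_clustering(_hard_model(true, 3, site_ids), db)
        b = score_clustering(
            _hard_model(true[order], 3, [site_ids[i] for i in order]), db
        )
        assert a.score == pytest.approx(b.score, rel=1e-12)

    def test_unknown_annotated_sites_rejected(self):
        model = _hard_model([0, 0, 1, 1], k=2)
        db = AnnotationDB({"K1": frozenset({"G0;S1", "NOT_THERE;S9"})})
        with pytest.raises(ValueError, match="NOT_THERE;S9"):
            score_clustering(model, db)

    def test_table_bookkeeping(self):
        site_ids, true, db = _three_group_setup()
        table = score_clustering(_hard_model(true, 3, site_ids), db)
        assert table.df == 6
        assert table.p.shape == (3, 3)
        np.testing.assert_allclose(table.cluster_p, table.p.min(axis=1))
        assert np.all((table.p > 0) & (table.p <= 1))


class TestEnrichedKinases:
    def _table(self):
        site_ids, true, db = _three_group_setup()
        return score_clustering(_hard_model(true, 3, site_ids), db)

    def test_each_cluster_reports_its_kinase(self):
        table = self._table()
        hits = enriched_kinases(table, alpha=0.05)
        assert [h[0][0] for h in hits] == ["K0", "K1", "K2"]
        for cluster_hits in hits:
            ps = [p for _, p in cluster_hits]
            assert ps == sorted(ps) and all(p < 0.05 for p in ps)

    def test_alpha_one_lists_all(self):
        table = self._table()
        hits = enriched_kinases(table, alpha=1.0)
        assert all(len(h) == len(table.kinases) for h in hits)

    def test_empty_table(self):
        model = _hard_model([0, 0, 1, 1], k=2)
        table = score_clustering(model, AnnotationDB({}))
        assert enriched_kinases(table) == [[], []]

    def test_bh_correction_is_more_conservative(self):
        table = self._table()
        raw = enriched_kinases(table, alpha=0.05)
        adj = enriched_kinases(table, alpha=0.05, bh_correct=True)
        for r, a in zip(raw, adj):
            assert {k for k, _ in a} <= {k for k, _ in r}

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            enriched_kinases(self._table(), alpha=0.0)


class TestMinMaxNormalize:
    def test_maximize(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_minimize_flips(self):
        np.testing.assert_allclose(
            minmax_normalize([2, 4, 6], direction="minimize"), [1, 0.5, 0]
        )

    def test_range_endpoints(self):
        rng = np.random.default_rng(2)
        out = minmax_normalize(rng.normal(size=19))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            minmax_normalize([1.0])
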