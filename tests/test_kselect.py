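import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cnvselect import (
    KSelector,
    assign_malignancy,
    de_top_genes,
    kmeans_over_range,
    select_k,
    separation_pvalue,
    ssgsea_score,
)
from cnvselect.kselect import NoCandidateGenesError

from oracles import min_wcss_two_clusters


def make_norm_adata(X, is_reference=None):
    n_cells, n_genes = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    if is_reference is not None:
        obs["is_reference"] = np.asarray(is_reference, dtype=bool)
    return ad.AnnData(
        X=np.asarray(X, dtype=float),
        obs=obs,
        var=pd.DataFrame(index=[f"g{j}" for j in range(n_genes)]),
    )


class TestKMeansOverRange:
    def test_full_range_returns_ten_labelings(self, rng):
        X = rng.random((40, 5))
        out = kmeans_over_range(X, 6, 15, seed=0)
        assert sorted(out) == list(range(6, 16))
        assert all(len(np.unique(lab)) == k for k, lab in out.items())

    def test_k_equal_to_distinct_points_gives_zero_wcss(self):
        X = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])
        out = kmeans_over_range(np.repeat(X, 2, axis=0), 4, 4, seed=1)
        labels = out[4]
        # each distinct point its own cluster: within-cluster scatter is zero
        for c in np.unique(labels):
            assert np.allclose(np.var(np.repeat(X, 2, axis=0)[labels == c], axis=0), 0)

    def test_two_planted_blobs_recovered_and_wcss_optimal(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(5, 0.1, (6, 2))])
        out = kmeans_over_range(pts, 2, 2, seed=3)
        labels = out[2]
        truth = np.array([0] * 6 + [1] * 6)
        assert adjusted_rand_score(truth, labels) == 1.0
        wcss = sum(
            ((pts[labels == c] - pts[labels == c].mean(axis=0)) ** 2).sum()
            for c in np.unique(labels)
        )
        assert wcss == pytest.approx(min_wcss_two_clusters(pts), rel=1e-9)

    def test_k_exceeding_distinct_points_is_error(self):
        X = np.zeros((10, 3))
        X[5:] = 1.0
        with pytest.raises(ValueError, match="distinct"):
            kmeans_over_range(X, 3, 3, seed=0)

    def test_k_range_validation(self, rng):
        X = rng.random((10, 2))
        with pytest.raises(ValueError, match="k_min"):
            kmeans_over_range(X, 1, 5, seed=0)
        with pytest.raises(ValueError, match="below the number of cells"):
            kmeans_over_range(X, 2, 10, seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.random((50, 4))
        a = kmeans_over_range(X, 3, 5, seed=9)
        b = kmeans_over_range(X, 3, 5, seed=9)
        assert all(np.array_equal(a[k], b[k]) for k in a)


class TestAssignMalignancy:
    def test_isolated_reference_cluster_is_the_nonmalignant_one(self):
        labels = np.array([0] * 10 + [1] * 10)
        is_ref = np.array([True] * 10 + [False] * 10)
        malignant, degenerate = assign_malignancy(labels, is_ref)
        assert malignant == {1}
        assert not degenerate

    def test_uniform_reference_mixing_degenerates(self):
        labels = np.array([0, 0, 1, 1] * 5)
        is_ref = np.array([True, False] * 10)  # every cluster at the global fraction
        malignant, degenerate = assign_malignancy(labels, is_ref)
        assert degenerate and malignant == set()

    def test_no_reference_cells_is_error(self):
        with pytest.raises(ValueError, match="no reference"):
            assign_malignancy(np.array([0, 1]), np.array([False, False]))


class TestDeTopGenes:
    def test_identical_groups_yield_no_candidates(self, rng):
        X = rng.normal(1.0, 0.2, size=(40, 30)).clip(min=0)
        adata = make_norm_adata(X)
        cells = np.asarray(adata.obs_names)
        with pytest.raises(NoCandidateGenesError):
            de_top_genes(adata, cells[:20], cells[20:])

    def test_single_shifted_gene_ranks_first(self, rng):
        X = rng.normal(1.0, 0.3, size=(400, 40)).clip(min=0)
        X[:200, 7] += 2.0  # +2 log-units in the malignant half
        adata = make_norm_adata(X)
        cells = np.asarray(adata.obs_names)
        gs = de_top_genes(adata, cells[:200], cells[200:], n_top=5)
        assert gs.genes[0] == "g7"

    def test_truncation_warns_when_fewer_candidates(self, rng):
        X = rng.normal(1.0, 0.1, size=(60, 20)).clip(min=0)
        X[:30, :3] += 3.0
        adata = make_norm_adata(X)
        cells = np.asarray(adata.obs_names)
        with pytest.warns(UserWarning, match="only 3 candidate"):
            gs = de_top_genes(adata, cells[:30], cells[30:], n_top=50)
        assert len(gs.genes) == 3

    def test_small_group_is_error(self, rng):
        X = rng.random((10, 5))
        adata = make_norm_adata(X)
        cells = np.asarray(adata.obs_names)
        with pytest.raises(ValueError, match=">= 3 cells"):
            de_top_genes(adata, cells[:2], cells[2:])

    def test_down_regulated_genes_excluded(self, rng):
        X = rng.normal(1.0, 0.2, size=(100, 10)).clip(min=0)
        X[:50, 2] += 2.0  # up in malignant
        X[:50, 5] -= 0.9  # down in malignant
        adata = make_norm_adata(X.clip(min=0))
        cells = np.asarray(adata.obs_names)
        with pytest.warns(UserWarning):
            gs = de_top_genes(adata, cells[:50], cells[50:], n_top=10)
        assert "g5" not in gs.genes


class TestSelectK:
    @pytest.fixture(scope="class")
    def selection(self, sim_profile, sim_bulk):
        ordered, profile, truth = sim_profile
        result = select_k(
            ordered, profile.chrom_features.to_numpy(), sim_bulk, k_min=2, k_max=8, seed=11
        )
        return ordered, profile, truth, result

    def test_selected_k_attains_minimum_p(self, selection):
        *_, result = selection
        pvals = {k: r.p_value for k, r in result.per_k.items()}
        assert result.per_k[result.selected_k].p_value == min(pvals.values())
        ties = [k for k, p in pvals.items() if p == min(pvals.values())]
        assert result.selected_k == min(ties)

    def test_every_cell_assigned_at_every_k(self, selection):
        ordered, _, _, result = selection
        for r in result.per_k.values():
            assert len(r.labels) == ordered.n_obs
            assert set(np.unique(r.labels)) == set(range(r.k))

    def test_malignancy_call_accuracy_against_truth(self, selection):
        _, _, truth, result = selection
        call = result.malignant_mask()
        accuracy = (call == truth["is_malignant"].to_numpy()).mean()
        assert accuracy >= 0.9

    def test_stored_pvalue_reproducible_from_stored_gene_set(self, selection, sim_bulk):
        *_, result = selection
        sel = result.selected
        es = ssgsea_score(sim_bulk, sel.gene_set)
        stat, p = separation_pvalue(es.to_numpy(), sim_bulk.labels.to_numpy())
        assert p == sel.p_value
        pd.testing.assert_series_equal(es, sel.es_scores, check_names=False)

    def test_pipeline_determinism(self, selection, sim_profile, sim_bulk):
        ordered, profile, _, result = selection
        rerun = select_k(
            ordered, profile.chrom_features.to_numpy(), sim_bulk, k_min=2, k_max=8, seed=11
        )
        assert rerun.selected_k == result.selected_k
        for k in result.per_k:
            assert np.array_equal(rerun.per_k[k].labels, result.per_k[k].labels)
            assert rerun.per_k[k].p_value == result.per_k[k].p_value

    def test_single_element_range_returned(self, sim_profile, sim_bulk):
        ordered, profile, _ = sim_profile
        result = select_k(
            ordered, profile.chrom_features.to_numpy(), sim_bulk, k_min=3, k_max=3, seed=1
        )
        assert result.selected_k == 3

    def test_degenerate_k_recorded_with_p_one(self, rng, sim_bulk):
        # features with no structure and reference cells mixed uniformly:
        # some K may degenerate but must stay in the table with P = 1
        X = rng.normal(0, 1e-6, size=(60, 4))
        adata = make_norm_adata(rng.random((60, 30)), is_reference=np.arange(60) % 2 == 0)
        try:
            result = select_k(adata, X, sim_bulk, k_min=2, k_max=4, seed=0)
        except ValueError as err:
            assert "no informative K" in str(err)
            return
        for r in result.per_k.values():
            if r.degenerate:
                assert r.p_value == 1.0

    def test_sklearn_estimator_surface(self, sim_profile, sim_bulk):
        ordered, profile, truth = sim_profile
        sel = KSelector(k_min=2, k_max=4, random_state=11)
        assert sel.get_params()["k_min"] == 2
        sel.set_params(k_max=3)
        sel.fit(
            profile.chrom_features.to_numpy(),
            normalized=ordered,
            is_reference=ordered.obs["is_reference"].to_numpy(),
            cohort=sim_bulk,
        )
        assert hasattr(sel, "selected_k_")
        assert sel.labels_.shape == (ordered.n_obs,)
        assert sel.malignant_mask_.dtype == bool
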