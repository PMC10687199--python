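import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from breedpanel import (
    DAPC,
    SimulationConfig,
    a_score_optimize,
    compare_panels,
    fit_dapc,
    fit_pca,
    simulate,
)

from conftest import make_table


@pytest.fixture(scope="module")
def strong_sim():
    return simulate(SimulationConfig(n_pops=3, n_per_pop=30, n_loci=60,
                                     fst_target=0.3, fis_target=0.0, seed=50))[0]


class TestPCA:
    def test_two_sample_single_locus(self):
        t = make_table([[0], [2]])
        model, scores = fit_pca(t)
        assert scores.shape == (2, 1)
        assert np.allclose(np.abs(scores[:, 0]), 1.0)
        assert model.var_fractions[0] == pytest.approx(1.0)

    def test_duplicated_column_doubles_leading_share(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=20)
        ind = rng.integers(0, 3, size=20)
        dup = make_table(np.column_stack([col, col]))
        indep = make_table(np.column_stack([col, ind]))
        m_dup, _ = fit_pca(dup)
        m_ind, _ = fit_pca(indep)
        assert m_dup.var_fractions[0] == pytest.approx(1.0)
        assert m_ind.var_fractions[0] < 1.0

    def test_reconstruction_identity(self, strong_sim):
        model, scores = fit_pca(strong_sim)
        X = strong_sim.dosages_float()
        X = np.where(np.isnan(X), model.means, X) - model.means
        assert np.allclose(scores @ model.loadings.T, X, atol=1e-10)

    def test_eigenvalues_non_increasing(self, strong_sim):
        model, _ = fit_pca(strong_sim)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues >= 0)

    def test_zero_variance_raises(self):
        t = make_table([[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pca(t)


class TestFitDAPC:
    def test_full_rank_equals_plain_lda(self, strong_sim):
        """With all PCs retained, DAPC assignments equal direct LDA."""
        model = DAPC(strong_sim)
        res = model.fit(n_pca=model.max_n_pca)
        ours = res.assign().assigned.to_numpy()
        X = strong_sim.dosages_float()
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        ref = LinearDiscriminantAnalysis().fit(X, strong_sim.population_labels)
        assert np.mean(ours == ref.predict(X)) == 1.0

    def test_axes_and_contribution_normalization(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=10)
        assert res.n_da == 2  # K - 1
        assert res.contributions.shape == (strong_sim.n_loci, 2)
        assert np.all(res.contributions >= 0)
        assert np.allclose(res.contributions.sum(axis=0), 1.0, atol=1e-12)

    def test_locus_permutation_permutes_contributions(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=10)
        perm = np.random.default_rng(1).permutation(strong_sim.n_loci)
        res_p = fit_dapc(strong_sim.subset(locus_idx=perm), n_pca=10)
        assert np.allclose(res_p.contributions, res.contributions[perm], atol=1e-8)

    def test_perfect_separation(self):
        d = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2)]).astype(np.int8)
        t = make_table(d, populations=["A"] * 10 + ["B"] * 10)
        res = fit_dapc(t, n_pca=1)
        rep = res.assign()
        assert rep.overall == 1.0
        assert res.n_da == 1

    def test_summary_mentions_retained_pcs(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=12)
        assert "retained PCs: 12" in res.summary()


class TestAssignment:
    def test_posteriors_sum_to_one(self, strong_sim):
        rep = fit_dapc(strong_sim, n_pca=10).assign()
        assert np.allclose(rep.posteriors.sum(axis=1), 1.0)
        assert np.all((rep.confusion.sum(axis=1) == 30).to_numpy())

    def test_sample_order_invariance(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=10)
        base = res.assign().assigned
        perm = np.random.default_rng(2).permutation(strong_sim.n_samples)
        rep_perm = res.assign(strong_sim.subset(sample_idx=perm))
        assert (rep_perm.assigned.to_numpy() == base.to_numpy()[perm]).all()

    def test_locus_mismatch_raises(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=5)
        with pytest.raises(ValueError, match="loci"):
            res.assign(strong_sim.subset(locus_idx=range(10)))

    def test_imperfect_band_at_study_conditions(self, default_table):
        res = fit_dapc(default_table, n_pca=30)
        rep = res.assign()
        assert 0.9 <= rep.overall <= 1.0


class TestAScore:
    def test_random_labels_give_near_zero_scores(self, strong_sim):
        rng = np.random.default_rng(3)
        labels = rng.permutation(strong_sim.population_labels)
        res = a_score_optimize(strong_sim, labels=labels,
                               candidate_grid=[2, 5, 10], n_sim=10, seed=4)
        assert np.all(np.abs(res.table["a_score"]) < 0.25)

    def test_permuted_reassignment_near_chance(self, default_table):
        # in-sample reassignment under permuted labels overfits upward as
        # n_pca/n grows; at the study size (n=300, 3 PCs) it sits near 1/K
        res = a_score_optimize(default_table, candidate_grid=[3], n_sim=20, seed=5)
        assert res.table.loc[0, "P_r"] == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_strong_structure_chooses_small_n_and_perfect_reassignment(self, strong_sim):
        res = a_score_optimize(strong_sim, n_sim=5, seed=6)
        best_row = res.table[res.table["n_pca"] == res.best_n_pca].iloc[0]
        assert best_row["P_t"] >= 0.98
        assert res.best_n_pca <= 10

    def test_deterministic_under_seed(self, strong_sim):
        a = a_score_optimize(strong_sim, n_sim=5, seed=7)
        b = a_score_optimize(strong_sim, n_sim=5, seed=7)
        assert a.best_n_pca == b.best_n_pca
        assert a.table.equals(b.table)

    def test_bad_grid_raises(self, strong_sim):
        with pytest.raises(ValueError):
            a_score_optimize(strong_sim, candidate_grid=[0, 5])
        with pytest.raises(ValueError):
            a_score_optimize(strong_sim, candidate_grid=[])


class TestPanelSelection:
    def test_threshold_zero_selects_all(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=10)
        panel = res.select_informative(threshold=0.0)
        assert len(panel) == strong_sim.n_loci

    def test_threshold_one_boundary(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=10)
        assert len(res.select_informative(threshold=1.0)) <= res.n_da

    def test_invalid_threshold_raises(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=10)
        with pytest.raises(ValueError):
            res.select_informative(threshold=1.5)

    def test_axis_policies(self, strong_sim):
        res = fit_dapc(strong_sim, n_pca=10)
        for policy in ("max", "axis1", "eigen-weighted"):
            panel = res.select_informative(threshold=0.01, axis_policy=policy)
            assert set(panel.locus_ids) <= set(strong_sim.locus_ids)

    def test_spiked_loci_enriched(self):
        """High-differentiation loci are over-represented in the panel."""
        hits = 0
        for seed in range(5):
            tn, _ = simulate(SimulationConfig(n_pops=3, n_per_pop=50, n_loci=90,
                                              fst_target=0.02, seed=seed))
            ts, _ = simulate(SimulationConfig(n_pops=3, n_per_pop=50, n_loci=10,
                                              fst_target=0.45, seed=100 + seed,
                                              anc_maf_range=(0.2, 0.5)))
            d = np.hstack([tn.dosages, ts.dosages])
            t = make_table(d, populations=[s.population for s in tn.samples])
            res = fit_dapc(t, n_pca=20)
            panel = res.select_informative(threshold=0.01)
            spiked = [l for l in panel.locus_ids if int(l[1:]) >= 90]
            frac_panel = len(spiked) / max(len(panel), 1)
            hits += frac_panel > 10 / 100  # enrichment beyond base rate
        assert hits >= 4


class TestComparePanels:
    def test_threshold_zero_identity(self, strong_sim):
        cmp = compare_panels(strong_sim, threshold=0.0, seed=8,
                             candidate_grid=[2, 5], n_sim=3)
        assert len(cmp.panel) == strong_sim.n_loci
        assert cmp.full.overall == cmp.reduced.overall
        assert cmp.full.per_population == cmp.reduced.per_population

    def test_deterministic(self, strong_sim):
        a = compare_panels(strong_sim, seed=9, candidate_grid=[2, 5], n_sim=3)
        b = compare_panels(strong_sim, seed=9, candidate_grid=[2, 5], n_sim=3)
        assert a.full.overall == b.full.overall
        assert a.panel.locus_ids == b.panel.locus_ids

    def test_strong_signal_both_perfect(self, strong_sim):
        cmp = compare_panels(strong_sim, threshold=0.01, seed=10,
                             candidate_grid=[2, 5], n_sim=3)
        assert cmp.full.overall == 1.0
        assert cmp.reduced.overall >= 0.9
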