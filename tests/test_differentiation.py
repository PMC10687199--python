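import numpy as np
import pytest

from breedpanel import (
    GenotypeTable,
    Locus,
    SimulationConfig,
    euclidean_pairwise,
    nei_gst_pairwise,
    outflank_scan,
    pairwise_fst,
    simulate,
    wc_components,
    wc_components_table,
)

from conftest import counts_table, make_table


# --- independent Weir–Cockerham oracle: direct scalar transcription --------

def oracle_wc(pop_counts):
    """a, b, c for one locus, coded independently from first principles."""
    r = len(pop_counts)
    n = [aa + ab + bb for aa, ab, bb in pop_counts]
    p = [(2 * bb + ab) / (2 * ni) for (aa, ab, bb), ni in zip(pop_counts, n)]
    h = [ab / ni for (aa, ab, bb), ni in zip(pop_counts, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def random_counts(rng, r=None):
    r = r or rng.integers(2, 5)
    out = []
    for _ in range(r):
        n = int(rng.integers(5, 80))
        aa = int(rng.integers(0, n + 1))
        ab = int(rng.integers(0, n - aa + 1))
        out.append((aa, ab, n - aa - ab))
    return out


class TestWCComponents:
    def test_worked_example(self):
        c = wc_components([(60, 30, 10), (10, 30, 60)])
        assert c.a == pytest.approx(0.12386, abs=5e-6)
        assert c.b == pytest.approx(0.03864, abs=5e-6)
        assert c.c == pytest.approx(0.15, abs=1e-12)
        assert c.theta == pytest.approx(0.39636, abs=5e-6)

    def test_fixed_difference_theta_one(self):
        c = wc_components([(100, 0, 0), (0, 0, 100)])
        assert c.theta == pytest.approx(1.0)

    def test_identical_populations_theta_nonpositive(self):
        c = wc_components([(60, 30, 10), (60, 30, 10)])
        assert c.theta <= 0.0
        a, b, cc = oracle_wc([(60, 30, 10), (60, 30, 10)])
        assert c.theta == pytest.approx(a / (a + b + cc))

    def test_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            counts = random_counts(rng)
            a, b, cc = oracle_wc(counts)
            if a + b + cc == 0:
                continue
            got = wc_components(counts)
            assert got.a == pytest.approx(a, abs=1e-12)
            assert got.b == pytest.approx(b, abs=1e-12)
            assert got.c == pytest.approx(cc, abs=1e-12)
            checked += 1

    def test_monomorphic_theta_flagged_nan(self):
        c = wc_components([(50, 0, 0), (30, 0, 0)])
        assert np.isnan(c.theta)
        assert c.a == c.b == c.c == 0.0

    def test_single_population_raises(self):
        with pytest.raises(ValueError):
            wc_components([(60, 30, 10)])


class TestPairwiseFst:
    def test_single_locus_consistency(self):
        t = counts_table([(60, 30, 10), (10, 30, 60)])
        mat = pairwise_fst(t)
        single = wc_components([(60, 30, 10), (10, 30, 60)])
        assert mat.iloc[0, 1] == pytest.approx(single.theta)

    def test_parameter_recovery(self):
        cfg = SimulationConfig(n_pops=2, n_per_pop=100, n_loci=1000,
                               fst_target=0.05, fis_target=0.0, seed=21)
        t, _ = simulate(cfg)
        assert pairwise_fst(t).iloc[0, 1] == pytest.approx(0.05, abs=0.01)

    def test_duplicated_population_near_zero(self):
        t, _ = simulate(SimulationConfig(n_pops=1, n_per_pop=100, n_loci=300,
                                         fst_target=0.04, seed=22))
        d = np.vstack([t.dosages, t.dosages[np.random.default_rng(0).permutation(100)]])
        pops = ["A"] * 100 + ["B"] * 100
        t2 = make_table(d, populations=pops)
        assert abs(pairwise_fst(t2).iloc[0, 1]) < 0.005

    def test_multilocus_between_per_locus_extremes(self, default_table):
        comp = wc_components_table(default_table)
        theta = comp["theta"].dropna()
        overall = pairwise_fst(default_table)
        # all-population multilocus value from the same components
        ok = np.isfinite(comp[["a", "b", "c"]]).all(axis=1)
        multi = comp.loc[ok, "a"].sum() / comp.loc[ok, ["a", "b", "c"]].sum().sum()
        assert theta.min() <= multi <= theta.max()
        assert np.allclose(overall.to_numpy(), overall.to_numpy().T)

    def test_symmetry_and_zero_diagonal(self, default_table):
        for fn in (pairwise_fst, nei_gst_pairwise, euclidean_pairwise):
            m = fn(default_table).to_numpy()
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0.0)


class TestNeiGst:
    def test_fixed_difference(self):
        t = counts_table([(0, 0, 50), (50, 0, 0)])  # p=1 vs p=0
        assert nei_gst_pairwise(t).iloc[0, 1] == pytest.approx(1.0)

    def test_closed_form_quarter(self):
        # pop1: p = (2*50+50)/200 = 0.75; pop2: p = 50/200 = 0.25
        # H_S = 0.375, H_T = 0.5 -> G_ST = 0.25
        t = counts_table([(0, 50, 50), (50, 50, 0)])
        assert nei_gst_pairwise(t).iloc[0, 1] == pytest.approx(0.25)

    def test_identical_frequencies_zero(self):
        t = counts_table([(60, 30, 10), (60, 30, 10)])
        assert nei_gst_pairwise(t).iloc[0, 1] == pytest.approx(0.0)

    def test_all_monomorphic_raises(self):
        t = counts_table([(50, 0, 0), (50, 0, 0)])
        with pytest.raises(ValueError, match="zero"):
            nei_gst_pairwise(t)


class TestEuclidean:
    def test_identical_zero(self):
        t = counts_table([(60, 30, 10), (60, 30, 10)])
        assert euclidean_pairwise(t).iloc[0, 1] == 0.0

    def test_uniform_delta_closed_form(self):
        # |dp| = 0.1 at each of 300 loci -> sqrt(300 * 0.01) = sqrt(3)
        n = 10
        d1 = np.tile([1] * 4 + [0] * 6, (300, 1)).T  # p = 0.2
        d2 = np.tile([1] * 6 + [0] * 4, (300, 1)).T  # p = 0.3
        t = make_table(np.vstack([d1, d2]), populations=["A"] * n + ["B"] * n)
        assert euclidean_pairwise(t).iloc[0, 1] == pytest.approx(np.sqrt(3.0))

    def test_single_locus(self):
        t = counts_table([(30, 20, 0), (10, 40, 0)])  # p = 0.2 vs 0.4
        assert euclidean_pairwise(t).iloc[0, 1] == pytest.approx(0.2)

    def test_scale_option(self):
        t = counts_table([(30, 20, 0), (10, 40, 0)])
        assert euclidean_pairwise(t, scale=100).iloc[0, 1] == pytest.approx(20.0)

    def test_rank_order_agreement_across_metrics(self):
        """Well-separated drift levels give the same distance ranking in
        theta, G_ST and Euclidean distance."""
        rng = np.random.default_rng(31)
        parts = []
        for F, seed in ((0.02, 1), (0.10, 2)):
            t, _ = simulate(SimulationConfig(n_pops=2, n_per_pop=100, n_loci=300,
                                             fst_target=F, fis_target=0.0, seed=seed))
            parts.append(t)
        close, far = parts
        d = np.vstack([close.dosages, far.dosages[close.dosages.shape[0] // 2:]])
        pops = (["A"] * 100 + ["B"] * 100) + ["C"] * 100
        t3 = make_table(d, populations=pops)
        fst = pairwise_fst(t3)
        gst = nei_gst_pairwise(t3)
        euc = euclidean_pairwise(t3)
        for m in (fst, gst, euc):
            assert m.loc["A", "B"] < m.loc["B", "C"]


class TestOutlierScan:
    def test_neutral_calibration(self):
        t, _ = simulate(SimulationConfig(n_pops=3, n_per_pop=100, n_loci=1000,
                                         fst_target=0.04, fis_target=0.0, seed=11))
        scan = outflank_scan(t)
        frac = scan.n_outliers / scan.table["included"].sum()
        assert scan.df_inferred > 0
        assert frac < 0.12  # right-tail flags stay near the nominal level
        assert scan.table.loc[scan.table["outlier"], "included"].all()

    def test_spiked_loci_flagged(self):
        tn, _ = simulate(SimulationConfig(n_pops=3, n_per_pop=100, n_loci=1000,
                                          fst_target=0.03, fis_target=0.0, seed=12))
        ts, _ = simulate(SimulationConfig(n_pops=3, n_per_pop=100, n_loci=5,
                                          fst_target=0.5, fis_target=0.0, seed=13,
                                          anc_maf_range=(0.2, 0.5)))
        loci = tn.loci + [Locus(f"spike{j}", "1", 10**6 + j, l.allele_ref, l.allele_alt)
                          for j, l in enumerate(ts.loci)]
        t = GenotypeTable(tn.samples, loci, np.hstack([tn.dosages, ts.dosages]))
        scan = outflank_scan(t)
        spiked = scan.table[scan.table["locus_id"].str.startswith("spike")]
        assert spiked["outlier"].sum() >= 4

    def test_too_few_loci_raises(self):
        t, _ = simulate(SimulationConfig(n_loci=10, seed=14))
        with pytest.raises(ValueError, match="too few"):
            outflank_scan(t)

    def test_degenerate_identical_theta_raises(self):
        # two copies of one locus pattern at every locus -> identical theta
        base, _ = simulate(SimulationConfig(n_loci=1, seed=15))
        d = np.tile(base.dosages, (1, 50))
        t = make_table(d, populations=[s.population for s in base.samples])
        with pytest.raises(ValueError, match="degenerate"):
            outflank_scan(t)
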