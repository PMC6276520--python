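"""Site signals, couplings, and Ising energies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from isingdmr import (EnergyEngine, combine_energies, compute_energy_table,
                      neighbor_coupling, paired_mean_pvalue,
                      pitman_morgan_pvalue, signal_from_pvalue, site_energy,
                      simulate_dataset, preset_config)
from isingdmr.energy import SIGNAL_ALPHA

from conftest import make_dataset


class TestPairedMeanPvalue:
    def test_matches_textbook_t_statistic(self):
        d = np.array([1.1, 0.9, 1.0, 1.2, 0.8])
        tumor = np.arange(5, dtype=float)
        normal = tumor - d
        n = len(d)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        expected = 2 * stats.t.sf(abs(t), df=n - 1)
        assert paired_mean_pvalue(tumor, normal) == pytest.approx(expected)
        # independent library route
        assert paired_mean_pvalue(tumor, normal) == pytest.approx(
            stats.ttest_rel(tumor, normal).pvalue)

    def test_identical_vectors_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert paired_mean_pvalue(x, x) == 1.0

    def test_constant_nonzero_difference_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert paired_mean_pvalue(x + 2.0, x) == 1.0

    def test_two_sided_symmetry_under_swap(self):
        rng = np.random.default_rng(3)
        t, n = rng.normal(size=8), rng.normal(size=8)
        assert paired_mean_pvalue(t, n) == pytest.approx(
            paired_mean_pvalue(n, t))

    def test_small_n_returns_one(self):
        assert paired_mean_pvalue([1.0, 2.0], [0.0, 1.0]) == 1.0


class TestPitmanMorgan:
    def test_matches_correlation_test_oracle(self):
        rng = np.random.default_rng(5)
        normal = rng.normal(size=30)
        tumor = 2.0 * rng.normal(size=30)
        expected = stats.pearsonr(tumor + normal, tumor - normal,
                                  alternative="greater").pvalue
        assert pitman_morgan_pvalue(tumor, normal) == pytest.approx(expected,
                                                                    rel=1e-9)

    def test_one_sided_antisymmetry(self):
        rng = np.random.default_rng(6)
        t, n = 1.5 * rng.normal(size=25), rng.normal(size=25)
        p = pitman_morgan_pvalue(t, n)
        assert pitman_morgan_pvalue(n, t) == pytest.approx(1.0 - p, abs=1e-9)

    def test_null_pvalues_uniform(self):
        # same-variance paired draws: p ~ Uniform(0,1) over replicates
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(400):
            t = rng.normal(size=500)
            n = rng.normal(size=500)
            ps.append(pitman_morgan_pvalue(t, n))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_inflated_variance(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            normal = rng.normal(size=100)
            tumor = 3.0 * normal + rng.normal(size=100)
            if pitman_morgan_pvalue(tumor, normal) < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_zero_variance_returns_one(self):
        x = np.ones(10)
        assert pitman_morgan_pvalue(x, x) == 1.0


class TestSignalFromPvalue:
    @pytest.mark.parametrize("p, expected", [
        (0.5, 0.0),
        (0.05, 0.0),
        (np.exp(-5.0), 5.0),
    ])
    def test_rule(self, p, expected):
        assert signal_from_pvalue(p) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            signal_from_pvalue(bad)

    def test_nonzero_signals_bounded_below(self):
        p = np.linspace(1e-12, 0.0499, 50)
        s = signal_from_pvalue(p)
        assert np.all(s >= -np.log(SIGNAL_ALPHA))

    def test_zero_p_is_floored_not_infinite(self):
        assert np.isfinite(signal_from_pvalue(0.0))


class TestNeighborCoupling:
    def test_identical_neighbor_rows_give_unit_coupling(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=12)
        values = np.vstack([row, row, rng.normal(size=12)])
        ds = make_dataset(n_sites=3, n_pairs=6, values=values)
        j_left, j_right = neighbor_coupling(ds)
        assert j_right[0] == pytest.approx(1.0)
        assert j_left[1] == pytest.approx(1.0)
        assert np.isnan(j_left[0]) and np.isnan(j_right[2])

    def test_independent_rows_have_small_coupling(self):
        ds = make_dataset(n_sites=20, n_pairs=1000, seed=4)
        _, j_right = neighbor_coupling(ds)
        assert np.nanmax(np.abs(j_right)) < 0.1

    def test_ar1_simulation_recovers_rho(self):
        # within-cluster adjacent correlation in normal samples ~ rho
        truth = simulate_dataset(preset_config(1, n_pairs=1000, n_sites=2000),
                                 seed=9)
        _, j_right = neighbor_coupling(truth.dataset)
        same_cluster = truth.cluster_ids[1:] == truth.cluster_ids[:-1]
        j_within = j_right[:-1][same_cluster]
        assert np.nanmean(j_within) == pytest.approx(0.7, abs=0.03)

    def test_zero_variance_site_gets_zero(self):
        values = np.vstack([np.ones(12), np.random.default_rng(1).normal(
            size=12)])
        ds = make_dataset(n_sites=2, n_pairs=6, values=values)
        _, j_right = neighbor_coupling(ds)
        assert j_right[0] == 0.0


class TestSiteEnergy:
    @pytest.mark.parametrize("args, expected", [
        ((0.0, 0.0, 0.0, 1.0, 1.0), 0.0),
        ((1.0, 1.0, 1.0, 1.0, 1.0), -4.0),
        ((2.0, 0.0, 1.0, np.nan, 0.5), -1.5),  # terminal site, left absent
    ])
    def test_hand_values(self, args, expected):
        assert site_energy(*args) == pytest.approx(expected)


class TestCombineEnergies:
    @pytest.mark.parametrize("em, ev, lam_e", [
        (-4.0, 0.0, (1.0, -4.0)),
        (0.0, 0.0, (0.5, 0.0)),
        (-2.0, -6.0, (0.25, -5.0)),
    ])
    def test_hand_values(self, em, ev, lam_e):
        lam, e = combine_energies(em, ev)
        assert (lam, e) == pytest.approx(lam_e)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=-50, max_value=0),
           st.floats(min_value=-50, max_value=0))
    def test_closed_form_identity(self, em, ev):
        lam, e = combine_energies(em, ev)
        if em + ev != 0:
            assert e == pytest.approx((em ** 2 + ev ** 2) / (em + ev))
            assert e == pytest.approx(lam * em + (1 - lam) * ev)
            assert 0.0 <= lam <= 1.0
        else:
            assert (lam, e) == (0.5, 0.0)
        assert e <= 0


def _scalar_energy_table(ds, signs=None):
    """Naive per-site composition of the scalar operations (oracle)."""
    tumor, normal = ds.to_m().paired_matrices()
    if signs is not None:
        flip = signs < 0
        tumor = tumor.copy()
        normal = normal.copy()
        tumor[:, flip], normal[:, flip] = normal[:, flip].copy(), \
            tumor[:, flip].copy()
    j_left, j_right = neighbor_coupling(ds)
    n_sites = ds.n_sites
    s_mean = np.array([signal_from_pvalue(
        paired_mean_pvalue(tumor[i], normal[i])) for i in range(n_sites)])
    s_var = np.array([signal_from_pvalue(
        pitman_morgan_pvalue(tumor[i], normal[i])) for i in range(n_sites)])
    rows = []
    for i in range(n_sites):
        sl_m = s_mean[i - 1] if i > 0 else 0.0
        sr_m = s_mean[i + 1] if i < n_sites - 1 else 0.0
        sl_v = s_var[i - 1] if i > 0 else 0.0
        sr_v = s_var[i + 1] if i < n_sites - 1 else 0.0
        em = site_energy(s_mean[i], sl_m, sr_m, j_left[i], j_right[i])
        ev = site_energy(s_var[i], sl_v, sr_v, j_left[i], j_right[i])
        _, e = combine_energies(em, ev)
        rows.append((em, ev, e))
    return np.array(rows)


class TestComputeEnergyTable:
    def test_identical_groups_give_zero_energy(self):
        ds = make_dataset(n_sites=6, n_pairs=5, seed=2)
        vals = ds.values.copy()
        tumor_cols = ds.samples.index[ds.samples["condition"] == "tumor"]
        normal_cols = ds.samples.index[ds.samples["condition"] == "normal"]
        vals[:, tumor_cols] = vals[:, normal_cols]
        ds_null = make_dataset(n_sites=6, n_pairs=5, values=vals)
        table = compute_energy_table(ds_null)
        assert np.all(table["e"] == 0.0)
        assert np.all(table["p_mean"] == 1.0)

    def test_matches_scalar_loop_oracle(self, random_dataset):
        table = compute_energy_table(random_dataset)
        oracle = _scalar_energy_table(random_dataset)
        np.testing.assert_allclose(table["e_mean"], oracle[:, 0], atol=1e-10)
        np.testing.assert_allclose(table["e_var"], oracle[:, 1], atol=1e-10)
        np.testing.assert_allclose(table["e"], oracle[:, 2], atol=1e-10)

    def test_shifted_site_depresses_neighborhood(self):
        # one strongly shifted site in correlated data: minimum energy there
        rng = np.random.default_rng(12)
        n_pairs = 40
        base = rng.normal(0, 0.3, size=(5, 2 * n_pairs))
        base += rng.normal(0, 0.5, size=(1, 2 * n_pairs))  # shared component
        base[2, :n_pairs] += 3.0  # tumor shift at the middle site
        ds = make_dataset(n_sites=5, n_pairs=n_pairs, values=base)
        table = compute_energy_table(ds)
        assert table["e"].idxmin() == 2
        assert table["e"].iloc[1] < 0 and table["e"].iloc[3] < 0

    def test_permuted_energies_match_scalar_relabeling(self, random_dataset):
        # engine with sign flips == scalar pipeline on swapped pairs, J fixed
        engine = EnergyEngine(random_dataset)
        rng = np.random.default_rng(13)
        signs = rng.integers(0, 2, size=engine.n_pairs) * 2.0 - 1.0
        e = engine.site_energies(signs[:, None])[:, 0]
        oracle = _scalar_energy_table(random_dataset, signs=signs)
        np.testing.assert_allclose(e, oracle[:, 2], atol=1e-10)

    def test_couplings_invariant_under_label_permutation(self, random_dataset):
        engine = EnergyEngine(random_dataset)
        j_before = [j.copy() for j in engine.couplings]
        engine.site_energies(-np.ones((engine.n_pairs, 1)))
        for a, b in zip(j_before, engine.couplings):
            np.testing.assert_array_equal(a, b)


class TestMonotonicity:
    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=0, max_value=10),
           st.floats(min_value=0, max_value=10),
           st.floats(min_value=0, max_value=10),
           st.floats(min_value=0, max_value=1),
           st.floats(min_value=0, max_value=1),
           st.floats(min_value=0, max_value=5))
    def test_energy_nonincreasing_in_signals(self, si, sl, sr, jl, jr, bump):
        base = site_energy(si, sl, sr, jl, jr)
        assert site_energy(si + bump, sl, sr, jl, jr) <= base + 1e-12
        assert site_energy(si, sl + bump, sr, jl, jr) <= base + 1e-12
        assert site_energy(si, sl, sr + bump, jl, jr) <= base + 1e-12
        assert base <= 0
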