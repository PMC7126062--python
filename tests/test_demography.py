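"""Expected-SFS engine, composite-likelihood fits, stairway trajectories."""

import numpy as np
import pytest

import larkline as lk
from larkline.demography import (
    DemographicModel,
    Epoch,
    branch_class_intensities,
    composite_loglik,
    expected_coalescent_times,
)


CONST = DemographicModel.constant()


class TestModel:
    def test_zero_duration_epoch_collapses(self):
        m = DemographicModel([Epoch(0.0, 5.0), Epoch(0.1, 2.0)])
        assert len(m.epochs) == 1 and m.epochs[0].nu == 2.0

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel([Epoch(0.1, -1.0)])
        with pytest.raises(ValueError):
            DemographicModel([Epoch(np.inf, 1.0)])

    def test_time_rescaling_round_trip(self, rng):
        m = DemographicModel([Epoch(0.05, 0.1), Epoch(0.2, 3.0)])
        t = rng.uniform(0, 2, size=50)
        np.testing.assert_allclose(m.real_from_scaled(m.scaled_from_real(t)), t)

    def test_model_file_round_trip(self, tmp_path):
        m = DemographicModel([Epoch(0.05, 0.1), Epoch(0.2, 3.0)])
        lk.write_model_file(m, tmp_path / "m.txt")
        back = lk.read_model_file(tmp_path / "m.txt")
        assert back.epochs == m.epochs


class TestExpectedSfs:
    @pytest.mark.parametrize("n", [4, 10, 20, 40, 52, 60])
    def test_constant_model_theta_over_i(self, n):
        # E[eta_i] = theta L / i, relative error < 1e-8 up to n = 60
        sfs = lk.expected_sfs(CONST, n, theta_site=1e-4, L=1e6)
        i = np.arange(1, n)
        np.testing.assert_allclose(sfs.counts[1:-1], 100.0 / i, rtol=1e-8)

    def test_constant_examples_n4(self):
        sfs = lk.expected_sfs(CONST, 4, theta_site=1e-4, L=1e6)
        np.testing.assert_allclose(sfs.counts[1:4], [100, 50, 100 / 3], rtol=1e-10)

    def test_n2_tmrca_closed_form(self):
        # n=2: E[eta_1] = theta L * E[TMRCA in 2N units]; constant case = theta L
        sfs = lk.expected_sfs(CONST, 2, theta_site=1e-4, L=1e6)
        assert np.isclose(sfs.counts[1], 100.0, rtol=1e-12)
        # a recent 10x expansion delays coalescence: E[T2] > 1
        m = DemographicModel([Epoch(0.5, 10.0)])
        assert expected_coalescent_times(m, 2)[0] > 1.0

    def test_total_length_conservation_constant(self):
        # sum_i i-weighted intensities equal theta/2 * E[total tree length]
        n = 12
        xi = branch_class_intensities(CONST, n)
        total = 2 * xi.sum()  # branch length units
        expected = 2 * np.sum(1.0 / np.arange(1, n))
        assert np.isclose(total, expected, rtol=1e-10)

    def test_matches_msprime_monte_carlo(self):
        # MC oracle on two piecewise models (scaled-down tree count; the
        # acceptance suite runs the full-size check)
        msprime = pytest.importorskip("msprime")
        rng = np.random.default_rng(2024)
        for eps in ([Epoch(0.05, 0.1)], [Epoch(0.02, 0.05), Epoch(0.3, 3.0)]):
            m = DemographicModel(eps)
            n = 20
            dem = msprime.Demography()
            dem.add_population(initial_size=eps[0].nu)
            t = 0.0
            for i, e in enumerate(eps):
                t += e.duration
                nxt = eps[i + 1].nu if i + 1 < len(eps) else 1.0
                dem.add_population_parameters_change(time=t, initial_size=nxt)
            reps = msprime.sim_ancestry(
                samples={0: n}, demography=dem, ploidy=1,
                num_replicates=30_000, random_seed=int(rng.integers(1, 2**31)),
            )
            acc = np.zeros(n - 1)
            acc2 = np.zeros(n - 1)
            cnt = 0
            for ts in reps:
                afs = ts.allele_frequency_spectrum(
                    mode="branch", polarised=True, span_normalise=False)[1:n]
                acc += afs
                acc2 += afs * afs
                cnt += 1
            mean = acc / cnt
            se = np.sqrt((acc2 / cnt - mean**2) / cnt)
            z = (mean - 2 * branch_class_intensities(m, n)) / se
            assert np.abs(z).max() < 3.5

    def test_eta0_budget_guard(self):
        with pytest.raises(ValueError):
            lk.expected_sfs(CONST, 10, theta_site=0.5, L=1000)

    def test_folded_output(self):
        un = lk.expected_sfs(CONST, 4, 1e-4, 1e6, folded=False)
        fo = lk.expected_sfs(CONST, 4, 1e-4, 1e6, folded=True)
        np.testing.assert_allclose(fo.counts, lk.fold(un).counts)

    def test_simulated_counts_deterministic_under_seed(self):
        a = lk.simulate_sfs_counts(CONST, 10, 0.001, 10000, seed=5)
        b = lk.simulate_sfs_counts(CONST, 10, 0.001, 10000, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestFitModel:
    def test_m0_shape_cl_is_multinomial_maximum(self):
        obs = lk.expected_sfs(CONST, 10, 0.001, 100_000, folded=True)
        fit = lk.fit_model(obs, 0)
        eta = obs.counts[1:]
        q = eta / eta.sum()
        assert np.isclose(fit.cl, np.sum(eta * np.log(q)), rtol=1e-10)

    def test_m1_on_constant_data_recovers_nu_near_one(self):
        obs = lk.expected_sfs(CONST, 10, 0.001, 1_000_000, folded=True)
        fit = lk.fit_model(obs, 1, restarts=10, seed=0)
        assert 0.9 <= fit.model.epochs[0].nu <= 1.1 or fit.cl <= \
            lk.fit_model(obs, 0).cl + 1e-6

    def test_nested_cl_ordering(self):
        m = DemographicModel([Epoch(0.1, 5.0)])
        obs = lk.simulate_sfs_counts(m, 12, 0.005, 200_000, seed=8, folded=True)
        cl0 = lk.fit_model(obs, 0).cl
        cl1 = lk.fit_model(obs, 1, restarts=8, seed=1).cl
        cl2 = lk.fit_model(obs, 2, restarts=8, seed=2).cl
        tol = 1e-4
        assert cl1 >= cl0 - tol
        assert cl2 >= cl1 - tol

    def test_empty_polymorphic_spectrum_rejected(self):
        from larkline.sfs import SiteFrequencySpectrum
        empty = SiteFrequencySpectrum(np.array([100.0, 0, 0, 0, 0]), 4)
        with pytest.raises(ValueError):
            lk.fit_model(empty, 1)

    def test_theta_profile_matches_observed_s(self):
        obs = lk.expected_sfs(CONST, 10, 0.002, 500_000, folded=True)
        fit = lk.fit_model(obs, 0)
        refit = lk.expected_sfs(fit.model, 10, fit.theta_hat, obs.n_sites)
        assert np.isclose(refit.counts[1:-1].sum(), obs.n_segregating, rtol=1e-8)


class TestCompareAndScan:
    def test_table_rows_and_ordering(self):
        m = DemographicModel([Epoch(0.1, 5.0)])
        obs = lk.simulate_sfs_counts(m, 12, 0.005, 300_000, seed=3, folded=True)
        table, fits = lk.compare_models(obs, restarts=4, seed=0, max_changes=1,
                                        include_fixed_contraction=False)
        assert list(table["model"]) == ["M0_constant", "M1_one_change"]
        assert table["cl"].iloc[1] >= table["cl"].iloc[0] - 1e-4

    def test_default_grid_endpoints(self):
        m = DemographicModel([Epoch(0.05, 0.2)])
        obs = lk.simulate_sfs_counts(m, 8, 0.005, 50_000, seed=4, folded=True)
        best, grid = lk.fixed_contraction_scan(obs, base_changes=0, restarts=2,
                                               seed=0)
        assert np.isclose(grid["nu_final"].min(), 0.001)
        assert np.isclose(grid["nu_final"].max(), 0.01)
        assert len(grid) == 10

    def test_grid_outside_unit_interval_rejected(self):
        obs = lk.expected_sfs(CONST, 8, 0.001, 50_000, folded=True)
        with pytest.raises(ValueError):
            lk.fixed_contraction_scan(obs, nu_final_grid=np.array([0.5, 1.5]))


class TestStairway:
    def test_default_breakpoint_options(self):
        import inspect
        sig = inspect.signature(lk.stairway_fit)
        assert sig.parameters["breakpoint_options"].default == (12, 25, 37, 50)
        assert sig.parameters["train_fraction"].default == 0.67
        assert sig.parameters["n_boot"].default == 200

    def test_constant_spectrum_gives_flat_trajectory(self):
        obs = lk.expected_sfs(CONST, 26, 0.005, 2_000_000, folded=True)
        traj = lk.stairway_fit(obs, n_boot=5, seed=1)
        ne = traj.steps["ne"].to_numpy()
        assert ne.max() / ne.min() < 1.5

    def test_expansion_sign_recovered(self):
        m = DemographicModel([Epoch(0.1, 5.0)])
        hits = 0
        for seed in range(10):
            obs = lk.simulate_sfs_counts(m, 26, 0.005, 2_000_000, seed=seed,
                                         folded=True)
            traj = lk.stairway_fit(obs, n_boot=2, seed=seed)
            s = traj.steps
            hits += s.iloc[0]["ne"] > s.iloc[-1]["ne"]
        assert hits >= 9

    def test_ci_brackets_point_estimate(self):
        obs = lk.simulate_sfs_counts(CONST, 16, 0.005, 500_000, seed=6,
                                     folded=True)
        traj = lk.stairway_fit(obs, n_boot=20, seed=2)
        s = traj.steps
        # percentile CIs from multinomial resampling should usually cover
        inside = ((s["ne_lo"] <= s["ne"] * 1.05) & (s["ne_hi"] >= s["ne"] * 0.95))
        assert inside.mean() > 0.8


class TestNaturalUnits:
    def test_scale_arithmetic(self):
        m = DemographicModel([Epoch(0.01, 0.5)])
        fit = lk.FitResult(m, "x", 2, 0.0, theta_hat=0.001, n_restarts=1,
                           converged=True, L_obs=1e6)
        table = lk.scale_to_natural_units(fit)
        n_anc = 0.001 / (4 * 4.6e-9)
        assert np.isclose(table.iloc[0]["N"], 0.5 * n_anc)
        assert np.isclose(table.iloc[-1]["N"], n_anc)
        # boundary: 0.01 * 2 * N_anc generations * 6.5 y
        assert np.isclose(table.iloc[0]["end_years"], 0.01 * 2 * n_anc * 6.5)

    def test_printed_conversion_examples(self):
        assert np.isclose(0.001 / (4 * 4.6e-9), 54347.826, rtol=1e-5)
        n_anc = 50_000
        gens = 0.01 * 2 * n_anc
        assert gens == 1000
        assert gens * 6.5 == 6500
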