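"""Monte Carlo transport kernel: sampling laws, boundaries, bookkeeping."""

import numpy as np
import pytest
from scipy.integrate import quad

import turbidslab as ts
from turbidslab.slab import C_UM_PS


class TestSamplingLaws:
    def test_free_path_inversion_point(self):
        assert ts.sample_free_path(13.0, np.exp(-1.0)) == pytest.approx(13.0)

    def test_free_path_mean(self):
        rng = np.random.default_rng(0)
        u = rng.random(1_000_000)
        draws = -25.0 * np.log(u)
        se = 25.0 / np.sqrt(len(u))      # exponential: sd = mean
        assert abs(draws.mean() - 25.0) < 5 * se

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.5])
    def test_free_path_domain(self, u):
        with pytest.raises(ValueError):
            ts.sample_free_path(10.0, u)

    @pytest.mark.parametrize("g", [0.0, 0.7])
    def test_scatter_first_moment_matches_phase_function(self, g):
        # independent oracle: first moment of the Henyey-Greenstein phase
        # function by numerical quadrature (equals g analytically)
        if g > 0:
            def pdf(mu):
                return 0.5 * (1 - g * g) / (1 + g * g - 2 * g * mu) ** 1.5
        else:
            def pdf(mu):
                return 0.5
        moment = quad(lambda mu: mu * pdf(mu), -1, 1)[0]
        assert moment == pytest.approx(g, abs=1e-9)

        rng = np.random.default_rng(7)
        n = 200_000
        incoming = np.array([0.0, 0.0, 1.0])
        cos = np.empty(n)
        for i in range(n):
            out = ts.sample_scatter_direction(g, rng.random(), rng.random(),
                                              incoming)
            cos[i] = out @ incoming
        var = quad(lambda mu: mu * mu * pdf(mu), -1, 1)[0] - moment**2
        assert abs(cos.mean() - moment) < 5 * np.sqrt(var / n)

    def test_scatter_output_is_unit_vector(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            out = ts.sample_scatter_direction(0.6, rng.random(), rng.random(),
                                              d)
            assert abs(np.linalg.norm(out) - 1.0) < 1e-9

    def test_scatter_domain(self):
        with pytest.raises(ValueError):
            ts.sample_scatter_direction(1.0, 0.5, 0.5,
                                        np.array([0.0, 0.0, 1.0]))


class TestFresnel:
    def test_matched_indices_pass_through(self):
        d = np.array([0.3, 0.4, np.sqrt(1 - 0.25)])
        kind, out = ts.fresnel_interaction(d, 1.52, 1.52, u=0.0)
        assert kind == "refracted"
        assert np.allclose(out, d)

    def test_normal_incidence_reflectance(self):
        # R = ((n1-n2)/(n1+n2))^2 ~ 0.0426 for 1 -> 1.52
        R = ((1.0 - 1.52) / (1.0 + 1.52)) ** 2
        d = np.array([0.0, 0.0, 1.0])
        kind_low, _ = ts.fresnel_interaction(d, 1.0, 1.52, u=R * 0.99)
        kind_high, _ = ts.fresnel_interaction(d, 1.0, 1.52, u=R * 1.01)
        assert (kind_low, kind_high) == ("reflected", "refracted")

    def test_total_internal_reflection(self):
        # beyond the critical angle for 1.52 -> 1 the packet always reflects
        sin_c = 1.0 / 1.52
        uz = np.sqrt(1 - min(sin_c * 1.05, 1.0) ** 2)
        d = np.array([np.sqrt(1 - uz**2), 0.0, uz])
        kind, out = ts.fresnel_interaction(d, 1.52, 1.0, u=0.999999)
        assert kind == "reflected"
        assert out[2] == pytest.approx(-d[2])


class TestTracePacket:
    def test_ballistic_limit(self):
        slab = ts.LayeredSlab.homogeneous(203.0, l_s=1e6 * 203.0, n=1.52,
                                          n_front=1.52, n_back=1.52)
        rec = ts.trace_packet(slab, seed=1)
        assert rec.side == "back"
        assert rec.weight == 1.0
        assert rec.exit_time == pytest.approx(203.0 * 1.52 / C_UM_PS,
                                              rel=1e-12)

    def test_conservative_medium_unit_weights(self):
        slab = ts.LayeredSlab.homogeneous(100.0, l_s=20.0, n=1.0)
        for i in range(100):
            rec = ts.trace_packet(slab, seed=5, packet_index=i)
            if rec.side in ("back", "front"):
                assert rec.weight == 1.0

    def test_transmission_decreases_with_thickness(self):
        thin = ts.LayeredSlab.homogeneous(100.0, l_s=10.0, n=1.0)
        thick = ts.LayeredSlab.homogeneous(300.0, l_s=10.0, n=1.0)
        binning = ts.BinningSpec(record_frames=False)
        T1 = ts.run_simulation(thin, 30_000, 8, binning).total_transmittance
        T2 = ts.run_simulation(thick, 30_000, 8, binning).total_transmittance
        assert T2 < T1


class TestRunSimulation:
    @pytest.mark.parametrize("slab", [
        ts.LayeredSlab.homogeneous(203.0, l_s=25.5, n=1.52),
        ts.LayeredSlab.homogeneous(203.0, l_s=24.1, mu_a=1 / 12000.0, n=1.52),
        ts.symmetric_five_layer((22.0, 60.0, 26.0), (11.0, 21.5, 3.5)),
        # strong absorption so Russian roulette fires
        ts.LayeredSlab.homogeneous(80.0, l_s=4.0, mu_a=5e-3, n=1.4),
    ], ids=["non-absorbing", "absorbing", "layered", "roulette"])
    def test_energy_balance_is_exact_bookkeeping(self, slab):
        res = ts.run_simulation(slab, 20_000, 11,
                                ts.BinningSpec(record_frames=False))
        assert res.energy_balance() == pytest.approx(1.0, abs=1e-10)
        assert np.all(res.T_hist >= 0) and np.all(res.R_hist >= 0)

    def test_no_absorption_means_zero_absorbed(self, homog_mc_result):
        assert homog_mc_result.absorbed_weight == 0.0

    def test_same_seed_bit_identical(self):
        slab = ts.LayeredSlab.homogeneous(100.0, l_s=15.0, n=1.3)
        b = ts.BinningSpec(record_frames=False)
        r1 = ts.run_simulation(slab, 50_000, 42, b)
        r2 = ts.run_simulation(slab, 50_000, 42, b)
        assert np.array_equal(r1.T_hist, r2.T_hist)
        assert np.array_equal(r1.R_hist, r2.R_hist)
        assert r1.absorbed_weight == r2.absorbed_weight

    def test_causality_no_exit_before_ballistic_time(self, homog_mc_result):
        res = homog_mc_result
        t_min = res.slab.ballistic_time
        early = res.t_edges[1:] <= t_min
        assert res.T_hist[early].sum() == 0.0

    def test_causality_transverse_bound(self):
        # no back-side exit can be displaced farther than free flight allows
        slab = ts.LayeredSlab.homogeneous(85.0, l_s=150.0, g=0.7, n=1.31)
        v = C_UM_PS / 1.31
        for i in range(500):
            rec = ts.trace_packet(slab, seed=13, packet_index=i)
            if rec.side == "back":
                rho_max = np.sqrt(max((v * rec.exit_time) ** 2 - 85.0**2, 0))
                assert np.hypot(*rec.exit_xy) <= rho_max + 1e-6

    def test_reciprocity_of_symmetric_stack(self, layered_result):
        rev = layered_result.slab.reversed()
        res2 = ts.run_simulation(rev, 200_000, 77,
                                 ts.BinningSpec(record_frames=False))
        T1 = layered_result.total_transmittance
        T2 = res2.total_transmittance
        se = np.sqrt(T1 * (1 - T1) / layered_result.n_packets
                     + T2 * (1 - T2) / res2.n_packets)
        assert abs(T1 - T2) < 5 * se

    def test_absorbed_fraction_homogeneous_da_coefficients(self):
        """MC with the DA-fit coefficients implies ~8% total absorption."""
        slab = ts.LayeredSlab.homogeneous(203.0, l_s=24.1, mu_a=1 / 12000.0,
                                          n=1.52)
        res = ts.run_simulation(slab, 300_000, 19,
                                ts.BinningSpec(record_frames=False))
        assert ts.absorbed_fraction(res) == pytest.approx(0.08, abs=0.015)

    def test_similarity_relation_in_thick_regime(self):
        """T(t) for (l_s=l_t(1-g), g) matches (l_t, 0) when L/l_t >= 8."""
        b = ts.BinningSpec(t_max=30.0, t_bin=0.5, record_frames=False)
        iso = ts.run_simulation(
            ts.LayeredSlab.homogeneous(203.0, l_s=25.0, n=1.52), 150_000, 3, b)
        aniso = ts.run_simulation(
            ts.LayeredSlab.homogeneous(203.0, l_s=25.0 * 0.4, g=0.6, n=1.52),
            150_000, 4, b)
        pk = iso.T_hist.argmax()
        sel = slice(pk, pk + 30)
        n1, n2 = iso.n_packets, aniso.n_packets
        err = np.sqrt(iso.T_hist[sel] / n1 + aniso.T_hist[sel] / n2)
        diff = np.abs(iso.T_hist[sel] - aniso.T_hist[sel])
        # agreement within 3 combined standard errors per bin, allowing the
        # expected ~1% of statistical outliers
        assert np.mean(diff <= 3 * err) > 0.95

    def test_tail_decay_time_matches_measured_value(self, homog_mc_result):
        """The l_t=25.5 um model reproduces the measured 6.01 ps decay."""
        from turbidslab.fits import mc_tail_decay
        tau = mc_tail_decay(homog_mc_result).params["tau"]
        assert tau == pytest.approx(6.01, rel=0.05)

    def test_tail_slope_stable_to_window_start(self, homog_mc_result):
        from turbidslab.fits import mc_tail_decay
        t1 = mc_tail_decay(homog_mc_result, start_factor=2.0).params["tau"]
        t2 = mc_tail_decay(homog_mc_result, start_factor=4.0).params["tau"]
        assert t2 == pytest.approx(t1, rel=0.02)

    def test_specular_entry_flag(self):
        slab = ts.LayeredSlab.homogeneous(100.0, l_s=20.0, n=1.52)
        b = ts.BinningSpec(record_frames=False)
        res = ts.run_simulation(slab, 10_000, 2, b,
                                include_specular_entry=True)
        R_spec = ((1 - 1.52) / (1 + 1.52)) ** 2
        assert res.R_hist[0] >= R_spec * 0.999
        assert res.energy_balance() == pytest.approx(1.0, abs=1e-10)

    def test_validation_errors(self):
        slab = ts.LayeredSlab.homogeneous(100.0, l_s=20.0)
        with pytest.raises(ValueError):
            ts.run_simulation(slab, 0, 1)
        with pytest.raises(ValueError):
            ts.BinningSpec(t_max=-1.0)

    def test_hdf5_round_trip(self, tmp_path):
        slab = ts.LayeredSlab.homogeneous(100.0, l_s=20.0, n=1.3)
        res = ts.run_simulation(slab, 5_000, 9, ts.BinningSpec())
        path = tmp_path / "run.h5"
        res.save(path)
        back = ts.SimulationResult.load(path)
        assert np.array_equal(back.T_hist, res.T_hist)
        assert np.array_equal(back.xyt_hist, res.xyt_hist)
        assert back.slab == res.slab
        assert back.seed == res.seed
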