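import math

import numpy as np
import pytest
from scipy import stats

from stickytube import (
    ChainParams,
    SimulationConfig,
    TubeSimulator,
    fene_factor,
    scaled_params,
    simulate_extension,
    stretch_distribution,
)
from stickytube.tube import (
    conformational_force,
    euler_step,
    init_equilibrium_state,
    sticker_bead_indices,
    update_stickers,
)


def exact_mean_stretch(Wi: float, Ze: int = 10, nb: int = 3) -> float:
    """Steady ensemble-mean stretch of the discretised harmonic chain.

    Independent oracle: solves the linear steady-state system
    0 = (kappa/zeta)*L R + boundary terms + eps*(R - mean(R)) directly.
    """
    n_bonds = Ze * (nb + 1)
    n_beads = n_bonds + 1
    kappa = 3.0 * n_bonds / Ze
    zeta = 3.0 * math.pi ** 2 * Ze / n_bonds
    dReq = Ze / n_bonds
    eps = Wi / Ze ** 2
    A = np.zeros((n_beads, n_beads))
    rhs = np.zeros(n_beads)
    for i in range(n_beads):
        if i > 0:
            A[i, i - 1] += kappa / zeta
            A[i, i] -= kappa / zeta
        else:
            rhs[i] = kappa * dReq / zeta
        if i < n_beads - 1:
            A[i, i + 1] += kappa / zeta
            A[i, i] -= kappa / zeta
        else:
            rhs[i] = -kappa * dReq / zeta
        A[i, :] -= eps / n_beads
        A[i, i] += eps
    R = np.linalg.solve(A, -rhs)
    return abs(R[-1] - R[0]) / Ze


class TestFeneFactor:
    def test_unit_stretch_normalisation(self):
        for lam_max in (2.0, 10.0, 23.6):
            assert fene_factor(1.0, lam_max) == pytest.approx(1.0, rel=1e-14)

    @pytest.mark.parametrize("lam, expected", [
        (0.0, 0.99880),
        (12.0, 1.23099),
    ])
    def test_reference_values(self, lam, expected):
        assert fene_factor(lam, 23.6) == pytest.approx(expected, abs=1e-5)

    def test_monotone_and_divergent(self):
        lam = np.linspace(1.0, 23.59, 200)
        ks = fene_factor(lam, 23.6)
        assert np.all(np.diff(ks) > 0)
        assert fene_factor(23.59, 23.6) > 100
        with pytest.raises(ValueError):
            fene_factor(23.6, 23.6)


class TestStickerPlacement:
    def test_interior_equally_spaced(self):
        idx = sticker_bead_indices(5, 41)
        assert idx.size == 5
        assert idx[0] >= 1 and idx[-1] <= 39
        assert np.all(np.diff(idx) > 0)
        spacings = np.diff(np.concatenate([[0], idx, [40]]))
        assert spacings.max() - spacings.min() <= 1

    def test_no_stickers(self):
        assert sticker_bead_indices(0, 41).size == 0


class TestInitialState:
    def test_equilibrium_statistics(self, silk_scaled):
        cfg = SimulationConfig(n_chains=4000, seed=3)
        state = init_equilibrium_state(silk_scaled, cfg)
        lam = state.stretch(silk_scaled.Ze)
        se_mean = lam.std(ddof=1) / math.sqrt(lam.size)
        assert abs(lam.mean() - 1.0) < 3 * se_mean
        cv = lam.std(ddof=1)  # mean is 1
        cv_target = 1.0 / math.sqrt(3 * silk_scaled.Ze)
        assert abs(cv - cv_target) < 3 * cv_target / math.sqrt(2 * lam.size)
        closed_frac = state.closed.mean()
        se_p = math.sqrt(0.9 * 0.1 / state.closed.size)
        assert abs(closed_frac - silk_scaled.p) < 3 * se_p


class TestConformationalForce:
    params = scaled_params(Zs=0)

    def test_zero_at_rest_spacing(self):
        cfg = SimulationConfig(n_chains=1, fene_on=True)
        sim = TubeSimulator(self.params, cfg)
        R = np.arange(sim.n_beads, dtype=float)[None, :] * sim.dR_eq
        np.testing.assert_allclose(sim.conf_force(R), 0.0, atol=1e-12)

    def test_displaced_bead_discrete_laplacian(self):
        cfg = SimulationConfig(n_chains=1, fene_on=False)
        sim = TubeSimulator(self.params, cfg)
        R = np.arange(sim.n_beads, dtype=float)[None, :] * sim.dR_eq
        d = 0.07
        j = 10
        R[0, j] += d
        F = sim.conf_force(R)
        assert F[0, j] == pytest.approx(-2 * sim.kappa * d, rel=1e-12)
        assert F[0, j - 1] == pytest.approx(sim.kappa * d, rel=1e-12)
        assert F[0, j + 1] == pytest.approx(sim.kappa * d, rel=1e-12)

    def test_energy_gradient_oracle(self, rng):
        """Harmonic force equals -grad of the discrete spring energy."""
        params = scaled_params(Zs=0, Ze=2, N=64)
        cfg = SimulationConfig(n_chains=1, n_beads_per_strand=1,
                               fene_on=False)
        sim = TubeSimulator(params, cfg)  # 4 bonds, 5 beads

        def energy(R):
            bonds = np.diff(R)
            return (0.5 * sim.kappa * np.sum(bonds ** 2)
                    + sim.kappa * sim.dR_eq * (R[0] - R[-1]))

        for _ in range(5):
            R = np.cumsum(rng.normal(sim.dR_eq, 0.1, size=sim.n_beads))
            F = sim.conf_force(R[None, :])[0]
            h = 1e-6
            for i in range(sim.n_beads):
                Rp, Rm = R.copy(), R.copy()
                Rp[i] += h
                Rm[i] -= h
                num = -(energy(Rp) - energy(Rm)) / (2 * h)
                assert F[i] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestEulerStep:
    def test_fluctuation_dissipation(self, rng):
        """Equilibrium bond variance -> kBT/kappa for two discretisations."""
        for nb in (1, 3):
            params = scaled_params(Zs=0, Ze=4, N=400)
            cfg = SimulationConfig(n_chains=400, n_beads_per_strand=nb,
                                   fene_on=False, seed=11)
            sim = TubeSimulator(params, cfg)
            state = sim.init_state(rng)
            for _ in range(3000):
                sim.step(state, rng)
            bonds = np.diff(state.R, axis=1) - sim.dR_eq
            var = bonds.var()
            # ~n_chains independent stiff modes: generous 3 SE band
            se = var * math.sqrt(2.0 / cfg.n_chains)
            assert abs(var - 1.0 / sim.kappa) < 3 * se

    def test_closed_stickers_do_not_move(self, rng):
        params = scaled_params()
        cfg = SimulationConfig(n_chains=8, rate=0.0, seed=5)
        sim = TubeSimulator(params, cfg)
        state = sim.init_state(rng)
        state.closed[:] = True
        frozen = state.R[:, sim.sticker_beads].copy()
        for _ in range(200):
            sim.step(state, rng, dt=1e-3)
            state.closed[:] = True  # re-pin any that opened
        np.testing.assert_array_equal(state.R[:, sim.sticker_beads], frozen)

    def test_flow_matches_exact_discrete_steady_state(self):
        """Mean stretch agrees with the linear-algebra steady state."""
        Wi = 0.5
        params = scaled_params(Zs=0)
        cfg = SimulationConfig(
            n_chains=256, rate=Wi / (params.tau_e * params.Ze ** 2),
            fene_on=False, t_burn=1500.0, t_sample=2500.0, seed=21)
        res = simulate_extension(params, cfg)
        target = exact_mean_stretch(Wi)
        blocks = np.array_split(res.mean_series, 8)
        bm = np.array([b.mean() for b in blocks])
        se = bm.std(ddof=1) / math.sqrt(bm.size)
        assert abs(res.distribution.mean() - target) < 4 * se + 0.01

    def test_dt_invariance_and_seed_invariance(self):
        """Stationary stretch distribution unchanged under dt/2, new seed."""
        params = scaled_params(Zs=0)
        base = SimulationConfig(
            n_chains=200, rate=0.25 / (params.tau_e * params.Ze ** 2),
            fene_on=False, t_burn=800.0, t_sample=1600.0,
            sample_every=200.0, dt=0.05, seed=31)
        ref = simulate_extension(params, base).distribution.samples
        half = simulate_extension(
            params, base.replace(dt=0.025, seed=32)).distribution.samples
        reseed = simulate_extension(
            params, base.replace(seed=77)).distribution.samples
        assert stats.ks_2samp(ref, half).pvalue > 0.01
        assert stats.ks_2samp(ref, reseed).pvalue > 0.01


class TestFunctionalSurface:
    def test_wrappers_delegate_to_simulator(self, rng):
        """Stateless wrappers agree with the TubeSimulator methods."""
        params = scaled_params()
        cfg = SimulationConfig(n_chains=4, seed=3, fene_on=True)
        sim = TubeSimulator(params, cfg)
        state = init_equilibrium_state(params, cfg)
        np.testing.assert_array_equal(state.sticker_beads, sim.sticker_beads)
        F = conformational_force(state, params, cfg)
        np.testing.assert_allclose(F, sim.conf_force(state.R), rtol=1e-14)
        t0 = state.t
        euler_step(state, params, cfg, rng, dt=0.01)
        assert state.t == pytest.approx(t0 + 0.01 / params.tau_e)
        assert np.all(np.isfinite(state.R))


class TestRouseScaling:
    def test_relaxation_time_scales_with_strands_squared(self):
        """End-to-end autocorrelation time ~ (number of strands)^2."""
        taus = {}
        for Ze, t_run in ((2, 500.0), (4, 2000.0)):
            params = scaled_params(Zs=0, Ze=Ze, N=100 * Ze)
            cfg = SimulationConfig(n_chains=512, n_beads_per_strand=1,
                                   fene_on=False, t_burn=10.0 * Ze ** 2,
                                   t_sample=t_run, sample_every=0.5 * Ze,
                                   dt=0.1, seed=41)
            res = simulate_extension(params, cfg)
            x = res.lam_series - res.lam_series.mean(axis=0, keepdims=True)
            nlag = 30
            acf = np.array([
                np.mean(x[:-k or None] * x[k:]) for k in range(nlag)])
            acf /= acf[0]
            # integrated autocorrelation time (sum truncated at first < 0.05)
            stop = np.argmax(acf < 0.05) or nlag
            dt_s = np.diff(res.t_series).mean()
            taus[Ze] = dt_s * (0.5 + acf[1:stop].sum())
        ratio = taus[4] / taus[2]
        assert ratio == pytest.approx(4.0, rel=0.3)


class TestStickerUpdate:
    def test_quiescent_occupancy(self, rng):
        """Force-free closed fraction relaxes to and stays at p."""
        params = scaled_params()
        cfg = SimulationConfig(n_chains=200, seed=9)
        sim = TubeSimulator(params, cfg)
        state = sim.init_state(rng)
        # uniform rest spacing -> exactly zero force at every sticker
        state.R = (np.arange(sim.n_beads, dtype=float)[None, :]
                   * sim.dR_eq).repeat(cfg.n_chains, axis=0)
        occ = []
        # dt*k_close = 0.009 keeps the discrete-update occupancy bias tiny
        for s in range(16000):
            update_stickers(state, params, cfg, rng, dt=0.1)
            if s >= 4000 and s % 2000 == 0:  # snapshots 2 tau_s0 apart
                occ.append(state.closed.mean())
        occ = np.asarray(occ)
        se = occ.std(ddof=1) / math.sqrt(occ.size)
        assert abs(occ.mean() - params.p) < 3 * max(se, 2e-3)

    def test_capped_opening_probability_under_extreme_force(self, rng):
        """ell*F >= E_act0 gives the closed-form capped opening probability."""
        params = scaled_params(ell=100.0)  # ell >> a: cap reached easily
        cfg = SimulationConfig(n_chains=6000, fene_on=False, seed=13)
        sim = TubeSimulator(params, cfg)
        state = sim.init_state(rng)
        # kink each sticker bead hard enough that ell_hat*|F| > E_act0
        state.R = (np.arange(sim.n_beads, dtype=float)[None, :]
                   * sim.dR_eq).repeat(cfg.n_chains, axis=0)
        state.R[:, sim.sticker_beads] += 0.5
        state.closed[:] = True
        F = sim.conf_force(state.R)
        assert np.all(sim.ell_hat * np.abs(F[:, sim.sticker_beads])
                      > params.E_act0)
        dt = 1e-3
        update_stickers(state, params, cfg, rng, dt=dt)
        frac_opened = 1.0 - state.closed.mean()
        k_cap = math.exp(params.E_act0) / (params.tau_s0 / params.tau_e)
        expected = -math.expm1(-k_cap * dt)
        se = math.sqrt(expected * (1 - expected) / state.closed.size)
        assert abs(frac_opened - expected) < 3 * se


class TestStretchBounds:
    def test_fene_keeps_bonds_below_lambda_max(self):
        """Strong sticky extensional flow never crosses lambda_max."""
        params = scaled_params(ell=0.1)
        tau_SR = params.tau_s0 * params.Zs ** 2
        cfg = SimulationConfig(n_chains=8, rate=5.0 / tau_SR,
                               t_burn=400.0, t_sample=400.0, seed=17)
        res = simulate_extension(params, cfg)
        assert np.all(res.distribution.samples < params.lambda_max)
        assert res.distribution.mean() > 1.5  # flow did stretch the chains


class TestStretchDistributionContainer:
    def test_histogram_normalised_and_reference_peak(self, rng):
        samples = rng.normal(2.0, 0.2, size=5000)
        density, edges, ref = stretch_distribution(samples, Ze=10, lam_ref=2.0)
        widths = np.diff(edges)
        assert np.sum(density * widths) == pytest.approx(1.0, rel=1e-9)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert centers[np.argmax(ref)] == pytest.approx(2.0, abs=0.1)

    def test_equilibrium_samples_pass_normality(self):
        cfg = SimulationConfig(n_chains=800, seed=23, fene_on=False,
                               t_burn=300.0, t_sample=300.0,
                               sample_every=300.0)
        params = scaled_params(Zs=0)
        res = simulate_extension(params, cfg)
        lam = res.lam_series[-1]
        assert stats.normaltest(lam).pvalue > 0.01

    def test_rejects_tiny_sample_histogram(self):
        from stickytube import StretchDistribution

        with pytest.raises(ValueError):
            StretchDistribution(np.ones(10), Ze=10).histogram()


class TestConfigValidation:
    def test_dt_above_stability_bound_rejected(self):
        params = scaled_params(Zs=0)
        with pytest.raises(ValueError, match="stability"):
            TubeSimulator(params, SimulationConfig(dt=1.0))

    def test_bad_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_chains=0)
        with pytest.raises(ValueError):
            SimulationConfig(rate=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(t_burn=-5.0)

    def test_from_weissenberg(self):
        params = scaled_params()
        cfg = SimulationConfig.from_weissenberg(params, Wi_bare=0.5)
        assert cfg.rate == pytest.approx(0.5 / (params.tau_e * params.Ze ** 2))
        cfg = SimulationConfig.from_weissenberg(params, Wi_sticky=2.0)
        assert cfg.rate == pytest.approx(
            2.0 / (params.tau_s0 * params.Zs ** 2))
        with pytest.raises(ValueError):
            SimulationConfig.from_weissenberg(params)
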