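"""Agent-based simulator: initialization, operator steps and their
closed-form/statistical oracles."""

import math

import numpy as np
import pytest

from stripesim.hybrid import (AgentPopulation, FieldGrid, HybridConfig,
                              density_histograms, init_population,
                              run_hybrid, step_division, step_fields,
                              step_internal, step_motion)
from stripesim.params import GrowthFieldParams, override


@pytest.fixture(scope="module")
def base_cfg():
    return HybridConfig(T_end=60.0, seed=12, n_init=500)


class TestInitPopulation:
    def test_inoculum_distribution(self, base_cfg, rng):
        means, sds = [], []
        for k in range(10):
            pop = init_population(base_cfg, np.random.default_rng(k))
            x = pop.view("x")
            means.append(x.mean())
            sds.append(x.std())
        assert abs(np.mean(means)) < 0.3
        assert 1.7 < np.mean(sds) < 2.3

    def test_equilibrium_internal_state(self, base_cfg, rng):
        pop = init_population(base_cfg, rng)
        assert (pop.view("z") == base_cfg.signaling.Zw).all()
        assert (pop.view("m") == base_cfg.signaling.m0).all()
        assert (pop.view("moving") == 1).all()
        assert set(np.unique(pop.view("heading"))) <= {-1.0, 1.0}

    def test_empty_population(self, rng):
        cfg = HybridConfig(n_init=0, T_end=60.0)
        pop = init_population(cfg, rng)
        assert pop.n == 0


class TestInternalStep:
    def test_z_fixed_below_threshold(self, base_cfg, rng):
        pop = init_population(base_cfg, rng)
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        step_internal(pop, fields, 0.2, base_cfg)
        assert (pop.view("z") == base_cfg.signaling.Zw).all()

    def test_z_exponential_decay_above_threshold(self, base_cfg, rng):
        # h >= h0 everywhere, n = 1: z(t) = Zw * exp(-r t) in the
        # continuum limit; the explicit scheme matches the product
        # (1 - r dt)^k, which approaches it to O(dt)
        pop = init_population(base_cfg, rng)
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        fields.h[:] = 0.9
        r = base_cfg.effective_growth.r
        dt, nsteps = 0.2, 5000
        for _ in range(nsteps):
            step_internal(pop, fields, dt, base_cfg)
        exact = base_cfg.signaling.Zw * math.exp(-r * nsteps * dt)
        assert pop.view("z")[0] == pytest.approx(exact, rel=1e-4)
        assert np.unique(pop.view("z")).size == 1

    def test_methylation_relaxes_toward_quasi_steady(self, base_cfg, rng,
                                                     tables):
        pop = init_population(base_cfg, rng)
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        ms = np.interp(base_cfg.signaling.Zw, tables.z, tables.mstar)
        dist = [abs(pop.view("m")[0] - ms)]
        for _ in range(100):
            step_internal(pop, fields, 0.2, base_cfg)
            dist.append(abs(pop.view("m")[0] - ms))
        assert all(b <= a + 1e-15 for a, b in zip(dist, dist[1:]))
        # converges to the tabulated equilibrium within the (m, z)
        # interpolation error of the lookup tables
        assert dist[-1] < 2e-4


class TestMotionStep:
    def test_zero_tumble_rate_is_ballistic_with_reflection(self, base_cfg):
        pop = AgentPopulation(1)
        pop.view("x")[:] = 24.9
        pop.view("heading")[:] = 1.0
        pop.view("moving")[:] = 1
        pop.view("lam")[:] = 0.0
        pop.view("mu")[:] = 1.0
        step_motion(pop, 10.0, base_cfg)   # travels 0.2 mm, reflects
        assert pop.view("x")[0] == pytest.approx(2 * 25.0 - (24.9 + 0.2))
        assert pop.view("heading")[0] == -1.0
        assert abs(pop.view("x")[0]) <= 25.0

    def test_stationary_moving_fraction(self, base_cfg):
        from stripesim import _kernels as K
        K.seed_rng(99)
        n = 10000
        pop = AgentPopulation(n)
        pop.view("moving")[:] = 1
        pop.view("heading")[:] = 1.0
        lam, mu = 0.6, 6.1
        pop.view("lam")[:] = lam
        pop.view("mu")[:] = mu
        step_motion(pop, 100.0, base_cfg)   # ~60 switching events deep
        frac = pop.view("moving").mean()
        expect = mu / (lam + mu)
        sigma = math.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 3.5 * sigma

    def test_positions_stay_inside_domain(self, base_cfg, rng):
        pop = init_population(base_cfg, rng)
        pop.view("lam")[:] = 0.5
        pop.view("mu")[:] = 5.0
        for _ in range(50):
            step_motion(pop, 1.0, base_cfg)
        assert (np.abs(pop.view("x")) <= base_cfg.L).all()


class TestDivisionStep:
    def test_exponential_growth_at_full_nutrient(self, rng):
        # no consumption: N(t) = N0 exp(r t) within branching-process noise
        g = override(GrowthFieldParams(), gamma_d=1e-300, alpha_d=0.0)
        cfg = HybridConfig(T_end=60.0, growth=g, n_init=2000)
        pop = init_population(cfg, rng)
        fields = FieldGrid.uniform(cfg.L, cfg.dx)
        T, dt = 3600.0, 60.0
        for _ in range(int(T / dt)):
            step_division(pop, fields, dt, cfg, rng)
        expect = 2000 * math.exp(g.r * T)
        sd = math.sqrt(2000 * math.exp(g.r * T) * (math.exp(g.r * T) - 1))
        assert abs(pop.n - expect) < 3.5 * sd

    def test_no_nutrient_no_divisions(self, base_cfg, rng):
        pop = init_population(base_cfg, rng)
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx, n0=1.0)
        fields.n[:] = 0.0
        for _ in range(100):
            k = step_division(pop, fields, 10.0, base_cfg, rng)
            assert k == 0
        assert pop.n == base_cfg.n_init

    def test_default_doubling_time_is_thirty_minutes(self, gp):
        assert math.log(2) / gp.r == pytest.approx(1800.0)
        assert gp.r == pytest.approx(3.85e-4, rel=1e-2)

    def test_daughters_inherit_state(self, base_cfg, rng):
        pop = init_population(base_cfg, rng)
        pop.view("z")[:] = 0.77
        pop.view("m")[:] = 0.9
        pop.view("lam")[:] = 1.0
        pop.view("mu")[:] = 1.0
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        n0 = pop.n
        while pop.n == n0:
            step_division(pop, fields, 50.0, base_cfg, rng)
        assert (pop.view("z")[n0:] == 0.77).all()
        assert (pop.view("m")[n0:] == 0.9).all()


class TestFieldStep:
    def test_uniform_decay_is_exact(self, base_cfg):
        # no cells: h decays as exp(-beta t) to machine precision
        pop = AgentPopulation(0)
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        fields.h[:] = 0.7
        beta = base_cfg.effective_growth.beta
        for _ in range(200):
            step_fields(fields, pop, 1.0, base_cfg)
        assert np.allclose(fields.h, 0.7 * math.exp(-beta * 200.0),
                           rtol=1e-10, atol=1e-12)

    def test_no_cells_nutrient_unchanged(self, base_cfg):
        pop = AgentPopulation(0)
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        for _ in range(50):
            step_fields(fields, pop, 1.0, base_cfg)
        assert np.allclose(fields.n, 1.0, rtol=1e-12)

    def test_single_source_steady_total(self, base_cfg):
        # one immobile cell: total AHL mass tends to alpha_d / beta
        pop = AgentPopulation(1)
        pop.view("x")[:] = 0.0
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        g = base_cfg.effective_growth
        for _ in range(8000):
            step_fields(fields, pop, 1.0, base_cfg)
        total = fields.h.sum() * fields.dx
        assert total == pytest.approx(g.alpha_d / g.beta, rel=0.01)


class TestRunHybrid:
    def test_same_seed_bit_identical(self):
        cfg = HybridConfig(T_end=600.0, seed=3, n_init=200,
                           snapshot_dt=300.0)
        a = run_hybrid(cfg)
        b = run_hybrid(cfg)
        for sa, sb in zip(a.snapshots, b.snapshots):
            for k in sa:
                assert np.array_equal(sa[k], sb[k])
        for (ha, na), (hb, nb) in zip(a.fields, b.fields):
            assert np.array_equal(ha, hb) and np.array_equal(na, nb)

    def test_different_realization_different_stream(self):
        cfg = HybridConfig(T_end=300.0, seed=3, n_init=200,
                           snapshot_dt=300.0)
        a = run_hybrid(cfg, realization=0)
        b = run_hybrid(cfg, realization=1)
        assert not np.array_equal(a.snapshots[-1]["x"],
                                  b.snapshots[-1]["x"])

    def test_cell_count_conserved_outside_division(self, base_cfg, rng):
        pop = init_population(base_cfg, rng)
        fields = FieldGrid.uniform(base_cfg.L, base_cfg.dx)
        step_internal(pop, fields, 0.2, base_cfg)
        n0 = pop.n
        step_motion(pop, 5.0, base_cfg)
        step_fields(fields, pop, 1.0, base_cfg)
        assert pop.n == n0


class TestHistograms:
    def test_counting_conservation(self, base_cfg, rng):
        pop = init_population(base_cfg, rng)
        snap = pop.snapshot()
        (xc, rho), (zc, rho_z) = density_histograms(
            snap, base_cfg.L, base_cfg.growth.rho_s)
        assert rho.sum() * 0.1 * base_cfg.growth.rho_s \
            == pytest.approx(pop.n)
        assert rho_z.sum() * 100.0 == pytest.approx(pop.n)

    def test_single_cell_single_bin(self, base_cfg):
        snap = {"x": np.array([0.03]), "z": np.array([1.23])}
        (xc, rho), _ = density_histograms(snap, base_cfg.L,
                                          base_cfg.growth.rho_s)
        assert (rho > 0).sum() == 1

    def test_uniform_positions_flat_histogram(self, base_cfg, rng):
        n = 10 ** 4
        snap = {"x": rng.uniform(-25, 25, n), "z": np.full(n, 1.23)}
        (xc, rho), _ = density_histograms(snap, 25.0, 1000.0)
        counts = rho * 0.1 * 1000.0
        p = 1 / len(counts)
        sigma = math.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) < 4.5 * sigma).all()


def test_agent_scaling_leaves_continuum_coefficients(base_cfg=None):
    cfg = HybridConfig(T_end=60.0, agent_scale=5.0)
    g = cfg.effective_growth
    g0 = cfg.growth
    assert g.alpha == pytest.approx(g0.alpha)
    assert g.gamma == pytest.approx(g0.gamma)
    assert cfg.n_init_effective == 100
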