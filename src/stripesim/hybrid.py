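"""Agent-based colony simulator (1D).

Cells are particles with position, heading, a run/tumble flag and the
internal state (z, m).  They move by a velocity-jump process whose
switching rates come from the flagellar-voting model, divide as a Poisson
process at rate r·n(x), and source the AHL field that in turn suppresses
their CheZ production.  AHL and nutrient live on a uniform grid and obey
reaction-diffusion equations with no-flux boundaries; per-cell delta
sources are deposited on the nearest node.

The update loop is operator-split: internal state and turning rates are
refreshed on ``dt_internal`` (the signaling variables drift on second-to-
minute scales), motion is simulated exactly (event-driven) within each
rate-refresh interval, and division and the fields advance on
``dt_field``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

from . import _kernels as K
from .motility import MotilityTables, motility_tables
from .params import GrowthFieldParams, MotilityParams, SignalingParams

__all__ = [
    "HybridConfig", "FieldGrid", "AgentPopulation", "HybridResult",
    "init_population", "step_internal", "step_motion", "step_division",
    "step_fields", "run_hybrid", "density_histograms",
]


@dataclass(frozen=True)
class HybridConfig:
    """Run settings for the agent-based model.

    ``agent_scale`` rescales the agent count for cheaper runs without
    changing the mean-field limit: n_init and rho_s are divided by it and
    the per-cell rates alpha_d, gamma_d multiplied by it, so the continuum
    coefficients alpha, gamma are untouched and only sampling noise grows.
    """

    L: float = 25.0             # domain is [-L, L] (mm)
    dx: float = 0.1             # field grid spacing (mm)
    n_init: int = 500
    sigma0: float = 2.0         # inoculum Gaussian width (mm)
    T_end: float = 36000.0      # s
    dt_internal: float = 0.2    # s (rate-refresh cadence; motion is exact)
    dt_field: float = 1.0       # s
    seed: int = 0
    n_realizations: int = 1
    snapshot_dt: float = 1800.0  # s
    mode: str = "mutant"        # "mutant" | "wildtype" | "cherb"
    m_fixed: float = 0.707      # frozen methylation for cherb mode
    agent_scale: float = 1.0
    signaling: SignalingParams = field(default_factory=SignalingParams)
    motility: MotilityParams = field(default_factory=MotilityParams)
    growth: GrowthFieldParams = field(default_factory=GrowthFieldParams)

    def __post_init__(self):
        if self.mode not in ("mutant", "wildtype", "cherb"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dt_internal > self.dt_field:
            raise ValueError("need dt_internal <= dt_field")
        if self.agent_scale <= 0:
            raise ValueError("agent_scale must be positive")

    @property
    def effective_growth(self) -> GrowthFieldParams:
        """Growth/field parameters with the agent rescaling applied."""
        g = self.growth
        a = self.agent_scale
        if a == 1.0:
            g2 = g
        else:
            g2 = replace(g, alpha_d=g.alpha_d * a, gamma_d=g.gamma_d * a,
                         rho_s=g.rho_s / a)
        if self.mode == "wildtype":
            g2 = replace(g2, alpha_d=0.0)
        return g2

    @property
    def n_init_effective(self) -> int:
        return int(round(self.n_init / self.agent_scale))


@dataclass
class FieldGrid:
    """AHL (h) and nutrient (n) on uniform nodes with spacing dx."""

    x: np.ndarray
    h: np.ndarray
    n: np.ndarray
    dx: float

    @classmethod
    def uniform(cls, L: float, dx: float, n0: float = 1.0) -> "FieldGrid":
        nx = int(round(2 * L / dx)) + 1
        x = np.linspace(-L, L, nx)
        return cls(x=x, h=np.zeros(nx), n=np.full(nx, float(n0)), dx=dx)


class AgentPopulation:
    """Growable arrays of cell state: x, heading (±1), moving flag,
    internal (z, m) and cached turning rates (lam, mu)."""

    _FIELDS = ("x", "heading", "moving", "z", "m", "lam", "mu")

    def __init__(self, n: int, capacity: int | None = None):
        cap = max(capacity or 4 * n, n, 16)
        self.n = n
        self.x = np.zeros(cap)
        self.heading = np.ones(cap)
        self.moving = np.ones(cap, dtype=np.uint8)
        self.z = np.zeros(cap)
        self.m = np.zeros(cap)
        self.lam = np.full(cap, np.nan)
        self.mu = np.full(cap, np.nan)

    def _grow(self, need: int):
        cap = self.x.shape[0]
        if need <= cap:
            return
        new = max(need, 2 * cap)
        for name in self._FIELDS:
            arr = getattr(self, name)
            big = np.zeros(new, dtype=arr.dtype)
            big[:cap] = arr
            setattr(self, name, big)

    def append(self, **arrays):
        k = len(arrays["x"])
        self._grow(self.n + k)
        for name in self._FIELDS:
            getattr(self, name)[self.n:self.n + k] = arrays[name]
        self.n += k

    def view(self, name):
        return getattr(self, name)[:self.n]

    def snapshot(self) -> dict:
        return {name: self.view(name).copy() for name in
                ("x", "heading", "moving", "z", "m")}


def init_population(config: HybridConfig, rng: np.random.Generator
                    ) -> AgentPopulation:
    """Seed the inoculum: positions ~ Normal(0, sigma0²) truncated to the
    domain, equilibrium internal state (z = Zw, m = m0), running cells
    with uniform random headings."""
    n = config.n_init_effective
    pop = AgentPopulation(n)
    if n:
        x = rng.normal(0.0, config.sigma0, size=n)
        bad = np.abs(x) > config.L
        while bad.any():
            x[bad] = rng.normal(0.0, config.sigma0, size=bad.sum())
            bad = np.abs(x) > config.L
        pop.view("x")[:] = x
        pop.view("heading")[:] = rng.choice([-1.0, 1.0], size=n)
        pop.view("moving")[:] = 1
        pop.view("z")[:] = config.signaling.Zw
        pop.view("m")[:] = (config.m_fixed if config.mode == "cherb"
                            else config.signaling.m0)
    return pop


def _tables_for(config: HybridConfig) -> MotilityTables:
    mutant_m = config.m_fixed if config.mode == "cherb" else None
    return motility_tables(config.signaling, config.motility,
                           mutant_m=mutant_m)


def step_internal(pop: AgentPopulation, fields: FieldGrid, dt: float,
                  config: HybridConfig,
                  tables: MotilityTables | None = None) -> None:
    """Advance every cell's (z, m) by one explicit step and refresh its
    turning rates from the lookup tables.

    The m-step is clamped at the quasi-steady m*(z) so it can approach
    but never overshoot equilibrium (the methylation dynamics are the
    stiffest internal timescale)."""
    tab = tables if tables is not None else _tables_for(config)
    sp, mp, gp = config.signaling, config.motility, config.effective_growth
    chooses = _chooses(mp.nf)
    freeze = config.mode == "cherb"
    inv_dzg = 1.0 / (tab.z[1] - tab.z[0])
    inv_dmg = 1.0 / (tab.m[1] - tab.m[0])
    key = (sp.Zw, freeze, config.m_fixed)
    cached = getattr(tab, "_fp_cache", None)
    if cached is None or cached[0] != key:
        fp = K.fixed_point_rates(sp.Zw, freeze, config.m_fixed,
                                 tab.mstar, tab.Yp_mz, tab.z[0], inv_dzg,
                                 tab.m[0], inv_dmg,
                                 mp.a1, mp.b1, mp.a2, mp.b2, mp.c,
                                 mp.nf, mp.w, chooses)
        tab._fp_cache = (key, fp)
    ms_w, lam_w, mu_w = tab._fp_cache[1]
    K.refresh_internal(
        pop.view("x"), pop.view("z"), pop.view("m"),
        pop.view("lam"), pop.view("mu"), fields.h, fields.n, pop.n,
        fields.x[0], 1.0 / fields.dx, dt, gp.r, sp.Zw, sp.h0,
        tab.mstar, tab.f_mz, tab.Yp_mz,
        tab.z[0], inv_dzg, tab.m[0], inv_dmg,
        mp.a1, mp.b1, mp.a2, mp.b2, mp.c, mp.nf, mp.w, chooses,
        freeze, ms_w, lam_w, mu_w)


def step_motion(pop: AgentPopulation, T: float, config: HybridConfig) -> None:
    """Exact velocity-jump motion over an interval T with the cached
    rates held frozen (event-driven exponential waiting times)."""
    if pop.n and not np.isfinite(pop.lam[0]):
        raise RuntimeError("turning rates not initialized; "
                           "call step_internal first")
    K.motion_steps(pop.view("x"), pop.view("heading"), pop.view("moving"),
                   pop.view("lam"), pop.view("mu"), pop.n,
                   T, config.motility.s0, -config.L, config.L)


def step_division(pop: AgentPopulation, fields: FieldGrid, dt: float,
                  config: HybridConfig, rng: np.random.Generator) -> int:
    """Each cell divides with probability 1 − exp(−r·n(x)·dt); the
    daughter sits at the mother's position, inherits (z, m) and the
    movement state, and gets a fresh uniform heading.  Returns the number
    of divisions."""
    if pop.n == 0:
        return 0
    gp = config.effective_growth
    idx = _node_index(pop.view("x"), fields)
    p = -np.expm1(-gp.r * fields.n[idx] * dt)
    divide = rng.random(pop.n) < p
    k = int(divide.sum())
    if k:
        pop.append(
            x=pop.view("x")[divide],
            heading=rng.choice([-1.0, 1.0], size=k),
            moving=pop.view("moving")[divide],
            z=pop.view("z")[divide],
            m=pop.view("m")[divide],
            lam=pop.view("lam")[divide],
            mu=pop.view("mu")[divide],
        )
    return k


def _node_index(x, fields: FieldGrid):
    idx = np.rint((x - fields.x[0]) / fields.dx).astype(np.intp)
    return np.clip(idx, 0, len(fields.x) - 1)


def _diffusion_banded(nx: int, a: float):
    """Banded matrix of the implicit no-flux diffusion solve
    (I − a·Lap) with mirrored ghost nodes."""
    ab = np.zeros((3, nx))
    ab[0, 1:] = -a
    ab[2, :-1] = -a
    ab[1, :] = 1.0 + 2.0 * a
    ab[1, 0] = 1.0 + a
    ab[1, -1] = 1.0 + a
    return ab


def step_fields(fields: FieldGrid, pop: AgentPopulation, dt: float,
                config: HybridConfig) -> None:
    """Advance AHL and nutrient by dt: implicit (unconditionally stable)
    diffusion, then exact exponential decay/consumption factors with
    nearest-node delta sources (alpha_d/dx per cell)."""
    gp = config.effective_growth
    nx = len(fields.x)
    if pop.n:
        counts = np.bincount(_node_index(pop.view("x"), fields),
                             minlength=nx).astype(float)
    else:
        counts = np.zeros(nx)
    ab_h = _diffusion_banded(nx, gp.Dh * dt / fields.dx ** 2)
    ab_n = _diffusion_banded(nx, gp.Dn * dt / fields.dx ** 2)
    h = solve_banded((1, 1), ab_h, fields.h)
    Eb = math.exp(-gp.beta * dt)
    fields.h[:] = h * Eb + gp.alpha_d * counts / fields.dx \
        * (1.0 - Eb) / gp.beta
    n = solve_banded((1, 1), ab_n, fields.n)
    fields.n[:] = n * np.exp(-gp.gamma_d * counts / fields.dx * dt)
    if (fields.h < 0).any() or (fields.n < 0).any():
        raise RuntimeError("negative field concentration (scheme unstable)")


def _chooses(nf: int) -> np.ndarray:
    return np.array([math.comb(nf, i) for i in range(nf + 1)], dtype=float)


@dataclass
class HybridResult:
    """Snapshot stream of one realization."""

    config: HybridConfig
    times: np.ndarray
    snapshots: list          # per time: dict of agent arrays
    fields: list             # per time: (h, n) copies
    x_nodes: np.ndarray
    seed: int


def run_hybrid(config: HybridConfig, realization: int = 0) -> HybridResult:
    """Run one realization of the hybrid model.

    Deterministic for a given (seed, realization): agent motion draws
    from a numba RNG and division/initialization from a NumPy generator,
    both seeded from them.
    """
    seed = (config.seed + 9973 * realization) % (2 ** 31)
    rng = np.random.default_rng(seed)
    K.seed_rng(seed)
    tab = _tables_for(config)
    pop = init_population(config, rng)
    fields = FieldGrid.uniform(config.L, config.dx,
                               config.effective_growth.n0)
    n_field_steps = int(round(config.T_end / config.dt_field))
    n_int = max(1, int(round(config.dt_field / config.dt_internal)))
    dt_int = config.dt_field / n_int
    snap_every = max(1, int(round(config.snapshot_dt / config.dt_field)))

    times, snaps, fsnaps = [], [], []

    def record(t):
        times.append(t)
        snaps.append(pop.snapshot())
        fsnaps.append((fields.h.copy(), fields.n.copy()))

    record(0.0)
    for k in range(1, n_field_steps + 1):
        for _ in range(n_int):
            step_internal(pop, fields, dt_int, config, tab)
            step_motion(pop, dt_int, config)
        step_division(pop, fields, config.dt_field, config, rng)
        step_fields(fields, pop, config.dt_field, config)
        if k % snap_every == 0 or k == n_field_steps:
            record(k * config.dt_field)
    return HybridResult(config=config, times=np.array(times),
                        snapshots=snaps, fields=fsnaps,
                        x_nodes=fields.x.copy(), seed=seed)


def density_histograms(snapshot: dict, L: float, rho_s: float,
                       dx_bin: float = 0.1, dz_bin: float = 0.03,
                       zmax: float | None = None, norm_cells: float = 100.0):
    """Normalized density histograms of an agent snapshot.

    Returns (x_centers, rho) with rho = counts/(rho_s·dx_bin), and
    (z_centers, rho_z) with rho_z = counts per (dx_bin × dz_bin) cell
    divided by ``norm_cells``.
    """
    x = snapshot["x"]
    z = snapshot["z"]
    nb = int(round(2 * L / dx_bin))
    xe = np.linspace(-L, L, nb + 1)
    counts, _ = np.histogram(x, bins=xe)
    rho = counts / (rho_s * dx_bin)
    zm = zmax if zmax is not None else (z.max() + dz_bin if len(z) else 1.3)
    nzb = max(1, int(math.ceil(zm / dz_bin)))
    ze = np.arange(nzb + 1) * dz_bin
    cz, _, _ = np.histogram2d(x, z, bins=[xe, ze])
    rho_z = cz / norm_cells
    xc = 0.5 * (xe[:-1] + xe[1:])
    zc = 0.5 * (ze[:-1] + ze[1:])
    return (xc, rho), (zc, rho_z)
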