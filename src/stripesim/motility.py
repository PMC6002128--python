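"""From intracellular state to whole-cell run/tumble switching.

Each of the ``nf`` flagellar motors switches CCW⇌CW at CheYp-dependent
rates; the cell runs when at least ``w`` motors rotate CCW.  The
whole-cell run→tumble rate λ and tumble→run rate μ follow from a voting
argument on the binomial distribution of CCW motors, and the effective
diffusion coefficient of the resulting velocity-jump process is
D(z) = s0²·μ0 / (d·λ0·(μ0+λ0)) with the rates evaluated at the
quasi-steady methylation level m*(z).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import binom

from .params import MotilityParams, SignalingParams
from .signaling import solve_phospho, steady_methylation

__all__ = [
    "TurningRates", "flagellum_rates", "p_ccw", "run_tumble_probs",
    "cell_rates", "run_fraction", "effective_diffusion",
    "cheRB_mutant_rates", "MotilityTables", "motility_tables",
]


@dataclass(frozen=True)
class TurningRates:
    """Whole-cell switching rates (s⁻¹): lam run→tumble, mu tumble→run."""

    lam: float
    mu: float

    def __post_init__(self):
        if not (self.lam > 0 and self.mu > 0 and
                np.isfinite(self.lam) and np.isfinite(self.mu)):
            raise ValueError(f"turning rates must be finite positive, "
                             f"got {self.lam}, {self.mu}")


def flagellum_rates(Yp, p: MotilityParams = MotilityParams()):
    """Single-motor switching rates (λ_f CCW→CW, μ_f CW→CCW) at CheYp.

    λ_f grows exponentially with Yp; μ_f is a stretched Gaussian in
    (b2 − Yp).  b2 < 0, so for physical Yp ≥ 0 no clamping is needed.
    """
    lam_f = p.a1 * np.exp(p.b1 * np.asarray(Yp, dtype=float))
    mu_f = p.a2 * np.exp(-((p.b2 - np.asarray(Yp, dtype=float)) ** 4) / p.c)
    return lam_f, mu_f


def p_ccw(i, lam_f, mu_f, p: MotilityParams = MotilityParams()):
    """Probability that exactly i of the nf independent motors are CCW."""
    i = np.asarray(i)
    if np.any((i < 0) | (i > p.nf)):
        raise IndexError(f"i must lie in [0, {p.nf}]")
    return binom.pmf(i, p.nf, mu_f / (lam_f + mu_f))


def run_tumble_probs(lam_f, mu_f, p: MotilityParams = MotilityParams()):
    """Stationary probabilities (P_run, P_tumble) of the voting model."""
    pr = binom.sf(p.w - 1, p.nf, mu_f / (lam_f + mu_f))
    return pr, 1.0 - pr


def _rates_from_Yp(Yp: float, p: MotilityParams) -> TurningRates:
    lam_f, mu_f = flagellum_rates(Yp, p)
    P_w = p_ccw(p.w, lam_f, mu_f, p)
    P_wm1 = p_ccw(p.w - 1, lam_f, mu_f, p)
    P_run, P_tum = run_tumble_probs(lam_f, mu_f, p)
    lam = p.w * lam_f * P_w / P_run
    mu = (p.nf - p.w + 1) * mu_f * P_wm1 / P_tum
    return TurningRates(lam=float(lam), mu=float(mu))


def cell_rates(m: float, z: float,
               sp: SignalingParams = SignalingParams(),
               mp: MotilityParams = MotilityParams()) -> TurningRates:
    """Whole-cell turning rates at internal state (m, z).

    λ = w·λ_f·P_CCW(w)/P_run (loss of one of exactly w CCW motors);
    μ = (nf−w+1)·μ_f·P_CCW(w−1)/P_tumble (gain of a CCW motor at w−1).
    """
    return _rates_from_Yp(solve_phospho(m, z, sp).Yp, mp)


def run_fraction(z: float,
                 sp: SignalingParams = SignalingParams(),
                 mp: MotilityParams = MotilityParams()) -> float:
    """Mean fraction of time spent running, μ/(λ+μ), at m = m*(z)."""
    r = cell_rates(steady_methylation(z, sp), z, sp, mp)
    return r.mu / (r.lam + r.mu)


def effective_diffusion(z: float, d: int = 1,
                        sp: SignalingParams = SignalingParams(),
                        mp: MotilityParams = MotilityParams()) -> float:
    """Effective diffusivity D(z) (mm²/s) of the velocity-jump process in
    d spatial dimensions, with rates at the quasi-steady methylation."""
    if d not in (1, 2, 3):
        raise ValueError("dimension d must be 1, 2 or 3")
    r = cell_rates(steady_methylation(z, sp), z, sp, mp)
    return mp.s0 ** 2 * r.mu / (d * r.lam * (r.mu + r.lam))


def cheRB_mutant_rates(m_fixed: float, z: float, d: int = 1,
                       sp: SignalingParams = SignalingParams(),
                       mp: MotilityParams = MotilityParams()):
    """Turning rates and diffusivity for the CheR⁻CheB⁻ double mutant.

    The adaptation branch is removed (R = Bt = Bp = 0) and the
    methylation level stays frozen at ``m_fixed``.  Returns
    (TurningRates, D).
    """
    Yp = solve_phospho(m_fixed, z, sp, mutant=True).Yp
    rates = _rates_from_Yp(Yp, mp)
    D = mp.s0 ** 2 * rates.mu / (d * rates.lam * (rates.mu + rates.lam))
    return rates, D


class MotilityTables:
    """Precomputed lookup tables over the internal state.

    The solvers never call the algebraic phospho solve in their inner
    loops; instead m*(z), Yp*(z), λ0(z), μ0(z), D(z) are tabulated on a
    uniform z-grid (spacing ``dz``) and, for the agent-based model,
    Yp(m, z) and dm/dt = f(m, z) on a uniform (m, z) grid, both linearly
    interpolated.  The tabulated curves are smooth, so linear
    interpolation at the default spacings is well inside solver error.
    """

    def __init__(self, sp: SignalingParams = SignalingParams(),
                 mp: MotilityParams = MotilityParams(),
                 zmax: float | None = None, dz: float = 0.005,
                 m_range: tuple = (0.0, 2.0), dm: float = 0.01,
                 mutant_m: float | None = None):
        self.sp, self.mp = sp, mp
        self.mutant_m = mutant_m
        self.zmax = float(zmax if zmax is not None else 1.05 * sp.Zw)
        nz = int(round(self.zmax / dz)) + 1
        self.z = np.linspace(0.0, self.zmax, nz)
        from .signaling import cheR_concentration, receptor_activity
        if mutant_m is None:
            self.mstar = np.array([steady_methylation(z, sp) for z in self.z])
            Yp0 = np.array([solve_phospho(m, z, sp).Yp
                            for m, z in zip(self.mstar, self.z)])
        else:
            self.mstar = np.full(nz, float(mutant_m))
            Yp0 = np.array([solve_phospho(mutant_m, z, sp, mutant=True).Yp
                            for z in self.z])
        self.Yp0 = Yp0
        rates = [_rates_from_Yp(y, mp) for y in Yp0]
        self.lam0 = np.array([r.lam for r in rates])
        self.mu0 = np.array([r.mu for r in rates])
        self._D1 = mp.s0 ** 2 * self.mu0 / (self.lam0 * (self.mu0 + self.lam0))
        # (m, z) tables for the agent-based model
        m_lo, m_hi = m_range
        nm = int(round((m_hi - m_lo) / dm)) + 1
        self.m = np.linspace(m_lo, m_hi, nm)
        Yp_mz = np.empty((nm, nz))
        f_mz = np.empty((nm, nz))
        A = receptor_activity(self.m, sp)
        R = cheR_concentration(self.m, sp)
        for i, m in enumerate(self.m):
            for j, z in enumerate(self.z):
                st = solve_phospho(m, z, sp, mutant=mutant_m is not None)
                Yp_mz[i, j] = st.Yp
                f_mz[i, j] = sp.kR * R[i] * (1.0 - A[i]) - sp.kBp * st.Bp * A[i]
        if mutant_m is not None:
            f_mz[:] = 0.0  # methylation frozen in the double mutant
        self.Yp_mz = Yp_mz
        self.f_mz = f_mz

    def D(self, z, d: int = 1):
        """Interpolated effective diffusivity D(z) in d dimensions."""
        return np.interp(z, self.z, self._D1) / d

    def rates0(self, z):
        """Interpolated quasi-steady whole-cell rates (λ0(z), μ0(z))."""
        return np.interp(z, self.z, self.lam0), np.interp(z, self.z, self.mu0)

    def to_dataframe(self) -> pd.DataFrame:
        """Single-cell summary table over the z-grid."""
        return pd.DataFrame({
            "z": self.z, "mstar": self.mstar, "Yp0": self.Yp0,
            "lambda0": self.lam0, "mu0": self.mu0,
            "run_fraction": self.mu0 / (self.lam0 + self.mu0),
            "D1": self._D1, "D2": self._D1 / 2.0,
        })


@lru_cache(maxsize=8)
def _cached_tables(sp: SignalingParams, mp: MotilityParams,
                   zmax, mutant_m) -> MotilityTables:
    return MotilityTables(sp, mp, zmax=zmax, mutant_m=mutant_m)


def motility_tables(sp: SignalingParams = SignalingParams(),
                    mp: MotilityParams = MotilityParams(),
                    zmax: float | None = None,
                    mutant_m: float | None = None) -> MotilityTables:
    """Cached accessor for :class:`MotilityTables` (building them costs a
    few seconds of root solves, so they are shared per parameter set)."""
    return _cached_tables(sp, mp, zmax, mutant_m)
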