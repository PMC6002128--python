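"""Intracellular chemotaxis signaling.

The internal state of a cell is the pair (z, m): total CheZ concentration
and mean receptor methylation level.  Total CheZ is produced at a rate
tied to cell growth and shut off by quorum sensing when extracellular AHL
exceeds the threshold h0; methylation adapts through the CheR/CheB cycle.
The fast phospho-proteins (receptor-CheA complexes Tp, CheYp, CheBp) are
in quasi-steady state and obey an algebraic system solved here by a
bracketed scalar root search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import SignalingParams

__all__ = [
    "InternalState", "PhosphoState", "receptor_activity",
    "cheR_concentration", "solve_phospho", "methylation_rhs", "chez_rhs",
    "steady_methylation", "steady_Yp",
]


@dataclass(frozen=True)
class InternalState:
    """Slow internal state of one cell: total CheZ z (μM) and mean
    receptor methylation m (dimensionless)."""

    z: float
    m: float

    def __post_init__(self):
        if not (self.z >= 0 and math.isfinite(self.z)
                and math.isfinite(self.m)):
            raise ValueError(f"invalid internal state (z={self.z}, "
                             f"m={self.m})")


@dataclass(frozen=True)
class PhosphoState:
    """Quasi-steady phospho-protein concentrations (μM).

    Tp: receptor-associated CheA-P; Yp: CheY-P; Bp: CheB-P;
    Y, Z, B: the corresponding free unphosphorylated concentrations.
    """

    Tp: float
    Yp: float
    Bp: float
    Y: float
    Z: float
    B: float

    def residuals(self, m: float, z: float,
                  p: SignalingParams = SignalingParams()) -> tuple:
        """Residuals of the three quasi-steady-state balance equations."""
        A = receptor_activity(m, p)
        r1 = p.kA * (p.Tt * A - self.Tp) - p.kY * self.Y * self.Tp \
            - p.kB * self.B * self.Tp
        r2 = p.kY * self.Y * self.Tp - p.muY * self.Yp \
            - p.kZ * self.Z * self.Yp
        r3 = p.kB * self.B * self.Tp - p.muB * self.Bp
        return (r1, r2, r3)


def receptor_activity(m, p: SignalingParams = SignalingParams()):
    """Mean receptor (kinase) activity A(m) ∈ (0, 1).

    A logistic function of the methylation level with a sharp transition
    at the reference level m0; steepness Nr·alpha0.
    """
    return 1.0 / (1.0 + np.exp(p.Nr * p.alpha0 * (p.m0 - m)))


def cheR_concentration(m, p: SignalingParams = SignalingParams()):
    """Free CheR concentration (μM), reduced by receptor sequestration.

    Inactive receptors bind CheR, so R rises toward Rt as activity
    increases with m.
    """
    A = receptor_activity(m, p)
    return p.Rt / (1.0 + p.KR * p.Tt * (1.0 - A))


def _phospho_residual(Yp: float, A: float, z: float, Bt: float,
                      p: SignalingParams) -> float:
    """CheA balance residual as a function of Yp alone.

    Given Yp, free CheZ follows from CheZ–CheYp binding, Tp from the
    CheYp phosphotransfer balance plus CheY conservation (closed form),
    and B/Bp from CheB conservation plus its balance.  Past the pole of
    the Tp expression (unphysically large Yp) the residual is clamped to
    a large negative value so a bracketed search stays on the physical
    branch.
    """
    Z = z / (1.0 + p.KZ * Yp)
    S = (p.muY + p.kZ * Z) * Yp / p.kY          # = Y * Tp
    Ybar = p.Yt - (1.0 + p.KZ * Z) * Yp          # = Y * (1 + KY*Tp)
    den = Ybar - S * p.KY
    if den <= 0.0:
        return -1e9 * p.kA * p.Tt
    Tp = S / den
    if Tp < 0.0:
        return -1e9 * p.kA * p.Tt
    B = Bt / (1.0 + p.KB * Tp + (1.0 + p.KBp * p.Tt * A) * p.kB * Tp / p.muB)
    Y = Ybar / (1.0 + p.KY * Tp)
    return p.kA * (p.Tt * A - Tp) - p.kY * Y * Tp - p.kB * B * Tp


def solve_phospho(m: float, z: float,
                  p: SignalingParams = SignalingParams(),
                  mutant: bool = False) -> PhosphoState:
    """Solve the quasi-steady phospho-protein system at internal state (m, z).

    Reduces the three balance equations to a scalar root problem in Yp on
    [0, Yt], solved by Brent's method; this guarantees the unique
    nonnegative physical root.  With ``mutant=True`` (CheR⁻CheB⁻ double
    knockout) the CheB branch is removed (Bt = Bp = 0).

    Raises
    ------
    RuntimeError
        If no sign change brackets a nonnegative solution (parameter
        pathology).
    """
    if z < 0:
        raise ValueError("z must be >= 0")
    A = float(receptor_activity(m, p))
    Bt = 0.0 if mutant else p.Bt
    f = lambda Yp: _phospho_residual(Yp, A, z, Bt, p)
    lo, hi = 1e-14, p.Yt * (1.0 - 1e-12)
    flo = f(lo)
    if flo < 0.0:
        # kinase essentially off: Yp -> 0
        Yp = 0.0
    else:
        try:
            Yp = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        except ValueError as err:  # pragma: no cover - parameter pathology
            raise RuntimeError(
                f"phospho root not bracketed at (m={m}, z={z})") from err
    Z = z / (1.0 + p.KZ * Yp)
    S = (p.muY + p.kZ * Z) * Yp / p.kY
    Ybar = p.Yt - (1.0 + p.KZ * Z) * Yp
    Tp = 0.0 if Yp == 0.0 else S / (Ybar - S * p.KY)
    B = Bt / (1.0 + p.KB * Tp + (1.0 + p.KBp * p.Tt * A) * p.kB * Tp / p.muB)
    Bp = p.kB * B * Tp / p.muB
    Y = Ybar / (1.0 + p.KY * Tp)
    state = PhosphoState(Tp=Tp, Yp=Yp, Bp=Bp, Y=Y, Z=Z, B=B)
    if min(Tp, Yp, Bp, Y, Z, B) < -1e-12:
        raise RuntimeError(f"nonphysical phospho root at (m={m}, z={z})")
    res = state.residuals(m, z, p)
    tol = 1e-10 * p.kA * p.Tt
    if max(abs(r) for r in res) > tol:
        raise RuntimeError(
            f"phospho residuals {res} exceed tolerance at (m={m}, z={z})")
    return state


def methylation_rhs(m: float, z: float,
                    p: SignalingParams = SignalingParams()) -> float:
    """dm/dt: CheR-mediated methylation minus CheBp-mediated demethylation."""
    A = float(receptor_activity(m, p))
    R = float(cheR_concentration(m, p))
    Bp = solve_phospho(m, z, p).Bp
    return p.kR * R * (1.0 - A) - p.kBp * Bp * A


def chez_rhs(z, h, kV, p: SignalingParams = SignalingParams(),
             smooth_eps: float | None = None):
    """dz/dt for total CheZ: production toward Zw below the AHL threshold,
    pure dilution above it (the h = h0 boundary suppresses).

    ``smooth_eps`` optionally replaces the hard switch by a logistic blend
    of width ``smooth_eps`` in h (a numerical convenience; the biological
    switch is sharp and the default is the hard switch).
    """
    if smooth_eps is None:
        on = np.where(np.asarray(h) >= p.h0, 1.0, 0.0)
    else:
        on = 1.0 / (1.0 + np.exp(-(np.asarray(h) - p.h0) / smooth_eps))
    val = (1.0 - on) * (kV * (p.Zw - z)) + on * (-kV * z)
    return val if np.ndim(val) else float(val)


def steady_methylation(z: float, p: SignalingParams = SignalingParams(),
                       bracket: tuple = (0.0, 3.0)) -> float:
    """Quasi-steady methylation level m*(z) with dm/dt = 0.

    Bracketed root search on the default interval [0, 3]; the bracket is
    widened once (×2 around its midpoint) before giving up.
    """
    f = lambda m: methylation_rhs(m, z, p)
    lo, hi = bracket
    try:
        return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    except ValueError:
        mid, half = 0.5 * (lo + hi), (hi - lo)
        lo2, hi2 = max(mid - half, -2.0), mid + half
        try:
            return brentq(f, lo2, hi2, xtol=1e-14, rtol=8.9e-16)
        except ValueError as err:
            raise RuntimeError(
                f"no steady methylation in [{lo2}, {hi2}] at z={z}") from err


def steady_Yp(z: float, p: SignalingParams = SignalingParams()) -> float:
    """Stationary CheYp concentration Yp*(z) at m = m*(z)."""
    return solve_phospho(steady_methylation(z, p), z, p).Yp
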