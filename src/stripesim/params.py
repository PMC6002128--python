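"""Parameter bundles for the signaling, motility and growth/field layers.

All defaults are the baseline values for the engineered stripe-forming
*E. coli* strain: intracellular chemotaxis-pathway rate constants, the
flagellar-motor switching coefficients, and the colony-scale growth and
AHL/nutrient reaction-diffusion constants.  Units follow the conventions
used throughout the package: concentrations in μM, lengths in mm, times
in seconds; AHL and nutrient are nondimensional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace


def _positive(obj, names):
    for name in names:
        if not getattr(obj, name) > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0")


@dataclass(frozen=True)
class SignalingParams:
    """Rate constants, association constants and protein totals of the
    intracellular chemotaxis pathway, plus the quorum-sensing threshold.

    Rates (s⁻¹ unless noted): kR methylation, kBp demethylation,
    kA autophosphorylation, kY/kB/kZ phosphotransfer and dephosphorylation
    (μM⁻¹s⁻¹), muY/muB phosphatase-independent decay.  K* are association
    constants (μM⁻¹); Bt, Rt, Tt, Yt total protein concentrations (μM);
    Zw the wild-type total-CheZ steady state (μM); h0 the nondimensional
    AHL threshold above which *cheZ* expression is shut off.  m0, alpha0
    and Nr set the receptor free-energy dependence on methylation.
    """

    kR: float = 3.82e-2
    kBp: float = 3.25
    kA: float = 100.0
    kY: float = 130.0
    kB: float = 7.5
    kZ: float = 8.45
    muY: float = 0.1
    muB: float = 1.0
    KB: float = 0.25
    KBp: float = 6.5
    KR: float = 0.15
    KY: float = 0.65
    KZ: float = 1.0
    Bt: float = 2.0
    Rt: float = 0.3
    Tt: float = 5.0 / 3.0
    Yt: float = 18.0
    Zw: float = 1.23
    h0: float = 0.25
    m0: float = 1.0
    alpha0: float = 1.7
    Nr: int = 6

    def __post_init__(self):
        _positive(self, ["kR", "kBp", "kA", "kY", "kB", "kZ", "muY", "muB",
                         "KB", "KBp", "KR", "KY", "KZ",
                         "Bt", "Rt", "Tt", "Yt", "Zw", "alpha0"])
        if not 0.0 < self.h0 < 1.0:
            raise ValueError("h0 must lie in (0, 1)")
        if self.Nr < 1:
            raise ValueError("Nr must be a positive integer")


@dataclass(frozen=True)
class MotilityParams:
    """Cell speed and the single-flagellum switching-rate coefficients.

    lambda_f = a1·exp(b1·Yp) is the CCW→CW rate and
    mu_f = a2·exp(−(b2−Yp)⁴/c) the CW→CCW rate of one motor as a function
    of CheYp (μM).  A cell runs when at least ``w`` of its ``nf`` flagella
    rotate CCW.
    """

    s0: float = 0.02         # mm/s
    a1: float = 0.0174001    # s^-1
    b1: float = 1.32887      # uM^-1
    a2: float = 12.0809      # s^-1
    b2: float = -5.83762     # uM
    c: float = 2892.12
    nf: int = 8
    w: int = 6

    def __post_init__(self):
        _positive(self, ["s0", "a1", "b1", "a2", "c"])
        if not 1 <= self.w <= self.nf:
            raise ValueError("need 1 <= w <= nf")


@dataclass(frozen=True)
class GrowthFieldParams:
    """Cell growth and AHL/nutrient reaction-diffusion constants.

    The maximum division rate r is derived from the doubling time at full
    nutrient, r = ln2 / doubling_time.  alpha_d and gamma_d are the
    per-cell AHL production and nutrient consumption rates; the continuum
    source coefficients are alpha = alpha_d·rho_s and gamma = gamma_d·rho_s
    with rho_s the cell-density scale (cells/mm in 1D).
    """

    doubling_time_min: float = 30.0
    Dh: float = 5e-4         # mm^2/s
    Dn: float = 7.7e-4       # mm^2/s
    alpha_d: float = 1e-6    # s^-1 per cell
    beta: float = 1e-3       # s^-1
    gamma_d: float = 1.155e-6  # s^-1 per cell
    rho_s: float = 1000.0    # cells/mm
    n0: float = 1.0

    def __post_init__(self):
        _positive(self, ["doubling_time_min", "Dh", "Dn", "beta",
                         "gamma_d", "rho_s", "n0"])
        if self.alpha_d < 0:
            raise ValueError("alpha_d must be >= 0")

    @property
    def r(self) -> float:
        """Maximum growth rate (s⁻¹), ln2 over the doubling time."""
        return math.log(2.0) / (self.doubling_time_min * 60.0)

    @property
    def alpha(self) -> float:
        """Continuum AHL production coefficient alpha_d·rho_s (s⁻¹)."""
        return self.alpha_d * self.rho_s

    @property
    def gamma(self) -> float:
        """Continuum nutrient consumption coefficient gamma_d·rho_s (s⁻¹)."""
        return self.gamma_d * self.rho_s


def override(params, **kwargs):
    """Return a copy of a frozen parameter bundle with fields replaced."""
    valid = {f.name for f in fields(params)}
    bad = set(kwargs) - valid
    if bad:
        raise KeyError(f"unknown parameter(s) for {type(params).__name__}: "
                       f"{sorted(bad)}")
    return replace(params, **kwargs)
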