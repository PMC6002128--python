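"""Parameter sweeps of the radial mean-field model.

Each sweep varies one cell-level parameter — swimming speed s0, doubling
time, or the CheZ turnover multiplier kappa — reruns the radial colony
simulation, and tabulates the pattern metrics (front speed over the
10–20 h window, wavelength, height and density ratios).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import Scenario, preset
from .metrics import front_speed, stripe_structure, wavelength
from .params import override
from .pde import run_pde

__all__ = ["sweep_parameter", "run_metrics_row"]

_DEFAULT_PRESET = {"s0": "speed_sweep", "doubling": "doubling_sweep",
                   "kappa": "kappa_sweep"}


def _apply(scenario: Scenario, parameter: str, value: float) -> Scenario:
    d = scenario.__dict__.copy()
    if parameter == "s0":
        d["motility"] = override(scenario.motility, s0=value)
    elif parameter == "doubling":
        d["growth"] = override(scenario.growth, doubling_time_min=value)
    elif parameter == "kappa":
        d["pde"] = {**scenario.pde, "kappa": value}
    else:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    return Scenario(**d)


def run_metrics_row(scenario: Scenario, threshold: float = 0.1,
                    t_window=(36000.0, 72000.0), **pde_extra) -> dict:
    """Run the scenario's PDE config and summarize the final pattern."""
    res = run_pde(scenario.pde_config(**pde_extra))
    radial = res.config.geometry == "radial"
    rho_T = res.rho[-1]
    try:
        speed = front_speed(res.times, res.rho, res.x, threshold, t_window)
    except ValueError:
        speed = float("nan")
    hr, dr = stripe_structure(res.x, rho_T, radial=radial)
    return {
        "front_speed_mm_per_h": speed,
        "wavelength_mm": wavelength(res.x, rho_T),
        "height_ratio": hr,
        "density_ratio": dr,
        "boundary_clear": res.front_never_reached_boundary(),
    }


def sweep_parameter(parameter: str, values, preset_name: str | None = None,
                    scenario: Scenario | None = None,
                    **pde_extra) -> pd.DataFrame:
    """Sweep one parameter over ``values`` and collect pattern metrics."""
    if scenario is None:
        scenario = preset(preset_name or _DEFAULT_PRESET[parameter])
    rows = []
    for v in values:
        row = {"parameter": parameter, "value": float(v)}
        row.update(run_metrics_row(_apply(scenario, parameter, v),
                                   **pde_extra))
        rows.append(row)
    return pd.DataFrame(rows)


def linear_fit_r2(x, y) -> float:
    """R² of an ordinary least-squares line through (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
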