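"""Scenario configuration: TOML loading, presets and run manifests.

A scenario bundles every parameter of a run — signaling, motility,
growth/field constants, geometry, numerics, mode and seeds.  All
figure-level experiments are parameter overrides of one baseline, so
presets are expressed as override dictionaries on top of the defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from .hybrid import HybridConfig
from .params import (GrowthFieldParams, MotilityParams, SignalingParams,
                     override)
from .pde import PDEConfig

__all__ = ["Scenario", "load_config", "scenario_from_dict", "PRESETS",
           "preset", "run_manifest"]


@dataclass(frozen=True)
class Scenario:
    """Fully resolved run description."""

    name: str = "baseline"
    description: str = ""
    kind: str = "pde"            # "pde" | "hybrid" | "reduced"
    seed: int = 0
    signaling: SignalingParams = field(default_factory=SignalingParams)
    motility: MotilityParams = field(default_factory=MotilityParams)
    growth: GrowthFieldParams = field(default_factory=GrowthFieldParams)
    pde: dict = field(default_factory=dict)      # PDEConfig overrides
    hybrid: dict = field(default_factory=dict)   # HybridConfig overrides

    def pde_config(self, **extra) -> PDEConfig:
        kw = dict(self.pde)
        kw.update(extra)
        return PDEConfig(signaling=self.signaling, motility=self.motility,
                         growth=self.growth, **kw)

    def hybrid_config(self, **extra) -> HybridConfig:
        kw = dict(self.hybrid)
        kw.update(extra)
        kw.setdefault("seed", self.seed)
        return HybridConfig(signaling=self.signaling,
                            motility=self.motility, growth=self.growth,
                            **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_SECTION_TYPES = {
    "signaling": SignalingParams,
    "motility": MotilityParams,
    "growth": GrowthFieldParams,
}
_TOP_KEYS = {"name", "description", "kind", "seed", "preset"}


def scenario_from_dict(data: dict, path: str = "<dict>") -> Scenario:
    """Build a scenario from a (possibly partial) mapping.

    Defaults fill every omitted key; unknown keys are rejected with the
    offending key path named.
    """
    data = dict(data)
    base = {}
    if "preset" in data:
        base = dict(PRESETS[data.pop("preset")])
        base.pop("description", None)
    merged = _merge(base, data)
    kwargs = {}
    for key, value in merged.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            try:
                kwargs[key] = override(cls(), **value)
            except KeyError as err:
                raise KeyError(f"{path}: [{key}] {err}") from None
        elif key in ("pde", "hybrid"):
            _check_overrides(key, value, path)
            kwargs[key] = dict(value)
        elif key in _TOP_KEYS:
            kwargs[key] = value
        else:
            raise KeyError(f"{path}: unknown configuration key {key!r}")
    return Scenario(**kwargs)


def _check_overrides(section, value, path):
    cls = PDEConfig if section == "pde" else HybridConfig
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = set(value) - valid
    if bad:
        raise KeyError(f"{path}: unknown key(s) in [{section}]: {sorted(bad)}")


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> Scenario:
    """Load a TOML scenario file (empty file → full baseline defaults)."""
    path = Path(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return scenario_from_dict(data, path=str(path))


# ---------------------------------------------------------------------------
# Shipped presets: the baseline plus the parameter overrides behind each
# simulated experiment (1D cross-sections, radial plate, CheZ inhibitor,
# CheR/CheB knockout, and the cell-speed / doubling-time / CheZ-turnover
# sweeps).
PRESETS: dict = {
    "baseline1d": {
        "description": "1D engineered-strain colony, hybrid + PDE "
                       "cross-validation scenario",
        "kind": "pde",
        "pde": {"geometry": "cartesian", "L": 25.0, "Nx": 500, "Nz": 60,
                "T_end": 36000.0, "mode": "mutant"},
        "hybrid": {"L": 25.0, "T_end": 36000.0, "mode": "mutant"},
    },
    "wildtype1d": {
        "description": "1D wild-type colony (no AHL secretion)",
        "kind": "pde",
        "pde": {"geometry": "cartesian", "L": 25.0, "Nx": 500, "Nz": 60,
                "T_end": 36000.0, "mode": "wildtype"},
        "hybrid": {"L": 25.0, "T_end": 36000.0, "mode": "wildtype"},
    },
    "radial_baseline": {
        "description": "Radially symmetric plate colony, engineered strain",
        "kind": "pde",
        "pde": {"geometry": "radial", "L": 50.0, "Nx": 500, "Nz": 60,
                "T_end": 45000.0, "mode": "mutant"},
    },
    "atc_zw_sweep": {
        "description": "CheZ-inhibitor scenario: reduced wild-type CheZ "
                       "steady state Zw (run per Zw value)",
        "kind": "pde",
        "signaling": {"Zw": 0.81},
        "pde": {"geometry": "radial", "L": 40.0, "Nx": 400, "Nz": 60,
                "T_end": 72000.0, "mode": "mutant"},
    },
    "cherb_mutant": {
        "description": "CheR-CheB- double knockout (methylation frozen)",
        "kind": "pde",
        "pde": {"geometry": "radial", "L": 40.0, "Nx": 400, "Nz": 60,
                "T_end": 72000.0, "mode": "cherb", "m_fixed": 0.707},
    },
    "kappa_sweep": {
        "description": "CheZ turnover-rate multiplier sweep "
                       "(kappa in {0.6, 1, 3, 10})",
        "kind": "pde",
        "pde": {"geometry": "radial", "L": 60.0, "Nx": 300, "Nz": 60,
                "T_end": 72000.0, "dt": 4.0, "mode": "mutant"},
    },
    "speed_sweep": {
        "description": "Cell-speed sweep (s0 multipliers on the baseline)",
        "kind": "pde",
        "pde": {"geometry": "radial", "L": 90.0, "Nx": 450, "Nz": 60,
                "T_end": 72000.0, "dt": 4.0, "mode": "mutant"},
    },
    "doubling_sweep": {
        "description": "Cell doubling-time sweep",
        "kind": "pde",
        "pde": {"geometry": "radial", "L": 70.0, "Nx": 350, "Nz": 60,
                "T_end": 72000.0, "dt": 4.0, "mode": "mutant"},
    },
}


def preset(name: str, **top_overrides) -> Scenario:
    """Instantiate a shipped preset as a scenario."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; "
                       f"available: {sorted(PRESETS)}")
    data = dict(PRESETS[name])
    data["name"] = name
    data.update(top_overrides)
    return scenario_from_dict(data, path=f"<preset:{name}>")


def run_manifest(scenario: Scenario, outputs: dict | None = None) -> dict:
    """Reproducibility record of a run: config hash, seed, code version
    and the output summary the caller supplies."""
    cfg = scenario.to_dict()
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    try:
        ver = version("stripesim")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    return {
        "scenario": scenario.name,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": scenario.seed,
        "stripesim_version": ver,
        "outputs": outputs or {},
    }
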