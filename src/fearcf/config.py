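"""Campaign configuration: a single YAML file describing system, RC graph,
grid, simulation conditions and campaign settings.

Physical quantities carry their unit in the key name (``timestep_fs``,
``min_A``...) so a config file is unambiguous and campaigns are exactly
reproducible from one file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .bias import DimSpec, GridSpec
from .driver import AnalyticParticleSystem, WaterDimerSystem
from .md import (SimulationConditions, WaterForceField, double_well_1d,
                 harmonic_nd)
from .rc_graph import build_graph, water_dimer_graph


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


_GRAPH_PRESETS = {
    "water_dimer_1d": lambda: water_dimer_graph(1),
    "water_dimer_2d": lambda: water_dimer_graph(2),
    "water_dimer_4d": lambda: water_dimer_graph(4),
}

_DEFAULTS = {
    "system": {"kind": "water_dimer", "temperature_K": 300.0,
               "boundary": "periodic", "box_edge_A": 12.0,
               "cavity_radius_A": 6.0, "separation_A": 2.9,
               "barrier_kcal": 2.0, "spring_kcal_A2": 1.0},
    "conditions": {"timestep_fs": 1.0, "thermostat": "nose_hoover",
                   "friction_fs": 0.01, "tau_fs": 100.0, "nh_substeps": 10,
                   "scale_interval": 100},
    "campaign": {"replicas": 16, "steps_per_replica": 20000,
                 "iterations": 15, "min_iterations": 8, "threshold": 2.5,
                 "master_seed": 0, "bias_mix": 1.0, "wall_k": 10.0,
                 "sample_stride": 1, "reinitialize": False,
                 "final_wham": True},
    "output": {"directory": ".", "checkpoint": None, "fev": "fev.txt",
               "traj_stride": 0},
}


@dataclass
class CampaignConfig:
    """Validated campaign configuration with defaults applied."""

    system: dict
    rc_graph: dict
    grid: dict
    conditions: dict
    campaign: dict
    output: dict

    def build_system(self):
        s = self.system
        kind = s["kind"]
        if kind == "water_dimer":
            return WaterDimerSystem(
                ff=WaterForceField(), separation=s["separation_A"],
                temperature=s["temperature_K"], boundary=s["boundary"],
                cavity_radius=s["cavity_radius_A"], box_edge=s["box_edge_A"])
        if kind == "double_well":
            return AnalyticParticleSystem(
                double_well_1d(a=s["barrier_kcal"]),
                temperature=s["temperature_K"], x0=1.0)
        if kind == "harmonic":
            return AnalyticParticleSystem(
                harmonic_nd(k=s["spring_kcal_A2"], ndim=1),
                temperature=s["temperature_K"], x0=0.0)
        raise ConfigError(f"system.kind: unknown system {kind!r}")

    def build_rc(self, system=None):
        g = self.rc_graph
        preset = g.get("preset")
        if preset == "cartesian":
            if system is None:
                system = self.build_system()
            return system.default_graph()
        if preset is not None:
            try:
                return _GRAPH_PRESETS[preset]()
            except KeyError:
                raise ConfigError(f"rc_graph.preset: unknown preset {preset!r}")
        return build_graph(g)

    def build_grid(self) -> GridSpec:
        dims = []
        for i, d in enumerate(self.grid["dims"]):
            key = f"grid.dims[{i}]"
            try:
                dims.append(DimSpec(d["name"], float(d["min"]),
                                    float(d["max"]), int(d["n_bins"]),
                                    bool(d.get("periodic", False))))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"{key}: {exc}") from exc
        return GridSpec(tuple(dims))

    def build_conditions(self) -> SimulationConditions:
        c = self.conditions
        try:
            return SimulationConditions(
                temperature=self.system["temperature_K"],
                timestep_fs=c["timestep_fs"],
                n_steps=self.campaign["steps_per_replica"],
                thermostat=c["thermostat"], friction_fs=c["friction_fs"],
                tau_fs=c["tau_fs"], nh_substeps=c["nh_substeps"],
                scale_interval=c["scale_interval"])
        except ValueError as exc:
            raise ConfigError(f"conditions: {exc}") from exc

    def campaign_kwargs(self) -> dict:
        c = self.campaign
        return dict(K=c["replicas"], n_iterations=c["iterations"],
                    min_iterations=c["min_iterations"],
                    convergence_threshold=c["threshold"],
                    master_seed=c["master_seed"], bias_mix=c["bias_mix"],
                    wall_k=c["wall_k"], sample_stride=c["sample_stride"],
                    reinitialize=c["reinitialize"],
                    final_wham=c["final_wham"])

    def dump(self) -> dict:
        return {"system": dict(self.system), "rc_graph": dict(self.rc_graph),
                "grid": dict(self.grid), "conditions": dict(self.conditions),
                "campaign": dict(self.campaign), "output": dict(self.output)}


def _merge(section: str, user: dict) -> dict:
    out = dict(_DEFAULTS[section])
    for k, v in (user or {}).items():
        if k not in out:
            raise ConfigError(f"{section}.{k}: unknown key")
        out[k] = v
    return out


def normalize(raw: dict) -> CampaignConfig:
    """Apply defaults and validate a raw config mapping."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"system", "rc_graph", "grid", "conditions",
                          "campaign", "output"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
    cfg = CampaignConfig(
        system=_merge("system", raw.get("system", {})),
        rc_graph=dict(raw.get("rc_graph", {"preset": "water_dimer_1d"})),
        grid=dict(raw.get("grid",
                          {"dims": [{"name": "r", "min": 2.2, "max": 6.0,
                                     "n_bins": 64}]})),
        conditions=_merge("conditions", raw.get("conditions", {})),
        campaign=_merge("campaign", raw.get("campaign", {})),
        output=_merge("output", raw.get("output", {})),
    )
    # eager validation so errors surface at load time with key names
    cfg.build_grid()
    if cfg.rc_graph.get("preset") != "cartesian":
        cfg.build_rc()
    cfg.build_conditions()
    if cfg.campaign["replicas"] < 1:
        raise ConfigError("campaign.replicas: must be >= 1")
    if cfg.campaign["iterations"] < 1:
        raise ConfigError("campaign.iterations: must be >= 1")
    return cfg


def load_config(path) -> CampaignConfig:
    """Load and validate a YAML campaign config."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable YAML: {exc}") from exc
    return normalize(raw)


def dump_config(cfg: CampaignConfig, path=None) -> str:
    text = yaml.safe_dump(cfg.dump(), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
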