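"""Run configuration: TOML file parsing, defaults, validation, provenance."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields as dc_fields

__all__ = ["RunConfig", "load_config"]


_SECTIONS = {
    "system": {
        "sequence": "A6G6",
        "sigma_p": 0.005,
        "nacl_mM": 10.0,
        "mgcl2_mM": 3.0,
        "ph": 7.0,
        "temperature_K": 298.0,
    },
    "chemistry": {
        "pKa_A": 3.5,
        "pKa_G": 1.6,
        "dG_AMg": -32.1,
        "dG_GMg": -35.6,
        "dG_ANa": -21.0,
        "dG_GNa": -21.0,
        "mg_exchange_pathway": True,
        "reference": "direct",
        "pKw": 14.0,
        "eps_r": 78.5,
        "v_water": 0.030,
        "v_na": 0.05,
        "v_mg": 0.18,
        "v_cl": 0.05,
        "v_monomer": 0.30,
    },
    "geometry": {
        "bond_length": 0.6,
        "bond_angle_deg": 112.0,
        "dihedral_trans": 180.0,
        "dihedral_gauche": 60.0,
        "first_monomer_z": 0.15,
    },
    "grid": {"n_layers": 100, "dz": 0.3},
    "ensemble": {
        "rotations_per_state": 38,
        "max_conformations": 0,  # 0 = keep all accepted
        "seed": 20181403,
    },
    "solver": {"tol": 1e-8, "max_iter": 100},
    "sweep": {"sigma_p": [], "mgcl2_mM": []},
}


@dataclass
class RunConfig:
    """Fully-resolved run parameters with per-key provenance.

    ``provenance`` maps 'section.key' to 'default' or 'user'.
    """

    system: dict = field(default_factory=lambda: dict(_SECTIONS["system"]))
    chemistry: dict = field(default_factory=lambda: dict(_SECTIONS["chemistry"]))
    geometry: dict = field(default_factory=lambda: dict(_SECTIONS["geometry"]))
    grid: dict = field(default_factory=lambda: dict(_SECTIONS["grid"]))
    ensemble: dict = field(default_factory=lambda: dict(_SECTIONS["ensemble"]))
    solver: dict = field(default_factory=lambda: dict(_SECTIONS["solver"]))
    sweep: dict = field(default_factory=lambda: dict(_SECTIONS["sweep"]))
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        sys_ = self.system
        if sys_["sigma_p"] < 0:
            raise ValueError("invalid value for system.sigma_p: must be >= 0")
        if sys_["nacl_mM"] < 0 or sys_["mgcl2_mM"] < 0:
            raise ValueError("invalid value for system.nacl_mM/mgcl2_mM: must be >= 0")
        if not (0.0 < sys_["ph"] < 14.0):
            raise ValueError("invalid value for system.ph: must lie in (0, 14)")
        if self.grid["n_layers"] < 3:
            raise ValueError("invalid value for grid.n_layers: must be >= 3")
        if self.grid["dz"] <= 0:
            raise ValueError("invalid value for grid.dz: must be > 0")
        if self.ensemble["rotations_per_state"] < 1:
            raise ValueError("invalid value for ensemble.rotations_per_state: must be >= 1")
        for key in ("sigma_p", "mgcl2_mM"):
            if any(v < 0 for v in self.sweep[key]):
                raise ValueError(f"invalid value in sweep.{key}: must be >= 0")

    def echo(self) -> str:
        """Human-readable parameter echo with provenance flags."""
        lines = []
        for f in dc_fields(self):
            if f.name == "provenance":
                continue
            section = getattr(self, f.name)
            for key, val in section.items():
                src = self.provenance.get(f"{f.name}.{key}", "default")
                lines.append(f"{f.name}.{key} = {val!r}  [{src}]")
        return "\n".join(lines)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a TOML config, apply defaults and flag overrides, validate.

    ``overrides`` maps 'section.key' to a value and takes precedence over the
    file. Unknown sections or keys are rejected with the offending name.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)

    cfg = RunConfig()
    for section, values in data.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"section {section!r} must be a table")
        target = getattr(cfg, section)
        for key, val in values.items():
            if key not in _SECTIONS[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            target[key] = val
            cfg.provenance[f"{section}.{key}"] = "user"
    for dotted, val in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if section not in _SECTIONS or key not in _SECTIONS[section]:
            raise ValueError(f"unknown config key {dotted}")
        getattr(cfg, section)[key] = val
        cfg.provenance[dotted] = "user"
    cfg.validate()
    return cfg
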