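"""Configuration loading and validation.

Configs are TOML files with up to five sections — ``[cell]``, ``[tissue]``,
``[geometry]``, ``[protocol]``, ``[sweep]`` — all optional; omitted keys take
the package defaults (the calibrated cell/tissue parameters).  Unknown
sections or keys are rejected, and all violations are reported at once.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields as dc_fields

from .errors import ConfigurationError
from .ionic import ATP_MAX, ATP_MIN, CellParams
from .solver import MonodomainParams, StimulusProtocol

__all__ = ["Config", "load_config", "validate_config", "default_config"]

_GEOMETRY_DEFAULTS = {
    "kind": "slab",  # slab | cube
    "width_cm": 4.0,
    "height_cm": 4.0,
    "n_layers": 1,
    "injured": "all",  # all | none | disc
    "disc_radius_cm": 1.4,
    "side_cm": 0.4,
}

_PROTOCOL_DEFAULTS = {
    "site": "edge",
    "start": 0.0,
    "duration": 2.0,
    "amplitude": 120.0,
}

_SWEEP_DEFAULTS = {
    "phi": [0.35, 0.38, 0.40],
    "atp": [2.0],
    "trials": 20,
    "master_seed": 0,
}

#: keys that must be strictly positive, by section
_POSITIVE = {
    "tissue": {"sigma", "beta", "Cm", "dt", "h"},
    "protocol": {"duration"},
    "sweep": {"trials"},
    "geometry": {"width_cm", "height_cm", "n_layers", "disc_radius_cm",
                 "side_cm"},
    "cell": {"Ko", "Nao", "Cao", "capacitance", "V_c", "V_sr", "V_ss",
             "katp_atp_half", "katp_hill", "ical_atp_half", "ical_atp_hill"},
}


def default_config() -> dict:
    return {
        "cell": {f.name: f.default for f in dc_fields(CellParams)
                 if isinstance(f.default, (int, float, str))},
        "tissue": {f.name: f.default for f in dc_fields(MonodomainParams)
                   if isinstance(f.default, (int, float))},
        "geometry": dict(_GEOMETRY_DEFAULTS),
        "protocol": dict(_PROTOCOL_DEFAULTS),
        "sweep": dict(_SWEEP_DEFAULTS),
    }


@dataclass
class Config:
    """Validated configuration with typed accessors."""

    raw: dict

    @property
    def cell(self) -> CellParams:
        kw = dict(self.raw["cell"])
        kw.pop("stim_amplitude", None)
        return CellParams(**kw)

    @property
    def tissue(self) -> MonodomainParams:
        return MonodomainParams(**self.raw["tissue"])

    def geometry(self):
        from .geometry import make_cube, make_slab
        g = self.raw["geometry"]
        h = self.raw["tissue"]["h"]
        if g["kind"] == "cube":
            return make_cube(g["side_cm"], h=h)
        injured = g["injured"]
        if injured == "disc":
            injured = ("disc", g["disc_radius_cm"])
        return make_slab(g["width_cm"], g["height_cm"], int(g["n_layers"]),
                         injured=injured, h=h)

    def protocol(self) -> StimulusProtocol:
        p = self.raw["protocol"]
        return StimulusProtocol(site=p["site"], start=p["start"],
                                duration=p["duration"],
                                amplitude=p["amplitude"])

    @property
    def sweep(self) -> dict:
        return self.raw["sweep"]


def validate_config(user: dict) -> Config:
    """Merge a raw dict onto the defaults, collecting every violation."""
    defaults = default_config()
    errors = []
    merged = {k: dict(v) for k, v in defaults.items()}
    if not isinstance(user, dict):
        raise ConfigurationError("config root must be a table/dict")
    for section, content in user.items():
        if section not in defaults:
            errors.append(f"unknown section [{section}]")
            continue
        if not isinstance(content, dict):
            errors.append(f"section [{section}] must be a table")
            continue
        for key, value in content.items():
            if key not in defaults[section]:
                errors.append(f"unknown key {section}.{key}")
                continue
            ref = defaults[section][key]
            if isinstance(ref, (int, float)) and not isinstance(ref, bool):
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    errors.append(f"{section}.{key} must be a number")
                    continue
            elif isinstance(ref, str) and not isinstance(value, str):
                errors.append(f"{section}.{key} must be a string")
                continue
            elif isinstance(ref, list) and not isinstance(value, list):
                errors.append(f"{section}.{key} must be a list")
                continue
            merged[section][key] = value
    for section, keys in _POSITIVE.items():
        for key in keys:
            v = merged[section].get(key)
            if isinstance(v, (int, float)) and v <= 0:
                errors.append(f"{section}.{key} must be positive (got {v})")
    for atp in merged["sweep"]["atp"]:
        if not (ATP_MIN <= atp <= ATP_MAX):
            errors.append(
                f"sweep.atp value {atp} outside supported hypoxia range "
                f"{ATP_MIN}-{ATP_MAX} mM")
    for phi in merged["sweep"]["phi"]:
        if not (0.0 <= phi <= 1.0):
            errors.append(f"sweep.phi value {phi} outside [0, 1]")
    if merged["geometry"]["kind"] not in ("slab", "cube"):
        errors.append("geometry.kind must be 'slab' or 'cube'")
    if merged["geometry"]["injured"] not in ("all", "none", "disc"):
        errors.append("geometry.injured must be 'all', 'none' or 'disc'")
    if errors:
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(errors))
    return Config(raw=merged)


def load_config(path) -> Config:
    """Read and validate a TOML config file."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return validate_config(user)
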