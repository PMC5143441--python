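"""Run configuration: YAML schema, validation, resolution to objects.

All internal quantities are SI; config files use explicit ``*_mm`` keys for
millimeter convenience, and CLI scalars accept explicit ``mm``/``m``
suffixes.  Every resolved run writes its fully expanded configuration next
to its outputs so a run is reproducible from that file plus its seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .arrays import TransducerArray, build_spherical_array
from .errors import ConfigError
from .grid import VoxelGrid, centered_grid
from .models import (
    AcousticModel,
    HUMappingConfig,
    HUVolume,
    generate_aberrator,
    generate_synthetic_skull,
    make_water_model,
    map_hu_to_properties,
)
from .solver import SolverConfig

DEFAULTS = {
    "seed": 0,
    "frequency": 1.0e6,
    "grid": {"dims": [64, 64, 80], "spacing_mm": [0.5, 0.5, 0.5], "z0_mm": 40.0},
    "medium": {"kind": "water"},
    "array": {
        "n_elements": 256,
        "aperture_diameter_mm": 145.0,
        "focal_length_mm": 130.0,
        "layout": "fermat",
    },
    "solver": {
        "evanescent": "zero",
        "pad_factor": 2.0,
        "taper_width": 10,
        "reflections": False,
    },
    "targets_mm": [],
    "output_dir": "hasim_out",
}


def parse_length(text) -> float:
    """Parse a CLI length: bare numbers are meters, 'Xmm' / 'Xm' explicit."""
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip().lower()
    if s.endswith("mm"):
        return float(s[:-2]) * 1e-3
    if s.endswith("cm"):
        return float(s[:-2]) * 1e-2
    if s.endswith("m"):
        return float(s[:-1])
    return float(s)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    raw: dict
    seed: int
    frequency: float
    grid: VoxelGrid
    solver: SolverConfig
    targets: list
    output_dir: str

    def build_array(self) -> TransducerArray:
        a = self.raw["array"]
        return build_spherical_array(
            n_elements=int(a["n_elements"]),
            aperture_diameter=float(a["aperture_diameter_mm"]) * 1e-3,
            focal_length=float(a["focal_length_mm"]) * 1e-3,
            frequency=self.frequency,
            layout_kind=a.get("layout", "fermat"),
            seed=a.get("seed"),
            layout_file=a.get("layout_file"),
        )

    def build_medium(self) -> AcousticModel:
        m = self.raw["medium"]
        kind = m.get("kind")
        if kind == "water":
            return make_water_model(self.grid.dims, self.grid.spacing,
                                    origin=self.grid.origin)
        if kind == "aberrator":
            model, _ = generate_aberrator(
                seed=int(m.get("seed", self.seed)),
                grid=self.grid,
                base_thickness=float(m.get("base_thickness_mm", 7.5)) * 1e-3,
                max_relief=float(m.get("max_relief_mm", 4.0)) * 1e-3,
                feature_scale=float(m.get("feature_scale_mm", 5.0)) * 1e-3,
                plate_speed=float(m.get("plate_speed", 2492.0)),
                plate_attenuation=float(m.get("plate_attenuation", 4.72)),
                plate_density=float(m.get("plate_density", 1175.0)),
            )
            return model
        if kind == "skull_phantom":
            hu = generate_synthetic_skull(seed=int(m.get("seed", self.seed)), grid=self.grid)
            return map_hu_to_properties(hu, self._mapping(m))
        if kind == "hu_file":
            from .io import load_hu_nifti

            if "path" not in m:
                raise ConfigError("medium.path", "required for kind 'hu_file'")
            return map_hu_to_properties(load_hu_nifti(m["path"]), self._mapping(m))
        raise ConfigError("medium.kind", f"unknown medium kind {kind!r}")

    @staticmethod
    def _mapping(m: dict) -> HUMappingConfig:
        kw = {}
        mp = m.get("hu_mapping", {})
        for key in (
            "density_intercept", "density_slope", "speed_knots",
            "attenuation_knots", "bone_threshold_hu",
        ):
            if key in mp:
                kw[key] = mp[key]
        if "speed_knots" in kw:
            kw["speed_knots"] = tuple(tuple(k) for k in kw["speed_knots"])
        if "attenuation_knots" in kw:
            kw["attenuation_knots"] = tuple(tuple(k) for k in kw["attenuation_knots"])
        try:
            return HUMappingConfig(**kw)
        except Exception as exc:
            raise ConfigError("medium.hu_mapping", str(exc)) from exc


def resolve_config(user: dict | None) -> RunConfig:
    """Merge user config over defaults and validate; errors name the key."""
    raw = _merge(DEFAULTS, user or {})

    def need(section, key, types):
        try:
            v = raw[section][key] if key else raw[section]
        except (KeyError, TypeError):
            raise ConfigError(f"{section}.{key}" if key else section, "missing required key")
        if not isinstance(v, types):
            raise ConfigError(f"{section}.{key}" if key else section,
                              f"expected {types}, got {type(v).__name__}")
        return v

    seed = raw.get("seed")
    if not isinstance(seed, int):
        raise ConfigError("seed", "must be an integer")
    freq = raw.get("frequency")
    if isinstance(freq, str):
        # YAML 1.1 reads '1.0e6' (no exponent sign) as a string; be lenient
        try:
            freq = float(freq)
        except ValueError:
            pass
    if not isinstance(freq, (int, float)) or freq <= 0:
        raise ConfigError("frequency", "must be a positive number (Hz)")

    gdims = need("grid", "dims", (list, tuple))
    gspace = need("grid", "spacing_mm", (list, tuple))
    gz0 = need("grid", "z0_mm", (int, float))
    if len(gdims) != 3 or any((not isinstance(d, int)) or d < 1 for d in gdims):
        raise ConfigError("grid.dims", "must be three integers >= 1")
    if len(gspace) != 3 or any(s <= 0 for s in gspace):
        raise ConfigError("grid.spacing_mm", "must be three positive lengths (mm)")
    grid = centered_grid(gdims, [s * 1e-3 for s in gspace], z0=gz0 * 1e-3)

    s = raw["solver"]
    try:
        solver = SolverConfig(
            dz=s.get("dz_mm") and float(s["dz_mm"]) * 1e-3,
            evanescent=s.get("evanescent", "zero"),
            pad_factor=float(s.get("pad_factor", 2.0)),
            taper_width=int(s.get("taper_width", 10)),
            reflections=bool(s.get("reflections", False)),
        )
    except Exception as exc:
        raise ConfigError("solver", str(exc)) from exc

    a = raw["array"]
    for key in ("n_elements", "aperture_diameter_mm", "focal_length_mm"):
        if key not in a:
            raise ConfigError(f"array.{key}", "missing required key")
    if a["aperture_diameter_mm"] >= 2 * a["focal_length_mm"]:
        raise ConfigError("array.aperture_diameter_mm",
                          "must be smaller than twice the focal length")

    targets = [np.asarray([t[0], t[1], t[2]], dtype=float) * 1e-3
               for t in raw.get("targets_mm", [])]

    return RunConfig(
        raw=raw,
        seed=seed,
        frequency=float(freq),
        grid=grid,
        solver=solver,
        targets=targets,
        output_dir=str(raw["output_dir"]),
    )


def load_config(path) -> RunConfig:
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    if not isinstance(user, dict):
        raise ConfigError("<root>", "config file must contain a mapping")
    return resolve_config(user)


def dump_resolved(cfg: RunConfig, path) -> None:
    """Write the fully expanded configuration next to a run's outputs."""
    with open(path, "w") as f:
        yaml.safe_dump(cfg.raw, f, sort_keys=False)
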