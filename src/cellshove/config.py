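"""Declarative run configuration, scenario presets, and run manifests.

Configs are flat YAML key-value documents; CLI flags override file values.
Every run writes a manifest (fully resolved config, root seed, package version,
sha256 of each output) sufficient for bit-identical replay.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .engine import SimulationConfig
from .ensemble import EnsembleConfig
from .injection import InjectionConfig, InjectionRegion, REGION_KINDS
from .lattice import LatticeConfig, Personality
from .pde import PDEConfig

_PERSONALITIES = {
    "gentleman": Personality.GENTLEMAN,
    "simple_shover": Personality.SIMPLE_SHOVER,
    "smart_shover": Personality.SMART_SHOVER,
    # short CLI aliases
    "simple": Personality.SIMPLE_SHOVER,
    "smart": Personality.SMART_SHOVER,
}

_DEFAULTS = {
    "Lx": 200,
    "Ly": 20,
    "c_G": 0.0,
    "resident_personality": "gentleman",
    "invader_personality": "simple_shover",
    "region": "band_2d",
    "region_x": None,          # optional custom rectangular region [x0, x1]
    "region_y": None,          # optional [y0, y1]
    "attempts_per_step": 4,
    "injection": True,
    "t_max": 250,
    "record_times": [50, 100, 250],
    "seed": 0,
    "n_realizations": 300,
    "n_jobs": 1,
    "exact_count_seeding": False,
    "horizontal_exit": True,
    "injection_first": False,
}

_VALIDATORS = {
    "c_G": lambda v: 0.0 <= float(v) <= 1.0,
    "Lx": lambda v: int(v) >= 1,
    "Ly": lambda v: int(v) >= 1,
    "attempts_per_step": lambda v: int(v) >= 1,
    "t_max": lambda v: int(v) >= 0,
    "n_realizations": lambda v: int(v) >= 1,
    "resident_personality": lambda v: v in _PERSONALITIES,
    "invader_personality": lambda v: v in _PERSONALITIES,
    "region": lambda v: v in REGION_KINDS,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Read a flat YAML config, apply defaults and overrides, validate.

    Unknown keys and out-of-range values are rejected with the offending key
    named.  An empty/missing config yields the pure defaults (the 2D-band
    empty-domain scenario).
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a flat key-value mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    for key, ok in _VALIDATORS.items():
        try:
            valid = ok(cfg[key])
        except (TypeError, ValueError):
            valid = False
        if not valid:
            raise ValueError(f"invalid value for config key {key!r}: {cfg[key]!r}")
    if "record_times" not in raw:
        # default record times adapt to a shortened horizon
        kept = [t for t in cfg["record_times"] if 0 <= int(t) <= int(cfg["t_max"])]
        cfg["record_times"] = kept or [int(cfg["t_max"])]
    bad = [t for t in cfg["record_times"] if not 0 <= int(t) <= int(cfg["t_max"])]
    if bad:
        raise ValueError(f"invalid value for config key 'record_times': "
                         f"{bad} outside [0, t_max]")
    return cfg


def build_simulation_config(cfg: dict) -> SimulationConfig:
    """Turn a resolved flat config into a :class:`SimulationConfig`."""
    lattice = LatticeConfig(int(cfg["Lx"]), int(cfg["Ly"]))
    injection = None
    if cfg["injection"]:
        if cfg["region_x"] is not None or cfg["region_y"] is not None:
            xr = tuple(int(v) for v in cfg["region_x"])
            yr = tuple(int(v) for v in cfg["region_y"])
            region = InjectionRegion("custom", xr, yr)
        else:
            region = InjectionRegion.from_kind(cfg["region"], lattice)
        injection = InjectionConfig(
            region=region,
            invader_personality=_PERSONALITIES[cfg["invader_personality"]],
            attempts_per_step=int(cfg["attempts_per_step"]),
        )
    return SimulationConfig(
        lattice=lattice,
        c_G=float(cfg["c_G"]),
        resident_personality=_PERSONALITIES[cfg["resident_personality"]],
        injection=injection,
        t_max=int(cfg["t_max"]),
        record_times=tuple(int(t) for t in cfg["record_times"]),
        seed=int(cfg["seed"]),
        exact_count_seeding=bool(cfg["exact_count_seeding"]),
        horizontal_exit=bool(cfg["horizontal_exit"]),
        injection_first=bool(cfg["injection_first"]),
    )


def build_ensemble_config(cfg: dict) -> EnsembleConfig:
    return EnsembleConfig(
        base=build_simulation_config(cfg),
        n_realizations=int(cfg["n_realizations"]),
        root_seed=int(cfg["seed"]),
        n_jobs=int(cfg["n_jobs"]),
    )


_GEOMETRIES = {"band": "band_2d", "midline": "midline", "upper": "upper_horizontal"}
_PRESET_PERS = {"gentleman": "gentleman", "simple": "simple_shover",
                "smart": "smart_shover"}


def scenario_presets() -> dict[str, dict]:
    """Named study scenarios: invasion of an empty domain (`fig3-*`, c_G = 0)
    and of a gentlemen background (`fig5-*`, c_G = 0.6), for each invader
    personality x invasion geometry, plus the continuum-comparison scenario
    `fig10` (c_G = 0.2, simple-shover invaders, 2D band)."""
    presets: dict[str, dict] = {}
    for fam, c_G in (("fig3", 0.0), ("fig5", 0.6)):
        for pkey, pers in _PRESET_PERS.items():
            for gkey, region in _GEOMETRIES.items():
                presets[f"{fam}-{pkey}-{gkey}"] = {
                    "c_G": c_G,
                    "invader_personality": pers,
                    "region": region,
                }
    presets["fig10"] = {"c_G": 0.2, "invader_personality": "simple_shover",
                        "region": "band_2d"}
    return presets


def preset_config(name: str, overrides: dict | None = None) -> dict:
    presets = scenario_presets()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(presets)}")
    merged = dict(presets[name])
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    return load_config(None, merged)


def pde_config_from(cfg: dict, dx: float = 0.1, D0: float = 0.25,
                    output_times=None) -> PDEConfig:
    """Continuum counterpart of a lattice scenario config."""
    invader = cfg["invader_personality"]
    if invader in ("simple", "smart"):
        invader += "_shover"
    region = InjectionRegion.from_kind(cfg["region"],
                                       LatticeConfig(int(cfg["Lx"]), int(cfg["Ly"])))
    # column-averaged source density: attempts spread over the region's columns
    # and the full column height; equals the per-site entry probability for the
    # 2D band (4/400 = 0.01), and stays 0.01 for the 1D line regions too
    width = region.x_range[1] - region.x_range[0] + 1
    p_entry = int(cfg["attempts_per_step"]) / (width * int(cfg["Ly"]))
    return PDEConfig(
        length=float(cfg["Lx"]), dx=dx, D0=D0, Ly=int(cfg["Ly"]),
        P_entry=p_entry, Zl=float(region.x_range[0]), Zr=float(region.x_range[1]),
        c_G=float(cfg["c_G"]), invader=invader,
        output_times=tuple(float(t) for t in
                           (output_times or cfg["record_times"])),
    )


def sha256_of(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir: Path, resolved_config: dict, root_seed: int,
                   outputs: list[Path], extra: dict | None = None) -> Path:
    """Write the run manifest: resolved config, seed, version, output checksums."""
    outdir = Path(outdir)
    manifest = {
        "package": "cellshove",
        "version": __version__,
        "root_seed": int(root_seed),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in resolved_config.items()},
        "outputs": {p.name: sha256_of(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
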