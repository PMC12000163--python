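"""Configuration loading with explicit laboratory units.

Config files are YAML with sections ``particle``, ``buffer``,
``syringe``, ``flow``, ``sim``, ``analysis`` and ``model``. Every
dimensional key carries its unit as a suffix (``radius_um``,
``density_g_cm3``, ``rate_ul_min``, ...) and is converted to SI on
load — unit mistakes fail loudly instead of silently rescaling an
experiment. Missing optional sections fall back to defaults;
invariant violations are reported with the offending keys.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .sim import SimConfig
from .specs import (
    BufferSpec,
    InvalidParameterError,
    ModelConstants,
    ParticleSpec,
    SyringeSpec,
)

__all__ = ["ConfigError", "AnalysisParams", "Config", "load_config", "config_hash"]

# unit-suffix -> factor to SI
_UNIT_FACTORS = {
    "um": 1e-6,
    "mm": 1e-3,
    "m": 1.0,
    "g_cm3": 1000.0,
    "kg_m3": 1.0,
    "mPa_s": 1e-3,
    "Pa_s": 1.0,
    "ul_min": 1e-9 / 60.0,
    "m3_s": 1.0,
    "s": 1.0,
    "ms": 1e-3,
    "hz": 1.0,
    "m_s2": 1.0,
}


class ConfigError(ValueError):
    """Invalid or missing configuration entries."""


@dataclass(frozen=True)
class AnalysisParams:
    """Signal-analysis chain parameters (SI units)."""

    lowpass_cutoff: float = 100.0
    threshold_sigmas: float = 5.0
    min_separation: float = 1e-3
    bin_width: float = 1.0
    init_window: float = 20.0
    smooth_bins: int = 21


@dataclass
class Config:
    """Validated run configuration (all SI)."""

    particle: ParticleSpec
    buffer: BufferSpec
    syringe: SyringeSpec
    flow_rate: float
    backend: str = "superposition"
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    constants: ModelConstants = field(default_factory=ModelConstants)
    K_S: Optional[float] = None
    raw: dict = field(default_factory=dict, repr=False)


class _Section:
    def __init__(self, name: str, data: dict, errors: list):
        self.name = name
        self.data = data or {}
        self.errors = errors
        if not isinstance(self.data, dict):
            errors.append(f"section '{name}' must be a mapping")
            self.data = {}

    def get(self, key: str, default=None, required: bool = False):
        if key in self.data:
            val = self.data[key]
            suffix = key.split("_", 1)[1] if "_" in key else None
            for suf, fac in _UNIT_FACTORS.items():
                if key.endswith("_" + suf):
                    try:
                        return float(val) * fac
                    except (TypeError, ValueError):
                        self.errors.append(f"{self.name}.{key}: not a number ({val!r})")
                        return default
            return val
        if required:
            self.errors.append(f"{self.name}.{key}: missing required key")
        return default


def load_config(path) -> Config:
    """Parse and validate a YAML configuration file.

    Raises :class:`ConfigError` listing every offending key when the
    file violates the schema or a physical invariant.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")

    errors: list = []
    pa = _Section("particle", raw.get("particle"), errors)
    bu = _Section("buffer", raw.get("buffer"), errors)
    sy = _Section("syringe", raw.get("syringe"), errors)
    fl = _Section("flow", raw.get("flow"), errors)
    si = _Section("sim", raw.get("sim"), errors)
    an = _Section("analysis", raw.get("analysis"), errors)
    mo = _Section("model", raw.get("model"), errors)

    # _Section.get converts unit-suffixed keys to SI when present and
    # returns the (already-SI) default when absent.
    r_p = pa.get("radius_um", required=True)
    rho_p = pa.get("density_g_cm3", required=True)
    rho_b = bu.get("density_g_cm3", 1000.0)
    eta = bu.get("viscosity_mPa_s", 1e-3)
    R_s = sy.get("barrel_radius_mm", required=True)
    L_s = sy.get("barrel_length_mm", 40e-3)
    R_o = sy.get("outlet_radius_mm", required=True)
    L_o = sy.get("outlet_length_mm", 5e-3)
    off = sy.get("outlet_offset_mm", 0.0)
    Q = fl.get("rate_ul_min", 0.0)
    backend = fl.get("backend", "superposition")
    g = mo.get("g_m_s2", 9.81)
    K_S = mo.get("K_S", None)

    def build(cls, err_prefix, /, **kw):
        try:
            return cls(**kw)
        except InvalidParameterError as exc:
            errors.append(f"{err_prefix}: {exc}")
            return None

    particle = buffer = syringe = constants = None
    if not errors:
        particle = build(ParticleSpec, "particle", radius=r_p, density=rho_p)
        buffer = build(BufferSpec, "buffer", density=rho_b, viscosity=eta)
        syringe = build(
            SyringeSpec, "syringe",
            barrel_radius=R_s, barrel_length=L_s, outlet_radius=R_o,
            outlet_length=L_o, outlet_offset=off,
        )
        constants = build(ModelConstants, "model", g=g)
        if Q is not None and Q < 0:
            errors.append("flow.rate_ul_min: must be >= 0")
        if K_S is not None and K_S <= 0:
            errors.append("model.K_S: must be > 0")
        sim_cfg = build(
            SimConfig, "sim",
            n_particles=int(si.get("n_particles", 2000)),
            dt=si.get("dt_s", 0.05),
            max_time=si.get("max_time_s", 1200.0),
            seed=int(si.get("seed", 0)),
            integrator=si.get("integrator", "euler"),
        )
        analysis = AnalysisParams(
            lowpass_cutoff=an.get("lowpass_cutoff_hz", 100.0),
            threshold_sigmas=float(an.get("threshold_sigmas", 5.0)),
            min_separation=an.get("min_separation_ms", 1e-3),
            bin_width=an.get("bin_width_s", 1.0),
            init_window=an.get("init_window_s", 20.0),
            smooth_bins=int(an.get("smooth_bins", 21)),
        )
    if errors:
        raise ConfigError(
            f"{path}: invalid configuration:\n  " + "\n  ".join(str(e) for e in errors)
        )
    return Config(
        particle=particle, buffer=buffer, syringe=syringe,
        flow_rate=float(Q), backend=str(backend),
        sim=sim_cfg, analysis=analysis, constants=constants,
        K_S=None if K_S is None else float(K_S), raw=raw,
    )


def config_hash(cfg: Config) -> str:
    """Stable short hash of the raw configuration, for provenance."""
    canon = yaml.safe_dump(cfg.raw, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
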