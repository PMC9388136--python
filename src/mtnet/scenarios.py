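"""Scenario presets, configuration I/O and scenario assembly.

A :class:`ScenarioConfig` materializes every parameter of a simulation
(YAML-serializable; keys carry units in their names so reconstructed
values are auditable).  Presets reproduce the published simulation
setups at full scale:

======================  ============================================
``fig5b_kif11``         60x60x0.2 µm, 0.8 MT/µm² (2,880 MT), 16
                        KIF11 per MT (46,080 motors)
``fig5d_hset``          40x40x0.2 µm, 1,280 MT, 32 HSET per MT
                        (40,960 motors)
``fig6a_mixed``         60x60x0.2 µm, 2 KIF11 per MT plus HSET at a
                        configurable ratio (default 2 HSET : 1 KIF11,
                        i.e. 4 per MT; 16:1 = 32 per MT)
``fig6c_sweep``         20x20x0.2 µm, 2 KIF11 per MT plus a variant
                        cross-linker at a configurable ratio
``fig6d_variant``       20x20x0.2 µm (320 MT), symmetric HSET-variant
                        constructs at 4 or 32 per MT
``si4_symmetric_minus`` as fig5d with the hypothetical symmetric
                        minus-end motor
``si6_variant``         20x20x0.2 µm, plus-directed or nondiffusive
                        HSET variants with sparse KIF11
``no_motor_control``    40x40x0.2 µm, no cross-linkers
======================  ============================================

``scale`` shrinks the linear box dimensions (filament count scales
with area at fixed density 0.8 MT/µm²) and, by default, durations and
analysis windows shrink linearly with the box edge so motor transit
times across structures stay commensurate.  The tubulin pool is
parameterized as (steady-state mean length target, default 2.5 µm)
x (filament count).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .crosslinkers import LinkerSpec, UnitSpec, linker_catalog
from .dynamics import PhysicsParams, SystemState
from .filaments import GrowthModel, draw_max_speed
from .geometry import SimulationBox

__all__ = [
    "ScenarioConfig",
    "PRESET_NAMES",
    "build_scenario",
    "build_state",
    "save_config",
    "load_config",
    "simulate_growth_only",
]

CONFIG_VERSION = 1


@dataclass
class ScenarioConfig:
    """Fully materialized simulation configuration.

    A config echoed by a run is self-contained: feeding it back through
    :func:`build_state` (no further scaling is applied) reproduces the
    run bit-for-bit for the same software version.
    """

    preset: str = "custom"
    scale: float = 1.0
    seed: int = 0
    # geometry
    size_x_um: float = 20.0
    size_y_um: float = 20.0
    size_z_um: float = 0.2
    # composition
    mt_density_per_um2: float = 0.8
    linker_ratios: dict = field(default_factory=dict)  # name -> per filament
    # schedule
    duration_s: float = 8000.0
    dt_s: float = 0.005
    frame_interval_s: float = 160.0
    delta_t_s: float = 640.0
    # growth
    alpha0_um_per_s: float = 0.05
    mean_length_um: float = 2.5
    growth_duration_s: float = 600.0
    nucleation_rate_per_s: float = 0.1
    initial_length_um: float = 0.1
    # mechanics
    rest_segment_um: float = 0.5
    kappa_pN_um2: float = 20.0
    eta_pN_s_per_um2: float = 0.5
    kBT_pN_um: float = 4.23e-3
    k_steric_pN_per_um: float = 50.0
    d_steric_um: float = 0.05
    max_vertices: int = 24
    # per-linker kinetic overrides, e.g. {"hset": {"k_spring": 80,
    # "unit_a": {"vm": 0.1}}}
    linker_overrides: dict = field(default_factory=dict)
    # resolved quantities (filled by build_scenario)
    n_filaments: int | None = None
    omega_um: float | None = None
    config_version: int = CONFIG_VERSION

    def resolve(self) -> "ScenarioConfig":
        cfg = copy.deepcopy(self)
        if cfg.n_filaments is None:
            cfg.n_filaments = int(round(cfg.mt_density_per_um2
                                        * cfg.size_x_um * cfg.size_y_um))
        if cfg.omega_um is None:
            cfg.omega_um = cfg.mean_length_um * cfg.n_filaments
        return cfg

    def linker_counts(self) -> dict[str, int]:
        if self.n_filaments is None:
            raise ValueError("config not resolved")
        return {name: int(round(ratio * self.n_filaments))
                for name, ratio in self.linker_ratios.items()}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        ver = d.pop("config_version", CONFIG_VERSION)
        if ver != CONFIG_VERSION:
            raise ValueError(f"config version {ver} not supported "
                             f"(expected {CONFIG_VERSION})")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


_PRESETS: dict[str, dict] = {
    "fig5b_kif11": dict(size_x_um=60.0, size_y_um=60.0,
                        linker_ratios={"kif11": 16.0}, duration_s=5000.0),
    "fig5d_hset": dict(size_x_um=40.0, size_y_um=40.0,
                       linker_ratios={"hset": 32.0}, duration_s=5000.0),
    "fig6a_mixed": dict(size_x_um=60.0, size_y_um=60.0,
                        linker_ratios={"kif11": 2.0, "hset": 4.0},
                        duration_s=8000.0),
    "fig6c_sweep": dict(size_x_um=20.0, size_y_um=20.0,
                        linker_ratios={"kif11": 2.0, "hset": 4.0},
                        duration_s=8000.0),
    "fig6d_variant": dict(size_x_um=20.0, size_y_um=20.0,
                          linker_ratios={"kif11": 2.0,
                                         "double_motor_hset": 4.0},
                          duration_s=8000.0),
    "si4_symmetric_minus": dict(size_x_um=40.0, size_y_um=40.0,
                                linker_ratios={"symmetric_minus": 32.0},
                                duration_s=5000.0),
    "si6_variant": dict(size_x_um=20.0, size_y_um=20.0,
                        linker_ratios={"kif11": 2.0, "hset_plus": 4.0},
                        duration_s=8000.0),
    "no_motor_control": dict(size_x_um=40.0, size_y_um=40.0,
                             linker_ratios={}, duration_s=5000.0),
}

PRESET_NAMES = tuple(_PRESETS)


def build_scenario(name: str, scale: float = 1.0, seed: int = 0,
                   overrides: dict | None = None,
                   n_filaments: int | None = None
                   ) -> tuple[ScenarioConfig, SystemState]:
    """Instantiate a preset at a given scale.

    ``scale`` multiplies the linear box dimensions (Z stays 0.2 µm)
    and, by default, duration, frame interval, analysis window and
    growth-phase duration.  ``overrides`` replaces any config field
    *after* scaling.  Returns the resolved config and the initial
    state (all linkers unbound, no filaments nucleated yet).
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; presets: "
                       f"{', '.join(PRESET_NAMES)}")
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    cfg = ScenarioConfig(preset=name, scale=scale, seed=seed,
                         **copy.deepcopy(_PRESETS[name]))
    cfg.size_x_um *= scale
    cfg.size_y_um *= scale
    cfg.duration_s *= scale
    cfg.frame_interval_s *= scale
    cfg.delta_t_s *= scale
    cfg.growth_duration_s *= scale
    if overrides:
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config field {key!r}")
            setattr(cfg, key, val)
    if n_filaments is not None:
        cfg.n_filaments = int(n_filaments)
    cfg = cfg.resolve()
    if cfg.n_filaments < 8:
        raise ValueError(
            f"scale {scale} yields only {cfg.n_filaments} filaments (< 8)")
    return cfg, build_state(cfg)


def _apply_unit_overrides(u: UnitSpec, d: dict) -> UnitSpec:
    return replace(u, **d)


def _spec_with_overrides(name: str, ov: dict) -> LinkerSpec:
    sp = linker_catalog(name)
    ov = dict(ov)
    ua = ov.pop("unit_a", None)
    ub = ov.pop("unit_b", None)
    if ua:
        sp = replace(sp, unit_a=_apply_unit_overrides(sp.unit_a, ua))
    if ub:
        sp = replace(sp, unit_b=_apply_unit_overrides(sp.unit_b, ub))
    if ov:
        sp = replace(sp, **ov)
    return sp


def build_state(cfg: ScenarioConfig) -> SystemState:
    """Build the initial :class:`SystemState` from a resolved config
    (values are taken literally; no scaling is applied here)."""
    cfg = cfg.resolve()
    box = SimulationBox(cfg.size_x_um, cfg.size_y_um, cfg.size_z_um)
    params = PhysicsParams(dt=cfg.dt_s, kBT=cfg.kBT_pN_um,
                           eta=cfg.eta_pN_s_per_um2,
                           k_steric=cfg.k_steric_pN_per_um,
                           d_steric=cfg.d_steric_um)
    growth = GrowthModel(alpha0=cfg.alpha0_um_per_s, omega=cfg.omega_um)
    counts = cfg.linker_counts()
    specs = [_spec_with_overrides(nm, cfg.linker_overrides.get(nm, {}))
             for nm in counts]
    return SystemState(
        box, params=params,
        linker_specs=specs, linker_counts=list(counts.values()),
        n_seeds=cfg.n_filaments, growth=growth,
        nucleation_rate=cfg.nucleation_rate_per_s,
        growth_duration=cfg.growth_duration_s,
        initial_length=cfg.initial_length_um,
        seg_rest=cfg.rest_segment_um, kappa=cfg.kappa_pN_um2,
        seed=cfg.seed, capacity=cfg.n_filaments,
        max_vertices=cfg.max_vertices)


def save_config(cfg: ScenarioConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path: str) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def simulate_growth_only(cfg: ScenarioConfig, seed: int | None = None,
                         dt: float = 0.01,
                         plateau_window_s: float = 100.0,
                         plateau_rel: float = 1e-4) -> dict:
    """Integrate nucleation and the pool-limited growth law with
    mechanics disabled, until the total polymer plateaus.

    Each unused seed fires with probability ``1 - exp(-rate dt)``;
    nucleated filaments draw a maximum speed ``alpha0 |1 + 0.25 Z|``
    and grow at ``alpha (1 - sum L / Omega)`` until the relative change
    of total length per ``plateau_window_s`` drops below
    ``plateau_rel`` or the growth phase ends.  Returns mean/total
    lengths and the per-filament length array.
    """
    cfg = cfg.resolve()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_seeds = cfg.n_filaments
    omega = cfg.omega_um
    p_nuc = -np.expm1(-cfg.nucleation_rate_per_s * dt)
    lengths = np.zeros(0)
    alphas = np.zeros(0)
    remaining = n_seeds
    total = 0.0
    t = 0.0
    t_check = plateau_window_s
    total_prev = 0.0
    while t < cfg.growth_duration_s:
        n_new = rng.binomial(remaining, p_nuc) if remaining else 0
        if n_new:
            remaining -= n_new
            newl = np.full(n_new, min(cfg.initial_length_um,
                                      max(omega - total, 0.0)))
            lengths = np.concatenate([lengths, newl])
            alphas = np.concatenate([alphas, [
                draw_max_speed(cfg.alpha0_um_per_s, rng)
                for _ in range(n_new)]])
            total += float(np.sum(newl))
        if lengths.size:
            dl = alphas * max(1.0 - total / omega, 0.0) * dt
            add = float(np.sum(dl))
            avail = omega - total
            if add > avail > 0:
                dl *= avail / add
                add = avail
            lengths += dl
            total += add
        t += dt
        if t >= t_check:
            if total > 0 and (total - total_prev) / total < plateau_rel:
                break
            total_prev = total
            t_check += plateau_window_s
    return {
        "time_s": t,
        "n_filaments": int(lengths.size),
        "total_length_um": total,
        "mean_length_um": float(np.mean(lengths)) if lengths.size else 0.0,
        "lengths_um": lengths,
    }
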