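"""Parameter vectors of the two HPS representations.

Three vectors describe the system: ``EASConfig`` (the five fascicular root
locations in UVC space plus the sub-endocardial layer bounds), a fascicle
vector (disc radius and the five earliest-activation-site timings), and a
Purkinje vector (fractal growth, branching and His-bundle bifurcation
points).  ``SimulationConfig`` carries the electrophysiology constants.
``baseline_config`` returns the published baseline for all four.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .geometry import UVCCoord

FASCICLE_ORDER = ("lv_af", "lv_sf", "lv_pf", "rv_sf", "rv_mod")


@dataclass
class EASConfig:
    """Fascicular root locations and sub-endocardial (SE) layer bounds."""

    b_lv_sf: UVCCoord
    b_lv_af: UVCCoord
    b_lv_pf: UVCCoord
    b_rv_sf: UVCCoord
    b_rv_mod: UVCCoord
    s_z_min: float = 0.15
    s_z_max: float = 0.9
    s_rho: float = 0.1

    @property
    def roots(self) -> dict:
        """The five roots keyed by fascicle name, in canonical order."""
        return {name: getattr(self, f"b_{name}") for name in FASCICLE_ORDER}


@dataclass
class FascicleConfig:
    """Disc radius (fraction of apicobasal endocardial arc length) and EAS timings (ms)."""

    delta_rad: float = 0.05
    t_his: tuple = (19.86, 24.81, 26.25, 37.30, 41.94)  # (lv_af, lv_sf, lv_pf, rv_sf, rv_mod)

    @property
    def timings(self) -> dict:
        return dict(zip(FASCICLE_ORDER, self.t_his))


@dataclass
class PurkinjeConfig:
    """Fractal growth, branching and His-bundle parameters."""

    delta_cov: float = 0.6       # target SE coverage per network, 1 = complete
    mu: float = 2100.0           # mean branch length, um
    sigma: float = 0.4           # relative spread of branch length
    r: float = 0.25              # repulsion factor in [0, 1]
    psi: float = 20.0            # branching half-angle, degrees
    b_h0: UVCCoord = UVCCoord(1.00, 0.50, 0.00, -1)
    b_h1: UVCCoord = UVCCoord(0.90, 0.50, 0.00, -1)
    b_h_lv: UVCCoord = UVCCoord(0.85, 0.8, 0.21, -1)
    b_h_rv: UVCCoord = UVCCoord(0.85, 0.2, 0.21, -1)
    b_h_rv_mid: UVCCoord = UVCCoord(0.3, 0.8, -0.2, -1)
    segment_resolution: float = 500.0  # um
    generation_cap: int = 40


@dataclass
class SimulationConfig:
    """Conduction, coupling and recording constants."""

    cv_myo: float = 0.70         # myocardial conduction velocity, m/s
    cv_purk: float = 3.70        # Purkinje / fast SE conduction velocity, m/s
    delay_antero: float = 8.0    # PVJ network->tissue delay, ms
    delay_retro: float = 3.0     # PVJ tissue->network delay, ms
    duration: float = 150.0      # ms
    sample_rate: float = 2000.0  # Hz
    anisotropy_ratio: float = 1.0  # 1 = isotropic myocardium


def baseline_config():
    """Published baseline: roots/SE bounds, timings, growth and EP constants."""
    eas = EASConfig(
        b_lv_sf=UVCCoord(0.61, 0.0, 0.73, -1),
        b_lv_af=UVCCoord(0.82, 0.0, 1.94, -1),
        b_lv_pf=UVCCoord(0.47, 0.0, -1.36, -1),
        b_rv_sf=UVCCoord(0.73, 1.0, -0.04, -1),
        b_rv_mod=UVCCoord(0.63, 0.0, 0.21, 1),
    )
    return eas, FascicleConfig(), PurkinjeConfig(), SimulationConfig()


# ------------------------------------------------------------------ validation


def _check(violations, ok, message):
    if not ok:
        violations.append(message)


def validate(eas=None, fascicle=None, purkinje=None, simulation=None) -> list[str]:
    """Collect invariant violations across the supplied configs.

    Violations are returned as data (field + rule strings), never raised.
    """
    v: list[str] = []
    if eas is not None:
        _check(v, eas.s_z_min < eas.s_z_max, "s_z_min < s_z_max")
        for f in ("s_z_min", "s_z_max", "s_rho"):
            _check(v, 0 <= getattr(eas, f) <= 1, f"{f} in [0, 1]")
        for name, b in eas.roots.items():
            _check(v, 0 <= b.z <= 1, f"b_{name}.z in [0, 1]")
            _check(v, 0 <= b.rho <= 1, f"b_{name}.rho in [0, 1]")
            _check(v, b.nu in (-1, 1), f"b_{name}.nu in {{-1, +1}}")
            _check(v, eas.s_z_min <= b.z <= eas.s_z_max,
                   f"b_{name}.z within [s_z_min, s_z_max]")
    if fascicle is not None:
        _check(v, fascicle.delta_rad > 0, "delta_rad > 0")
        _check(v, len(fascicle.t_his) == 5, "t_his has 5 entries")
        _check(v, all(t >= 0 for t in fascicle.t_his), "t_his >= 0")
    if purkinje is not None:
        _check(v, 0 <= purkinje.delta_cov <= 1, "delta_cov in [0, 1]")
        _check(v, purkinje.mu > 0, "mu > 0")
        _check(v, purkinje.sigma >= 0, "sigma >= 0")
        _check(v, 0 <= purkinje.r <= 1, "r in [0, 1]")
        _check(v, 0 < purkinje.psi < 90, "psi in (0, 90) degrees")
        _check(v, purkinje.segment_resolution > 0, "segment_resolution > 0")
        for name in ("b_h0", "b_h1", "b_h_lv", "b_h_rv", "b_h_rv_mid"):
            b = getattr(purkinje, name)
            _check(v, 0 <= b.z <= 1 and 0 <= b.rho <= 1 and b.nu in (-1, 1),
                   f"{name} within UVC domain")
    if simulation is not None:
        for f in ("cv_myo", "cv_purk", "delay_antero", "delay_retro",
                  "duration", "sample_rate", "anisotropy_ratio"):
            _check(v, getattr(simulation, f) > 0, f"{f} > 0")
        _check(v, simulation.delay_antero >= simulation.delay_retro,
               "delay_antero >= delay_retro")
    return v


# --------------------------------------------------------------- serialization

_SECTIONS = {
    "eas": EASConfig,
    "fascicle": FascicleConfig,
    "purkinje": PurkinjeConfig,
    "simulation": SimulationConfig,
}


def _to_plain(obj):
    if isinstance(obj, UVCCoord):
        return [float(obj.z), float(obj.rho), float(obj.phi), int(obj.nu)]
    if isinstance(obj, tuple):
        return [float(x) for x in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def save_config(path, eas, fascicle, purkinje, simulation):
    """Write all four configs to one YAML file, full float precision."""
    doc = {}
    for section, obj in (("eas", eas), ("fascicle", fascicle),
                         ("purkinje", purkinje), ("simulation", simulation)):
        doc[section] = {
            f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path):
    """Read back a config file written by :func:`save_config`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = []
    for section, cls in _SECTIONS.items():
        kwargs = {}
        for f in fields(cls):
            if f.name not in doc.get(section, {}):
                continue
            raw = doc[section][f.name]
            if f.name.startswith("b_"):
                kwargs[f.name] = UVCCoord(raw[0], raw[1], raw[2], int(raw[3]))
            elif f.name == "t_his":
                kwargs[f.name] = tuple(raw)
            else:
                kwargs[f.name] = raw
        out.append(cls(**kwargs))
    return tuple(out)


def override(config, **kwargs):
    """Return a copy of a config dataclass with scalar fields replaced."""
    return dataclasses.replace(config, **kwargs)
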