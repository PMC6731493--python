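"""Run and sweep configuration with YAML round-trip.

A :class:`RunConfig` bundles everything a single simulation needs --
geometry, wave, pyloric schedule, lattice, run length, tracers, outputs --
and is serialized verbatim into every output bundle so runs are
self-describing and reproducible (the tracer seed fixes initialization
exactly; the solver itself is deterministic).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from gastroflow.geometry import GeometryParams
from gastroflow.lbm import FreeSurfaceModel, LatticeConfig
from gastroflow.motility import PyloricSchedule, WaveParams

MODES = ("full3d", "reduced3d", "channel2d")
_MODE_DX = {"full3d": 1.5, "reduced3d": 3.0}


@dataclass
class RunConfig:
    """Complete specification of one gastric simulation."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    wave: WaveParams = field(default_factory=WaveParams)
    schedule: PyloricSchedule = field(default_factory=PyloricSchedule.control)
    lattice: LatticeConfig = field(default_factory=lambda: LatticeConfig(dx=3.0))
    free_surface: FreeSurfaceModel = field(
        default_factory=lambda: FreeSurfaceModel(k_flat=50.0, accel_cap=0.002)
    )
    mode: str = "reduced3d"
    n_cycles: float = 5.0
    transient_cycles: float = 2.0
    fill_fraction: float = 0.8
    tracer_count: int = 0
    tracer_every: int = 10  # solver steps between tracer RK4 updates
    seed: int = 0
    record_every: int = 4
    snapshot_every: float = 0.0  # s; 0 disables VTK snapshots
    mixing_snapshots: int = 24  # velocity snapshots over the final cycle

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "channel2d":
            raise ValueError("channel2d is the validation mode; use `gastroflow validate`")
        if self.n_cycles <= self.transient_cycles:
            raise ValueError("n_cycles must exceed transient_cycles")

    @classmethod
    def for_mode(cls, mode: str, **kw) -> "RunConfig":
        lat = kw.pop("lattice", None) or LatticeConfig(dx=_MODE_DX.get(mode, 3.0))
        return cls(mode=mode, lattice=lat, **kw)

    # -- YAML ---------------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("geometry", GeometryParams),
            ("wave", WaveParams),
            ("schedule", PyloricSchedule),
            ("lattice", LatticeConfig),
            ("free_surface", FreeSurfaceModel),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "geometry":
                    for f_ in ("centerline_control_points", "radius_knots"):
                        if f_ in sub:
                            sub[f_] = tuple(tuple(x) for x in sub[f_])
                if key == "wave":
                    for f_ in ("epsilon_profile", "velocity_profile"):
                        if sub.get(f_) is not None:
                            sub[f_] = tuple(tuple(x) for x in sub[f_])
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SweepSpec:
    """Cartesian sweep over viscosity and pyloric coordination.

    Defaults follow the study design: two viscosities (Re = 30 and
    Re ~ 0.1), closure durations T_C/T in {0, 1/6, 1/3, 1/2, 2/3, 5/6, 1}
    and delays T_D/T in eighths of a cycle.
    """

    mu: tuple[float, ...] = (4.2e-3, 1.3)
    tc_frac: tuple[float, ...] = (0.0, 1 / 6, 1 / 3, 1 / 2, 2 / 3, 5 / 6, 1.0)
    td_frac: tuple[float, ...] = (0.0, 1 / 8, 1 / 4, 3 / 8, 1 / 2, 5 / 8, 3 / 4, 7 / 8)

    def cells(self) -> list[tuple[float, float, float]]:
        """Deterministic enumeration of (mu, T_C/T, T_D/T) cells."""
        return [
            (m, tc, td)
            for m in self.mu
            for tc in self.tc_frac
            for td in self.td_frac
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepSpec":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**{k: tuple(v) for k, v in d.items()})
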