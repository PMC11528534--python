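"""TOML scenario configuration with published defaults.

An empty file yields the full default configuration (Kc = 0.3, Kv = 0.06,
k = 0.001, gamma = 16, lambda_h = 0.15, T0 = 36 days, tau1 = 17.13 y,
tau2 = 13.82 y, 400 basal cycles).  Unknown keys are errors; a dumped
configuration loads back identically.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from ..cell_fate import ClockParams
from ..grn_dde import DelayConfig, GrnParameters
from ..homeostasis import HomeostasisParams
from ..tissue_mech import MechanicsParams, TissueDomain

__all__ = ["SimConfig", "load_config", "loads_config", "dumps_config", "default_config"]

#: initial cancer-cell counts of the published scenario sweep
SCENARIO_CANCER_COUNTS = (0, 6, 10, 14, 18)


@dataclass
class SimConfig:
    """All scenario parameters; defaults follow the published values."""

    seed: int = 0
    n_cells: int = 100
    n_cancer: int = 0
    total_cycles: float = 400.0
    snapshot_stride: int = 0  # snapshots every k fate checks; 0 disables
    dt_grn: float = 0.02
    dt_mech: float = 0.3
    gating: bool = True
    elongation: bool = True
    cancer_placement: str = "nearest_duct"  # or "random"
    grn_offset_cycles: float = 0.0  # tissue time 0 maps to this GRN time
    glucose_diffusivity: float = 1.0
    glucose_calibration: str = "balanced"  # "balanced" | "mean" | "none"
    glucose_target_mean: float = 0.5
    #: concentration band whose occupancy the balanced calibration equalizes
    #: (slightly asymmetric around the clock bands to offset the crowding gate)
    glucose_balance_band: tuple = (0.44, 0.575)
    #: elevated tumour glucose consumption relative to healthy cells
    cancer_uptake_factor: float = 1.0
    #: autonomous cancer cell-cycle pace (clock units per model-time unit);
    #: 0 keeps cancer clocks glucose-paced like healthy cells
    cancer_clock_rate: float = 0.05
    #: dysplastic enlargement: fractional growth of a cancer cell's demanded
    #: (basal) area per fate check, up to the cap below
    cancer_hypertrophy: float = 0.025
    cancer_hypertrophy_max: float = 3.0  # cap, in multiples of the initial cell size
    driver_u0: float = 1.5
    driver_v0: float = 0.7

    domain: TissueDomain = field(default_factory=lambda: TissueDomain(
        kind="u_shape", duct_length=1.5, width=2.0, channel_width=0.5, bulb_radius=0.75))
    delays: DelayConfig = field(default_factory=DelayConfig)
    grn: GrnParameters = field(default_factory=GrnParameters)
    mech: MechanicsParams = field(default_factory=MechanicsParams)
    clock: ClockParams = field(default_factory=ClockParams)
    homeo: HomeostasisParams = field(default_factory=HomeostasisParams)

    def __post_init__(self):
        self.glucose_balance_band = tuple(self.glucose_balance_band)
        if not (0 < self.glucose_balance_band[0] < self.glucose_balance_band[1] < 1):
            raise ValueError("glucose_balance_band must be increasing within (0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.n_cancer < 0:
            raise ValueError("n_cancer must be non-negative")
        if self.n_cancer > self.n_cells:
            raise ValueError("n_cancer cannot exceed n_cells")
        if self.total_cycles < 0:
            raise ValueError("total_cycles must be non-negative")
        if self.dt_grn <= 0 or self.dt_mech <= 0:
            raise ValueError("time steps must be positive")
        if self.cancer_placement not in ("nearest_duct", "random", "spread"):
            raise ValueError("cancer_placement must be nearest_duct, random or spread")
        if self.glucose_calibration not in ("balanced", "mean", "none"):
            raise ValueError("glucose_calibration must be 'balanced', 'mean' or 'none'")
        # the clock's basal period is the model-time span of one cytokine cycle
        if abs(self.clock.T0 - self.delays.time_units_per_cycle) > 1e-12:
            raise ValueError("clock.T0 must equal delays.time_units_per_cycle")

    @property
    def total_time_units(self) -> float:
        return self.total_cycles * self.delays.time_units_per_cycle

    @property
    def run_months(self) -> float:
        """Total simulated duration in 30-day months."""
        return self.total_cycles * self.delays.days_per_cycle / self.delays.days_per_month


_SECTION_TYPES = {
    "domain": TissueDomain,
    "delays": DelayConfig,
    "grn": GrnParameters,
    "mech": MechanicsParams,
    "clock": ClockParams,
    "homeo": HomeostasisParams,
}

_TOP_FIELDS = {
    f.name for f in dataclasses.fields(SimConfig) if f.name not in _SECTION_TYPES
}


def _build_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in [{path}]: {sorted(unknown)}")
    kwargs = dict(data)
    # TOML has no tuples; coerce list-valued fields
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid [{path}] section: {e}") from e


def loads_config(text: str) -> SimConfig:
    """Parse a TOML configuration string (empty string = all defaults)."""
    data = tomllib.loads(text)
    kwargs = {}
    for key, val in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(val, dict):
                raise ValueError(f"[{key}] must be a table")
            kwargs[key] = _build_section(_SECTION_TYPES[key], val, key)
        elif key in _TOP_FIELDS:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    # a domain/clock section tied to custom delays must stay consistent
    if "delays" in kwargs and "clock" not in kwargs:
        kwargs["clock"] = ClockParams(T0=kwargs["delays"].time_units_per_cycle)
    try:
        return SimConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid configuration: {e}") from e


def load_config(path) -> SimConfig:
    """Load, default and validate a TOML configuration file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return loads_config(p.read_text())


def default_config() -> SimConfig:
    return SimConfig()


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dumps_config(cfg: SimConfig) -> str:
    """Serialize a configuration to TOML (round-trips through loads)."""
    lines: list[str] = []
    for f in dataclasses.fields(SimConfig):
        if f.name in _SECTION_TYPES:
            continue
        lines.append(f"{f.name} = {_fmt(getattr(cfg, f.name))}")
    for name, cls in _SECTION_TYPES.items():
        section = getattr(cfg, name)
        lines.append("")
        lines.append(f"[{name}]")
        sub = {}
        for sf in dataclasses.fields(cls):
            v = getattr(section, sf.name)
            if v is None:
                continue
            if isinstance(v, dict):
                sub[sf.name] = v
                continue
            lines.append(f"{sf.name} = {_fmt(v)}")
        for sub_name, d in sub.items():
            lines.append("")
            lines.append(f"[{name}.{sub_name}]")
            for k, v in d.items():
                lines.append(f"{k} = {_fmt(v)}")
    return "\n".join(lines) + "\n"
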