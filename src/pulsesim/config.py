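"""Simulator configuration: the single source of tunable truth.

:class:`SimulatorConfig` gathers every physical setting of the four simulated
hardware modules — left-ventricle piston/cylinder, aorta with compliance
chamber and reflection site, peripheral resistance valves, and the
constant-pressure reservoir.  All pressures are gauge mmHg (absolute pressure
appears only inside the gas law), times are milliseconds, volumes mL and flows
mL/s; conversions are centralized in :mod:`pulsesim.core`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["SimulatorConfig", "ValveSpec", "load_config", "save_config"]


@dataclass(frozen=True)
class ValveSpec:
    """A forward-only check valve with a cracking threshold.

    Flow is exactly zero at or below ``opening_threshold`` (differential
    pressure, mmHg) and follows a linear post-crack law above it with slope
    ``1/open_resistance``.  Reverse flow is always exactly zero.
    """

    opening_threshold: float  # mmHg
    open_resistance: float    # mmHg·s/mL

    def __post_init__(self) -> None:
        if not (self.opening_threshold >= 0.0):
            raise ConfigurationError(
                f"opening_threshold must be >= 0, got {self.opening_threshold}")
        if not (self.open_resistance > 0.0):
            raise ConfigurationError(
                f"open_resistance must be > 0, got {self.open_resistance}")


@dataclass(frozen=True)
class SimulatorConfig:
    """All tunable settings of the radial pulsation simulator.

    Defaults reproduce the published operating point: an 80 mL piston stroke
    every 750 ms, a mitral check valve cracking at 14 mmHg, aortic ejection
    beginning near 100 mmHg left-ventricular pressure, and a reservoir holding
    the diastolic baseline at 80 mmHg.
    """

    # --- left ventricle simulation module -------------------------------
    cycle_period: float = 750.0       # ms per beat
    stroke_volume: float = 80.0       # mL displaced by the piston per cycle
    systolic_fraction: float = 0.30   # fraction of the cycle spent ejecting
    mitral_opening_dp: float = 14.0   # mmHg cracking differential, inflow
    aortic_opening_p: float = 100.0   # mmHg gauge LV pressure at ejection onset
    mitral_resistance: float = 0.02   # mmHg·s/mL post-crack
    aortic_resistance: float = 0.05   # mmHg·s/mL post-crack

    # --- aorta simulation module (compliance chamber + reflection) ------
    chamber_air_volume: float = 10.0    # mL of trapped air (0 = rigid)
    chamber_ref_pressure: float = 80.0  # mmHg gauge at which air volume is set
    reflection_gamma: float = 0.40798   # reflection coefficient at bifurcation
    reflection_delay: float = 140.0     # ms round trip to the reflection site
    radial_delay: float = 60.0          # ms central -> radial transit
    valve_rebound: float = 0.8          # re-reflection at the closed valve

    # --- peripheral resistance module / reservoir -----------------------
    aortic_valve_opening: float = 0.5      # throttle fraction, direct return
    peripheral_valve_opening: float = 0.5  # throttle fraction, radial branch
    reservoir_pressure: float = 80.0       # mmHg gauge, diastolic set point

    # --- physics and numerics -------------------------------------------
    atmospheric_pressure: float = 760.0  # mmHg absolute
    dt: float = 0.5                      # ms integration step

    # --- lumped-element constants (hardware geometry surrogates) --------
    lv_compliance: float = 0.05          # mL/mmHg cylinder/seal elasticity
    lv_end_diastolic_volume: float = 130.0  # mL fluid at start of ejection
    structural_compliance: float = 0.15     # mL/mmHg silicone-tube compliance
    aortic_inertance: float = 2e-3         # mmHg·s^2/mL valve fluid column
    aortic_return_resistance: float = 0.06  # mmHg·s/mL at full valve opening
    peripheral_resistance: float = 0.5    # mmHg·s/mL at full valve opening
    characteristic_resistance: float = 0.01 # mmHg·s/mL aorta->radial segment
    peripheral_inertance: float = 3e-3  # mmHg·s^2/mL radial branch
    radial_compliance: float = 0.05        # mL/mmHg radial-site compartment
    reflection_attenuation_volume: float = 40.0  # mL half-damping air volume
    valve_smoothing: float = 0.5            # mmHg C1 blend band at thresholds
    polytropic_exponent: float = 1.0        # 1 = isothermal air spring

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first violated field."""
        def require(cond: bool, field: str, constraint: str) -> None:
            if not cond:
                raise ConfigurationError(
                    f"{field}: {constraint} (got {getattr(self, field)!r})")

        import math
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigurationError(f"{f.name}: must be a finite number")

        require(self.cycle_period > 0, "cycle_period", "must be > 0")
        require(self.stroke_volume >= 0, "stroke_volume", "must be >= 0")
        require(0 < self.systolic_fraction <= 0.5, "systolic_fraction",
                "must lie in (0, 0.5] (ejection plus mirrored refill "
                "must fit in one cycle)")
        require(self.mitral_opening_dp >= 0, "mitral_opening_dp", "must be >= 0")
        require(self.mitral_resistance > 0, "mitral_resistance", "must be > 0")
        require(self.aortic_resistance > 0, "aortic_resistance", "must be > 0")
        require(0 <= self.chamber_air_volume <= 20, "chamber_air_volume",
                "must lie in [0, 20] mL")
        require(0 < self.aortic_valve_opening <= 1, "aortic_valve_opening",
                "must lie in (0, 1]")
        require(0 < self.peripheral_valve_opening <= 1,
                "peripheral_valve_opening", "must lie in (0, 1]")
        require(0 <= self.reflection_gamma <= 1, "reflection_gamma",
                "must lie in [0, 1]")
        require(self.reflection_delay >= 0, "reflection_delay", "must be >= 0")
        require(self.radial_delay >= 0, "radial_delay", "must be >= 0")
        require(0 <= self.valve_rebound <= 1, "valve_rebound",
                "must lie in [0, 1]")
        require(self.atmospheric_pressure > 0, "atmospheric_pressure",
                "must be > 0")
        require(self.dt > 0, "dt", "must be > 0")
        require(self.dt <= self.cycle_period / 100.0, "dt",
                "must be <= cycle_period/100")
        require(self.aortic_opening_p > self.reservoir_pressure,
                "aortic_opening_p", "must exceed reservoir_pressure")
        require(self.lv_compliance > 0, "lv_compliance", "must be > 0")
        require(self.lv_end_diastolic_volume > self.stroke_volume,
                "lv_end_diastolic_volume", "must exceed stroke_volume")
        require(self.structural_compliance > 0, "structural_compliance",
                "must be > 0")
        require(self.aortic_inertance > 0, "aortic_inertance", "must be > 0")
        require(self.aortic_return_resistance > 0, "aortic_return_resistance",
                "must be > 0")
        require(self.peripheral_resistance > 0, "peripheral_resistance",
                "must be > 0")
        require(self.characteristic_resistance > 0,
                "characteristic_resistance", "must be > 0")
        require(self.peripheral_inertance > 0, "peripheral_inertance",
                "must be > 0")
        require(self.radial_compliance > 0, "radial_compliance",
                "must be > 0")
        require(self.reflection_attenuation_volume > 0,
                "reflection_attenuation_volume", "must be > 0")
        require(self.valve_smoothing >= 0, "valve_smoothing", "must be >= 0")
        require(self.polytropic_exponent >= 1.0, "polytropic_exponent",
                "must be >= 1 (1 = isothermal)")

    # ------------------------------------------------------------------
    def replace(self, **changes) -> "SimulatorConfig":
        """Return a validated copy with the given fields changed."""
        unknown = set(changes) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulatorConfig":
        """Build a config from a mapping; unknown keys are rejected by name."""
        if not isinstance(mapping, dict):
            raise ConfigurationError(
                f"configuration must be a mapping, got {type(mapping).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        return cls(**mapping)

    # derived quantities ------------------------------------------------
    @property
    def aortic_crack_dp(self) -> float:
        """Cracking differential of the aortic valve, mmHg.

        The ~100 mmHg opening pressure is the LV gauge pressure at ejection
        onset with the downstream side at the diastolic baseline, so the
        differential across the valve is ``aortic_opening_p - reservoir``.
        """
        return self.aortic_opening_p - self.reservoir_pressure

    @property
    def mitral_valve(self) -> ValveSpec:
        return ValveSpec(self.mitral_opening_dp, self.mitral_resistance)

    @property
    def aortic_valve(self) -> ValveSpec:
        return ValveSpec(self.aortic_crack_dp, self.aortic_resistance)


# ----------------------------------------------------------------------
def load_config(path: str | Path) -> SimulatorConfig:
    """Load a YAML or JSON configuration file.

    An empty mapping yields the full default configuration; unknown keys are
    rejected with a message naming the key.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    return SimulatorConfig.from_dict(data)


def save_config(config: SimulatorConfig, path: str | Path) -> None:
    """Write a configuration as YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
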