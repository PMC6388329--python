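"""Parametric synthetic radial waveforms (test fixtures).

Each pulse is a diastolic baseline plus a sum of periodically extended
Gaussian bumps — one each for the early-systolic (forward) wave, the
reflected wave and the dicrotic wave — with optional seeded Gaussian noise.
The parameterization gives direct analytic control over the fiducial
geometry: with well-separated narrow components the augmentation index is
simply the reflected-over-early amplitude ratio, so fixtures can be built
with an exact AI by construction.  These fixtures emulate the age trend of
averaged human radial tonometry (AI and pulse pressure rising with age); they
make no claim of clinical realism beyond that fiducial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .waveform import WaveformRecord

__all__ = ["SyntheticPulseSpec", "synth_waveform", "age_fixture"]

# Fixture parameters per age group: early amplitude (mmHg), reflected center
# (ms) — amplitudes of the reflected bump are derived from the published
# augmentation indices so each fixture's analytic AI is exact.
_FIXTURE_AI = {"young": 64.0, "middle": 75.0, "older": 91.0}
_FIXTURE_EARLY_AMP = {"young": 40.0, "middle": 45.0, "older": 50.0}
_FIXTURE_REFL_CENTER = {"young": 330.0, "middle": 310.0, "older": 290.0}


@dataclass
class SyntheticPulseSpec:
    """Gaussian-bump description of one radial pulse.

    ``components`` lists (amplitude mmHg, center ms, width ms) for the
    early-systolic, reflected and dicrotic bumps, in that time order.
    """

    diastolic_p: float = 80.0
    components: list[tuple[float, float, float]] = field(default_factory=list)
    period: float = 750.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.period <= 0:
            raise ConfigurationError("period: must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        last_center = -np.inf
        for i, (amp, center, width) in enumerate(self.components):
            if amp < 0:
                raise ConfigurationError(
                    f"components[{i}].amplitude: must be >= 0")
            if width <= 0:
                raise ConfigurationError(
                    f"components[{i}].width: must be > 0")
            if not (last_center < center < self.period):
                raise ConfigurationError(
                    f"components[{i}].center: centers must be strictly "
                    "increasing and inside the period")
            last_center = center


def synth_waveform(spec: SyntheticPulseSpec, n_cycles: int = 1,
                   dt: float = 2.0) -> WaveformRecord:
    """Render a synthetic radial waveform over ``n_cycles`` periods.

    ``p(t) = diastolic_p + sum of periodically extended Gaussian bumps +
    N(0, noise_sd)``; bitwise reproducible for a fixed spec and seed.
    """
    spec.validate()
    if n_cycles < 1:
        raise ConfigurationError("n_cycles: must be >= 1")
    n = int(round(spec.period / dt)) * n_cycles
    t = np.arange(n) * dt
    tau = t % spec.period
    p = np.full(n, spec.diastolic_p, dtype=float)
    for amp, center, width in spec.components:
        # wrap each bump into the neighbouring periods for continuity
        for shift in (-spec.period, 0.0, spec.period):
            p += amp * np.exp(-0.5 * ((tau - center - shift) / width) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        p += rng.normal(0.0, spec.noise_sd, size=n)
    return WaveformRecord("radial", t, p, spec.period)


def age_fixture(group: str) -> SyntheticPulseSpec:
    """Fixture spec with the published AI of an age group, by construction.

    The reflected-bump amplitude is the early amplitude times AI/100, so the
    analytic augmentation index equals 64 / 75 / 91 % for young / middle /
    older; the early amplitude (hence pulse pressure) grows with age.
    """
    if group not in _FIXTURE_AI:
        raise ConfigurationError(
            f"unknown age group {group!r}; valid labels: "
            + ", ".join(sorted(_FIXTURE_AI)))
    a1 = _FIXTURE_EARLY_AMP[group]
    ai = _FIXTURE_AI[group]
    return SyntheticPulseSpec(
        diastolic_p=80.0,
        components=[
            (a1, 120.0, 28.0),                          # early systolic
            (a1 * ai / 100.0, _FIXTURE_REFL_CENTER[group], 40.0),  # reflected
            (0.12 * a1, 520.0, 30.0),                   # dicrotic wave
        ],
        period=750.0,
        noise_sd=0.0,
        seed=0,
    )
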