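"""Left-ventricular pressure–volume loop analysis.

The PV loop pairs LV fluid volume against LV pressure over one steady-state
cycle.  Its width is the stroke volume; its top the systolic peak.  Raising
the afterload — operationalized here exactly as in the hardware, by reducing
the opening of the aortic/peripheral resistance valves — shrinks the stroke
volume and raises the systolic peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulatorConfig
from .core import NumericalDivergenceError, SimulationResult, run_to_steady_state
from .errors import InputError

__all__ = ["PVLoop", "build_pv_loop", "afterload_sweep"]


@dataclass
class PVLoop:
    """One closed LV pressure–volume trajectory with its summary numbers."""

    volume: np.ndarray            # mL over one cycle
    pressure: np.ndarray          # mmHg on the same grid
    stroke_volume: float          # mL, max(volume) - min(volume)
    systolic_peak: float          # mmHg, max(pressure)
    ejection_onset_pressure: float  # mmHg, LV pressure at first aortic flow


def build_pv_loop(result: SimulationResult) -> PVLoop:
    """Pair the final-cycle LV volume and pressure traces into a loop.

    Refuses non-converged results: a transient loop is not closed and its
    summary numbers are meaningless.
    """
    if not result.converged:
        raise InputError(
            "simulation did not converge to a periodic steady state "
            f"(residual {result.residual:.3g} mmHg after "
            f"{result.n_cycles_run} cycles); PV analysis refused")
    vol = result.lv_volume.p
    prs = result.lv_pressure.p
    q_a = result.aortic_flow.p
    eject = np.flatnonzero(q_a > 0.0)
    onset = float(prs[eject[0]]) if eject.size else float("nan")
    return PVLoop(
        volume=vol.copy(),
        pressure=prs.copy(),
        stroke_volume=float(np.max(vol) - np.min(vol)),
        systolic_peak=float(np.max(prs)),
        ejection_onset_pressure=onset,
    )


def afterload_sweep(base: SimulatorConfig,
                    openings: list[float]) -> list[PVLoop]:
    """Steady-state PV loops over a descending sweep of valve openings.

    Each opening fraction is applied to both resistance valves (aortic return
    and peripheral branch) with every other setting fixed; decreasing the
    opening raises the flow resistance to the reservoir and therefore the
    afterload.  Deterministic: identical openings yield identical loops.
    """
    if len(openings) < 2:
        raise InputError("afterload sweep needs at least 2 opening values")
    if any(openings[i] < openings[i + 1] for i in range(len(openings) - 1)):
        raise InputError("openings must be sorted descending "
                         "(decreasing opening = increasing afterload)")
    loops = []
    for opening in openings:
        cfg = base.replace(aortic_valve_opening=opening,
                           peripheral_valve_opening=opening)
        try:
            result = run_to_steady_state(cfg)
        except NumericalDivergenceError as exc:
            raise NumericalDivergenceError(
                f"afterload sweep diverged at opening {opening:g}: {exc}"
            ) from exc
        loops.append(build_pv_loop(result))
    return loops
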