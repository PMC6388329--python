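"""Radial pressure waveform analytics.

Detects the three fiducial landmarks of a radial pulse — the early-systolic
peak produced by the forward ejection wave, the late-systolic shoulder where
the reflected wave summates with the forward wave, and the dicrotic notch
marking aortic valve closure — and computes the derived indices used in
arterial-stiffness work: the radial augmentation index

    AI = 100 x (late-systolic pulse pressure) / (early-systolic pulse pressure)

with both pulse pressures measured above the diastolic foot, and the pulse
pressure (systolic minus diastolic).
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import FeatureAbsentError, InputError, UndefinedIndexError

__all__ = [
    "WaveformRecord",
    "PulseFeatures",
    "detect_features",
    "radial_ai",
    "pulse_pressure",
    "normalize_waveform",
    "compare_waveforms",
]

_COMPARE_GRID = 512  # samples per normalized cycle when comparing


@dataclass
class WaveformRecord:
    """A uniformly sampled pressure time series at a named site."""

    site: str
    t: np.ndarray        # ms, strictly increasing, uniform step
    p: np.ndarray        # mmHg gauge (or dimensionless once normalized)
    period: float = 0.0  # ms; 0 when unknown

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.p.shape:
            raise InputError("t and p must be 1-D arrays of equal length")
        if self.t.size == 0:
            raise InputError("empty waveform record")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise InputError(f"time axis of '{self.site}' must be "
                                 "strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise InputError(f"non-uniform sampling in '{self.site}'")
        if not np.all(np.isfinite(self.p)):
            raise InputError(f"non-finite pressure in '{self.site}'")

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise InputError("record too short to define a sampling step")
        return float(self.t[1] - self.t[0])

    def copy(self) -> "WaveformRecord":
        return WaveformRecord(self.site, self.t.copy(), self.p.copy(),
                              self.period)


@dataclass(frozen=True)
class PulseFeatures:
    """Fiducial points of one pulse cycle and the indices derived from them.

    Feature times are in the time base of the input record; pressures in its
    pressure units.
    """

    diastolic_p: float                     # cycle minimum (foot)
    early_systolic: tuple[float, float]    # (time ms, pressure)
    late_systolic: tuple[float, float]
    dicrotic_notch: tuple[float, float]
    pulse_pressure: float
    ai_percent: float


# ----------------------------------------------------------------------
def _infer_period(w: WaveformRecord) -> float:
    """Estimate the cycle period from the spacing of the systolic peaks.

    Every pulse cycle carries one dominant (early-systolic) peak, so the
    median spacing between high-prominence maxima is the beat period; this
    is far more robust on baseline-heavy pulse signals than
    autocorrelation.  Requires at least two cycles.
    """
    n = w.p.size
    if n < 32:
        raise InputError("record too short to infer a period")
    pp = float(np.max(w.p) - np.min(w.p))
    if pp <= 0:
        raise InputError("cannot infer period of a constant record")
    peaks, _ = find_peaks(w.p, prominence=0.5 * pp)
    if peaks.size < 2:
        raise InputError(
            "cannot infer period: record holds fewer than two systolic "
            "peaks (pass an explicit period for single-cycle records)")
    return float(np.median(np.diff(peaks)) * w.dt)


def _first_cycle(w: WaveformRecord) -> tuple[np.ndarray, float, float]:
    """Extract one full cycle starting at the diastolic foot.

    Returns ``(pressure_cycle, t0_ms, dt_ms)`` where ``t0`` is the absolute
    time of the first cycle sample.  Records that hold exactly one period of a
    periodic steady state are extended periodically (wrap-around), which is
    exact for converged simulator output.
    """
    period = w.period if w.period > 0 else _infer_period(w)
    dt = w.dt
    n_per = int(round(period / dt))
    if n_per < 16:
        raise InputError("fewer than 16 samples per cycle")
    if w.p.size < n_per:
        raise InputError("record does not cover one full cycle")

    # foot = minimum before the first systolic upstroke: search the window
    # leading up to the first prominent maximum of the record
    i_max = int(np.argmax(w.p[:n_per]))
    search_end = i_max if i_max > 0 else n_per
    i_foot = int(np.argmin(w.p[:search_end])) if search_end > 0 else 0
    # prefer the latest sample of a flat minimum run (the true foot)
    pmin = w.p[i_foot]
    tol = 1e-9 + 1e-6 * max(1.0, abs(pmin))
    while i_foot + 1 < search_end and w.p[i_foot + 1] <= pmin + tol:
        i_foot += 1

    if w.p.size >= i_foot + n_per:
        cyc = w.p[i_foot:i_foot + n_per].copy()
    else:  # wrap-around for single-period records
        rolled = np.roll(w.p[:n_per], -i_foot)
        cyc = rolled.copy()
    return cyc, float(w.t[0] + i_foot * dt), dt


def _smooth(cyc: np.ndarray, window_frac: float = 0.05) -> np.ndarray:
    n = cyc.size
    win = max(5, int(round(window_frac * n)) | 1)
    if win >= n:
        win = (n - 1) | 1
    return savgol_filter(cyc, window_length=win, polyorder=3, mode="wrap")


def detect_features(w: WaveformRecord) -> PulseFeatures:
    """Locate the fiducial points of the first complete cycle of ``w``.

    The early-systolic peak is the first prominent maximum after the
    diastolic foot.  The late-systolic feature is the second local maximum
    when the reflected wave peaks on its own; when it only shoulders the
    decay, it is localized at the slope plateau (interior maximum of the
    first derivative of the smoothed signal) between the early peak and the
    notch.  The dicrotic notch is the most prominent local minimum after the
    late-systolic feature and before end-cycle.

    Raises :class:`FeatureAbsentError` naming the missing feature when the
    waveform lacks the corresponding structure.
    """
    cyc, t0, dt = _first_cycle(w)
    n = cyc.size
    s = _smooth(cyc)
    dia = float(np.min(cyc))
    pp = float(np.max(cyc) - dia)
    if pp <= 0:
        raise FeatureAbsentError("early_systolic", "flat waveform")

    def most_prominent_min(lo: int, hi: int, floor: float = 0.005):
        """(index, prominence) of the deepest local minimum in (lo, hi)."""
        lo, hi = max(lo, 0), min(hi, n)
        if hi - lo < 3:
            return None
        mins, props = find_peaks(-s[lo:hi], prominence=floor * pp)
        if mins.size == 0:
            return None
        j = int(np.argmax(props["prominences"]))
        return lo + int(mins[j]), float(props["prominences"][j])

    def shoulder_between(a: int, b: int) -> int:
        """Late-systolic shoulder in (a, b): small local max, else the slope
        plateau (interior maximum of the first derivative) of the decay."""
        small, _ = find_peaks(s[a:b], prominence=1e-3 * pp)
        if small.size > 0:
            return a + int(small[0])
        margin = max(2, int(0.03 * n))
        aa, bb = a + margin, b - margin
        if bb - aa < 3:
            raise FeatureAbsentError("late_systolic")
        d1 = np.gradient(s, dt)
        plat, _ = find_peaks(d1[aa:bb])
        if plat.size == 0:
            raise FeatureAbsentError(
                "late_systolic", "no reflected-wave shoulder on the decay")
        return aa + int(plat[np.argmax(d1[aa:bb][plat])])

    # prominent maxima: candidates for P1, a peaking P2, the dicrotic wave
    maxima, _ = find_peaks(s, prominence=0.10 * pp)
    if maxima.size == 0:
        raise FeatureAbsentError("early_systolic")
    i_p1 = int(maxima[0])
    h = lambda i: (s[i] - dia) / (s[i_p1] - dia)  # height above the foot

    if maxima.size >= 3:
        # P1, peaking P2 and dicrotic wave all resolved
        i_p2 = int(maxima[1])
        found = most_prominent_min(i_p2 + 1, int(maxima[2]))
        if found is None:
            raise FeatureAbsentError("dicrotic_notch")
        i_notch = found[0]
    elif maxima.size == 2:
        i_m1 = int(maxima[1])
        valley = most_prominent_min(i_p1 + 1, i_m1)
        if valley is None:
            raise FeatureAbsentError("dicrotic_notch")
        later = most_prominent_min(i_m1 + 1, int(0.95 * n))
        later_prom = later[1] if later else 0.0
        if valley[1] > 2.0 * later_prom and h(valley[0]) < 0.6:
            # the second peak looks like the dicrotic wave: the deep valley
            # is the notch and the late-systolic feature only shoulders the
            # decay; if no shoulder exists there, the second peak really was
            # the late-systolic peak after all
            try:
                i_notch = valley[0]
                i_p2 = shoulder_between(i_p1, i_notch)
            except FeatureAbsentError:
                if later is None:
                    raise
                i_p2, i_notch = i_m1, later[0]
        else:
            i_p2 = i_m1
            if later is None:
                raise FeatureAbsentError("dicrotic_notch")
            i_notch = later[0]
    else:
        # single prominent peak: notch from the closure incisura, then the
        # shoulder on the decay between peak and notch
        found = most_prominent_min(i_p1 + 1, int(0.95 * n))
        if found is None:
            raise FeatureAbsentError(
                "late_systolic",
                "no post-systolic minimum: waveform decays monotonically, "
                "late_systolic (and dicrotic_notch) absent")
        i_notch = found[0]
        i_p2 = shoulder_between(i_p1, i_notch)

    if not (i_p1 < i_p2 < i_notch):
        raise FeatureAbsentError("late_systolic", "feature ordering violated")

    def at(i: int) -> tuple[float, float]:
        return (t0 + i * dt, float(cyc[i]))

    return PulseFeatures(
        diastolic_p=dia,
        early_systolic=at(i_p1),
        late_systolic=at(i_p2),
        dicrotic_notch=at(i_notch),
        pulse_pressure=pp,
        ai_percent=100.0 * (cyc[i_p2] - dia) / (cyc[i_p1] - dia),
    )


# ----------------------------------------------------------------------
def radial_ai(f: PulseFeatures) -> float:
    """Radial augmentation index in percent.

    ``100 x (P2 - diastolic) / (P1 - diastolic)`` — late- over early-systolic
    pulse pressure, both measured above the diastolic foot.
    """
    early = f.early_systolic[1] - f.diastolic_p
    late = f.late_systolic[1] - f.diastolic_p
    if early <= 0:
        raise UndefinedIndexError(
            "early-systolic pulse pressure is zero; AI undefined")
    return 100.0 * late / early


def pulse_pressure(w: WaveformRecord) -> float:
    """Systolic-minus-diastolic pressure over one cycle, mmHg."""
    if w.p.size == 0:
        raise InputError("empty record")
    if w.period > 0:
        n_per = int(round(w.period / w.dt)) if w.p.size >= 2 else w.p.size
        seg = w.p[:max(n_per, 1)]
    else:
        seg = w.p
    return float(np.max(seg) - np.min(seg))


def normalize_waveform(w: WaveformRecord) -> WaveformRecord:
    """Rescale pressure to [0, 1] and rebase time to the cycle start."""
    pp = float(np.max(w.p) - np.min(w.p))
    if pp <= 0:
        raise InputError("zero pulse pressure: cannot normalize")
    p = (w.p - np.min(w.p)) / pp
    return WaveformRecord(w.site, w.t - w.t[0], p, w.period)


def compare_waveforms(a: WaveformRecord, b: WaveformRecord) -> dict[str, float]:
    """RMSE and Pearson correlation of two normalized single-cycle waveforms.

    Both records are linearly resampled to a common 512-point grid over their
    own normalized time span; the result is symmetric in its arguments.
    """
    for w in (a, b):
        if np.min(w.p) < -1e-9 or np.max(w.p) > 1 + 1e-9:
            raise InputError(
                f"'{w.site}' is not normalized to [0, 1]; "
                "call normalize_waveform first")
        if w.t.size < 2:
            raise InputError("record too short to resample")

    def resample(w: WaveformRecord) -> np.ndarray:
        x = (w.t - w.t[0]) / (w.t[-1] - w.t[0])
        grid = np.linspace(0.0, 1.0, _COMPARE_GRID)
        return np.interp(grid, x, w.p)

    pa, pb = resample(a), resample(b)
    rmse = float(np.sqrt(np.mean((pa - pb) ** 2)))
    # symmetric Pearson correlation: elementwise products keep the result
    # bitwise identical under argument exchange
    da, db = pa - np.mean(pa), pb - np.mean(pb)
    na, nb = float(np.sum(da * da)), float(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        raise InputError("constant waveform: correlation undefined")
    corr = float(np.sum(da * db)) / math.sqrt(na * nb)
    return {"rmse": rmse, "peak_corr": corr}
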