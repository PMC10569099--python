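"""Current-voltage and time-trace analysis for nanopipette sensors.

A charged conical nanopore passes more current at one bias polarity than the
other (ion current rectification, ICR).  The rectification coefficient

    r = log10( |I(+V)| / |I(-V)| )

is the standard single-number summary: its sign tracks the polarity of the
wall charge (negative for bare quartz or a DNA aptamer layer, positive after
aminosilane coating) and its magnitude the strength of the asymmetry.
Sensor responses are percent current changes at a fixed extraction bias
(+0.5 V by default), and detection limits follow the 3-sigma blank rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import V_EVAL_DEFAULT
from .errors import PreconditionError, RangeError, UndefinedRatioError

__all__ = [
    "IVCurve",
    "TimeTrace",
    "CalibrationSeries",
    "NOT_DETECTED",
    "rectification_coefficient",
    "sensor_response",
    "build_calibration",
    "detection_threshold",
    "limit_of_detection",
    "normalize_trace",
]

#: Sentinel returned by :func:`limit_of_detection` when no concentration
#: exceeds the blank threshold.
NOT_DETECTED = None


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise PreconditionError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise PreconditionError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class IVCurve:
    """One voltage sweep (or full CV cycle) of a nanopore sensor.

    Parameters
    ----------
    voltage : array of volts
    current : array of amperes
    label : free-text description (electrode state, analyte, ...).
    """

    voltage: np.ndarray
    current: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        v = _as_float_array(self.voltage, "voltage")
        i = _as_float_array(self.current, "current")
        if v.size != i.size:
            raise PreconditionError("voltage and current must have equal length")
        if v.size < 3:
            raise PreconditionError("an IV curve needs at least 3 samples")
        for lo, hi in _branch_slices(v):
            dv = np.diff(v[lo:hi])
            if not (np.all(dv > 0) or np.all(dv < 0)):
                raise PreconditionError("voltage must be strictly monotone within a branch")
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "current", i)


@dataclass(frozen=True)
class TimeTrace:
    """A real-time current recording with known injection times."""

    time: np.ndarray
    current: np.ndarray
    events: tuple = ()
    label: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = _as_float_array(self.time, "time")
        i = _as_float_array(self.current, "current")
        if t.size != i.size:
            raise PreconditionError("time and current must have equal length")
        if np.any(np.diff(t) <= 0):
            raise PreconditionError("time must be strictly increasing")
        ev = tuple(float(e) for e in self.events)
        if any(e < t[0] or e > t[-1] for e in ev):
            raise PreconditionError("events must lie within the recorded time range")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)
        object.__setattr__(self, "events", ev)


@dataclass(frozen=True)
class CalibrationSeries:
    """Concentration-response summary (mean/SD/SEM per concentration).

    Concentration 0 denotes the blank; responses are percent current changes.
    """

    concentration: np.ndarray  # mol/L, sorted ascending, >= 0
    mean_response: np.ndarray  # percent
    sd_response: np.ndarray  # percent
    n_replicates: np.ndarray  # counts
    label: str = ""

    def __post_init__(self):
        c = _as_float_array(self.concentration, "concentration")
        m = _as_float_array(self.mean_response, "mean_response")
        s = _as_float_array(self.sd_response, "sd_response")
        n = np.asarray(self.n_replicates, dtype=int)
        if not (c.size == m.size == s.size == n.size):
            raise PreconditionError("calibration arrays must have equal length")
        if np.any(c < 0):
            raise PreconditionError("concentrations must be non-negative")
        if np.any(np.diff(c) < 0):
            raise PreconditionError("concentrations must be sorted ascending")
        if np.any(s < 0) or np.any(n < 1):
            raise PreconditionError("sd >= 0 and n >= 1 required")
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "mean_response", m)
        object.__setattr__(self, "sd_response", s)
        object.__setattr__(self, "n_replicates", n)

    @property
    def sem_response(self) -> np.ndarray:
        return self.sd_response / np.sqrt(self.n_replicates)

    @property
    def has_blank(self) -> bool:
        return self.concentration.size > 0 and self.concentration[0] == 0.0


def _branch_slices(v: np.ndarray):
    """Split a CV voltage array into maximal monotone branches.

    Returns a list of (start, stop) index pairs; a plain monotone sweep is a
    single branch.
    """
    if v.size < 2:
        return [(0, v.size)]
    sign = np.sign(np.diff(v))
    out = []
    start = 0
    for k in range(1, sign.size):
        if sign[k] != 0 and sign[k] != sign[k - 1]:
            out.append((start, k + 1))
            start = k
    out.append((start, v.size))
    return out


def _interp_current(iv: IVCurve, v: float) -> float:
    """Current at bias ``v``, linearly interpolated; branch ties averaged."""
    vals = []
    for lo, hi in _branch_slices(iv.voltage):
        vb, ib = iv.voltage[lo:hi], iv.current[lo:hi]
        if vb[0] > vb[-1]:
            vb, ib = vb[::-1], ib[::-1]
        if vb[0] <= v <= vb[-1]:
            vals.append(float(np.interp(v, vb, ib)))
    if not vals:
        raise RangeError(f"bias {v:g} V outside the sweep range "
                         f"[{iv.voltage.min():g}, {iv.voltage.max():g}] V")
    return float(np.mean(vals))


def rectification_coefficient(iv: IVCurve, v_eval: float = V_EVAL_DEFAULT) -> float:
    """log10 of |I(+v_eval)| / |I(-v_eval)|.

    Negative r means transport is favoured at negative bias (negatively
    charged walls); currents at the two biases are linearly interpolated,
    averaging forward/backward CV branches where both cover the bias.
    """
    i_pos = _interp_current(iv, +abs(v_eval))
    i_neg = _interp_current(iv, -abs(v_eval))
    if i_pos == 0.0 or i_neg == 0.0:
        raise UndefinedRatioError("zero current at an evaluation bias; r is undefined")
    return math.log10(abs(i_pos) / abs(i_neg))


def sensor_response(iv_baseline: IVCurve, iv_target: IVCurve,
                    v_eval: float = V_EVAL_DEFAULT, magnitude: bool = False) -> float:
    """Percent current change at +v_eval between baseline and target sweeps.

    Negative values are current decreases (the dopamine direction), positive
    are increases (serotonin).  ``magnitude=True`` reports |response|, the
    convention used when quoting selectivity percentages.
    """
    i_base = _interp_current(iv_baseline, +abs(v_eval))
    i_tgt = _interp_current(iv_target, +abs(v_eval))
    if i_base == 0.0:
        raise UndefinedRatioError("zero baseline current; response is undefined")
    resp = 100.0 * (i_tgt - i_base) / abs(i_base)
    return abs(resp) if magnitude else resp


def build_calibration(responses: Mapping[float, Sequence[float]],
                      label: str = "") -> CalibrationSeries:
    """Collapse replicate percent responses per concentration into a series.

    SD is the sample standard deviation (ddof=1); a concentration with a
    single replicate gets SD 0.
    """
    if not responses:
        raise PreconditionError("empty response map")
    concs = sorted(float(c) for c in responses)
    means, sds, ns = [], [], []
    for c in concs:
        reps = np.asarray(list(responses[c]), dtype=float)
        if reps.size < 1:
            raise PreconditionError(f"no replicates for concentration {c:g}")
        means.append(reps.mean())
        sds.append(reps.std(ddof=1) if reps.size > 1 else 0.0)
        ns.append(reps.size)
    return CalibrationSeries(np.array(concs), np.array(means),
                             np.array(sds), np.array(ns), label=label)


def limit_of_detection(cal: CalibrationSeries):
    """3-sigma limit of detection from a calibration series.

    The threshold is |blank mean| + 3 * blank SD; the LOD is the lowest
    concentration whose mean response magnitude reaches the threshold,
    refined by linear interpolation of |response| against log10(concentration)
    between the bracketing points (detection limits live on a log axis).
    Returns :data:`NOT_DETECTED` if no concentration crosses.
    """
    if not cal.has_blank:
        raise PreconditionError("calibration series has no blank (zero concentration) entry")
    threshold = abs(cal.mean_response[0]) + 3.0 * cal.sd_response[0]
    conc = cal.concentration[1:]
    resp = np.abs(cal.mean_response[1:])
    above = resp > threshold
    if not np.any(above):
        return NOT_DETECTED
    k = int(np.argmax(above))  # first supra-threshold concentration
    if k == 0:
        return float(conc[0])
    c_lo, c_hi = conc[k - 1], conc[k]
    r_lo, r_hi = resp[k - 1], resp[k]
    if r_hi == r_lo:
        return float(c_hi)
    x = (threshold - r_lo) / (r_hi - r_lo)
    return float(10 ** (math.log10(c_lo) + x * (math.log10(c_hi) - math.log10(c_lo))))


def detection_threshold(cal: CalibrationSeries) -> float:
    """The 3-sigma blank threshold (percent) used by :func:`limit_of_detection`."""
    if not cal.has_blank:
        raise PreconditionError("calibration series has no blank (zero concentration) entry")
    return float(abs(cal.mean_response[0]) + 3.0 * cal.sd_response[0])


def normalize_trace(trace: TimeTrace, baseline_window: tuple | None = None) -> TimeTrace:
    """Divide a current trace by its baseline mean.

    ``baseline_window`` is a (start, end) pair in seconds; the default is all
    samples before the first injection event.  The normalized baseline mean
    is 1 by construction.
    """
    if baseline_window is None:
        if not trace.events:
            baseline_window = (trace.time[0], trace.time[-1])
        else:
            baseline_window = (trace.time[0], min(trace.events))
    t0, t1 = baseline_window
    mask = (trace.time >= t0) & (trace.time < t1)
    if mask.sum() < 2:
        raise PreconditionError("baseline window must contain at least 2 samples")
    base = float(trace.current[mask].mean())
    if base == 0.0:
        raise UndefinedRatioError("baseline mean current is zero")
    return TimeTrace(trace.time, trace.current / base, events=trace.events,
                     label=trace.label, metadata={**trace.metadata, "normalized": True})
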