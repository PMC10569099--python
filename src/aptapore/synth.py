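"""Seeded generators of synthetic sensor measurements.

The analyses in this package were developed against measurements that live
only in published figures, so every stage is exercised on synthetic data with
the same statistical structure: rectifying I-V sweeps with a controllable
rectification coefficient, stepwise QCM-D traces with drift, real-time
sensing traces with injection events, and saturating concentration-response
series with a detection floor.  All generators take an explicit integer seed
and are bit-for-bit reproducible; none touch global random state.

The rectifying I-V form I(V) = (V/R) * exp(alpha*V) is a test fixture, not a
physical model: it is the simplest strictly monotone curve whose
rectification coefficient at +-v_eval can be dialled exactly
(alpha = r_true*ln(10)/(2*v_eval)) while the slope at the origin stays 1/R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import V_EVAL_DEFAULT
from .errors import PreconditionError
from .iv import IVCurve, TimeTrace
from .qcmd import QcmdTrace

__all__ = [
    "GeneratorSpec",
    "gen_iv",
    "gen_qcmd_trace",
    "gen_realtime_trace",
    "gen_calibration",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Bundled truth parameters of a synthetic study, serializable to config.

    The defaults are the study conditions the analyses target: +-0.5 V
    sweeps, a 1 fM detection floor with saturation at 1 nM, and few-percent
    multiplicative noise.
    """

    seed: int = 0
    noise_sd: float = 0.02  # relative (Gaussian, multiplicative)
    r_true: float = -0.5
    R_true: float = 367e6  # ohms
    lod_floor: float = 1e-15  # mol/L
    saturation: float = 1e-9  # mol/L
    max_response: float = 11.0  # percent
    schedule: tuple = ()  # (time, size) injection pairs

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "noise_sd": self.noise_sd, "r_true": self.r_true,
            "R_true": self.R_true, "lod_floor": self.lod_floor,
            "saturation": self.saturation, "max_response": self.max_response,
            "schedule": [list(x) for x in self.schedule],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        d["schedule"] = tuple(tuple(x) for x in d.get("schedule", ()))
        return cls(**d)


def gen_iv(r_true: float, R_true: float, v_range: float = 0.5, n_points: int = 101,
           noise_sd: float = 0.0, seed: int = 0,
           v_eval: float = V_EVAL_DEFAULT, label: str = "") -> IVCurve:
    """Synthetic rectifying sweep over [-v_range, +v_range].

    Noiseless, ``rectification_coefficient(curve, v_eval)`` returns exactly
    ``r_true`` and the slope at the origin is 1/R_true.  ``noise_sd`` is the
    relative SD of multiplicative Gaussian noise.
    """
    if v_range <= 0 or n_points < 3:
        raise PreconditionError("need a positive symmetric range and >= 3 points")
    if noise_sd < 0:
        raise PreconditionError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    v = np.linspace(-v_range, v_range, n_points)
    alpha = r_true * math.log(10.0) / (2.0 * v_eval)
    i = (v / R_true) * np.exp(alpha * v)
    if noise_sd > 0:
        i = i * (1.0 + noise_sd * rng.standard_normal(i.shape))
    return IVCurve(v, i, label=label or f"synthetic r={r_true:g}")


def gen_qcmd_trace(steps: Sequence[tuple], drift: float = 0.0, noise_sd: float = 0.0,
                   seed: int = 0, duration: float = 600.0, dt: float = 1.0,
                   dD_per_Hz: float | None = None) -> QcmdTrace:
    """Stepwise QCM-D Δf trace: steps + linear drift + Gaussian noise.

    ``steps`` is a list of (time s, Δf Hz) injections; ``drift`` is Hz/s;
    ``noise_sd`` is the absolute SD in Hz.  With ``dD_per_Hz`` set, a ΔD
    channel proportional to the accumulated frequency steps is included
    (units of 1e-6 per Hz; adsorption of a rigid film has |ΔD/Δf| well below
    0.4e-6 per Hz).
    """
    times = [t for t, _ in steps]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise PreconditionError("step times must be increasing")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    f = np.full_like(t, 0.0)
    for t_step, df in steps:
        f[t >= t_step] += df
    dD = None if dD_per_Hz is None else dD_per_Hz * f
    f = f + drift * t
    if noise_sd > 0:
        f = f + noise_sd * rng.standard_normal(t.shape)
        if dD is not None:
            dD = dD + abs(dD_per_Hz) * noise_sd * rng.standard_normal(t.shape)
    return QcmdTrace(t, f, delta_D=dD, label="synthetic qcmd")


def gen_realtime_trace(I0: float, events: Sequence[tuple], noise_sd: float = 0.0,
                       seed: int = 0, duration: float = 300.0,
                       dt: float = 0.1) -> TimeTrace:
    """Real-time sensing trace: baseline I0 with multiplicative steps.

    ``events`` is a list of (time s, fractional step); a 100 uM dopamine
    injection is about -0.11, serotonin injections are positive.  Noise is
    multiplicative Gaussian with relative SD ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    i = np.full_like(t, float(I0))
    for t_ev, frac in events:
        i[t >= t_ev] *= (1.0 + frac)
    if noise_sd > 0:
        i = i * (1.0 + noise_sd * rng.standard_normal(t.shape))
    return TimeTrace(t, i, events=tuple(t_ev for t_ev, _ in events),
                     label="synthetic realtime")


def response_curve(conc: float, floor: float = 1e-15, saturation: float = 1e-9,
                   max_response: float = 11.0) -> float:
    """Noiseless mean response (percent) of the synthetic dose-response model.

    A logistic in log10(concentration) centred between the detection floor
    and the saturation level, hard-clipped to 0 below the floor.  The floor
    and saturation defaults are the fM-to-nM operating window of the
    aptamer-nanopipette sensors these fixtures emulate.  Not an equilibrium
    binding isotherm.
    """
    if floor >= saturation:
        raise PreconditionError("floor must lie below saturation")
    if conc < floor:
        return 0.0
    x = math.log10(conc)
    x_lo, x_hi = math.log10(floor), math.log10(saturation)
    x0 = 0.5 * (x_lo + x_hi)
    s = (x_hi - x_lo) / 12.0  # ~0 at the floor, ~max at saturation
    return max_response / (1.0 + math.exp(-(x - x0) / s))


def gen_calibration(concs: Sequence[float], floor: float = 1e-15,
                    saturation: float = 1e-9, max_response: float = 11.0,
                    n_reps: int = 5, noise_sd: float = 0.5, seed: int = 0,
                    scrambled: bool = False) -> dict:
    """Raw replicate percent responses per concentration (includes blanks).

    Returns a map concentration -> list of replicate responses suitable for
    :func:`aptapore.iv.build_calibration`.  ``noise_sd`` is the absolute
    replicate SD in percent.  ``scrambled=True`` emulates the
    scrambled-sequence control sensor: pure noise at every concentration.
    """
    if n_reps < 1:
        raise PreconditionError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for c in concs:
        if c < 0:
            raise PreconditionError("concentrations must be non-negative")
        mean = 0.0 if (scrambled or c == 0.0) else response_curve(
            c, floor=floor, saturation=saturation, max_response=max_response)
        out[float(c)] = list(mean + noise_sd * rng.standard_normal(n_reps))
    return out
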