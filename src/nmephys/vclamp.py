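"""Voltage-clamp sweep handling: traces, protocols, steady-state currents, I-V curves.

Units throughout the package: mV, ms, pA, nS, pF, MΩ (1 nS · mV = 1 pA).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List

import numpy as np

__all__ = [
    "Trace",
    "VClampProtocol",
    "SweepFamily",
    "IVCurve",
    "correct_junction_potential",
    "steady_state_current",
    "build_iv_curve",
]

DEFAULT_LJP = -10.0  # liquid junction potential, mV; corrected = nominal + LJP


@dataclass
class Trace:
    """One sampled signal (current in pA or voltage in mV) on a uniform time base.

    Parameters
    ----------
    signal : array
        Sample values, pA for ``kind="current"``, mV for ``kind="voltage"``.
    dt : float
        Sampling interval in ms (uniform grid starting at t = 0).
    kind : {"current", "voltage"}
    """

    signal: np.ndarray
    dt: float
    kind: str = "current"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size < 2:
            raise ValueError("trace needs >= 2 samples on one axis")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError("sampling interval must be positive")
        if self.kind not in ("current", "voltage"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def time(self) -> np.ndarray:
        """Time base in ms (t = 0 at the first sample)."""
        return np.arange(self.signal.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.signal.size - 1) * self.dt

    def resampled(self, factor: int) -> "Trace":
        """Linear-interpolation resampling at `factor`× the rate (test utility)."""
        t = self.time
        t2 = np.arange(0.0, t[-1] + self.dt / factor / 2, self.dt / factor)
        t2 = t2[t2 <= t[-1] + 1e-12]
        return Trace(np.interp(t2, t, self.signal), self.dt / factor, self.kind)


@dataclass
class VClampProtocol:
    """Family of square voltage commands from a common holding potential.

    `levels` are nominal command voltages (mV); the liquid junction potential
    `ljp` is added exactly once when an I-V curve is built (`ljp_applied`
    guards against double correction).
    """

    holding: float = -70.0
    levels: np.ndarray = field(default_factory=lambda: np.arange(-100.0, 20.0 + 1e-9, 5.0))
    duration: float = 150.0
    ljp: float = DEFAULT_LJP
    ljp_applied: bool = False
    dt: float = 0.1

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.size == 0:
            raise ValueError("protocol has no command levels")
        if self.levels.size > 1 and np.any(np.diff(self.levels) <= 0):
            raise ValueError("command levels must be strictly ascending")
        if self.duration <= 10.0:
            raise ValueError("command duration must exceed 10 ms")

    @property
    def increment(self) -> float:
        return float(np.diff(self.levels)[0]) if self.levels.size > 1 else 0.0


def correct_junction_potential(levels: Iterable[float], ljp: float = DEFAULT_LJP) -> np.ndarray:
    """Shift nominal command voltages by the liquid junction potential.

    corrected = nominal + ljp (ljp = −10 mV by default), order preserved.
    """
    if not np.isfinite(ljp):
        raise ValueError("ljp must be finite")
    return np.asarray(levels, dtype=float) + ljp


@dataclass
class SweepFamily:
    """One current trace per command level, sharing a time base."""

    sweeps: Dict[float, Trace]
    protocol: VClampProtocol

    def __post_init__(self) -> None:
        missing = [lv for lv in self.protocol.levels if float(lv) not in self.sweeps]
        if missing:
            raise ValueError(f"missing sweeps for declared levels: {missing}")
        sizes = {tr.signal.size for tr in self.sweeps.values()}
        dts = {tr.dt for tr in self.sweeps.values()}
        if len(sizes) > 1 or len(dts) > 1:
            raise ValueError("all sweeps must share one time base")

    def with_offset(self, offset_pa: float) -> "SweepFamily":
        """Copy with a constant current offset added to every sweep (test utility)."""
        sweeps = {
            lv: Trace(tr.signal + offset_pa, tr.dt, tr.kind) for lv, tr in self.sweeps.items()
        }
        return SweepFamily(sweeps, replace(self.protocol))


@dataclass
class IVCurve:
    """Steady-state current (pA) versus junction-corrected command voltage (mV)."""

    V: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.V.shape != self.I.shape or self.V.ndim != 1:
            raise ValueError("V and I must be 1-D arrays of equal length")
        if self.V.size > 1 and np.any(np.diff(self.V) <= 0):
            raise ValueError("V must be strictly ascending")

    def __len__(self) -> int:
        return self.V.size


def steady_state_current(
    trace: Trace,
    duration: float,
    end_offset: float = 3.0,
    width: float = 1.0,
) -> float:
    """Mean current over a late window of a square voltage command.

    The window is the half-open interval
    ``[duration − end_offset, duration − end_offset + width)`` — by default
    1 ms of samples beginning 3 ms before the command ends (so a 150 ms
    command is averaged over [147, 148) ms).  Window endpoints are resolved
    to the nearest sample of the trace grid.
    """
    if duration - end_offset - width < -1e-9:
        raise ValueError("window does not fit inside the command")
    start = duration - end_offset
    i0 = int(round(start / trace.dt))
    i1 = int(round((start + width) / trace.dt))
    if i0 < 0 or i1 > trace.signal.size or i1 <= i0:
        raise ValueError("averaging window lies outside the trace extent")
    return float(np.mean(trace.signal[i0:i1]))


def build_iv_curve(
    family: SweepFamily,
    end_offset: float = 3.0,
    width: float = 1.0,
) -> IVCurve:
    """Assemble the junction-corrected I-V curve from a voltage-clamp family.

    Junction correction is applied exactly once (guarded by the protocol's
    ``ljp_applied`` flag); the steady-state current of each sweep is the late
    1 ms window mean.
    """
    proto = family.protocol
    if not family.sweeps:
        raise ValueError("empty sweep family")
    nominal = proto.levels
    corrected = nominal if proto.ljp_applied else correct_junction_potential(nominal, proto.ljp)
    currents = [
        steady_state_current(family.sweeps[float(lv)], proto.duration, end_offset, width)
        for lv in nominal
    ]
    order = np.argsort(corrected)
    return IVCurve(corrected[order], np.asarray(currents)[order])
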