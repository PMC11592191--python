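"""Current-clamp analysis: action-potential features and passive membrane properties.

Active properties come from suprathreshold square current injections: the
latency to the first AP peak, the maximum positive dV/dt (rise rate) and the
maximum negative dV/dt (repolarization rate) during the AP, and the peak
amplitude, averaged across repetitions that contain a spike.  The current
threshold I_T is the lowest injected amplitude that evokes an AP on at least
half of the repetitions (5 or more of 10); suprathreshold stimulation is
1.25 · I_T.

Passive properties come from a −10 pA step: the membrane time constant from a
single-exponential fit to the first 10 ms (5 ms for E20–21 cells) of the
response, the input resistance from the late steady-state voltage change, and
the capacitance through C = τ/R.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .vclamp import Trace

__all__ = [
    "Detection",
    "APEvent",
    "APFeatures",
    "ThresholdResult",
    "PassiveProps",
    "detect_aps",
    "ap_features",
    "find_current_threshold",
    "mean_suprathreshold_features",
    "passive_properties",
    "SUPRATHRESHOLD_FACTOR",
]

SUPRATHRESHOLD_FACTOR = 1.25  # suprathreshold stimulus = 25% above I_T
BASELINE_WINDOW_MS = 20.0  # RMP = mean of this much pre-onset trace
FIT_BLANK_MS = 0.1  # post-onset blanking before the exponential fit


@dataclass(frozen=True)
class Detection:
    """Spike-detector settings (the recordings themselves don't define one).

    An AP is a local voltage peak above `peak_min` preceded by an upward
    dV/dt crossing of `dvdt_min`.
    """

    peak_min: float = -20.0  # mV
    dvdt_min: float = 10.0  # mV/ms
    min_separation: float = 1.0  # ms between distinct peaks
    prominence: float = 10.0  # mV


@dataclass
class APEvent:
    """One detected action potential: peak time/value and window extent."""

    t_peak: float
    v_peak: float
    i_start: int
    i_peak: int
    i_end: int


@dataclass
class APFeatures:
    """Active-property summary of (the first AP of) a sweep or sweep average."""

    latency: float  # ms, stimulus onset -> AP peak
    rise_rate: float  # mV/ms, max positive dV/dt
    repol_rate: float  # mV/ms, max negative dV/dt (negative number)
    peak_amplitude: float  # mV
    n_spikes: int
    n_contributing: int = 1  # repetitions averaged (for across-trace means)

    def __post_init__(self) -> None:
        if self.n_spikes >= 1:
            if not self.rise_rate > 0:
                raise ValueError("rise rate must be positive when a spike is present")
            if not self.repol_rate < 0:
                raise ValueError("repolarization rate must be negative when a spike is present")


@dataclass
class ThresholdResult:
    """Outcome of the current-threshold search.

    ``I_T`` is None when no tested amplitude satisfied the rule (an explicit
    no-threshold result, not an error).
    """

    I_T: Optional[float]
    spike_counts_per_level: Dict[float, tuple]  # amplitude -> (n_spiking, n_reps)

    @property
    def suprathreshold_amplitude(self) -> Optional[float]:
        return None if self.I_T is None else SUPRATHRESHOLD_FACTOR * self.I_T


@dataclass
class PassiveProps:
    """Passive membrane properties from a −10 pA step."""

    tau: float  # ms
    R_in: float  # MΩ
    C_m: float  # pF (= 1000 * tau/R_in with tau in ms, R in MΩ)
    fit_window: float  # ms of post-onset trace used for the exponential fit
    rmp: float  # mV

    def __post_init__(self) -> None:
        if abs(self.C_m - 1000.0 * self.tau / self.R_in) > 1e-9 * max(abs(self.C_m), 1.0):
            raise ValueError("capacitance must satisfy C = tau/R")


def _dvdt(trace: Trace) -> np.ndarray:
    """Central-difference dV/dt (mV/ms) on the native grid."""
    return np.gradient(trace.signal, trace.dt)


def detect_aps(trace: Trace, detection: Detection = Detection()) -> List[APEvent]:
    """Detect action potentials in a voltage trace.

    Candidate peaks (above `peak_min`, separated by `min_separation`, with the
    required prominence) are kept when the preceding 2 ms contains an upward
    dV/dt crossing of `dvdt_min`.  Event windows span from that crossing to
    the post-peak sample where dV/dt decays back above −1 mV/ms, clipped at
    neighbouring events; windows never overlap.  Deterministic; returns an
    empty list when nothing fires.
    """
    if trace.kind != "voltage":
        raise ValueError("AP detection requires a voltage trace")
    v = trace.signal
    dv = _dvdt(trace)
    dist = max(int(round(detection.min_separation / trace.dt)), 1)
    peaks, _ = find_peaks(v, height=detection.peak_min, distance=dist, prominence=detection.prominence)

    look_back = max(int(round(2.0 / trace.dt)), 2)
    look_forward = max(int(round(5.0 / trace.dt)), 2)
    events: List[APEvent] = []
    for pk in peaks:
        lo = max(pk - look_back, 0)
        seg = dv[lo : pk + 1]
        above = np.nonzero(seg >= detection.dvdt_min)[0]
        if above.size == 0:
            continue
        i_start = lo + int(above[0])
        # repolarization window: up to 5 ms past the peak (clipped below at
        # the next event's rise so windows never overlap)
        i_end = min(pk + look_forward, v.size - 1)
        if events and i_start <= events[-1].i_end:
            events[-1].i_end = i_start - 1
        events.append(APEvent(pk * trace.dt, float(v[pk]), i_start, int(pk), i_end))
    return events


def ap_features(
    trace: Trace, onset: float, detection: Detection = Detection()
) -> APFeatures:
    """Extract active properties from the first AP of a suprathreshold sweep.

    Latency is the time from stimulus onset to the AP peak; rise and
    repolarization rates are the extreme finite-difference dV/dt values
    within the AP window.
    """
    events = detect_aps(trace, detection)
    if not events:
        raise ValueError("no action potential detected")
    ev = events[0]
    dv = _dvdt(trace)
    rise = float(np.max(dv[ev.i_start : ev.i_peak + 1]))
    repol = float(np.min(dv[ev.i_peak : ev.i_end + 1]))
    return APFeatures(
        latency=ev.t_peak - onset,
        rise_rate=rise,
        repol_rate=repol,
        peak_amplitude=ev.v_peak,
        n_spikes=len(events),
    )


def find_current_threshold(
    sweeps: Mapping[float, Sequence[Trace]],
    detection: Detection = Detection(),
) -> ThresholdResult:
    """Lowest injected amplitude that spikes on at least half the repetitions.

    With the standard 10 repetitions this is the "5 or more out of 10" rule;
    with fewer repetitions the rule generalizes proportionally (≥ 50%).
    Amplitudes are scanned in ascending order; when no amplitude qualifies an
    explicit no-threshold result is returned.
    """
    counts: Dict[float, tuple] = {}
    i_t: Optional[float] = None
    for amp in sorted(sweeps):
        reps = sweeps[amp]
        n_spiking = sum(1 for tr in reps if detect_aps(tr, detection))
        counts[float(amp)] = (n_spiking, len(reps))
        if i_t is None and len(reps) > 0 and n_spiking >= 0.5 * len(reps):
            i_t = float(amp)
    return ThresholdResult(i_t, counts)


def mean_suprathreshold_features(
    reps: Sequence[Trace], onset: float, detection: Detection = Detection()
) -> APFeatures:
    """Arithmetic mean of per-repetition AP features at 1.25·I_T.

    Only repetitions containing a detected AP contribute; their count is
    reported on the result.
    """
    per_rep = []
    for tr in reps:
        try:
            per_rep.append(ap_features(tr, onset, detection))
        except ValueError:
            continue
    if not per_rep:
        raise ValueError("no repetition contained a detected action potential")
    return APFeatures(
        latency=float(np.mean([f.latency for f in per_rep])),
        rise_rate=float(np.mean([f.rise_rate for f in per_rep])),
        repol_rate=float(np.mean([f.repol_rate for f in per_rep])),
        peak_amplitude=float(np.mean([f.peak_amplitude for f in per_rep])),
        n_spikes=int(round(np.mean([f.n_spikes for f in per_rep]))),
        n_contributing=len(per_rep),
    )


def passive_properties(
    trace: Trace,
    onset: float,
    duration: float = 100.0,
    age: str = "E13",
    current: float = -10.0,
) -> PassiveProps:
    """Passive membrane properties from a small negative current step.

    τ from a least-squares single-exponential fit
    V(t) = V_ss + ΔV·exp(−(t−onset)/τ) over the first 10 ms after onset
    (5 ms for E20–21 cells), with a 0.1 ms post-onset blank against stimulus
    artifacts; R_in from the voltage change averaged over the last 5 ms of
    the injection divided by the injected current; C = τ/R.  RMP is the mean
    of the 20 ms preceding onset.
    """
    if current >= 0:
        raise ValueError("passive protocol expects a negative current step")
    fit_window = 5.0 if age == "E20_21" else 10.0
    t = trace.time
    n = trace.signal.size
    if onset + duration > t[-1] + 1e-9:
        raise ValueError("step extends past the trace")

    base_mask = (t >= onset - BASELINE_WINDOW_MS) & (t < onset)
    if not np.any(base_mask):
        raise ValueError("no pre-onset baseline available")
    rmp = float(np.mean(trace.signal[base_mask]))

    ss_mask = (t >= onset + duration - 5.0) & (t < onset + duration)
    v_ss = float(np.mean(trace.signal[ss_mask]))
    dv = v_ss - rmp
    if dv >= 0:
        raise ValueError("positive-going response to a negative current step")
    r_in = dv / current * 1000.0  # mV/pA = GΩ -> MΩ

    fit_mask = (t >= onset + FIT_BLANK_MS) & (t <= onset + fit_window)
    tf = t[fit_mask] - onset
    vf = trace.signal[fit_mask]

    # the asymptote is pinned to the measured steady state: the short fit
    # window (about one time constant) cannot constrain a free asymptote,
    # while the late-step average estimates it to high precision
    def model(tt, delta, tau):
        return v_ss + delta * np.exp(-tt / tau)

    popt, _ = curve_fit(
        model,
        tf,
        vf,
        p0=(rmp - v_ss, fit_window / 3.0),
        bounds=([0.0, 1e-3], [150.0, 500.0]),
        maxfev=10000,
    )
    tau = float(popt[1])
    return PassiveProps(
        tau=tau,
        R_in=r_in,
        C_m=1000.0 * tau / r_in,
        fit_window=fit_window,
        rmp=rmp,
    )
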