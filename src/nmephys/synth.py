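"""Synthetic single-compartment conductance-model recordings.

Generates voltage-clamp and current-clamp sweep families from a neuron model
with two Boltzmann-activated potassium conductances (LVA, Kv1-like; HVA,
Kv3-like), a leak, and a minimal m³h sodium mechanism for spiking, so that
every downstream analysis stage is testable against known ground truth.

Two conventions are supported for the steady-state K⁺ I-V (``iv_form``):

* ``"ohmic"`` — chord form  G_max · P_O(V) · (V − E_K): the textbook
  conductance equation.
* ``"boltzmann_slope"`` — the current whose *differential* conductance is
  exactly G_max · P_O(V) (the antiderivative of the Boltzmann sigmoid,
  referenced so the channel current vanishes at E_K).  Condition presets use
  this form because the study's fitted G_max is a differential-conductance
  maximum, so the generator's G_max must carry the same meaning for
  parameter-recovery to be well-posed.

Current-clamp dynamics always use chord conductances with first-order gates
(dynamics require a conductance, not an I-V template); ``iv_form`` only
selects the voltage-clamp steady-state target.

Units: mV, ms, pA, nS, pF (1 nS·mV = 1 pA; pA/pF = mV/ms).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .vclamp import SweepFamily, Trace, VClampProtocol

__all__ = [
    "BoltzmannChannel",
    "SpikeParams",
    "ChannelParams",
    "ConditionSpec",
    "CurrentStep",
    "SimulatedNeuron",
    "Cohort",
    "steady_state_model_current",
    "simulate_vclamp_family",
    "simulate_cclamp_trace",
    "resting_potential",
    "make_cohort",
    "e13_high_freq_base",
    "condition_presets",
]

# integration step for current clamp (ms); recording grids may be coarser
DT_INTEGRATION = 0.01


@dataclass
class BoltzmannChannel:
    """One Boltzmann-activated K⁺ conductance (steady state + first-order gate)."""

    G_max: float  # nS
    V50: float  # mV
    K: float  # mV, > 0
    B: float = 0.0  # baseline open fraction in [0, 1)
    tau: float = 3.0  # activation time constant, ms (<= 5 so 147 ms is >= 28 tau)

    def __post_init__(self) -> None:
        if self.G_max < 0:
            raise ValueError("G_max must be >= 0")
        if self.K <= 0:
            raise ValueError("slope factor K must be > 0")
        if not 0.0 <= self.B < 1.0:
            raise ValueError("B must lie in [0, 1)")
        if self.tau <= 0:
            raise ValueError("activation tau must be > 0")

    def p_inf(self, V):
        return self.B + (1.0 - self.B) * expit((np.asarray(V, dtype=float) - self.V50) / self.K)


@dataclass
class SpikeParams:
    """Minimal Hodgkin–Huxley-style Na conductance (m³h). Fixture, not a claim."""

    g_na: float = 1000.0  # nS
    E_na: float = 50.0  # mV
    act_v50: float = -45.0
    act_k: float = 4.0
    inact_v50: float = -52.0
    inact_k: float = 5.0
    tau_m: float = 0.05  # ms
    tau_h: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.g_na < 0:
            raise ValueError("g_na must be >= 0")
        if self.act_k <= 0 or self.inact_k <= 0 or self.tau_m <= 0 or self.tau_h <= 0:
            raise ValueError("slope factors and time constants must be > 0")

    def m_inf(self, V):
        return expit((np.asarray(V, dtype=float) - self.act_v50) / self.act_k)

    def h_inf(self, V):
        return expit(-(np.asarray(V, dtype=float) - self.inact_v50) / self.inact_k)


@dataclass
class ChannelParams:
    """Ground-truth generator parameters for one model neuron."""

    g_leak: float = 1.2  # nS
    E_leak: float = -72.0  # mV
    E_K: float = -90.0  # mV
    lva: BoltzmannChannel = field(default_factory=lambda: BoltzmannChannel(20.19, -50.0, 5.0))
    hva: BoltzmannChannel = field(
        default_factory=lambda: BoltzmannChannel(72.76, -3.0, 7.0, tau=1.5)
    )
    spike: SpikeParams = field(default_factory=SpikeParams)
    C_m: float = 50.0  # pF
    noise_sd_current: float = 10.0  # pA, recording noise in voltage clamp
    noise_sd_voltage: float = 0.3  # mV, recording noise in current clamp
    iv_form: str = "ohmic"  # "ohmic" | "boltzmann_slope"

    def __post_init__(self) -> None:
        if self.g_leak < 0 or self.C_m <= 0:
            raise ValueError("g_leak must be >= 0 and C_m > 0")
        if self.noise_sd_current < 0 or self.noise_sd_voltage < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.iv_form not in ("ohmic", "boltzmann_slope"):
            raise ValueError(f"unknown iv_form {self.iv_form!r}")


def _channel_ss_current(chan: BoltzmannChannel, V, E_K: float, iv_form: str):
    """Steady-state channel current (pA) at command voltage V."""
    V = np.asarray(V, dtype=float)
    if iv_form == "ohmic":
        return chan.G_max * chan.p_inf(V) * (V - E_K)
    # antiderivative of G_max * P_O, referenced to zero at E_K
    K = chan.K
    lse = K * (np.logaddexp(V / K, chan.V50 / K) - np.logaddexp(E_K / K, chan.V50 / K))
    return chan.G_max * (chan.B * (V - E_K) + (1.0 - chan.B) * lse)


def steady_state_model_current(params: ChannelParams, V) -> np.ndarray:
    """Noise-free steady-state membrane current (pA) at command voltage V.

    leak + LVA + HVA; the Na mechanism is inactivated at steady state and
    contributes nothing (its steady m³h product is treated as zero, matching
    recordings where Na currents are transient or negligible at the late
    window).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("command voltage must be finite")
    i = params.g_leak * (V - params.E_leak)
    for chan in (params.lva, params.hva):
        i = i + _channel_ss_current(chan, V, params.E_K, params.iv_form)
    return i if i.ndim else float(i)


def simulate_vclamp_family(
    params: ChannelParams,
    protocol: Optional[VClampProtocol] = None,
    seed: int = 0,
) -> SweepFamily:
    """Simulate a voltage-clamp sweep family (one current trace per level).

    Each channel's current relaxes first-order (time constant `tau`) from its
    holding-potential activation toward the steady-state value at the command
    level; leak is instantaneous.  I.i.d. Gaussian recording noise of SD
    ``noise_sd_current`` is added.  The same seed reproduces the family
    bit-for-bit.
    """
    protocol = protocol or VClampProtocol()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.duration + 1e-9, protocol.dt)
    # the membrane sees the junction-corrected voltage; nominal levels are
    # what the protocol reports (unless it is already corrected)
    shift = 0.0 if protocol.ljp_applied else protocol.ljp
    hold = protocol.holding + shift
    sweeps: Dict[float, Trace] = {}
    for lv in protocol.levels:
        v_true = lv + shift
        i_t = params.g_leak * (v_true - params.E_leak) * np.ones_like(t)
        for chan in (params.lva, params.hva):
            i_ss = float(_channel_ss_current(chan, v_true, params.E_K, params.iv_form))
            p_lv = float(chan.p_inf(v_true))
            r0 = float(chan.p_inf(hold)) / p_lv if p_lv > 1e-12 else 0.0
            i_t = i_t + i_ss * (1.0 + (r0 - 1.0) * np.exp(-t / chan.tau))
        if params.noise_sd_current > 0:
            i_t = i_t + rng.normal(0.0, params.noise_sd_current, size=t.size)
        sweeps[float(lv)] = Trace(i_t, protocol.dt, "current")
    return SweepFamily(sweeps, protocol)


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------


@dataclass
class CurrentStep:
    """Square current injection: `amplitude` pA from `onset` for `duration` ms."""

    amplitude: float
    onset: float = 20.0
    duration: float = 100.0
    post: float = 10.0  # recorded tail after the step, ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.onset < 0 or self.post < 0:
            raise ValueError("onset and post must be >= 0")

    @property
    def total(self) -> float:
        return self.onset + self.duration + self.post


def _ionic_current(params: ChannelParams, V, p_l, p_h, m, h):
    """Total ionic membrane current (pA) in the chord-conductance dynamics."""
    i = params.g_leak * (V - params.E_leak)
    i = i + params.lva.G_max * p_l * (V - params.E_K)
    i = i + params.hva.G_max * p_h * (V - params.E_K)
    i = i + params.spike.g_na * (m**3) * h * (V - params.spike.E_na)
    return i


def resting_potential(params: ChannelParams) -> float:
    """Zero-current resting potential of the chord-conductance dynamics (mV)."""

    def f(v: float) -> float:
        return _ionic_current(
            params,
            v,
            params.lva.p_inf(v),
            params.hva.p_inf(v),
            params.spike.m_inf(v),
            params.spike.h_inf(v),
        )

    # bracket the lowest zero crossing on a coarse grid; a wide bracket can
    # fail outright when the Na window current dominates at its upper end
    grid = np.arange(-110.0, -29.0, 1.0)
    vals = np.array([f(v) for v in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:  # pragma: no cover - pathological parameter sets
        raise ValueError("no resting potential in [-110, -30] mV")
    j = sign_change[0]
    return float(brentq(f, grid[j], grid[j + 1], xtol=1e-10))


def _integrate_batch(
    params: ChannelParams,
    amplitudes: np.ndarray,
    step: CurrentStep,
    dt: float = DT_INTEGRATION,
    record_dt: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Forward-Euler integration of C_m dV/dt = −I_ion + I_inj for a batch of
    amplitudes sharing one stimulus timing.  Returns (V[n_amp, n_rec], record_dt).

    The integration step is fixed (≤ 0.01 ms by default); the recorded grid
    may subsample it.  Deterministic — recording noise is added by callers.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if record_dt is None:
        record_dt = dt
    stride = max(int(round(record_dt / dt)), 1)
    record_dt = stride * dt

    n_steps = int(round(step.total / dt))
    n_rec = n_steps // stride + 1
    v0 = resting_potential(params)

    V = np.full(amplitudes.shape, v0)
    p_l = np.asarray(params.lva.p_inf(V))
    p_h = np.asarray(params.hva.p_inf(V))
    m = np.asarray(params.spike.m_inf(V))
    h = np.asarray(params.spike.h_inf(V))

    out = np.empty((amplitudes.size, n_rec))
    out[:, 0] = V
    i_on = int(round(step.onset / dt))
    i_off = int(round((step.onset + step.duration) / dt))

    lva, hva, spk = params.lva, params.hva, params.spike
    a_l = dt / lva.tau
    a_h = dt / hva.tau
    a_m = dt / spk.tau_m
    a_hh = dt / spk.tau_h
    rec = 1
    for k in range(1, n_steps + 1):
        i_inj = amplitudes if i_on < k <= i_off else 0.0
        dv = (i_inj - _ionic_current(params, V, p_l, p_h, m, h)) / params.C_m
        V = V + dt * dv
        if not np.all(np.isfinite(V)):
            raise FloatingPointError("non-finite membrane potential during integration")
        p_l = p_l + a_l * (lva.p_inf(V) - p_l)
        p_h = p_h + a_h * (hva.p_inf(V) - p_h)
        m = m + a_m * (spk.m_inf(V) - m)
        h = h + a_hh * (spk.h_inf(V) - h)
        if k % stride == 0:
            out[:, rec] = V
            rec += 1
    return out[:, :rec], record_dt


def simulate_cclamp_trace(
    params: ChannelParams,
    stim: CurrentStep,
    seed: int = 0,
    dt: float = DT_INTEGRATION,
    record_dt: Optional[float] = None,
) -> Trace:
    """Simulate one current-clamp voltage trace for a square current step.

    Subthreshold negative steps charge mono-exponentially (RC behaviour when
    the spike and K conductances are zeroed); suprathreshold steps fire.
    Gaussian recording noise of SD ``noise_sd_voltage`` is added to the
    recorded samples; the same seed gives an identical trace.
    """
    v, rdt = _integrate_batch(params, np.array([stim.amplitude]), stim, dt, record_dt)
    sig = v[0]
    if params.noise_sd_voltage > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, params.noise_sd_voltage, size=sig.size)
    return Trace(sig, rdt, "voltage")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class ConditionSpec:
    """One experimental condition as a generator parameter set.

    ``scale_lva``/``scale_hva`` multiply the base channel G_max; they encode
    the observed condition effects (e.g. the BDNF-induced conductance
    reduction in early high-frequency neurons).  Per-neuron biological
    variability is log-normal on conductances and capacitance with the given
    coefficients of variation.
    """

    name: str
    age: str = "E13"  # "E13" | "E20_21"
    region: str = "high_freq"  # "high_freq" | "low_freq"
    scale_lva: float = 1.0
    scale_hva: float = 1.0
    rmp_mean: float = -65.0
    rmp_sd: float = 1.2
    n_neurons: int = 16
    cv_lva: float = 0.18
    cv_hva: float = 0.30
    cv_leak: float = 0.20
    cv_cm: float = 0.10

    def __post_init__(self) -> None:
        if self.scale_lva <= 0 or self.scale_hva <= 0:
            raise ValueError("condition multipliers must be > 0")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.age not in ("E13", "E20_21"):
            raise ValueError(f"unknown age {self.age!r}")
        if self.region not in ("high_freq", "low_freq"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class SimulatedNeuron:
    """One synthetic neuron: metadata, ground truth, and raw sweep families."""

    neuron_id: str
    embryo_id: str
    age: str
    region: str
    condition: str
    params: ChannelParams  # ground truth (post-jitter, post-scaling)
    rmp: float  # mV, resting potential of the model
    series_resistance: float  # MΩ, recording metadata for QC
    seed: int
    vclamp: Optional[SweepFamily] = None
    passive_reps: List[Trace] = field(default_factory=list)  # −10 pA steps
    ladder_reps: Dict[float, List[Trace]] = field(default_factory=dict)
    passive_step: Optional[CurrentStep] = None
    ladder_step: Optional[CurrentStep] = None


@dataclass
class Cohort:
    """A condition's worth of simulated neurons; a pure function of (spec, base, seed)."""

    neurons: List[SimulatedNeuron]
    spec: ConditionSpec
    base: ChannelParams
    seed: int


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with the requested arithmetic mean and CV (right-skewed,
    strictly positive — the natural shape for conductances)."""
    if cv <= 0 or mean <= 0:
        return mean
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


MAX_CELLS_PER_EMBRYO = 6
_CELLS_PER_EMBRYO = 5  # grouping used when assigning neurons to embryos


def _jitter_neuron(
    base: ChannelParams, spec: ConditionSpec, rng: np.random.Generator
) -> ChannelParams:
    p = replace(
        base,
        g_leak=_lognormal(rng, base.g_leak, spec.cv_leak),
        C_m=_lognormal(rng, base.C_m, spec.cv_cm),
        lva=replace(base.lva, G_max=_lognormal(rng, base.lva.G_max, spec.cv_lva) * spec.scale_lva),
        hva=replace(base.hva, G_max=_lognormal(rng, base.hva.G_max, spec.cv_hva) * spec.scale_hva),
    )
    # pin the resting potential to the condition's RMP distribution by
    # solving for the leak reversal that balances the other currents there
    v_t = rng.normal(spec.rmp_mean, spec.rmp_sd)
    i_other = _ionic_current(
        p, v_t, p.lva.p_inf(v_t), p.hva.p_inf(v_t), p.spike.m_inf(v_t), p.spike.h_inf(v_t)
    ) - p.g_leak * (v_t - p.E_leak)
    return replace(p, E_leak=v_t + i_other / p.g_leak)


def make_cohort(
    spec: ConditionSpec,
    base: Optional[ChannelParams] = None,
    seed: int = 0,
    vclamp_protocol: Optional[VClampProtocol] = None,
    include_cclamp: bool = True,
    ladder_amplitudes: Optional[Sequence[float]] = None,
    n_reps: int = 10,
) -> Cohort:
    """Generate a cohort of simulated neurons for one condition.

    Per-neuron parameters are jittered log-normally around `base`, channel
    G_max values are multiplied by the condition's scale factors, and full
    voltage-clamp (and optionally current-clamp) sweep families are attached.
    Child seeds are derived deterministically from (seed, neuron index), so
    regeneration with the same arguments is bit-identical.
    """
    base = base or e13_high_freq_base()
    # commands extended to +30 mV nominal so the junction-corrected axis
    # reaches +20 mV (the protocol's "or more" headroom)
    protocol = vclamp_protocol or VClampProtocol(levels=np.arange(-100.0, 30.0 + 1e-9, 5.0))
    if ladder_amplitudes is None:
        ladder_amplitudes = np.arange(10.0, 250.0 + 1e-9, 10.0)
    passive_step = CurrentStep(-10.0, onset=20.0, duration=100.0, post=10.0)
    ladder_step = CurrentStep(0.0, onset=20.0, duration=100.0, post=10.0)

    neurons: List[SimulatedNeuron] = []
    for i in range(spec.n_neurons):
        rng = np.random.default_rng([seed, i])
        child_seed = int(rng.integers(0, 2**31 - 1))
        p = _jitter_neuron(base, spec, rng)
        rs = _lognormal(rng, 6.5, 0.35)  # series resistance, MΩ; a tail exceeds 10

        neuron = SimulatedNeuron(
            neuron_id=f"{spec.name}_{i:03d}",
            embryo_id=f"{spec.name}_emb{i // _CELLS_PER_EMBRYO:02d}",
            age=spec.age,
            region=spec.region,
            condition=spec.name,
            params=p,
            rmp=resting_potential(p),
            series_resistance=rs,
            seed=child_seed,
            vclamp=simulate_vclamp_family(p, protocol, seed=child_seed),
            passive_step=passive_step,
            ladder_step=ladder_step,
        )
        if include_cclamp:
            nrng = np.random.default_rng([child_seed, 1])
            v_pass, rdt = _integrate_batch(
                p, np.array([passive_step.amplitude]), passive_step, record_dt=0.02
            )
            neuron.passive_reps = [
                Trace(v_pass[0] + nrng.normal(0.0, p.noise_sd_voltage, v_pass.shape[1]), rdt, "voltage")
                for _ in range(n_reps)
            ]
            amps = np.asarray(ladder_amplitudes, dtype=float)
            v_lad, rdt_l = _integrate_batch(p, amps, ladder_step, record_dt=0.05)
            neuron.ladder_reps = {
                float(a): [
                    Trace(
                        v_lad[j] + nrng.normal(0.0, p.noise_sd_voltage, v_lad.shape[1]),
                        rdt_l,
                        "voltage",
                    )
                    for _ in range(n_reps)
                ]
                for j, a in enumerate(amps)
            }
        neurons.append(neuron)
    return Cohort(neurons, spec, base, seed)


def suprathreshold_reps(
    neuron: SimulatedNeuron, amplitude: float, n_reps: int = 10
) -> List[Trace]:
    """Simulate repetitions of a suprathreshold step for one synthetic neuron
    (mirrors the rig re-running the stimulus once the threshold is known)."""
    step = replace(neuron.ladder_step or CurrentStep(0.0), amplitude=float(amplitude))
    v, rdt = _integrate_batch(neuron.params, np.array([amplitude]), step, record_dt=0.02)
    nrng = np.random.default_rng([neuron.seed, 2])
    sd = neuron.params.noise_sd_voltage
    return [
        Trace(v[0] + nrng.normal(0.0, sd, v.shape[1]), rdt, "voltage") for _ in range(n_reps)
    ]


def make_boltzmann_iv(
    B: float,
    V50: float,
    K: float,
    G_max: float,
    C_int: float,
    V: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Sample an I-V curve directly from the closed-form Boltzmann model.

    This is the single-channel generator used for parameter-recovery
    simulations: the curve's differential conductance is exactly
    G_max·P_O(V), so the fit model is identifiable and fit errors measure
    the estimator, not model mismatch.  `noise_sd` is i.i.d. Gaussian current
    noise in pA (e.g. 2% of the maximum current).
    """
    from .boltzmann import integrated_iv
    from .vclamp import IVCurve

    V = np.asarray(V, dtype=float)
    I = integrated_iv(V, B, V50, K, G_max, C_int)
    if noise_sd > 0:
        I = I + np.random.default_rng(seed).normal(0.0, noise_sd, V.size)
    return IVCurve(V, I)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def e13_high_freq_base() -> ChannelParams:
    """Base parameters emulating an early-development high-frequency neuron.

    LVA: G_max 20.19 nS, V50 −50 mV, K 5 mV (open probability ≈ 0.82 at
    −42.5 mV); HVA: G_max 72.76 nS, V50 −3 mV, K 7 mV (≈ 0.52 at −2.5 mV);
    C_m 50 pF and a leak sized so that, with the LVA conductance partly
    active at rest (≈ −65 mV), the input resistance is near 170 MΩ and the
    membrane time constant near 8–9 ms.  The voltage-clamp K⁺ I-V
    uses the boltzmann_slope form so fitted G_max estimates the generator's
    G_max directly.
    """
    return ChannelParams(
        g_leak=1.2,
        E_leak=-72.0,
        E_K=-90.0,
        lva=BoltzmannChannel(G_max=20.19, V50=-50.0, K=5.0, B=0.0, tau=3.0),
        hva=BoltzmannChannel(G_max=72.76, V50=-3.0, K=7.0, B=0.0, tau=1.5),
        spike=SpikeParams(),
        C_m=50.0,
        noise_sd_current=10.0,
        noise_sd_voltage=0.3,
        iv_form="boltzmann_slope",
    )


def condition_presets(age: str = "E13", region: str = "high_freq") -> Dict[str, ConditionSpec]:
    """Condition presets for the early high-frequency stratum.

    Scale factors are ratios of the fitted group-mean G_max values under each
    condition to control (LVA: 11.92/20.19 under BDNF, 18.39/20.19 under
    BDNF+ANA-12; HVA: 50.40/72.76 and 80.16/72.76), with the group sizes used
    in that stratum.
    """
    common = dict(age=age, region=region)
    return {
        "control": ConditionSpec("control", n_neurons=16, **common),
        "BDNF": ConditionSpec(
            "BDNF", scale_lva=11.92 / 20.19, scale_hva=50.40 / 72.76, n_neurons=20, **common
        ),
        "BDNF_ANA12": ConditionSpec(
            "BDNF_ANA12",
            scale_lva=18.39 / 20.19,
            scale_hva=80.16 / 72.76,
            n_neurons=11,
            **common,
        ),
        "ANA12": ConditionSpec("ANA12", n_neurons=6, **common),
    }
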