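"""Boltzmann modeling of steady-state potassium conductances.

The pipeline implemented here:

1. The steady-state I-V curve is differentiated between consecutive command
   levels (forward difference, reported at the midpoint), giving the
   differential conductance dI/dV in nS.
2. Within a voltage bin — LVA [−60, −25] mV or HVA [−20, +30] mV on
   junction-corrected voltages — the differential conductance is normalized by
   its largest value to an empirical open probability P_O ∈ [0, 1].
3. P_O(V) is fitted with the Boltzmann sigmoid

       P_O(V) = B + (1 − B) / (1 + exp((V50 − V) / K)),

   where V50 is the half-activation voltage (mV), K > 0 the slope factor (mV)
   and B the baseline open fraction (fixed at 0 for the LVA bin; free for the
   HVA bin, where residual LVA current forms a baseline).
4. Treating dI/dV = G_max · P_O(V) as a separable first-order ODE gives the
   closed form fitted directly to the raw in-bin I-V points:

       I(V) = B·G_max·V + G_max·(1 − B)·K·ln(e^{V/K} + e^{V50/K}) + C,

   with C an integration constant (pA).  This second route yields G_max (nS),
   the maximal differential conductance, a proxy for channel number.

Per-fit read-outs (open probability and differential conductance at fixed
voltages: −42.5 mV for LVA, −2.5 and +17.5 mV for HVA) feed the group
statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import lmfit
import numpy as np
from scipy.special import expit

from .vclamp import IVCurve

__all__ = [
    "VoltageBin",
    "LVA_BIN",
    "HVA_BIN",
    "LVA_READOUT_MV",
    "HVA_PO_READOUT_MV",
    "HVA_G_READOUT_MV",
    "ConductanceCurve",
    "OpenProbCurve",
    "BoltzmannFit",
    "boltzmann_po",
    "differential_conductance_model",
    "integrated_iv",
    "differential_conductance",
    "normalize_open_probability",
    "fit_boltzmann",
    "fit_integrated_iv",
    "readout_at",
]

# Standard read-out voltages for group comparisons (5-mV midpoint grid).
LVA_READOUT_MV = -42.5
HVA_PO_READOUT_MV = -2.5
HVA_G_READOUT_MV = 17.5


@dataclass(frozen=True)
class VoltageBin:
    """Closed voltage interval assigning I-V points to one channel class."""

    name: str  # "LVA" or "HVA"
    lo: float
    hi: float
    b_policy: str  # "fixed_zero" | "free"

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("bin lower edge must be below upper edge")
        if self.b_policy not in ("fixed_zero", "free"):
            raise ValueError(f"unknown B policy {self.b_policy!r}")
        if self.name == "LVA" and self.b_policy != "fixed_zero":
            raise ValueError("LVA bin requires B fixed at 0")

    def contains(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return (v >= self.lo - 1e-9) & (v <= self.hi + 1e-9)


LVA_BIN = VoltageBin("LVA", -60.0, -25.0, "fixed_zero")
HVA_BIN = VoltageBin("HVA", -20.0, 30.0, "free")


def boltzmann_po(V, B: float, V50: float, K: float):
    """Boltzmann open probability B + (1−B)/(1 + e^((V50−V)/K)).

    Strictly increasing in V with limits B (V → −∞) and 1 (V → +∞).
    Evaluated through the logistic function, so it is overflow-safe.
    """
    if K <= 0:
        raise ValueError("slope factor K must be positive")
    return B + (1.0 - B) * expit((np.asarray(V, dtype=float) - V50) / K)


def differential_conductance_model(V, B: float, V50: float, K: float, G_max: float):
    """Model differential conductance dI/dV = G_max · P_O(V), in nS."""
    return G_max * boltzmann_po(V, B, V50, K)


def integrated_iv(V, B: float, V50: float, K: float, G_max: float, C_int: float):
    """Closed-form steady-state I-V: the antiderivative of G_max·P_O(V).

    I(V) = B·G_max·V + G_max·(1−B)·K·ln(e^{V/K} + e^{V50/K}) + C_int,
    evaluated with log-sum-exp so large |V|/K cannot overflow.
    """
    if K <= 0:
        raise ValueError("slope factor K must be positive")
    V = np.asarray(V, dtype=float)
    lse = K * np.logaddexp(V / K, V50 / K)
    return B * G_max * V + G_max * (1.0 - B) * lse + C_int


@dataclass
class ConductanceCurve:
    """Differential conductance dI/dV (nS) at voltage-increment midpoints."""

    V_mid: np.ndarray
    g: np.ndarray
    bin: VoltageBin

    def __post_init__(self) -> None:
        self.V_mid = np.asarray(self.V_mid, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.V_mid.shape != self.g.shape:
            raise ValueError("V_mid and g must have equal length")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("non-finite conductance values")


@dataclass
class OpenProbCurve:
    """Empirical open probability: dI/dV normalized by its largest value."""

    V_mid: np.ndarray
    p_o: np.ndarray
    g_max_empirical: float
    bin: VoltageBin
    n_clipped: int = 0  # negative noisy slopes clipped to 0


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters for one voltage bin.

    ``C_int`` is the integration constant of the closed-form I-V (pA); it is
    only populated by the raw-I-V route.  ``stderr`` holds per-parameter
    standard errors where the fit could estimate them.
    """

    B: float
    V50: float
    K: float
    G_max: float
    bin: VoltageBin
    C_int: Optional[float] = None
    stderr: Dict[str, Optional[float]] = field(default_factory=dict)
    converged: bool = True
    residual_rms: float = np.nan
    n_points: int = 0
    source: str = ""  # "open_probability" | "integrated_iv"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("fitted K must be positive")
        if self.bin.b_policy == "fixed_zero" and self.B != 0.0:
            raise ValueError("LVA fit must report B = 0")

    def to_dict(self) -> Dict[str, object]:
        d = {
            "bin": self.bin.name,
            "B": self.B,
            "V50": self.V50,
            "K": self.K,
            "G_max": self.G_max,
            "C_int": self.C_int,
            "converged": self.converged,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "source": self.source,
        }
        for k, v in self.stderr.items():
            d[f"{k}_stderr"] = v
        return d


def differential_conductance(iv: IVCurve, vbin: VoltageBin) -> ConductanceCurve:
    """Forward-difference slope of the I-V curve at in-bin midpoints.

    g_j = (I_{j+1} − I_j)/(V_{j+1} − V_j), reported at (V_j + V_{j+1})/2, for
    consecutive level pairs whose *both* endpoints lie inside the closed bin
    (so no midpoint straddles the gap between the LVA and HVA bins).
    pA / mV = nS.
    """
    inb = vbin.contains(iv.V)
    pair = inb[:-1] & inb[1:]
    if np.count_nonzero(pair) < 1 or np.count_nonzero(inb) < 2:
        raise ValueError(f"fewer than 2 I-V points inside bin {vbin.name}")
    dV = np.diff(iv.V)[pair]
    dI = np.diff(iv.I)[pair]
    vmid = ((iv.V[:-1] + iv.V[1:]) / 2.0)[pair]
    return ConductanceCurve(vmid, dI / dV, vbin)


def normalize_open_probability(gc: ConductanceCurve, clip_negative: bool = True) -> OpenProbCurve:
    """Normalize differential conductance by its largest value (P_O ∈ [0, 1]).

    Small negative slopes (recording noise) are clipped to 0 for the
    probability curve only; the raw conductance is left untouched for the
    closed-form I-V fit.  The number of clipped points is reported.
    """
    gmax = float(np.max(gc.g))
    if gmax <= 0:
        raise ValueError("non-positive maximum conductance: not an outward-activating curve")
    p = gc.g / gmax
    n_clip = 0
    if clip_negative:
        n_clip = int(np.count_nonzero(p < 0))
        p = np.clip(p, 0.0, None)
    return OpenProbCurve(gc.V_mid.copy(), p, gmax, gc.bin, n_clip)


def _initial_guess(vmid: np.ndarray, g: np.ndarray, vbin: VoltageBin) -> Dict[str, float]:
    """Heuristic starting values from the shape of an activation curve."""
    gmax0 = float(np.max(g))
    gmin0 = float(np.min(g))
    if vbin.b_policy == "free" and gmax0 > 0:
        b0 = min(max(gmin0 / gmax0, 0.0), 0.8)
    else:
        b0 = 0.0
    # half-activation: first midpoint whose value crosses halfway between extremes
    half = gmin0 + 0.5 * (gmax0 - gmin0)
    above = np.nonzero(g >= half)[0]
    v50_0 = float(vmid[above[0]]) if above.size else float(np.median(vmid))
    k0 = max((vmid[-1] - vmid[0]) / 6.0, 2.0)
    return {"B": b0, "V50": v50_0, "K": k0, "G_max": max(gmax0, 1e-3)}


def _fit_result_fields(result: lmfit.model.ModelResult) -> Dict[str, Optional[float]]:
    return {
        name: (None if par.stderr is None else float(par.stderr))
        for name, par in result.params.items()
        if par.vary
    }


def fit_boltzmann(
    po: OpenProbCurve,
    vbin: Optional[VoltageBin] = None,
    init: Optional[Dict[str, float]] = None,
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit to an open-probability curve.

    B is fixed at 0 for the LVA bin and free in [0, 1) for the HVA bin.
    G_max is not a parameter of this route (the curve is already normalized);
    the empirical normalizer is carried through on the returned fit.
    """
    vbin = vbin or po.bin
    n_free = 2 if vbin.b_policy == "fixed_zero" else 3
    if po.V_mid.size < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} points to fit bin {vbin.name}")

    model = lmfit.Model(lambda V, B, V50, K: boltzmann_po(V, B, V50, K))
    params = model.make_params()
    guess = _initial_guess(po.V_mid, po.p_o, vbin)
    if init:
        guess.update(init)
    params["V50"].set(value=guess["V50"], min=-150.0, max=80.0)
    params["K"].set(value=guess["K"], min=0.3, max=60.0)
    if vbin.b_policy == "fixed_zero":
        params["B"].set(value=0.0, vary=False)
    else:
        params["B"].set(value=min(guess["B"], 0.9), min=0.0, max=0.999)

    result = model.fit(po.p_o, params, V=po.V_mid)
    resid = result.residual
    return BoltzmannFit(
        B=float(result.params["B"].value),
        V50=float(result.params["V50"].value),
        K=float(result.params["K"].value),
        G_max=po.g_max_empirical,
        bin=vbin,
        C_int=None,
        stderr=_fit_result_fields(result),
        converged=bool(result.success),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(po.V_mid.size),
        source="open_probability",
    )


def fit_integrated_iv(
    iv: IVCurve,
    vbin: VoltageBin,
    init: Optional[Dict[str, float]] = None,
) -> BoltzmannFit:
    """Fit the closed-form I-V directly to the raw in-bin (V, I) points.

    The integration constant C_int is initialized so the model passes through
    the lowest-voltage in-bin point and is then co-fitted.  Returns V50, K and
    G_max with standard errors; these G_max values feed the group statistics.
    """
    mask = vbin.contains(iv.V)
    V = iv.V[mask]
    I = iv.I[mask]
    if not np.all(np.isfinite(I)):
        raise ValueError(f"non-finite in-bin currents in bin {vbin.name}")
    n_free = 4 if vbin.b_policy == "fixed_zero" else 5  # V50, K, G_max, C_int (+B)
    if V.size < n_free:
        raise ValueError(
            f"bin {vbin.name} has {V.size} in-bin points; need >= {n_free}"
        )

    # slope-based initialization
    g = np.diff(I) / np.diff(V)
    vmid = (V[:-1] + V[1:]) / 2.0
    guess = _initial_guess(vmid, g, vbin)
    if init:
        guess.update(init)

    model = lmfit.Model(
        lambda V, B, V50, K, G_max, C_int: integrated_iv(V, B, V50, K, G_max, C_int)
    )
    params = model.make_params()
    params["V50"].set(value=guess["V50"], min=-150.0, max=80.0)
    params["K"].set(value=guess["K"], min=0.3, max=60.0)
    params["G_max"].set(value=guess["G_max"], min=1e-6)
    if vbin.b_policy == "fixed_zero":
        params["B"].set(value=0.0, vary=False)
    else:
        params["B"].set(value=min(guess["B"], 0.9), min=0.0, max=0.999)
    c0 = float(
        I[0]
        - integrated_iv(V[0], params["B"].value, guess["V50"], guess["K"], guess["G_max"], 0.0)
    )
    params["C_int"].set(value=c0)

    result = model.fit(I, params, V=V)
    resid = result.residual
    converged = bool(result.success)
    # a rank-deficient or non-estimable fit is reported, not silently accepted
    if result.covar is None:
        converged = False
    return BoltzmannFit(
        B=float(result.params["B"].value),
        V50=float(result.params["V50"].value),
        K=float(result.params["K"].value),
        G_max=float(result.params["G_max"].value),
        bin=vbin,
        C_int=float(result.params["C_int"].value),
        stderr=_fit_result_fields(result),
        converged=converged,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(V.size),
        source="integrated_iv",
    )


def readout_at(fit: BoltzmannFit, V: float) -> Dict[str, float]:
    """Open probability and differential conductance of a fit at voltage V.

    p_o is the Boltzmann sigmoid; g = G_max · P_O(V) is the model dI/dV in nS.
    These per-neuron values at the standard read-out voltages (−42.5, −2.5,
    +17.5 mV) are what the condition statistics compare.
    """
    if not fit.converged:
        raise ValueError("cannot read out an unconverged fit")
    p = float(boltzmann_po(V, fit.B, fit.V50, fit.K))
    g = float(differential_conductance_model(V, fit.B, fit.V50, fit.K, fit.G_max))
    return {"p_o": p, "g": g}
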