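"""Diagnostic plots of activation curves and fits (requires matplotlib)."""
from __future__ import annotations

from typing import Optional

import numpy as np

from . import boltzmann as bz
from .vclamp import IVCurve


def plot_bin_fit(iv: IVCurve, fit: bz.BoltzmannFit, ax=None, n_curve: int = 200):
    """Open probability and differential conductance versus voltage for one bin.

    Left axis: empirical P_O points (normalized forward-difference slopes)
    with the fitted sigmoid; right axis: model dI/dV in nS.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    gc = bz.differential_conductance(iv, fit.bin)
    po = bz.normalize_open_probability(gc)
    vgrid = np.linspace(fit.bin.lo, fit.bin.hi, n_curve)

    ax.plot(po.V_mid, po.p_o, "o", color="k", label="data")
    ax.plot(vgrid, bz.boltzmann_po(vgrid, fit.B, fit.V50, fit.K), "-", color="C0",
            label=f"fit: V50={fit.V50:.1f} mV, K={fit.K:.1f} mV")
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("open probability")
    ax.set_ylim(-0.05, 1.1)
    ax.legend(frameon=False, fontsize=8)

    ax2 = ax.twinx()
    ax2.plot(vgrid, bz.differential_conductance_model(vgrid, fit.B, fit.V50, fit.K, fit.G_max),
             "--", color="C1", alpha=0.7)
    ax2.set_ylabel("dI/dV (nS)", color="C1")
    ax.set_title(f"{fit.bin.name} bin")
    return ax


def plot_iv(iv: IVCurve, fit: Optional[bz.BoltzmannFit] = None, ax=None):
    """Raw I-V points, optionally overlaid with a closed-form fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(iv.V, iv.I, "o-", color="k", ms=3, lw=0.7)
    if fit is not None and fit.C_int is not None:
        mask = fit.bin.contains(iv.V)
        vgrid = np.linspace(iv.V[mask][0], iv.V[mask][-1], 200)
        ax.plot(vgrid, bz.integrated_iv(vgrid, fit.B, fit.V50, fit.K, fit.G_max, fit.C_int),
                "-", color="C3", label=f"{fit.bin.name} fit")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("current (pA)")
    ax.axhline(0, color="gray", lw=0.5)
    return ax
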