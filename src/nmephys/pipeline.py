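"""End-to-end analysis: sweep families → per-neuron feature and fit tables.

Mirrors the experimental workflow: build the junction-corrected I-V curve and
fit both Boltzmann routes per voltage bin; find the current threshold from
the amplitude ladder, collect 1.25·I_T repetitions, and average AP features;
extract passive properties from the −10 pA step; then apply the QC inclusion
rules.  Each neuron is processed in isolation — a failure is logged on that
neuron's row and the rest of the cohort proceeds.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import boltzmann as bz
from . import cclamp as cc
from .qc_stats import inclusion_flag
from .synth import Cohort, SimulatedNeuron, suprathreshold_reps
from .vclamp import IVCurve, SweepFamily, build_iv_curve

log = logging.getLogger("nmephys")

__all__ = [
    "analyze_vclamp",
    "analyze_neuron_cclamp",
    "analyze_cohort",
    "DEFAULT_METRICS",
]

DEFAULT_METRICS = (
    "latency",
    "rise_rate",
    "repol_rate",
    "peak_amplitude",
    "i_threshold",
    "tau",
    "r_in",
    "c_m",
    "rmp",
    "lva_g_max",
    "hva_g_max",
    "lva_v50",
    "hva_v50",
    "lva_po_readout",
    "hva_po_readout",
    "lva_g_readout",
    "hva_g_readout",
    "i_at_m40",
    "i_at_p20",
)


def analyze_vclamp(family: SweepFamily) -> Tuple[IVCurve, Dict[str, bz.BoltzmannFit]]:
    """I-V curve plus per-bin closed-form Boltzmann fits for one neuron."""
    iv = build_iv_curve(family)
    fits: Dict[str, bz.BoltzmannFit] = {}
    for vbin in (bz.LVA_BIN, bz.HVA_BIN):
        fits[vbin.name] = bz.fit_integrated_iv(iv, vbin)
    return iv, fits


def _iv_lookup(iv: IVCurve, v: float) -> float:
    idx = np.argmin(np.abs(iv.V - v))
    if abs(iv.V[idx] - v) > 1e-6:
        return np.nan
    return float(iv.I[idx])


def analyze_neuron_cclamp(
    neuron: SimulatedNeuron, detection: cc.Detection = cc.Detection()
) -> Dict[str, float]:
    """Active and passive current-clamp features for one synthetic neuron."""
    out: Dict[str, float] = {}
    step = neuron.passive_step
    if neuron.passive_reps and step is not None:
        props = [
            cc.passive_properties(tr, step.onset, step.duration, neuron.age)
            for tr in neuron.passive_reps
        ]
        out["tau"] = float(np.mean([p.tau for p in props]))
        out["r_in"] = float(np.mean([p.R_in for p in props]))
        out["c_m"] = 1000.0 * out["tau"] / out["r_in"]
        out["rmp_measured"] = float(np.mean([p.rmp for p in props]))

    if neuron.ladder_reps and neuron.ladder_step is not None:
        onset = neuron.ladder_step.onset
        thr = cc.find_current_threshold(neuron.ladder_reps, detection)
        if thr.I_T is not None:
            out["i_threshold"] = thr.I_T
            supra = thr.suprathreshold_amplitude
            out["suprathreshold_amplitude"] = supra
            reps = suprathreshold_reps(neuron, supra)
            feats = cc.mean_suprathreshold_features(reps, onset, detection)
            out.update(
                latency=feats.latency,
                rise_rate=feats.rise_rate,
                repol_rate=feats.repol_rate,
                peak_amplitude=feats.peak_amplitude,
                n_contributing=feats.n_contributing,
            )
    return out


def analyze_cohort(
    cohort: Cohort,
    detection: cc.Detection = cc.Detection(),
    apply_qc: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline over a cohort.

    Returns ``(features, fits)``: one row per neuron with metadata, QC flags,
    current-clamp features, fitted Boltzmann parameters and read-outs; and a
    long table with one row per neuron × bin for both fit routes.
    """
    feat_rows: List[Dict[str, object]] = []
    fit_rows: List[Dict[str, object]] = []
    for neuron in cohort.neurons:
        row: Dict[str, object] = {
            "neuron_id": neuron.neuron_id,
            "embryo_id": neuron.embryo_id,
            "age": neuron.age,
            "region": neuron.region,
            "condition": neuron.condition,
            "rmp": neuron.rmp,
            "series_resistance": neuron.series_resistance,
        }
        if apply_qc:
            row["included"], row["exclusion_reason"] = inclusion_flag(
                neuron.age, neuron.rmp, neuron.series_resistance
            )
            if not row["included"]:
                log.info("excluded %s: %s", neuron.neuron_id, row["exclusion_reason"])
        else:
            row["included"], row["exclusion_reason"] = True, ""

        try:
            if neuron.vclamp is not None:
                iv, fits = analyze_vclamp(neuron.vclamp)
                row["i_at_m40"] = _iv_lookup(iv, -40.0)
                row["i_at_p20"] = _iv_lookup(iv, 20.0)
                for name, fit in fits.items():
                    pref = name.lower()
                    row[f"{pref}_g_max"] = fit.G_max
                    row[f"{pref}_v50"] = fit.V50
                    row[f"{pref}_k"] = fit.K
                    row[f"{pref}_b"] = fit.B
                    row[f"{pref}_converged"] = fit.converged
                    if fit.converged:
                        if name == "LVA":
                            ro = bz.readout_at(fit, bz.LVA_READOUT_MV)
                            row["lva_po_readout"] = ro["p_o"]
                            row["lva_g_readout"] = ro["g"]
                        else:
                            row["hva_po_readout"] = bz.readout_at(
                                fit, bz.HVA_PO_READOUT_MV
                            )["p_o"]
                            row["hva_g_readout"] = bz.readout_at(
                                fit, bz.HVA_G_READOUT_MV
                            )["g"]
                    fit_rows.append({"neuron_id": neuron.neuron_id, **fit.to_dict()})
                    # open-probability route, kept alongside for cross-checks
                    gc = bz.differential_conductance(iv, fit.bin)
                    po = bz.normalize_open_probability(gc)
                    po_fit = bz.fit_boltzmann(po)
                    fit_rows.append({"neuron_id": neuron.neuron_id, **po_fit.to_dict()})
            row.update(analyze_neuron_cclamp(neuron, detection))
        except Exception as exc:  # noqa: BLE001 - isolate per-neuron failures
            row["included"] = False
            row["exclusion_reason"] = f"analysis failure: {exc}"
            log.warning("skipping %s: %s", neuron.neuron_id, exc)
        feat_rows.append(row)
    return pd.DataFrame(feat_rows), pd.DataFrame(fit_rows)
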