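"""Readers and writers binding the pipeline stages together.

Sweep families are stored in an HDF5 container (one group per neuron, one
dataset per sweep, units and sampling metadata as attributes) with a flat CSV
alternative; ground-truth generator parameters go to a JSON sidecar.  Every
file written carries the package version and the generation seed so runs are
attributable.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .synth import (
    BoltzmannChannel,
    ChannelParams,
    Cohort,
    ConditionSpec,
    CurrentStep,
    SimulatedNeuron,
    SpikeParams,
)
from .vclamp import SweepFamily, Trace, VClampProtocol

__all__ = [
    "save_cohort_hdf5",
    "load_cohort_hdf5",
    "save_cohort_csv",
    "save_ground_truth",
    "load_ground_truth",
]


def _params_to_dict(p: ChannelParams) -> Dict:
    return dataclasses.asdict(p)


def _params_from_dict(d: Dict) -> ChannelParams:
    d = dict(d)
    d["lva"] = BoltzmannChannel(**d["lva"])
    d["hva"] = BoltzmannChannel(**d["hva"])
    d["spike"] = SpikeParams(**d["spike"])
    return ChannelParams(**d)


def save_ground_truth(cohort: Cohort, path: str | Path) -> None:
    """JSON sidecar with the generation seed, condition spec and per-neuron
    ground-truth parameters."""
    payload = {
        "version": __version__,
        "seed": cohort.seed,
        "spec": dataclasses.asdict(cohort.spec),
        "base": _params_to_dict(cohort.base),
        "neurons": {
            n.neuron_id: {
                "params": _params_to_dict(n.params),
                "rmp": n.rmp,
                "series_resistance": n.series_resistance,
                "seed": n.seed,
            }
            for n in cohort.neurons
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: str | Path) -> Dict:
    return json.loads(Path(path).read_text())


def _write_trace(group: h5py.Group, name: str, trace: Trace, **attrs) -> None:
    ds = group.create_dataset(
        name, data=trace.signal, compression="gzip", compression_opts=4, track_times=False
    )
    ds.attrs["dt_ms"] = trace.dt
    ds.attrs["kind"] = trace.kind
    ds.attrs["units"] = "pA" if trace.kind == "current" else "mV"
    for k, v in attrs.items():
        ds.attrs[k] = v


def _read_trace(ds: h5py.Dataset) -> Trace:
    return Trace(ds[()], float(ds.attrs["dt_ms"]), str(ds.attrs["kind"]))


def save_cohort_hdf5(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort's raw sweep families to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        f.attrs["seed"] = cohort.seed
        f.attrs["spec"] = json.dumps(dataclasses.asdict(cohort.spec))
        neurons = f.create_group("neurons")
        for n in cohort.neurons:
            g = neurons.create_group(n.neuron_id)
            g.attrs.update(
                {
                    "embryo_id": n.embryo_id,
                    "age": n.age,
                    "region": n.region,
                    "condition": n.condition,
                    "rmp_mV": n.rmp,
                    "series_resistance_MOhm": n.series_resistance,
                    "seed": n.seed,
                    "params": json.dumps(_params_to_dict(n.params)),
                }
            )
            if n.vclamp is not None:
                vg = g.create_group("vclamp")
                proto = n.vclamp.protocol
                vg.attrs.update(
                    {
                        "holding_mV": proto.holding,
                        "duration_ms": proto.duration,
                        "ljp_mV": proto.ljp,
                        "ljp_applied": proto.ljp_applied,
                        "dt_ms": proto.dt,
                        "levels_mV": proto.levels,
                    }
                )
                for j, lv in enumerate(proto.levels):
                    _write_trace(vg, f"sweep_{j:03d}", n.vclamp.sweeps[float(lv)], level_mV=lv)
            if n.passive_reps:
                pg = g.create_group("passive")
                step = n.passive_step
                pg.attrs.update(
                    {"amplitude_pA": step.amplitude, "onset_ms": step.onset, "duration_ms": step.duration}
                )
                for j, tr in enumerate(n.passive_reps):
                    _write_trace(pg, f"rep_{j:02d}", tr)
            if n.ladder_reps:
                lg = g.create_group("ladder")
                step = n.ladder_step
                lg.attrs.update({"onset_ms": step.onset, "duration_ms": step.duration})
                for amp, reps in sorted(n.ladder_reps.items()):
                    ag = lg.create_group(f"amp_{amp:+08.1f}")
                    ag.attrs["amplitude_pA"] = amp
                    for j, tr in enumerate(reps):
                        _write_trace(ag, f"rep_{j:02d}", tr)


def load_cohort_hdf5(path: str | Path) -> Cohort:
    """Round-trip reader for the HDF5 container."""
    with h5py.File(path, "r") as f:
        spec = ConditionSpec(**json.loads(f.attrs["spec"]))
        seed = int(f.attrs["seed"])
        neurons: List[SimulatedNeuron] = []
        base: Optional[ChannelParams] = None
        for nid in sorted(f["neurons"]):
            g = f["neurons"][nid]
            params = _params_from_dict(json.loads(g.attrs["params"]))
            if base is None:
                base = params
            vclamp = None
            if "vclamp" in g:
                vg = g["vclamp"]
                proto = VClampProtocol(
                    holding=float(vg.attrs["holding_mV"]),
                    levels=np.asarray(vg.attrs["levels_mV"], dtype=float),
                    duration=float(vg.attrs["duration_ms"]),
                    ljp=float(vg.attrs["ljp_mV"]),
                    ljp_applied=bool(vg.attrs["ljp_applied"]),
                    dt=float(vg.attrs["dt_ms"]),
                )
                sweeps = {
                    float(vg[name].attrs["level_mV"]): _read_trace(vg[name]) for name in vg
                }
                vclamp = SweepFamily(sweeps, proto)
            neuron = SimulatedNeuron(
                neuron_id=nid,
                embryo_id=str(g.attrs["embryo_id"]),
                age=str(g.attrs["age"]),
                region=str(g.attrs["region"]),
                condition=str(g.attrs["condition"]),
                params=params,
                rmp=float(g.attrs["rmp_mV"]),
                series_resistance=float(g.attrs["series_resistance_MOhm"]),
                seed=int(g.attrs["seed"]),
                vclamp=vclamp,
            )
            if "passive" in g:
                pg = g["passive"]
                neuron.passive_step = CurrentStep(
                    float(pg.attrs["amplitude_pA"]),
                    onset=float(pg.attrs["onset_ms"]),
                    duration=float(pg.attrs["duration_ms"]),
                )
                neuron.passive_reps = [_read_trace(pg[name]) for name in sorted(pg)]
            if "ladder" in g:
                lg = g["ladder"]
                neuron.ladder_step = CurrentStep(
                    0.0, onset=float(lg.attrs["onset_ms"]), duration=float(lg.attrs["duration_ms"])
                )
                neuron.ladder_reps = {
                    float(lg[name].attrs["amplitude_pA"]): [
                        _read_trace(lg[name][r]) for r in sorted(lg[name])
                    ]
                    for name in sorted(lg)
                }
            neurons.append(neuron)
    return Cohort(neurons, spec, base, seed)


def save_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Flat CSV alternative: neuron_id, sweep_id, command, time_ms, value.

    Voltage-clamp sweeps only (the format is meant for inspection and
    language portability, not bulk storage).
    """
    frames = []
    for n in cohort.neurons:
        if n.vclamp is None:
            continue
        for j, lv in enumerate(n.vclamp.protocol.levels):
            tr = n.vclamp.sweeps[float(lv)]
            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": n.neuron_id,
                        "sweep_id": f"sweep_{j:03d}",
                        "command_mV": lv,
                        "time_ms": tr.time,
                        "value_pA": tr.signal,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
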