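"""Shared fixtures: noise-free parameter sets and small simulated cohorts."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nmephys import synth
from nmephys.vclamp import VClampProtocol


@pytest.fixture
def quiet_base() -> synth.ChannelParams:
    """The early high-frequency preset with all recording noise turned off."""
    base = synth.e13_high_freq_base()
    return dataclasses.replace(base, noise_sd_current=0.0, noise_sd_voltage=0.0)


@pytest.fixture
def rc_only() -> synth.ChannelParams:
    """Pure RC neuron: leak 5 nS (R = 200 MΩ), C = 40 pF, tau = 8 ms."""
    return synth.ChannelParams(
        g_leak=5.0,
        E_leak=-70.0,
        lva=synth.BoltzmannChannel(0.0, -50.0, 5.0),
        hva=synth.BoltzmannChannel(0.0, -3.0, 7.0),
        spike=synth.SpikeParams(g_na=0.0),
        C_m=40.0,
        noise_sd_current=0.0,
        noise_sd_voltage=0.0,
    )


@pytest.fixture(scope="session")
def small_vclamp_cohorts():
    """Control and BDNF-like cohorts, voltage clamp only (fast), n = 6 each."""
    presets = synth.condition_presets()
    base = synth.e13_high_freq_base()
    ctrl = dataclasses.replace(presets["control"], n_neurons=6)
    bdnf = dataclasses.replace(presets["BDNF"], n_neurons=6)
    return (
        synth.make_cohort(ctrl, base, seed=101, include_cclamp=False),
        synth.make_cohort(bdnf, base, seed=202, include_cclamp=False),
    )


@pytest.fixture(scope="session")
def tiny_full_cohort():
    """A 4-neuron cohort with current clamp, small ladder (shared, ~5 s)."""
    spec = dataclasses.replace(synth.condition_presets()["control"], n_neurons=4)
    return synth.make_cohort(
        spec,
        synth.e13_high_freq_base(),
        seed=7,
        include_cclamp=True,
        ladder_amplitudes=np.arange(40.0, 220.0 + 1e-9, 20.0),
        n_reps=6,
    )


@pytest.fixture
def standard_protocol() -> VClampProtocol:
    return VClampProtocol()
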