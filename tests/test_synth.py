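"""Conductance-model generator: closed forms, determinism, noise and cohorts."""
import dataclasses

import numpy as np
import pytest
import sympy

from nmephys import boltzmann as bz
from nmephys import synth
from nmephys.vclamp import VClampProtocol, build_iv_curve, steady_state_current


def leak_only(g_leak=1.0, e_leak=-70.0, **kw):
    return synth.ChannelParams(
        g_leak=g_leak,
        E_leak=e_leak,
        lva=synth.BoltzmannChannel(0.0, -50.0, 5.0),
        hva=synth.BoltzmannChannel(0.0, -3.0, 7.0),
        spike=synth.SpikeParams(g_na=0.0),
        noise_sd_current=0.0,
        noise_sd_voltage=0.0,
        **kw,
    )


class TestSteadyStateCurrent:
    def test_zero_at_leak_reversal(self):
        assert synth.steady_state_model_current(leak_only(), -70.0) == 0.0

    def test_half_open_chord_current(self):
        # P_O = 0.5 at V50; 20 nS · 0.5 · (−40 − (−90)) = 500 pA
        p = synth.ChannelParams(
            g_leak=0.0,
            E_leak=-70.0,
            E_K=-90.0,
            lva=synth.BoltzmannChannel(20.0, -40.0, 5.0),
            hva=synth.BoltzmannChannel(0.0, -3.0, 7.0),
            spike=synth.SpikeParams(g_na=0.0),
            noise_sd_current=0.0,
            noise_sd_voltage=0.0,
        )
        assert synth.steady_state_model_current(p, -40.0) == pytest.approx(500.0, rel=1e-12)

    def test_two_channel_closed_form_against_high_precision(self):
        """Hand evaluation of leak + LVA + HVA chord currents at V = −20."""
        p = synth.ChannelParams(
            g_leak=1.5,
            E_leak=-65.0,
            E_K=-90.0,
            lva=synth.BoltzmannChannel(20.0, -40.0, 5.0),
            hva=synth.BoltzmannChannel(70.0, -5.0, 8.0, B=0.1),
            spike=synth.SpikeParams(g_na=0.0),
            noise_sd_current=0.0,
            noise_sd_voltage=0.0,
        )
        V = sympy.Integer(-20)
        sig = lambda z: 1 / (1 + sympy.exp(-z))  # noqa: E731
        expected = (
            sympy.Rational(3, 2) * (V + 65)
            + 20 * sig(sympy.Rational(-20 + 40, 5)) * (V + 90)
            + 70
            * (sympy.Rational(1, 10) + sympy.Rational(9, 10) * sig(sympy.Rational(-20 + 5, 8)))
            * (V + 90)
        ).evalf(50)
        got = synth.steady_state_model_current(p, -20.0)
        assert got == pytest.approx(float(expected), rel=1e-14)

    def test_boltzmann_slope_form_reverses_at_ek_and_has_model_slope(self):
        p = dataclasses.replace(leak_only(g_leak=0.0), iv_form="boltzmann_slope")
        p = dataclasses.replace(p, lva=synth.BoltzmannChannel(20.0, -45.0, 5.0))
        assert synth.steady_state_model_current(p, -90.0) == pytest.approx(0.0, abs=1e-12)
        h = 1e-5
        for v in (-60.0, -45.0, -30.0):
            slope = (
                synth.steady_state_model_current(p, v + h)
                - synth.steady_state_model_current(p, v - h)
            ) / (2 * h)
            assert slope == pytest.approx(
                float(bz.differential_conductance_model(v, 0.0, -45.0, 5.0, 20.0)), rel=1e-8
            )

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            synth.steady_state_model_current(leak_only(), np.nan)


class TestVClampSimulation:
    def test_late_window_equals_steady_state_noiseless(self, quiet_base):
        fam = synth.simulate_vclamp_family(quiet_base, seed=0)
        for lv in fam.protocol.levels[::6]:
            got = steady_state_current(fam.sweeps[float(lv)], fam.protocol.duration)
            want = synth.steady_state_model_current(quiet_base, lv + fam.protocol.ljp)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_seed_determinism(self, quiet_base):
        base = dataclasses.replace(quiet_base, noise_sd_current=5.0)
        a = synth.simulate_vclamp_family(base, seed=17)
        b = synth.simulate_vclamp_family(base, seed=17)
        c = synth.simulate_vclamp_family(base, seed=18)
        for lv in a.protocol.levels:
            assert np.array_equal(a.sweeps[float(lv)].signal, b.sweeps[float(lv)].signal)
        assert not np.array_equal(a.sweeps[-100.0].signal, c.sweeps[-100.0].signal)

    def test_window_mean_standard_error_scales_with_sample_count(self, quiet_base):
        """SD of the late-window mean ≈ noise SD / √n over Monte-Carlo seeds."""
        noisy = dataclasses.replace(quiet_base, noise_sd_current=5.0)
        proto = VClampProtocol(levels=np.array([-40.0]), duration=20.0, dt=0.001)
        means = []
        for seed in range(200):
            fam = synth.simulate_vclamp_family(noisy, proto, seed=seed)
            means.append(steady_state_current(fam.sweeps[-40.0], 20.0))  # 1000 samples
        sem = np.std(means, ddof=1)
        assert sem == pytest.approx(5.0 / np.sqrt(1000), rel=0.15)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            VClampProtocol(levels=np.array([]))
        with pytest.raises(ValueError):
            VClampProtocol(duration=5.0)


class TestCClampSimulation:
    def test_rc_response_matches_analytic_solution(self, rc_only):
        """−10 pA into R = 200 MΩ, C = 40 pF: ΔV = −2 mV, τ = 8 ms."""
        step = synth.CurrentStep(-10.0, onset=20.0, duration=100.0)
        tr = synth.simulate_cclamp_trace(rc_only, step, seed=0)
        t = tr.time
        in_step = (t >= 20.0) & (t <= 120.0)
        analytic = -70.0 - 2.0 * (1.0 - np.exp(-(t[in_step] - 20.0) / 8.0))
        err = np.max(np.abs(tr.signal[in_step] - analytic))
        assert err <= 0.005 * 2.0  # within 0.5% of the 2 mV deflection

    def test_zero_current_stays_at_rest(self, rc_only):
        tr = synth.simulate_cclamp_trace(rc_only, synth.CurrentStep(0.0), seed=0)
        assert np.max(np.abs(tr.signal - (-70.0))) < 1e-9

    def test_suprathreshold_step_fires_and_tracks_fine_reference(self, quiet_base):
        """A step 25% above rheobase fires; a 10× finer integration agrees."""
        from nmephys import cclamp as cc

        rheo = None
        for amp in np.arange(40.0, 400.0, 20.0):
            tr = synth.simulate_cclamp_trace(quiet_base, synth.CurrentStep(amp), seed=0, record_dt=0.02)
            if cc.detect_aps(tr):
                rheo = amp
                break
        assert rheo is not None
        step = synth.CurrentStep(1.25 * rheo)
        coarse = synth.simulate_cclamp_trace(quiet_base, step, seed=0, record_dt=0.02)
        fine = synth.simulate_cclamp_trace(
            quiet_base, step, seed=0, dt=0.001, record_dt=0.02
        )
        ev_c = cc.detect_aps(coarse)
        ev_f = cc.detect_aps(fine)
        assert len(ev_c) >= 1 and len(ev_f) == len(ev_c)
        assert ev_c[0].t_peak == pytest.approx(ev_f[0].t_peak, abs=0.5)
        feats = cc.ap_features(coarse, step.onset)
        assert feats.rise_rate > abs(feats.repol_rate)

    def test_cclamp_seed_determinism(self, quiet_base):
        noisy = dataclasses.replace(quiet_base, noise_sd_voltage=0.3)
        step = synth.CurrentStep(100.0)
        a = synth.simulate_cclamp_trace(noisy, step, seed=5)
        b = synth.simulate_cclamp_trace(noisy, step, seed=5)
        assert np.array_equal(a.signal, b.signal)


class TestCohorts:
    def test_count_and_reproducibility(self):
        spec = synth.ConditionSpec("control", n_neurons=3)
        a = synth.make_cohort(spec, seed=9, include_cclamp=False)
        b = synth.make_cohort(spec, seed=9, include_cclamp=False)
        assert len(a.neurons) == 3
        for na, nb in zip(a.neurons, b.neurons):
            assert na.params == nb.params
            for lv in na.vclamp.protocol.levels:
                assert np.array_equal(
                    na.vclamp.sweeps[float(lv)].signal, nb.vclamp.sweeps[float(lv)].signal
                )

    def test_embryo_assignment_caps_cells_per_embryo(self):
        spec = synth.ConditionSpec("control", n_neurons=16)
        cohort = synth.make_cohort(spec, seed=1, include_cclamp=False)
        from collections import Counter

        counts = Counter(n.embryo_id for n in cohort.neurons)
        assert max(counts.values()) <= synth.MAX_CELLS_PER_EMBRYO
        assert len(counts) >= 4

    def test_identity_condition_recovers_base_gmax(self, small_vclamp_cohorts):
        """With unit scale factors the fitted LVA G_max centres on the base value.

        The raw-I-V fit also absorbs the leak slope (~1 nS), so the centre
        sits slightly above the channel's own G_max; the check bounds that
        total bias.
        """
        ctrl, _ = small_vclamp_cohorts
        fits = [
            bz.fit_integrated_iv(build_iv_curve(n.vclamp), bz.LVA_BIN) for n in ctrl.neurons
        ]
        mean_g = np.mean([f.G_max for f in fits])
        assert mean_g == pytest.approx(ctrl.base.lva.G_max, rel=0.2)

    def test_bdnf_preset_scales_match_group_mean_ratios(self):
        presets = synth.condition_presets()
        assert presets["BDNF"].scale_lva == pytest.approx(11.92 / 20.19)
        assert presets["BDNF"].scale_hva == pytest.approx(50.40 / 72.76)
        assert presets["control"].n_neurons == 16
        assert presets["BDNF"].n_neurons == 20

    def test_scaling_lva_up_strictly_increases_current_at_minus40(self, quiet_base):
        currents = []
        for s in (0.5, 1.0, 1.5, 2.0):
            p = dataclasses.replace(
                quiet_base, lva=dataclasses.replace(quiet_base.lva, G_max=quiet_base.lva.G_max * s)
            )
            currents.append(synth.steady_state_model_current(p, -40.0))
        assert np.all(np.diff(currents) > 0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            synth.ConditionSpec("control", n_neurons=0)
        with pytest.raises(ValueError):
            synth.ConditionSpec("control", scale_lva=0.0)
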