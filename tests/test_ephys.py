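"""Sweep quantification: G-V, F-V, Boltzmann fits, XE991 inhibition."""

import dataclasses

import numpy as np
import pytest

from vsdkit.ephys import (BoltzmannFit, SweepSet, VoltageProtocol, boltzmann,
                          fit_boltzmann, fv_from_fluorescence, gv_from_tails,
                          steady_state_current, time_dependent_inhibition,
                          xe991_inhibition)
from vsdkit.synthetic import GatingModelSpec, simulate_sweeps

SLOW_SINGLE = GatingModelSpec(z1=1.0, v1_mV=0.0, z2=1.0, v2_mV=300.0,
                              g_io_uS=10.0, g_ao_uS=0.0,
                              tau1_s=0.5, tau2_s=0.5)
DRUG_PROTOCOL = VoltageProtocol(holding_mV=-20.0, pre_duration_s=1.0,
                                test_duration_s=4.0, tail_voltage_mV=-40.0,
                                tail_duration_s=2.0)


class TestBoltzmann:
    def test_midpoint_value(self):
        assert boltzmann(0.0, 1.0, 0.0) == pytest.approx(0.5)

    def test_one_rt_unit_above_midpoint(self):
        # zF(V - V1/2)/RT = 1 at +25.4 mV for z = 1 at 295.15 K
        assert boltzmann(25.4, 1.0, 0.0) == pytest.approx(0.731, abs=0.001)

    def test_noise_free_single_fit_exact(self):
        v = np.arange(-100, 101, 10.0)
        y = boltzmann(v, 1.0, 0.0)
        fit = fit_boltzmann(v, y, 1)
        (z, vh, amp) = fit.components[0]
        assert z == pytest.approx(1.0, abs=1e-6)
        assert vh == pytest.approx(0.0, abs=1e-5)

    def test_noise_free_double_fit_exact(self):
        v = np.arange(-160, 101, 10.0)
        y = 0.6 * boltzmann(v, 2.0, -60.0) + 0.4 * boltzmann(v, 1.2, 10.0)
        fit = fit_boltzmann(v, y, 2)
        (z1, v1, a1), (z2, v2, a2) = fit.components
        assert v1 < v2
        assert v1 == pytest.approx(-60.0, abs=1e-3)
        assert v2 == pytest.approx(10.0, abs=1e-3)
        assert a1 == pytest.approx(0.6, abs=1e-4)

    def test_component_ordering_enforced(self):
        v = np.arange(-160, 101, 20.0)
        y = 0.5 * boltzmann(v, 2.0, -60.0) + 0.5 * boltzmann(v, 1.0, 20.0)
        fit = fit_boltzmann(v, y, 2)
        assert fit.components[0][1] < fit.components[1][1]

    def test_noisy_vhalf_recovery(self):
        """2 percent noise: V1/2 recovered within 2 mV across replicates."""
        v = np.arange(-100, 101, 10.0)
        truth = boltzmann(v, 1.0, -20.0)
        errs = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            y = truth + rng.normal(0.0, 0.02, truth.shape)
            fit = fit_boltzmann(v, y, 1)
            errs.append(abs(fit.components[0][1] - (-20.0)))
        assert np.mean(errs) < 2.0

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0, 10, 20], [0.1, 0.5, 0.9], 1)


class TestGV:
    def test_single_boltzmann_roundtrip(self):
        proto = VoltageProtocol(test_duration_s=6.0)
        ss = simulate_sweeps(SLOW_SINGLE, proto, np.arange(-120, 121, 20.0))
        gv = gv_from_tails(ss, tail_window_s=0.02, settle_gap_s=0.002)
        fit = fit_boltzmann(gv["test_voltage_mV"], gv["g_normalized"], 1)
        z, vh, _ = fit.components[0]
        assert z == pytest.approx(1.0, rel=0.05)
        assert abs(vh) < 2.0

    def test_constitutively_open_gv_flat(self):
        # channel with voltage-independent conductance: normalized G-V = 1
        spec = dataclasses.replace(SLOW_SINGLE, v1_mV=-300.0)
        ss = simulate_sweeps(spec, VoltageProtocol(),
                             np.arange(-120, 121, 40.0))
        gv = gv_from_tails(ss)
        assert np.allclose(gv["g_normalized"], 1.0, atol=0.01)

    def test_max_normalization_is_exact(self):
        ss = simulate_sweeps(SLOW_SINGLE, VoltageProtocol(),
                             np.arange(-80, 81, 40.0))
        gv = gv_from_tails(ss)
        assert gv["g_normalized"].abs().max() == pytest.approx(1.0)


class TestFV:
    def test_pure_bleach_corrected_to_zero(self):
        # no voltage response: after baseline subtraction |dF/F| ~ 0
        spec = GatingModelSpec(f1_amp=0.0, f2_amp=0.0, bleach_tau_s=20.0)
        ss = simulate_sweeps(spec, VoltageProtocol(),
                             np.arange(-80, 81, 40.0))
        fv = fv_from_fluorescence(ss)
        assert np.abs(fv["delta_f_over_f"]).max() < 1e-3

    def test_two_transition_fv_recovers_half_voltages(self):
        spec = GatingModelSpec(tau1_s=0.05, tau2_s=0.2)
        ss = simulate_sweeps(spec, VoltageProtocol(),
                             np.arange(-160, 101, 20.0))
        fv = fv_from_fluorescence(ss)
        fit = fit_boltzmann(fv["test_voltage_mV"], fv["f_normalized"], 2)
        (z1, v1, a1), (z2, v2, a2) = fit.components
        assert v1 == pytest.approx(spec.v1_mV, abs=5.0)
        assert v2 == pytest.approx(spec.v2_mV, abs=5.0)

    def test_outputs_normalized(self):
        spec = GatingModelSpec()
        ss = simulate_sweeps(spec, VoltageProtocol(),
                             np.arange(-160, 101, 20.0))
        fv = fv_from_fluorescence(ss)
        assert fv["f_normalized"].abs().max() == pytest.approx(1.0)


class TestInhibition:
    def test_no_block_gives_zero(self):
        assert xe991_inhibition(2.0, 2.0, 0.1).f_xe991 == pytest.approx(0.0)

    def test_complete_block_gives_one(self):
        assert xe991_inhibition(2.0, 0.1, 0.1).f_xe991 == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        res = xe991_inhibition(2.0, 0.5, 0.1)
        assert res.f_xe991 == pytest.approx(1.5 / 1.9)

    def test_scaling_invariance(self):
        a = xe991_inhibition(2.0, 0.5, 0.1).f_xe991
        b = xe991_inhibition(6.0, 1.5, 0.3).f_xe991
        assert a == pytest.approx(b)

    def test_equal_control_and_chromanol_raise(self):
        with pytest.raises(ZeroDivisionError):
            xe991_inhibition(1.0, 0.5, 1.0)

    @pytest.mark.parametrize("g_io,g_ao,expected", [
        (10.0, 0.0, 0.8),   # IO-only channel blocked by block_io
        (0.0, 10.0, 0.2),   # AO-only channel blocked by block_ao
    ])
    def test_full_pipeline_state_dependence(self, g_io, g_ao, expected):
        """Sweep -> steady state -> inhibition fraction reproduces the
        IO/AO block asymmetry of the generator."""
        spec = GatingModelSpec(g_io_uS=g_io, g_ao_uS=g_ao,
                               block_io=0.8, block_ao=0.2,
                               tau1_s=0.05, tau2_s=0.2)

        def steady(drug):
            ss = simulate_sweeps(spec, DRUG_PROTOCOL, [40.0], drug=drug)
            return steady_state_current(ss.sweeps[0], DRUG_PROTOCOL)

        res = xe991_inhibition(steady("control"), steady("xe991"),
                               steady("chromanol"))
        assert res.f_xe991 == pytest.approx(expected, abs=0.01)


class TestTimeDependentInhibition:
    def test_identical_sweeps_ratio_one(self):
        ss = simulate_sweeps(GatingModelSpec(), DRUG_PROTOCOL, [40.0])
        df = time_dependent_inhibition(ss.sweeps[0], ss.sweeps[0],
                                       DRUG_PROTOCOL)
        assert np.allclose(df["ratio"].dropna(), 1.0)

    def test_uniform_block_constant_ratio(self):
        spec = GatingModelSpec(block_io=0.5, block_ao=0.5)
        c = simulate_sweeps(spec, DRUG_PROTOCOL, [40.0], drug="control")
        d = simulate_sweeps(spec, DRUG_PROTOCOL, [40.0], drug="xe991")
        df = time_dependent_inhibition(c.sweeps[0], d.sweeps[0],
                                       DRUG_PROTOCOL)
        assert np.allclose(df["ratio"].dropna(), 0.5, atol=1e-9)

    def test_io_selective_block_relaxes_toward_one(self):
        # IO-selective block: ratio rises as activated-state occupancy
        # grows during the pulse
        spec = GatingModelSpec(block_io=0.8, block_ao=0.0,
                               tau1_s=0.05, tau2_s=1.0)
        c = simulate_sweeps(spec, DRUG_PROTOCOL, [40.0], drug="control")
        d = simulate_sweeps(spec, DRUG_PROTOCOL, [40.0], drug="xe991")
        df = time_dependent_inhibition(c.sweeps[0], d.sweeps[0],
                                       DRUG_PROTOCOL)
        r = df["ratio"].dropna().to_numpy()
        assert r[-1] > r[len(r) // 10]
        assert r[-1] < 1.0


class TestSweepCsv:
    def test_round_trip(self, tmp_path):
        ss = simulate_sweeps(GatingModelSpec(), VoltageProtocol(),
                             [-40.0, 0.0, 40.0])
        path = tmp_path / "sweeps.csv"
        ss.write_csv(path)
        back = SweepSet.read_csv(path)
        assert [s.test_voltage_mV for s in back.sweeps] == [-40.0, 0.0, 40.0]
        assert np.allclose(back.sweeps[0].current_uA,
                           ss.sweeps[0].current_uA)
        assert back.protocol == ss.protocol
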