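"""Sweep handling: junction correction, instantaneous/steady currents, ramps."""

import numpy as np
import pytest

from wholecell.biophysics import ghk_current
from wholecell.protocols import (
    RampProtocol,
    StepLevelError,
    StepProtocol,
    Sweep,
    SweepRecording,
    correct_membrane_potential,
    current_density,
    instantaneous_current,
    ramp_timecourse,
    read_sweeps_csv,
    steady_state_current,
    write_sweeps_csv,
)
from wholecell.synthetic import CaccModelParams, simulate_step_sweeps

FS = 2500.0


def _ohmic_step_recording(g_ns: float = 1.0, level: float = 80.0,
                          duration: float = 2.0) -> SweepRecording:
    protocol = StepProtocol(start_mv=level, stop_mv=level,
                            step_duration_s=duration)
    n_pre = int(0.1 * FS)
    n_step = int(duration * FS)
    n_post = int(0.1 * FS)
    t = np.arange(n_pre + n_step + n_post) / FS
    v = np.full(t.size, protocol.holding_mv)
    v[n_pre:n_pre + n_step] = level
    i = g_ns * v
    return SweepRecording("ohmic", FS, [Sweep(t, v, i)])


class TestJunctionCorrection:
    @pytest.mark.parametrize("vout, vlj, expected",
                             [(80.0, 0.0, 80.0), (80.0, 13.0, 67.0),
                              (100.0, 7.0, 93.0), (-40.0, 7.0, -47.0)])
    def test_vm_is_vout_minus_vlj(self, vout, vlj, expected):
        assert correct_membrane_potential(vout, vlj) == expected

    def test_correction_is_a_pure_horizontal_shift(self):
        v = np.arange(-100.0, 121.0, 20.0)
        assert np.allclose(correct_membrane_potential(v, 13.0), v - 13.0)


class TestInstantaneousCurrent:
    def test_gate_still_at_holding_value_one_ms_in(self, cl_context):
        """With tau = 200 ms the 1-ms read reflects the pre-step open fraction."""
        model = CaccModelParams(noise_sd_pa=0.0, leak_ns=0.0,
                                tau_activation_s=0.2)
        protocol = StepProtocol()
        rng = np.random.default_rng(0)
        rec = simulate_step_sweeps(model, protocol, cl_context, rng,
                                   free_ca_um=1.0)
        for level in (80.0, 120.0):
            i_inst = instantaneous_current(rec, level)
            # closed-form gate relaxation evaluated at the 1 ms read point
            p0 = float(model.gate_steady(protocol.holding_mv))  # vlj = 0 here
            p_inf = float(model.gate_steady(level))
            gate_1ms = p_inf - (p_inf - p0) * np.exp(-1e-3 / model.tau_activation_s)
            expected = ghk_current(model.p_max_m3s, level, cl_context) \
                * gate_1ms * model.ca_gate(1.0)
            assert i_inst == pytest.approx(expected, rel=0.01)

    def test_ohmic_leak_is_read_exactly(self):
        rec = _ohmic_step_recording(g_ns=1.0, level=80.0)
        assert instantaneous_current(rec, 80.0) == pytest.approx(80.0)

    def test_delay_beyond_step_duration_rejected(self):
        rec = _ohmic_step_recording(duration=0.5)
        with pytest.raises(ValueError, match="exceeds the step duration"):
            instantaneous_current(rec, 80.0, delay_s=1.0)

    def test_absent_step_level_rejected(self):
        rec = _ohmic_step_recording(level=80.0)
        with pytest.raises(StepLevelError):
            instantaneous_current(rec, -60.0)


class TestSteadyStateCurrent:
    def test_relaxed_gate_matches_steady_state_value(self, cl_context):
        """After 2 s with tau = 200 ms the residual relaxation is e^-10."""
        model = CaccModelParams(noise_sd_pa=0.0, leak_ns=0.0)
        rec = simulate_step_sweeps(model, StepProtocol(), cl_context,
                                   np.random.default_rng(0), free_ca_um=1.0)
        for level in (60.0, 100.0):
            expected = ghk_current(model.p_max_m3s, level, cl_context) \
                * float(model.gate_steady(level)) * model.ca_gate(1.0)
            assert steady_state_current(rec, level) == \
                pytest.approx(expected, rel=1e-3)

    def test_flat_trace_returns_its_value(self):
        rec = _ohmic_step_recording(g_ns=0.5, level=40.0)
        assert steady_state_current(rec, 40.0) == pytest.approx(20.0)

    def test_full_window_equals_whole_step_mean(self):
        rec = _ohmic_step_recording()
        assert steady_state_current(rec, 80.0, window_fraction=1.0) == \
            pytest.approx(80.0)

    def test_converges_to_instantaneous_reading_for_long_delays(self, cl_context):
        """Late instantaneous reads approach the steady-state statistic."""
        model = CaccModelParams(noise_sd_pa=0.0, leak_ns=0.0)
        rec = simulate_step_sweeps(model, StepProtocol(), cl_context,
                                   np.random.default_rng(0), free_ca_um=1.0)
        late = instantaneous_current(rec, 100.0, delay_s=1.99)
        ss = steady_state_current(rec, 100.0)
        assert late == pytest.approx(ss, rel=1e-3)


class TestRampTimecourse:
    def _ohmic_ramp_recording(self, g_ns: float, n_ramps: int = 4,
                              vlj: float = 7.0) -> SweepRecording:
        ramp = RampProtocol()
        n = int(ramp.ramp_duration_s * FS) + 1
        sweeps = []
        for k in range(n_ramps):
            t = k * ramp.repeat_interval_s + np.arange(n) / FS
            v = np.linspace(ramp.start_mv, ramp.stop_mv, n)
            vm = v - vlj
            sweeps.append(Sweep(t, v, g_ns * vm))
        return SweepRecording("ramp", FS, sweeps, vlj_mv=vlj)

    def test_ohmic_cell_gives_g_times_v_at_every_ramp(self):
        rec = self._ohmic_ramp_recording(g_ns=1.0)
        series = ramp_timecourse(rec, [93.0])
        t, i = series[93.0]
        assert len(t) == 4
        assert np.allclose(i, 93.0, atol=1e-6)

    def test_target_outside_span_rejected(self):
        rec = self._ohmic_ramp_recording(g_ns=1.0)
        with pytest.raises(ValueError, match="outside the corrected ramp span"):
            ramp_timecourse(rec, [-200.0])


class TestCurrentDensity:
    def test_pa_per_pf(self):
        assert current_density(500.0, 25.0) == pytest.approx(20.0)
        assert current_density(0.0, 25.0) == 0.0

    @pytest.mark.parametrize("bad", [0.0, -5.0, None])
    def test_invalid_capacitance_rejected(self, bad):
        with pytest.raises(ValueError):
            current_density(500.0, bad)


class TestSweepIo:
    def test_csv_round_trip_preserves_data_and_metadata(self, tmp_path,
                                                        cl_context):
        model = CaccModelParams(noise_sd_pa=2.0)
        rec = simulate_step_sweeps(model, StepProtocol(), cl_context,
                                   np.random.default_rng(3), cell_id="c1",
                                   vlj_mv=12.5, free_ca_um=1.0)
        path = write_sweeps_csv([rec], tmp_path / "sweeps.csv")
        back = read_sweeps_csv(path)
        assert len(back) == 1 and back[0].cell_id == "c1"
        assert back[0].vlj_mv == pytest.approx(12.5)
        assert len(back[0].sweeps) == len(rec.sweeps)
        np.testing.assert_allclose(back[0].sweeps[0].i_pa, rec.sweeps[0].i_pa,
                                   rtol=1e-4, atol=1e-3)
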