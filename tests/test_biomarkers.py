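"""Biomarker extraction: APD, EADs, pseudo-ECG, QT, dispersion."""

import numpy as np
import pytest

from cardiosim import biomarkers
from cardiosim.biomarkers import (BiomarkerError, ECGTrace, apd, detect_eads,
                                  measure_qt, pseudo_ecg,
                                  transmural_dispersion)
from cardiosim.ord import Trace
from cardiosim.strand import StrandTrace
from cardiosim.synthetic import (SyntheticAPParams, make_ap_trace,
                                 make_strand_activation)


class TestAPD:
    def test_linear_repolarization_geometry(self):
        # instant rise to 0 mV, linear fall to -90 mV over 300 ms:
        # the 90% level (-81 mV) is crossed at 270 ms
        t = np.arange(0.0, 400.0, 0.1)
        v = np.full_like(t, -90.0)
        up = 10.0
        fall = (t >= up) & (t < up + 300.0)
        v[fall] = 0.0 - 90.0 * (t[fall] - up) / 300.0
        v[t >= up + 300.0] = -90.0
        assert apd(Trace(t=t, vm=v), level=90) == pytest.approx(270.0,
                                                                abs=0.2)

    def test_exponential_crossing_matches_closed_form(self):
        p = SyntheticAPParams(apd90=250.0, shape="exponential")
        tr = make_ap_trace(p)
        assert apd(tr) == pytest.approx(250.0, abs=p.sample_dt + 1e-6)

    def test_apd_monotone_in_level(self):
        tr = make_ap_trace(SyntheticAPParams(apd90=300.0))
        assert apd(tr, level=90) > apd(tr, level=50)

    def test_rest_only_trace_rejected(self):
        t = np.arange(0.0, 100.0, 0.1)
        with pytest.raises(BiomarkerError, match="no AP"):
            apd(Trace(t=t, vm=np.full_like(t, -85.0)))

    def test_repolarization_failure_flagged(self):
        p = SyntheticAPParams(apd90=900.0, bcl=400.0)
        tr = make_ap_trace(p)   # trace ends before the 90% crossing
        with pytest.raises(BiomarkerError, match="repolarization failure"):
            apd(tr)


class TestEADs:
    def test_single_injected_bump_detected(self):
        tr = make_ap_trace(SyntheticAPParams(ead_amplitude=10.0,
                                             ead_onset_frac=0.5))
        rep = detect_eads(tr)
        assert rep.counts == [1]
        assert rep.amplitudes[0] > 2.0

    def test_clean_repolarization_has_no_eads(self):
        tr = make_ap_trace(SyntheticAPParams())
        assert detect_eads(tr).total == 0
        assert detect_eads(tr).pattern == "none"

    def test_alternating_bumps_label_two_to_one(self):
        p = SyntheticAPParams(ead_amplitude=10.0, ead_onset_frac=0.5,
                              beat_pattern=(False, True))
        tr = make_ap_trace(p, n_beats=6)
        rep = detect_eads(tr)
        assert rep.counts == [0, 1, 0, 1, 0, 1]
        assert rep.pattern == "2:1"

    def test_every_beat_labelled_one_to_one(self):
        p = SyntheticAPParams(ead_amplitude=10.0, ead_onset_frac=0.5,
                              beat_pattern=(True,))
        tr = make_ap_trace(p, n_beats=4)
        assert detect_eads(tr).pattern == "1:1"

    def test_sub_prominence_bump_ignored(self):
        tr = make_ap_trace(SyntheticAPParams(ead_amplitude=1.0,
                                             ead_onset_frac=0.5))
        assert detect_eads(tr, prominence=2.0).total == 0


class TestPseudoECG:
    def test_uniform_field_gives_zero_potential(self):
        base = make_strand_activation(70.0)
        vm = np.tile(base.vm[0], (len(base.x), 1))
        tr = StrandTrace(t=base.t, vm=vm, x=base.x,
                         stim_times=base.stim_times, stim_log=[])
        assert np.abs(pseudo_ecg(tr).phi).max() < 1e-12

    def test_three_node_toy_matches_brute_force_sum(self):
        # independent term-by-term evaluation of the discrete integral
        x = np.array([0.05, 0.20, 0.35])
        dx = 0.15
        vm = np.array([[-80.0, 10.0], [-40.0, -20.0], [-85.0, 30.0]])
        t = np.array([0.0, 1.0])
        elec, a = 2.0, 1.1
        expected = np.zeros(2)
        grad = np.gradient(vm, x, axis=0)
        for k in range(3):
            r = abs(elec - x[k])
            dinvr = (elec - x[k]) / r ** 3
            expected += (a ** 2 / 4.0) * (-grad[k]) * dinvr * dx
        tr = StrandTrace(t=t, vm=vm, x=x, stim_times=np.array([0.0]),
                         stim_log=[])
        got = pseudo_ecg(tr, electrode_mm=elec, radius_mm=a).phi
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_linearity_in_vm(self):
        tr = make_strand_activation(70.0,
                                    apd_per_node=np.linspace(320, 260, 100))
        a = pseudo_ecg(tr).phi
        tr2 = StrandTrace(t=tr.t, vm=3.0 * tr.vm, x=tr.x,
                          stim_times=tr.stim_times, stim_log=[])
        np.testing.assert_allclose(pseudo_ecg(tr2).phi, 3.0 * a,
                                   rtol=1e-9, atol=1e-12)

    def test_amplitude_decays_with_electrode_distance(self):
        tr = make_strand_activation(70.0,
                                    apd_per_node=np.linspace(320, 260, 100))
        amps = [np.abs(pseudo_ecg(tr, electrode_mm=tr.x[-1] + d).phi).max()
                for d in (10.0, 20.0, 40.0)]
        assert amps[0] > amps[1] > amps[2]

    def test_electrode_on_node_rejected(self):
        tr = make_strand_activation(70.0)
        with pytest.raises(ValueError, match="coincides"):
            pseudo_ecg(tr, electrode_mm=float(tr.x[3]))

    def test_distal_short_apd_gradient_gives_upright_t_wave(self):
        tr = make_strand_activation(
            70.0, apd_per_node=np.linspace(330, 250, 100))
        qt = measure_qt(pseudo_ecg(tr))
        assert qt["t_amplitude"] > 0


class TestQT:
    @staticmethod
    def _synthetic_ecg(t_end_target=410.0, scale=1.0):
        # steep QRS onset at exactly 10 ms; T-wave descending limb returns
        # to baseline at exactly t_end_target
        t = np.arange(0.0, 500.0, 1.0)
        phi = np.zeros_like(t)
        phi[(t >= 10) & (t < 40)] = 1.0
        rise = (t >= 300) & (t < 360)
        phi[rise] = 0.5 * (t[rise] - 300) / 60.0
        desc = (t >= 360) & (t < t_end_target)
        phi[desc] = 0.5 * (t_end_target - t[desc]) / (t_end_target - 360)
        return ECGTrace(t=t, phi=scale * phi, stim_times=np.array([5.0]))

    def test_constructed_landmarks_recovered_within_one_sample(self):
        qt = measure_qt(self._synthetic_ecg())
        assert qt["qrs_onset_ms"] == pytest.approx(10.0, abs=1.0)
        assert qt["t_end_ms"] == pytest.approx(410.0, abs=1.0)
        assert qt["qt_ms"] == pytest.approx(400.0, abs=2.0)

    def test_amplitude_scale_invariance(self):
        a = measure_qt(self._synthetic_ecg(scale=1.0))
        b = measure_qt(self._synthetic_ecg(scale=10.0))
        assert a["qt_ms"] == b["qt_ms"]

    def test_flat_signal_rejected(self):
        t = np.arange(0.0, 400.0, 1.0)
        ecg = ECGTrace(t=t, phi=np.zeros_like(t), stim_times=np.array([5.0]))
        with pytest.raises(BiomarkerError, match="no QRS"):
            measure_qt(ecg)

    def test_qt_monotone_with_apd(self):
        short = make_strand_activation(
            70.0, apd_per_node=np.linspace(300, 240, 100))
        long = make_strand_activation(
            70.0, apd_per_node=np.linspace(360, 300, 100))
        qs = measure_qt(pseudo_ecg(short))["qt_ms"]
        ql = measure_qt(pseudo_ecg(long))["qt_ms"]
        assert ql >= qs

    def test_repolarization_failure_flagged(self):
        t = np.arange(0.0, 500.0, 1.0)
        phi = np.zeros_like(t)
        phi[(t >= 10) & (t < 40)] = 1.0
        phi[t >= 300] = 0.5     # T wave never returns to baseline
        ecg = ECGTrace(t=t, phi=phi, stim_times=np.array([5.0]))
        with pytest.raises(BiomarkerError, match="repolarization failure"):
            measure_qt(ecg)


class TestDispersion:
    def test_printed_example_values(self):
        d = transmural_dispersion({"ENDO": 250.0, "MID": 313.0,
                                   "EPI": 202.0})
        assert d["MID-ENDO"] == pytest.approx(63.0)
        assert d["MID-EPI"] == pytest.approx(111.0)

    def test_equal_apds_give_zero_deltas(self):
        d = transmural_dispersion({"ENDO": 300.0, "MID": 300.0,
                                   "EPI": 300.0})
        assert d == {"MID-ENDO": 0.0, "MID-EPI": 0.0}

    def test_antisymmetry_under_swap(self):
        d1 = transmural_dispersion({"ENDO": 250.0, "MID": 310.0,
                                    "EPI": 200.0})
        d2 = transmural_dispersion({"ENDO": 310.0, "MID": 250.0,
                                    "EPI": 200.0})
        assert d1["MID-ENDO"] == -d2["MID-ENDO"]

    def test_missing_type_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            transmural_dispersion({"ENDO": 250.0, "MID": 310.0})
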