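"""ERP averaging, component measurement, and task-state SC/NI."""

import numpy as np
import pytest

from docndf import (Epochs, ERPWaveform, GroupParams, RawRecording,
                    StimulusSequence, average_erp, baseline_and_reject,
                    compute_sc_ni, extract_epochs, generate_task_recording,
                    mmn_difference, peak_measure, segment_at_events,
                    task_sc_ni, wavelet_denoise)


def _epochs(data, conditions=None, fs=500.0):
    n = data.shape[2]
    times = (np.arange(n) - 50) / fs * 1000.0
    return Epochs(data=data, times_ms=times,
                  conditions=conditions or ["STD"] * data.shape[0],
                  fs=fs, labels=[f"CH{i}" for i in range(data.shape[1])])


class TestWaveletDenoise:
    def test_zero_input_zero_output(self):
        ep = _epochs(np.zeros((2, 1, 256)))
        out = wavelet_denoise(ep)
        assert np.allclose(out.data, 0.0)

    def test_shape_conserved(self, rng):
        ep = _epochs(rng.normal(size=(3, 2, 250)))
        out = wavelet_denoise(ep)
        assert out.data.shape == ep.data.shape

    def test_improves_snr_on_noisy_template(self, rng):
        t = np.linspace(-100, 400, 250)
        template = -5.0 * np.exp(-((t - 110) ** 2) / (2 * 18.0**2))
        wins = 0
        for _ in range(20):
            noisy = template + rng.normal(0.0, 5.0, size=250)
            ep = _epochs(noisy[None, None, :])
            den = wavelet_denoise(ep).data[0, 0]
            rmse_in = np.sqrt(np.mean((noisy - template) ** 2))
            rmse_out = np.sqrt(np.mean((den - template) ** 2))
            wins += rmse_out < rmse_in
        assert wins >= 18

    def test_too_short_epoch_raises(self, rng):
        ep = _epochs(rng.normal(size=(1, 1, 16)))
        with pytest.raises(ValueError):
            wavelet_denoise(ep, level=6)


class TestAverageErp:
    def test_mean_of_two_epochs(self):
        data = np.array([[[1.0]], [[3.0]]])
        ep = _epochs(data)
        ep.times_ms = np.array([0.0])
        out = average_erp(ep, "STD")
        assert out.data[0, 0] == 2.0 and out.n_epochs_averaged == 2

    def test_rejected_epochs_excluded(self):
        data = np.array([[[1.0]], [[3.0]], [[100.0]]])
        ep = _epochs(data)
        ep.times_ms = np.array([0.0])
        ep.rejected = np.array([False, False, True])
        out = average_erp(ep, "STD")
        assert out.data[0, 0] == 2.0 and out.n_epochs_averaged == 2

    def test_no_usable_epochs_raises(self):
        ep = _epochs(np.zeros((2, 1, 10)))
        ep.rejected = np.array([True, True])
        with pytest.raises(ValueError):
            average_erp(ep, "STD")


class TestMmnDifference:
    def _wave(self, values, condition):
        return ERPWaveform(data=np.asarray(values, dtype=float),
                           times_ms=np.arange(len(values[0]), dtype=float),
                           condition=condition, labels=["FZ"],
                           n_epochs_averaged=1)

    def test_equal_waveforms_give_zero(self):
        std = self._wave([[1.0, 2.0]], "STD")
        dev = self._wave([[1.0, 2.0]], "DEV")
        assert np.allclose(mmn_difference(dev, std).data, 0.0)

    def test_arithmetic(self):
        std = self._wave([[-1.0]], "STD")
        dev = self._wave([[-2.0]], "DEV")
        assert mmn_difference(dev, std).data[0, 0] == -1.0

    def test_antisymmetry(self, rng):
        a = self._wave(rng.normal(size=(1, 20)), "DEV")
        b = self._wave(rng.normal(size=(1, 20)), "STD")
        assert np.allclose(mmn_difference(a, b).data,
                           -mmn_difference(b, a).data)

    def test_mismatched_shapes_raise(self):
        std = self._wave([[1.0, 2.0]], "STD")
        dev = self._wave([[1.0, 2.0, 3.0]], "DEV")
        with pytest.raises(ValueError):
            mmn_difference(dev, std)


class TestPeakMeasure:
    def test_argmin_example(self):
        w = ERPWaveform(data=np.array([[0.0, -1.0, -5.0, -2.0, 0.0]]),
                        times_ms=np.array([0.0, 50.0, 100.0, 150.0, 200.0]),
                        condition="STD", labels=["CZ"], n_epochs_averaged=1)
        m = peak_measure(w, "N1", window_ms=(50.0, 150.0))[0]
        assert m.amplitude_uV == -5.0 and m.latency_ms == 100.0

    def test_flat_waveform_ties_to_window_start(self):
        w = ERPWaveform(data=np.zeros((1, 5)),
                        times_ms=np.array([0.0, 50.0, 100.0, 150.0, 200.0]),
                        condition="STD", labels=["CZ"], n_epochs_averaged=1)
        m = peak_measure(w, "N1", window_ms=(50.0, 150.0))[0]
        assert m.amplitude_uV == 0.0 and m.latency_ms == 50.0

    def test_empty_window_raises(self):
        w = ERPWaveform(data=np.zeros((1, 5)),
                        times_ms=np.arange(5.0), condition="STD",
                        labels=["CZ"], n_epochs_averaged=1)
        with pytest.raises(ValueError):
            peak_measure(w, "N1", window_ms=(400.0, 500.0))


class TestNoiselessRecovery:
    """On noiseless synthetic runs, averaging recovers the injected
    templates exactly and peak measures match the generator parameters."""

    @pytest.fixture
    def run(self, silent_params):
        seq = StimulusSequence(
            onsets_ms=tuple(float(i * 1000) for i in range(8)),
            conditions=("STD", "STD", "STD", "DEV", "STD", "STD", "STD",
                        "DEV"),
            soa_ms=1000.0)
        return generate_task_recording(silent_params, seq, 30, 500.0, seed=0)

    def test_average_equals_template(self, run):
        ep = baseline_and_reject(extract_epochs(run))
        std = average_erp(ep, "STD")
        j = run.labels.index("CZ")
        post = std.times_ms >= 0
        tpl = run.meta["n1_template"] * run.meta["n1_gains"][j]
        assert np.allclose(std.data[j, post], tpl, atol=1e-9)

    def test_peak_latency_matches_generator(self, run, silent_params):
        ep = baseline_and_reject(extract_epochs(run))
        std = average_erp(ep, "STD")
        dev = average_erp(ep, "DEV")
        mmn = mmn_difference(dev, std)
        n1 = {m.channel: m for m in peak_measure(std, "N1")}
        mm = {m.channel: m for m in peak_measure(mmn, "MMN")}
        dt = 1000.0 / run.fs
        assert abs(n1["CZ"].latency_ms - silent_params.n1_lat_ms) <= dt
        assert abs(mm["FZ"].latency_ms - silent_params.mmn_lat_ms) <= dt
        assert n1["CZ"].amplitude_uV == pytest.approx(
            silent_params.n1_amp_uV * run.meta["n1_gains"][
                run.labels.index("CZ")], abs=1e-9)


class TestTaskScNi:
    def test_delegation_matches_grid_segmentation(self, rng):
        # events on a contiguous 1 s grid from sample 0: stimulus-anchored
        # and grid segmentation coincide
        fs = 500.0
        data = rng.normal(0.0, 3.0, size=(3, 5000))
        events = [(i * 500, "STD") for i in range(10)]
        rec = RawRecording(data=data, fs=fs, labels=["FZ", "CZ", "PZ"],
                           events=events, state="task")
        esc, eni = task_sc_ni(rec, T=1.0)
        ref = compute_sc_ni(rec, bands=None, T=1.0)["full"]
        assert np.allclose(esc.Z, ref.sc.Z, atol=1e-12)
        assert np.allclose(eni.P, ref.ni.P, atol=1e-12)

    def test_segment_count_equals_event_count(self, rng):
        fs = 500.0
        n_ev = 900
        data = rng.normal(size=(2, n_ev * 500 + 600))
        events = [(100 + i * 500, "STD") for i in range(n_ev)]
        rec = RawRecording(data=data, fs=fs, labels=["A", "B"],
                           events=events, state="task")
        stack = segment_at_events(rec, T=1.0)
        assert stack.n_segments == n_ev

    def test_task_esc_exceeds_rest_rsc(self):
        """Auditory stimulation recruits shared activity: whole-brain ESC
        is higher than the resting-state full-band SC at equal segment
        counts, in at least 9/10 paired replicates."""
        from docndf import (generate_oddball_sequence,
                            generate_resting_recording)
        wins = 0
        for s in range(10):
            p = GroupParams("MCS", synchrony=0.5, transient_prob=0.2)
            seq = generate_oddball_sequence(25, 5, 3, 1000.0, seed=s)
            task = generate_task_recording(p, seq, 10, 500.0, seed=s)
            esc, _ = task_sc_ni(task, T=1.0)
            rest = generate_resting_recording(p, 10, 500.0, 30.0, seed=s)
            rsc = compute_sc_ni(rest, bands=None, T=1.0)["full"].sc
            wins += esc.whole_brain > rsc.whole_brain
        assert wins >= 9
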