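"""-dF/F arithmetic, windowing, zero-phase filtering, node maps."""

import numpy as np
import pytest

import glomnet as gn
from glomnet.preprocess import TrialTensor, WINDOW_NAMES
from glomnet.synthdata import RawRecording


def make_raw(traces, fs=100.0, onset=1.0):
    """Wrap (n_trials, n_glomeruli, T) traces into a RawRecording."""
    traces = np.asarray(traces, dtype=float)[None, None]  # subject, odor
    M = traces.shape[3]
    return RawRecording(fluorescence=traces,
                        mask=np.ones((1, M), dtype=bool),
                        sampling_rate=fs, stimulus_onset=onset,
                        stimulus_offset=onset + 1.0,
                        glomerulus_ids=tuple(str(i) for i in range(M)),
                        odor_names=("odor0",))


def make_tensor(dff, fs=100.0, onset=1.0, mask=None):
    """Wrap (n_trials, n_glomeruli, T) -dF/F into a TrialTensor."""
    dff = np.asarray(dff, dtype=float)[None, None]
    M = dff.shape[3]
    if mask is None:
        mask = np.ones((1, M), dtype=bool)
    return TrialTensor(dff=dff, mask=mask, sampling_rate=fs, time_zero=onset,
                       glomerulus_ids=tuple(str(i) for i in range(M)),
                       odor_names=("odor0",))


class TestDffNormalize:
    @pytest.mark.parametrize("baseline,during,expected", [
        (100.0, 90.0, +0.10),   # fluorescence dip -> excitatory, positive
        (100.0, 100.0, 0.0),    # no change
        (200.0, 210.0, -0.05),  # fluorescence rise -> inhibitory, negative
    ])
    def test_sign_and_magnitude(self, baseline, during, expected):
        T = 300
        f = np.full((1, 1, 1, 1, T), baseline)
        f[..., 100:200] = during
        raw = make_raw(f[0, 0])
        tensor = gn.dff_normalize(raw)
        np.testing.assert_allclose(tensor.dff[0, 0, 0, 0, 100:200], expected,
                                   atol=1e-12)
        np.testing.assert_allclose(tensor.dff[0, 0, 0, 0, :100], 0.0,
                                   atol=1e-12)

    def test_baseline_is_per_trial(self):
        f = np.stack([np.full((1, 300), 100.0), np.full((1, 300), 50.0)])
        raw = make_raw(f)
        tensor = gn.dff_normalize(raw)
        np.testing.assert_allclose(tensor.dff, 0.0, atol=1e-12)

    def test_nonpositive_baseline_masks_channel(self):
        f = np.full((1, 2, 300), 100.0)
        f[0, 1, :] = -1.0
        raw = make_raw(f)
        with pytest.warns(RuntimeWarning, match="non-positive baseline"):
            tensor = gn.dff_normalize(raw)
        assert not tensor.mask[0, 1]
        assert np.all(np.isnan(tensor.dff[0, 0, :, 1, :]))
        assert tensor.mask[0, 0]

    def test_requires_enough_baseline_samples(self):
        raw = make_raw(np.full((1, 1, 300), 100.0), onset=0.5)
        with pytest.raises(ValueError, match="pre-stimulus"):
            gn.dff_normalize(raw, baseline_length=1.0)


class TestWindowConcatenate:
    @pytest.mark.parametrize("n_trials,expected", [(30, 3000), (1, 100),
                                                   (5, 500)])
    def test_sample_counts(self, n_trials, expected):
        tensor = make_tensor(np.zeros((n_trials, 2, 900)))
        ws = gn.window_concatenate(tensor, "ON", 0, 0)
        assert ws.data.shape == (expected, 2)

    def test_total_samples_across_all_windows(self):
        n_trials = 4
        tensor = make_tensor(np.zeros((n_trials, 2, 900)))
        total = sum(gn.window_concatenate(tensor, w, 0, 0).n_samples
                    for w in WINDOW_NAMES)
        assert total == 7 * n_trials * 100

    def test_trial_order_is_preserved(self):
        dff = np.zeros((3, 1, 900))
        for r in range(3):
            dff[r, 0, :] = r
        ws = gn.window_concatenate(make_tensor(dff), "ON", 0, 0)
        np.testing.assert_array_equal(ws.data[:, 0],
                                      np.repeat([0.0, 1.0, 2.0], 100))

    def test_window_beyond_recording_raises(self):
        tensor = make_tensor(np.zeros((2, 1, 400)))  # only 3 s after onset
        with pytest.raises(ValueError, match="beyond"):
            gn.window_concatenate(tensor, "OFF6", 0, 0)

    def test_masked_channels_never_appear(self):
        mask = np.array([[True, False, True]])
        tensor = make_tensor(np.zeros((2, 3, 900)), mask=mask)
        ws = gn.window_concatenate(tensor, "ON", 0, 0)
        assert ws.labels == ("0", "2")
        assert ws.data.shape[1] == 2

    def test_trial_subset(self):
        tensor = make_tensor(np.zeros((10, 1, 900)))
        ws = gn.window_concatenate(tensor, "ON", 0, 0, trials=[0, 3, 4])
        assert ws.n_samples == 300


class TestDecompose:
    fs = 100.0

    def _tensor_from_signal(self, per_trial):  # (n_trials, T)
        return make_tensor(np.asarray(per_trial)[:, None, :], fs=self.fs)

    def test_dc_input_goes_to_slow(self):
        tensor = self._tensor_from_signal(np.full((3, 900), 0.5))
        slow, fast = gn.decompose(tensor)
        np.testing.assert_allclose(slow.dff, 0.5, atol=1e-6)
        np.testing.assert_allclose(fast.dff, 0.0, atol=1e-6)

    def test_trial_mean_subtraction_removes_stereotyped_oscillation(self):
        t = np.arange(900) / self.fs
        identical = np.tile(np.sin(2 * np.pi * 10 * t), (5, 1))
        rng = np.random.default_rng(0)
        jittered = np.stack([np.sin(2 * np.pi * 10 * t + ph)
                             for ph in rng.uniform(0, 2 * np.pi, 5)])
        _, fast_ident = gn.decompose(self._tensor_from_signal(identical))
        _, fast_jit = gn.decompose(self._tensor_from_signal(jittered))
        rms_ident = np.sqrt(np.mean(fast_ident.dff ** 2))
        rms_jit = np.sqrt(np.mean(fast_jit.dff ** 2))
        assert rms_ident < 1e-10          # stereotyped component removed
        assert rms_jit > 0.3              # trial-varying 10 Hz survives

    def test_passband_gains_match_design(self):
        t = np.arange(900) / self.fs
        rng = np.random.default_rng(1)
        # phase-jittered so the trial mean does not cancel the probe
        slow_probe = np.stack([np.sin(2 * np.pi * 0.5 * t + ph)
                               for ph in rng.uniform(0, 2 * np.pi, 6)])
        tensor = self._tensor_from_signal(slow_probe)
        slow, fast = gn.decompose(tensor)
        mid = slice(200, 700)  # avoid filter edge transients
        gain_slow = np.sqrt(np.mean(slow.dff[..., mid] ** 2)
                            / np.mean(tensor.dff[..., mid] ** 2))
        gain_fast = np.sqrt(np.mean(fast.dff[..., mid] ** 2)
                            / np.mean(tensor.dff[..., mid] ** 2))
        assert gain_slow > 0.95   # 0.5 Hz inside the low-pass passband
        assert gain_fast < 0.05   # far below the 2.5 Hz high-pass corner

    @pytest.mark.parametrize("freq,which,max_lag", [(0.5, "slow", 20),
                                                    (10.0, "fast", 4)])
    def test_zero_phase_property(self, freq, which, max_lag):
        # cross-correlation of a narrowband probe with its filtered version
        # must peak at lag zero for a zero-phase filter; the search stays
        # within half the probe period to avoid periodic aliases
        t = np.arange(900) / self.fs
        rng = np.random.default_rng(2)
        probes = np.stack([np.sin(2 * np.pi * freq * t + ph)
                           for ph in rng.uniform(0, 2 * np.pi, 3)])
        tensor = self._tensor_from_signal(probes)
        slow, fast = gn.decompose(tensor)
        out = (slow if which == "slow" else fast).dff[0, 0, 0, 0]
        x = tensor.dff[0, 0, 0, 0]
        lags = range(-max_lag, max_lag + 1)
        cc = [np.corrcoef(x[20:-20], np.roll(out, lag)[20:-20])[0, 1]
              for lag in lags]
        assert list(lags)[int(np.argmax(cc))] == 0

    def test_cutoff_beyond_nyquist_raises(self):
        tensor = self._tensor_from_signal(np.zeros((2, 900)))
        with pytest.raises(ValueError, match="Nyquist"):
            gn.decompose(tensor, high_cut=60.0)


class TestNodeResponseMap:
    def test_zero_signal_gives_zero_vector(self):
        tensor = make_tensor(np.zeros((3, 4, 900)))
        np.testing.assert_array_equal(gn.node_response_map(tensor, "ON", 0, 0),
                                      np.zeros(4))

    def test_single_responsive_glomerulus(self):
        dff = np.zeros((3, 4, 900))
        dff[:, 2, 100:200] = 0.1
        amp = gn.node_response_map(make_tensor(dff), "ON", 0, 0)
        np.testing.assert_allclose(amp, [0.0, 0.0, 0.1, 0.0], atol=1e-12)

    def test_masked_glomerulus_propagates_nan(self):
        mask = np.array([[True, False]])
        tensor = make_tensor(np.zeros((2, 2, 900)), mask=mask)
        tensor.dff[0, 0, :, 1, :] = np.nan
        amp = gn.node_response_map(tensor, "ON", 0, 0)
        assert np.isnan(amp[1]) and amp[0] == 0.0

    def test_recovers_planted_responsive_set(self, protocol_dataset,
                                             protocol_tensor):
        cfg, raw, _ = protocol_dataset
        resp = raw.responsive[raw.odor_names[0]]
        amp = gn.node_response_map(protocol_tensor, "ON", 0, 0)
        top = set(np.argsort(amp)[-len(resp):])
        assert top == set(resp)
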