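"""Preprocessing unit tests against direct-summation and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

import rsvpbci as rb
from rsvpbci.cohort import Session

from .conftest import make_epochset


def _session_from(signal: np.ndarray, rate: float = 512.0,
                  events: pd.DataFrame | None = None) -> Session:
    n_ch = signal.shape[0]
    if events is None:
        events = pd.DataFrame({"sample": [signal.shape[1] // 2],
                               "stim_type": ["target"], "trial_id": [0],
                               "flash_id": [0], "character": ["A"]})
    return Session(signal=signal, rate=rate,
                   channel_names=tuple(f"ch{i}" for i in range(n_ch)),
                   events=events, kind="rsvp")


class TestCommonAverageReference:
    def test_two_channel_constant(self):
        sess = _session_from(np.array([[3.0] * 10, [1.0] * 10]))
        out = rb.common_average_reference(sess)
        assert np.allclose(out.signal[0], 1.0)
        assert np.allclose(out.signal[1], -1.0)

    def test_idempotent_on_zero_mean_montage(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(4, 50))
        sig -= sig.mean(axis=0)
        out = rb.common_average_reference(_session_from(sig))
        assert np.allclose(out.signal, sig)

    def test_column_means_vanish_direct_summation(self):
        rng = np.random.default_rng(1)
        sess = _session_from(rng.normal(size=(32, 200)))
        out = rb.common_average_reference(sess)
        col_means = [sum(out.signal[c, t] for c in range(32)) / 32
                     for t in range(0, 200, 17)]
        assert max(abs(m) for m in col_means) < 1e-10

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rb.common_average_reference(_session_from(np.ones((1, 10))))

    def test_input_not_mutated(self):
        sig = np.random.default_rng(2).normal(size=(3, 40))
        sess = _session_from(sig.copy())
        rb.common_average_reference(sess)
        assert np.array_equal(sess.signal, sig)


class TestBandpassFilter:
    rate = 512.0

    def _sine(self, freq, dur=20.0):
        t = np.arange(int(dur * self.rate)) / self.rate
        return np.sin(2 * np.pi * freq * t)

    def test_dc_removed(self):
        sess = _session_from(np.full((2, 8000), 7.0), rate=self.rate)
        out = rb.bandpass_filter(sess)
        mid = out.signal[:, 2000:-2000]
        assert np.abs(mid).max() < 0.05

    def test_passband_amplitude_preserved(self):
        # 5 Hz sits mid-passband: squared 4th-order Butterworth response ~ 1
        sig = np.vstack([self._sine(5.0)] * 2)
        out = rb.bandpass_filter(_session_from(sig, rate=self.rate))
        mid = out.signal[0, 4000:-4000]
        assert 0.95 <= np.abs(mid).max() <= 1.05

    def test_stopband_attenuated(self):
        # |H(50 Hz)|^2 for a 4th-order 10 Hz low edge is ~(10/50)^8 << 0.01
        sig = np.vstack([self._sine(50.0)] * 2)
        out = rb.bandpass_filter(_session_from(sig, rate=self.rate))
        mid = out.signal[0, 4000:-4000]
        assert np.abs(mid).max() < 0.01

    def test_invalid_cutoffs(self):
        sess = _session_from(np.ones((2, 100)), rate=100.0)
        with pytest.raises(ValueError):
            rb.bandpass_filter(sess, low=0.5, high=60.0)


class TestExtractEpochs:
    def test_sample_counts_at_512hz(self):
        rng = np.random.default_rng(3)
        events = pd.DataFrame({"sample": [600], "stim_type": ["target"],
                               "trial_id": [0], "flash_id": [0],
                               "character": ["A"]})
        sess = _session_from(rng.normal(size=(2, 2000)), events=events)
        epochs = rb.extract_epochs(sess)
        assert epochs.n_samples == 409   # floor(0.8 * 512)
        assert epochs.n_epochs == 1

    def test_constant_signal_zero_after_baseline(self):
        events = pd.DataFrame({"sample": [300, 700], "stim_type": ["target"] * 2,
                               "trial_id": [0, 1], "flash_id": [0, 0],
                               "character": ["A", "B"]})
        sess = _session_from(np.full((3, 1600), 4.2), events=events)
        epochs = rb.extract_epochs(sess)
        assert np.allclose(epochs.data, 0.0)

    def test_baseline_window_mean_zero_direct_summation(self):
        rng = np.random.default_rng(4)
        events = pd.DataFrame({"sample": [500], "stim_type": ["target"],
                               "trial_id": [0], "flash_id": [0],
                               "character": ["A"]})
        sig = rng.normal(size=(2, 1500))
        epochs = rb.extract_epochs(_session_from(sig, events=events))
        # re-cut the baseline directly from the raw signal
        base = sig[:, 500 - 102:500]
        corrected = base - base.mean(axis=1, keepdims=True)
        redone = sig[:, 500:500 + 409] - base.mean(axis=1, keepdims=True)
        assert np.allclose(epochs.data[0], redone)
        assert abs(corrected.mean()) < 1e-12

    def test_edge_event_dropped_with_warning(self):
        events = pd.DataFrame({"sample": [10, 800], "stim_type": ["target"] * 2,
                               "trial_id": [0, 1], "flash_id": [0, 0],
                               "character": ["A", "B"]})
        sess = _session_from(np.zeros((2, 1600)), events=events)
        with pytest.warns(UserWarning):
            epochs = rb.extract_epochs(sess)
        assert epochs.n_epochs == 1


class TestRejectArtifacts:
    def test_absolute_threshold(self):
        rng = np.random.default_rng(5)
        data = rng.normal(scale=5.0, size=(10, 2, 50))
        data[3, 1, 20] = 150.0
        epochs = make_epochset(data, ["target"] * 10)
        out = rb.reject_artifacts(epochs)
        assert out.reject_mask[3] and out.reject_reason[3] == "abs"

    def test_identical_epochs_never_sd_rejected(self):
        data = np.tile(np.ones((1, 2, 30)), (8, 1, 1))
        out = rb.reject_artifacts(make_epochset(data, ["target"] * 8))
        assert not out.reject_mask.any()

    def test_sd_outlier_flagged_against_bruteforce(self):
        rng = np.random.default_rng(6)
        data = rng.normal(scale=1.0, size=(20, 3, 40))
        # place an outlier 8 clean-SDs above the mean peak on channel 1
        peaks = np.abs(data).max(axis=2)
        mu, sd = peaks[:, 1].mean(), peaks[:, 1].std(ddof=1)
        data[7, 1, :] = 0.0
        data[7, 1, 10] = mu + 8 * sd
        out = rb.reject_artifacts(make_epochset(data, ["target"] * 20),
                                  abs_thresh=1e9)
        # brute-force recomputation: mean/SD over the *other* 19 epochs
        peaks = np.abs(data).max(axis=2)
        expect = np.zeros(20, dtype=bool)
        for e in range(20):
            for c in range(3):
                others = np.delete(peaks[:, c], e)
                if abs(peaks[e, c] - others.mean()) > 5 * others.std(ddof=1):
                    expect[e] = True
        assert np.array_equal(out.reject_mask, expect)
        assert out.reject_mask[7]

    def test_too_few_epochs_rejected(self):
        data = np.zeros((2, 2, 10))
        with pytest.raises(ValueError):
            rb.reject_artifacts(make_epochset(data, ["target"] * 2))


class TestDropAdjacentNontargets:
    def _stream_epochs(self, target_pos, stream_len=21):
        labels = ["nontarget"] * stream_len
        labels[target_pos] = "target"
        data = np.zeros((stream_len, 1, 10))
        ep = make_epochset(data, labels)
        ep.info["trial_id"] = 0
        ep.info["flash_id"] = np.arange(stream_len)
        return ep

    def test_three_following_removed(self):
        out = rb.drop_adjacent_nontargets(self._stream_epochs(9))  # pos 10, 1-based
        dropped = set(out.info.loc[out.reject_mask, "flash_id"])
        assert dropped == {10, 11, 12}
        retained_nt = (~out.reject_mask & ~out.is_target).sum()
        assert retained_nt == 17

    def test_target_at_final_position_boundary(self):
        out = rb.drop_adjacent_nontargets(self._stream_epochs(20))
        assert not out.reject_mask.any()

    def test_default_rsvp_bookkeeping(self, rsvp_epochs):
        """40 trials: 40 targets, 40*20 - 40*3 = 680 non-targets short of rejection."""
        reasons = rsvp_epochs.reject_reason
        assert (reasons == "adjacent").sum() == 40 * 3
        nontarget_pool = (~rsvp_epochs.is_target
                          & (reasons != "adjacent")).sum()
        assert nontarget_pool == 680

    def test_missing_metadata_rejected(self):
        ep = self._stream_epochs(5)
        ep.info.drop(columns=["flash_id"], inplace=True)
        with pytest.raises(ValueError):
            rb.drop_adjacent_nontargets(ep)


def test_epoch_count_conservation(rsvp_epochs):
    retained = (~rsvp_epochs.reject_mask).sum()
    rejected = np.isin(rsvp_epochs.reject_reason, ["abs", "sd"]).sum()
    dropped = (rsvp_epochs.reject_reason == "adjacent").sum()
    assert retained + rejected + dropped == rsvp_epochs.n_epochs


def test_pipeline_rerun_bit_identical(quiet_profile, fast_paradigm):
    sess, _ = rb.generate_rsvp_session(quiet_profile, fast_paradigm, seed=13)
    a = rb.preprocess_session(sess)
    b = rb.preprocess_session(sess)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.reject_mask, b.reject_mask)
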