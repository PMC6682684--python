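"""Continuous-session cleaning and epoch extraction.

Pipeline order: common-average reference -> 0.5-10 Hz zero-phase Butterworth
bandpass -> 800 ms epochs with 200 ms pre-onset baseline correction ->
automatic artifact rejection (absolute 100 μV and 5x across-trial SD rules)
-> exclusion of the non-target epochs immediately following each RSVP target
(their epochs still contain the target-evoked response at a 10 Hz
presentation rate).

All transforms are pure: they return new objects and never mutate their
input. Rejected epochs stay in the container with a mask and a reason code,
so epoch-count conservation (retained + rejected + dropped = extracted) is
checkable at any point.

An ICA-based ocular-artifact correction stage used on real recordings is
represented by a pass-through hook (`ica_artifact_hook`): the simulator does
not generate ocular artifacts, and a real-data adapter may plug in there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import Session

__all__ = [
    "EpochSet",
    "common_average_reference",
    "bandpass_filter",
    "extract_epochs",
    "reject_artifacts",
    "drop_adjacent_nontargets",
    "ica_artifact_hook",
    "preprocess_session",
]


@dataclass
class EpochSet:
    """Time-locked epoch tensor with labels and a rejection mask.

    data: epochs x channels x samples (μV), spanning [0, 800) ms post-onset
    after baseline correction over [-200, 0) ms. info carries one row per
    epoch (label, trial_id, flash_id, character, sample). reject_mask is True
    for epochs excluded from analysis; reject_reason holds 'abs', 'sd',
    'adjacent' or ''.
    """

    data: np.ndarray
    labels: np.ndarray
    rate: float
    channel_names: tuple[str, ...]
    info: pd.DataFrame
    reject_mask: np.ndarray
    reject_reason: np.ndarray

    def __post_init__(self):
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.info) == len(self.reject_mask)
                == len(self.reject_reason) == n):
            raise ValueError("inconsistent epoch-set lengths")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def is_target(self) -> np.ndarray:
        return self.labels == "target"

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx].copy(),
            labels=self.labels[idx].copy(),
            rate=self.rate,
            channel_names=self.channel_names,
            info=self.info.iloc[idx].reset_index(drop=True),
            reject_mask=self.reject_mask[idx].copy(),
            reject_reason=self.reject_reason[idx].copy(),
        )

    def retained(self) -> "EpochSet":
        """Epochs surviving every rejection rule."""
        return self.subset(np.flatnonzero(~self.reject_mask))


def common_average_reference(session: Session) -> Session:
    """Subtract the instantaneous across-channel mean from every channel."""
    if session.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    sig = session.signal - session.signal.mean(axis=0, keepdims=True)
    return replace(session, signal=sig, events=session.events.copy())


def bandpass_filter(session: Session, low: float = 0.5, high: float = 10.0,
                    order: int = 4) -> Session:
    """Zero-phase 4th-order Butterworth bandpass (0.5-10 Hz).

    Applied forward-backward (sosfiltfilt) so the effective magnitude
    response is |H(f)|^2 and ERP latencies are not shifted by group delay.
    """
    nyq = session.rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"cutoffs ({low}, {high}) violate 0 < low < high < "
                         f"Nyquist ({nyq})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=session.rate,
                     output="sos")
    sig = sps.sosfiltfilt(sos, session.signal, axis=1)
    return replace(session, signal=sig, events=session.events.copy())


def extract_epochs(session: Session,
                   window_ms: tuple[float, float] = (0.0, 800.0),
                   baseline_ms: tuple[float, float] = (-200.0, 0.0),
                   ) -> EpochSet:
    """Cut per-event epochs and baseline-correct each one.

    Windows are half-open in samples: an 800 ms epoch at 512 Hz has
    floor(0.8 * 512) = 409 samples including the onset sample; the 200 ms
    baseline has floor(0.2 * 512) = 102 samples strictly before onset. The
    per-epoch, per-channel baseline mean is subtracted. Events too close to a
    recording edge are dropped with a warning.
    """
    rate = session.rate
    n_post = int(math.floor((window_ms[1] - window_ms[0]) / 1000.0 * rate))
    n_base = int(math.floor((baseline_ms[1] - baseline_ms[0]) / 1000.0 * rate))
    start_off = int(round(window_ms[0] / 1000.0 * rate))

    onsets = session.events["sample"].to_numpy()
    ok = (onsets + start_off - n_base >= 0) & \
         (onsets + start_off + n_post <= session.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} event(s) too close to the "
                      "recording edge", stacklevel=2)
    events = session.events.loc[ok].reset_index(drop=True)
    starts = events["sample"].to_numpy() + start_off

    idx = starts[:, None] + np.arange(-n_base, n_post)[None, :]
    cuts = session.signal[:, idx]                 # ch x epochs x (base+post)
    cuts = np.moveaxis(cuts, 0, 1)                # epochs x ch x samples
    baseline = cuts[:, :, :n_base].mean(axis=2, keepdims=True) if n_base else 0.0
    data = cuts[:, :, n_base:] - baseline

    n = len(events)
    return EpochSet(
        data=np.ascontiguousarray(data),
        labels=events["stim_type"].to_numpy(dtype=object).astype(str),
        rate=rate,
        channel_names=session.channel_names,
        info=events.rename(columns={"stim_type": "label"}),
        reject_mask=np.zeros(n, dtype=bool),
        reject_reason=np.array([""] * n, dtype=object),
    )


def reject_artifacts(epochs: EpochSet, abs_thresh: float = 100.0,
                     sd_mult: float = 5.0) -> EpochSet:
    """Flag artifact epochs by amplitude and across-trial-SD rules.

    An epoch is rejected when its peak absolute amplitude on any channel
    exceeds ``abs_thresh`` μV (reason 'abs'), or when on any channel its peak
    absolute amplitude deviates from the across-trial mean by more than
    ``sd_mult`` sample SDs (reason 'sd'). The mean and SD for an epoch are
    computed over the *other* epochs (leave-one-out): with the tested epoch
    included, a single extreme epoch inflates the SD enough to mask itself —
    the largest attainable deviation at n epochs is (n-1)/sqrt(n) SDs, below
    a 5-SD threshold for any n < 27. Previously set masks are preserved.
    """
    n = epochs.n_epochs
    if n == 0:
        raise ValueError("empty epoch set")
    if n < 3:
        raise ValueError("the leave-one-out SD rule needs >= 3 epochs")
    peak = np.abs(epochs.data).max(axis=2)          # epochs x channels
    abs_hit = (peak > abs_thresh).any(axis=1)
    s1 = peak.sum(axis=0, keepdims=True)
    s2 = (peak ** 2).sum(axis=0, keepdims=True)
    loo_mean = (s1 - peak) / (n - 1)
    loo_var = (s2 - peak ** 2 - (n - 1) * loo_mean ** 2) / (n - 2)
    loo_sd = np.sqrt(np.maximum(loo_var, 0.0))
    tol = 1e-9 * np.maximum(1.0, np.abs(loo_mean))  # absorb float round-off
    sd_hit = (np.abs(peak - loo_mean) > sd_mult * loo_sd + tol).any(axis=1)

    mask = epochs.reject_mask.copy()
    reason = epochs.reject_reason.copy()
    new_abs = abs_hit & ~mask
    reason[new_abs] = "abs"
    new_sd = sd_hit & ~mask & ~new_abs
    reason[new_sd] = "sd"
    mask = mask | abs_hit | sd_hit
    return replace(epochs, data=epochs.data.copy(), labels=epochs.labels.copy(),
                   info=epochs.info.copy(), reject_mask=mask,
                   reject_reason=reason)


def drop_adjacent_nontargets(epochs: EpochSet, k: int = 3) -> EpochSet:
    """Exclude the k non-target epochs following each RSVP target.

    At a 10 Hz presentation rate the epochs of the next few non-targets still
    contain the target-evoked response, so for each target at stream position
    p the non-targets at positions p+1 .. p+k of the same trial are masked
    with reason 'adjacent'.
    """
    for col in ("trial_id", "flash_id"):
        if col not in epochs.info.columns:
            raise ValueError(f"missing stream-position metadata column {col!r}")
    trial = epochs.info["trial_id"].to_numpy()
    pos = epochs.info["flash_id"].to_numpy()
    mask = epochs.reject_mask.copy()
    reason = epochs.reject_reason.copy()
    target_rows = np.flatnonzero(epochs.is_target)
    hit = np.zeros(epochs.n_epochs, dtype=bool)
    for r in target_rows:
        same = (trial == trial[r]) & (pos > pos[r]) & (pos <= pos[r] + k) \
            & ~epochs.is_target
        hit |= same
    reason[hit & ~mask] = "adjacent"
    return replace(epochs, data=epochs.data.copy(), labels=epochs.labels.copy(),
                   info=epochs.info.copy(), reject_mask=mask | hit,
                   reject_reason=reason)


def ica_artifact_hook(session: Session) -> Session:
    """Pass-through ocular-artifact correction hook (identity on synthetic data)."""
    return session


def preprocess_session(session: Session, low: float = 0.5, high: float = 10.0,
                       abs_thresh: float = 100.0, sd_mult: float = 5.0,
                       adjacent_k: int = 3) -> EpochSet:
    """Full cleaning chain for one session.

    CAR -> bandpass -> (ICA hook) -> epochs -> artifact rejection, plus the
    adjacent-non-target exclusion for RSVP sessions.
    """
    sess = common_average_reference(session)
    sess = bandpass_filter(sess, low=low, high=high)
    sess = ica_artifact_hook(sess)
    epochs = extract_epochs(sess)
    epochs = reject_artifacts(epochs, abs_thresh=abs_thresh, sd_mult=sd_mult)
    if session.kind == "rsvp":
        epochs = drop_adjacent_nontargets(epochs, k=adjacent_k)
    return epochs
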