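"""RSVP feature extraction: the five per-subject predictors.

X1 = RSVP T1% (behavioral target-detection accuracy; a non-response counts
as a wrong answer), X2/X3 = mean single-trial P300 amplitude (μV) and
latency (ms) on the channel-averaged (Fz, Cz, Pz, CP1, CP2) waveform, and
X4/X5 = the across-trial sample SDs of the same per-trial amplitude and
latency series ("trial variations").

Per-trial definition: the peak is searched on each retained target epoch
separately (250-750 ms window, earliest sample on ties); the amplitude is
the mean over +-50 ms around that peak, clipped at epoch edges. X2/X3 are
the means of this per-trial series so that X4/X5 are the SDs of the exact
same quantities — one consistent estimator for level and variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ERP_CHANNELS
from .preprocess import EpochSet

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "channel_average",
    "p300_peak",
    "trial_variation",
    "rsvp_t1_percent",
    "per_trial_measurements",
    "subject_features",
    "features_from_trials",
    "per_channel_measurements",
]

FEATURE_NAMES = ("t1_percent", "p300_amplitude", "p300_latency",
                 "amp_trial_sd", "lat_trial_sd")


@dataclass(frozen=True)
class FeatureVector:
    """The five RSVP predictors for one subject."""

    t1_percent: float        # X1, %
    p300_amplitude: float    # X2, μV
    p300_latency: float      # X3, ms
    amp_trial_sd: float      # X4, μV
    lat_trial_sd: float      # X5, ms
    n_trials_used: int

    def __post_init__(self):
        if not (0.0 <= self.t1_percent <= 100.0):
            raise ValueError("t1_percent outside [0, 100]")
        if self.amp_trial_sd < 0 or self.lat_trial_sd < 0:
            raise ValueError("trial variations must be non-negative")

    def to_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in FEATURE_NAMES}
                         | {"n_trials_used": self.n_trials_used})


def channel_average(epochs: EpochSet,
                    channels: tuple[str, ...] = ERP_CHANNELS) -> EpochSet:
    """Sample-wise mean over a channel subset -> single-channel epoch set."""
    missing = [c for c in channels if c not in epochs.channel_names]
    if missing:
        raise ValueError(f"channels not in montage: {missing}")
    idx = [epochs.channel_names.index(c) for c in channels]
    data = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=data, labels=epochs.labels.copy(),
                   channel_names=("avg",), info=epochs.info.copy(),
                   reject_mask=epochs.reject_mask.copy(),
                   reject_reason=epochs.reject_reason.copy())


def _search_slice(n_samples: int, rate: float,
                  search_ms: tuple[float, float]) -> tuple[int, int]:
    i0 = int(math.ceil(search_ms[0] / 1000.0 * rate))
    i1 = int(math.floor(search_ms[1] / 1000.0 * rate))
    return max(i0, 0), min(i1, n_samples - 1)


def p300_peak(waveform: np.ndarray, rate: float,
              search_ms: tuple[float, float] = (250.0, 750.0),
              halfwindow_ms: float = 50.0) -> tuple[float, float]:
    """Single-epoch P300 measure on one waveform.

    Latency = time of the maximum sample within the search window (earliest
    sample on ties); amplitude = mean of the samples within +-halfwindow_ms
    of that peak, with the window clipped at the epoch edges.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if np.isnan(waveform).all():
        raise ValueError("all-NaN epoch")
    i0, i1 = _search_slice(waveform.size, rate, search_ms)
    seg = waveform[i0:i1 + 1]
    peak = i0 + int(np.argmax(seg))        # argmax returns the first maximum
    half = int(round(halfwindow_ms / 1000.0 * rate))
    lo, hi = max(peak - half, 0), min(peak + half, waveform.size - 1)
    return float(waveform[lo:hi + 1].mean()), peak / rate * 1000.0


def trial_variation(values) -> float:
    """Across-trial sample SD (n-1 denominator) of a per-trial measure."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("trial variation needs >= 2 trials")
    return float(values.std(ddof=1))


def rsvp_t1_percent(log: pd.DataFrame) -> float:
    """Percent of RSVP trials with a correct target report."""
    if len(log) == 0:
        raise ValueError("empty behavior log")
    return 100.0 * float(log["correct"].mean())


def per_trial_measurements(epochs: EpochSet,
                           channels: tuple[str, ...] = ERP_CHANNELS,
                           search_ms: tuple[float, float] = (250.0, 750.0),
                           ) -> pd.DataFrame:
    """Per-trial P300 amplitude/latency series from retained target epochs.

    Returns a tidy table (trial_id, amplitude, latency), one row per retained
    target epoch, measured on the channel-averaged waveform. This table is
    the common substrate of `subject_features` and the trial-count sweep.
    """
    avg = channel_average(epochs, channels)
    keep = avg.is_target & ~avg.reject_mask
    rows = []
    for i in np.flatnonzero(keep):
        amp, lat = p300_peak(avg.data[i, 0], avg.rate, search_ms=search_ms)
        rows.append((int(avg.info["trial_id"].iloc[i]), amp, lat))
    return pd.DataFrame(rows, columns=["trial_id", "amplitude", "latency"])


def features_from_trials(trials: pd.DataFrame, log: pd.DataFrame,
                         first_n: int | None = None) -> FeatureVector:
    """Build the feature vector from a per-trial measurement table.

    ``first_n`` restricts the analysis to the first N RSVP trials: the ERP
    series uses the first min(N, retained) retained target trials in
    presentation order (artifact rejection leaves different trials per
    subject, so fewer than N may remain) and the behavioral log the first N
    trials.
    """
    if first_n is not None:
        trials = trials.sort_values("trial_id").head(first_n)
        log = log[log["trial_id"] < first_n]
    if len(trials) < 5:
        raise ValueError("need >= 5 retained target trials for trial-variation "
                         f"features, got {len(trials)}")
    amps = trials["amplitude"].to_numpy()
    lats = trials["latency"].to_numpy()
    return FeatureVector(
        t1_percent=rsvp_t1_percent(log),
        p300_amplitude=float(amps.mean()),
        p300_latency=float(lats.mean()),
        amp_trial_sd=trial_variation(amps),
        lat_trial_sd=trial_variation(lats),
        n_trials_used=len(trials),
    )


def subject_features(rsvp_epochs: EpochSet, log: pd.DataFrame,
                     first_n: int | None = None,
                     channels: tuple[str, ...] = ERP_CHANNELS) -> FeatureVector:
    """X1..X5 for one subject from preprocessed RSVP epochs and the log."""
    trials = per_trial_measurements(rsvp_epochs, channels=channels)
    return features_from_trials(trials, log, first_n=first_n)


def per_channel_measurements(epochs: EpochSet,
                             search_ms: tuple[float, float] = (250.0, 750.0),
                             halfwindow_ms: float = 50.0,
                             ) -> pd.DataFrame:
    """Per-channel ERP measures for topography analyses.

    For every channel separately, measures the per-trial peak on each
    retained target epoch and summarizes: mean amplitude, mean latency and
    their across-trial SDs. Returns one row per channel.
    """
    keep = np.flatnonzero(epochs.is_target & ~epochs.reject_mask)
    if keep.size < 2:
        raise ValueError("need >= 2 retained target epochs")
    data = epochs.data[keep]                    # trials x channels x samples
    rate = epochs.rate
    i0, i1 = _search_slice(data.shape[2], rate, search_ms)
    seg = data[:, :, i0:i1 + 1]
    peak_rel = seg.argmax(axis=2)
    peak = i0 + peak_rel                        # trials x channels
    half = int(round(halfwindow_ms / 1000.0 * rate))
    n_samp = data.shape[2]
    amps = np.empty(peak.shape)
    for t in range(peak.shape[0]):
        for c in range(peak.shape[1]):
            lo, hi = max(peak[t, c] - half, 0), min(peak[t, c] + half, n_samp - 1)
            amps[t, c] = data[t, c, lo:hi + 1].mean()
    lats = peak / rate * 1000.0
    return pd.DataFrame({
        "channel": list(epochs.channel_names),
        "p300_amplitude": amps.mean(axis=0),
        "p300_latency": lats.mean(axis=0),
        "amp_trial_sd": amps.std(axis=0, ddof=1),
        "lat_trial_sd": lats.std(axis=0, ddof=1),
    })
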