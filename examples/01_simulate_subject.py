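"""Simulate one subject's RSVP run and inspect the raw session.

Draws a cohort profile, synthesizes the 40-trial RSVP stream session and
prints the paradigm bookkeeping: 21 stimuli per trial at 10 Hz, exactly one
green target per stream, and the behavioral log the T1% feature is computed
from.
"""

import rsvpbci as rb

profile = rb.sample_cohort(n_subjects=1, seed=7)[0]
print(f"latent profile: amplitude {profile.amp_mean:.2f} uV, "
      f"latency {profile.lat_mean:.0f} ms, latency jitter "
      f"{profile.lat_sd:.0f} ms, P(correct report) {profile.t1_prob:.2f}")

config = rb.ParadigmConfig(sampling_rate=256.0, response_window=1.0)
session, behavior = rb.generate_rsvp_session(profile, config, seed=1)

targets = (session.events.stim_type == "target").sum()
print(f"session: {session.n_channels} channels x {session.n_samples} samples "
      f"at {session.rate:.0f} Hz")
print(f"events: {len(session.events)} stimuli, {targets} targets "
      f"(one per trial x {config.rsvp_trials} trials)")
print(f"behavior: {behavior.correct.sum()}/{len(behavior)} targets reported "
      f"correctly -> T1% = {rb.rsvp_t1_percent(behavior):.1f}")
# The T1% printed here is the X1 predictor; the EEG features follow in
# example 02 after preprocessing.
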