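"""How many RSVP trials are enough? Sweep the task length.

Recomputes the features from the first N trials only (N = 5..40) and tracks
the correlation of each feature with speller AUC. In the full study the
correlation strength stabilizes by roughly 25 trials, i.e. half the task
suffices for prediction.
"""

import rsvpbci as rb

config = rb.RunConfig(
    seed=4,
    n_subjects=16,
    paradigm=rb.ParadigmConfig(sampling_rate=128.0, response_window=0.5,
                               repetitions=4, test_words=("NEURONS",)),
    folds=5,
)
result = rb.run_full_study(config)

sweep = rb.trial_sweep(result.trial_tables, result.logs, result.auc,
                       n_range=range(5, 41, 5), include_multi=False)
pivot = sweep.pivot(index="N", columns="predictor", values="r").round(2)
print(pivot[["p300_amplitude", "lat_trial_sd", "t1_percent"]])
# |r| of the latency-variation feature should be near its final value well
# before N = 40; early N are noisy because the trial-level SD itself is
# estimated from few trials.
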