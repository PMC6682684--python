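"""Score a matrix-speller session with cross-validated SWLDA.

Simulates speller test runs, cuts flash-locked epochs, decimates each to
channel x time-block features and runs stepwise linear discriminant analysis
(max 60 features, p-enter 0.10 / p-remove 0.15) under stratified 10-fold
cross-validation. The mean AUC over folds is the subject's single-trial
offline performance; targets and non-targets are 1:5, which is why AUC
rather than accuracy is the metric.
"""

import rsvpbci as rb

profile = rb.sample_cohort(n_subjects=1, seed=7)[0]
config = rb.ParadigmConfig(sampling_rate=256.0, repetitions=5,
                           test_words=("SUBJECT", "NEURONS"))

session = rb.generate_speller_session(profile, config, config.test_words,
                                      seed=2)
targets = (session.events.stim_type == "target").sum()
print(f"flash events: {len(session.events)} ({targets} target, "
      f"{len(session.events) - targets} non-target)")

epochs = rb.preprocess_session(session)
mean_auc, fold_aucs = rb.crossval_auc(epochs, k=10, seed=3)
print("per-fold AUC:", " ".join(f"{a:.3f}" for a in fold_aucs))
print(f"mean 10-fold AUC = {mean_auc:.3f}")
# ~0.5 would be chance; well-performing subjects in this paradigm sit
# around 0.8-0.9.
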