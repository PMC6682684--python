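"""End-to-end study orchestration.

``run_full_study`` ties all stages together for one simulated cohort:
simulate RSVP and speller sessions per subject -> preprocess -> extract the
five RSVP features -> cross-validated SWLDA speller AUC -> outlier screen ->
seven-predictor regression table (in-sample and leave-one-subject-out, with
and without outliers) -> group contrasts and channel topographies -> optional
trial-count sweep. Every source of randomness derives from one top-level
seed via spawned child streams, so a config plus seed reproduces the whole
bundle bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (ERP_CHANNELS, ParadigmConfig, PopulationSpec,
                     generate_rsvp_session, generate_speller_session,
                     sample_cohort)
from .cohort_stats import (correlation_topography, detect_outliers, pearson,
                           split_groups, trial_sweep, unpaired_ttest)
from .features import (FEATURE_NAMES, features_from_trials,
                       per_channel_measurements, per_trial_measurements)
from .io import save_session
from .predictor import predictor_table
from .preprocess import preprocess_session
from .swlda import crossval_auc

__all__ = ["RunConfig", "StudyResult", "run_subject", "run_full_study",
           "make_fixture"]

log = logging.getLogger("rsvpbci")


@dataclass
class RunConfig:
    """Serializable configuration of one full study run."""

    seed: int = 0
    n_subjects: int = 48
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    # preprocessing
    low_hz: float = 0.5
    high_hz: float = 10.0
    abs_thresh: float = 100.0
    sd_mult: float = 5.0
    adjacent_k: int = 3
    # classifier
    folds: int = 10
    max_features: int = 60
    p_enter: float = 0.10
    p_remove: float = 0.15
    decim_block: int = 24
    # cohort statistics
    n_top: int = 10
    outlier_k: float = 2.5
    fdr_q: float = 0.1
    run_trial_sweep: bool = False
    sweep_step: int = 5

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "paradigm" in d:
            p = d["paradigm"]
            for key in ("channel_names", "calib_words", "test_words"):
                if key in p:
                    p[key] = tuple(p[key])
            d["paradigm"] = ParadigmConfig(**p)
        if "population" in d:
            d["population"] = PopulationSpec(
                **{k: tuple(v) if isinstance(v, (list, tuple)) else v
                   for k, v in d["population"].items()})
        return cls(**d)


@dataclass
class StudyResult:
    """In-memory report bundle of one study run."""

    config: RunConfig
    profiles: list
    features: pd.DataFrame          # subjects x (X1..X5, n_trials_used)
    auc: pd.Series                  # subjects -> mean 10-fold AUC
    fold_aucs: pd.DataFrame         # subject, fold, auc
    outliers: list
    predictors: pd.DataFrame        # 7 predictors x {in_sample, loso} x {all, no_outliers}
    group_stats: pd.DataFrame
    topography: pd.DataFrame
    sweep: pd.DataFrame | None
    manifest: dict
    trial_tables: dict = field(default_factory=dict, repr=False)
    logs: dict = field(default_factory=dict, repr=False)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage integer seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run_subject(profile, config: RunConfig, seed: int,
                words: tuple[str, ...] | None = None) -> dict:
    """Simulate and analyze a single subject.

    Returns per-trial RSVP measurements, the behavior log, the feature
    vector, the speller cross-validated AUC and per-stage epoch counters.
    """
    rsvp_seed, speller_seed, cv_seed = _spawn_seeds(seed, 3)
    paradigm = config.paradigm
    words = words or paradigm.test_words

    rsvp, behavior = generate_rsvp_session(profile, paradigm, seed=rsvp_seed)
    rsvp_epochs = preprocess_session(rsvp, low=config.low_hz, high=config.high_hz,
                                     abs_thresh=config.abs_thresh,
                                     sd_mult=config.sd_mult,
                                     adjacent_k=config.adjacent_k)
    trials = per_trial_measurements(rsvp_epochs)
    feats = features_from_trials(trials, behavior)
    per_channel = per_channel_measurements(rsvp_epochs)

    speller = generate_speller_session(profile, paradigm, words,
                                       seed=speller_seed)
    speller_epochs = preprocess_session(speller, low=config.low_hz,
                                        high=config.high_hz,
                                        abs_thresh=config.abs_thresh,
                                        sd_mult=config.sd_mult)
    mean_auc, fold_aucs = crossval_auc(speller_epochs, k=config.folds,
                                       seed=cv_seed,
                                       max_features=config.max_features,
                                       p_enter=config.p_enter,
                                       p_remove=config.p_remove,
                                       block=config.decim_block)
    counters = {}
    for name, ep in (("rsvp", rsvp_epochs), ("speller", speller_epochs)):
        counters[name] = {
            "extracted": int(ep.n_epochs),
            "rejected": int(np.isin(ep.reject_reason, ["abs", "sd"]).sum()),
            "dropped_adjacent": int((ep.reject_reason == "adjacent").sum()),
            "retained": int((~ep.reject_mask).sum()),
        }
    return {"trials": trials, "behavior": behavior, "features": feats,
            "per_channel": per_channel, "auc": mean_auc,
            "fold_aucs": fold_aucs, "counters": counters}


def _predictor_block(features: pd.DataFrame, auc: pd.Series, subset,
                     label: str) -> pd.DataFrame:
    table = predictor_table(features.loc[subset, list(FEATURE_NAMES)],
                            auc.loc[subset])
    table.insert(0, "cohort", label)
    return table


def run_full_study(config: RunConfig, out_dir=None) -> StudyResult:
    """Run the complete simulated study for one cohort."""
    profiles = sample_cohort(config.n_subjects, config.population,
                             seed=config.seed,
                             channel_names=config.paradigm.channel_names)
    subj_seeds = _spawn_seeds(config.seed + 1, config.n_subjects)

    rows, auc_map, fold_rows, counters = {}, {}, [], []
    trial_tables, logs, per_channel = {}, {}, {}
    for profile, sseed in zip(profiles, subj_seeds):
        res = run_subject(profile, config, sseed)
        sid = profile.subject_id
        rows[sid] = res["features"].to_series()
        auc_map[sid] = res["auc"]
        trial_tables[sid] = res["trials"]
        logs[sid] = res["behavior"]
        per_channel[sid] = res["per_channel"]
        counters.append(res["counters"])
        for f, a in enumerate(res["fold_aucs"]):
            fold_rows.append((sid, f, a))
        log.info("subject %s: auc=%.3f retained_rsvp=%d", sid, res["auc"],
                 res["counters"]["rsvp"]["retained"])

    features = pd.DataFrame(rows).T
    auc = pd.Series(auc_map, name="auc")
    fold_aucs = pd.DataFrame(fold_rows, columns=["subject", "fold", "auc"])

    outliers = detect_outliers(auc, k=config.outlier_k)
    keep = [s for s in auc.index if s not in outliers]
    predictors = pd.concat(
        [_predictor_block(features, auc, list(auc.index), "with_outliers"),
         _predictor_block(features, auc, keep, "without_outliers")],
        ignore_index=True)

    # group contrast on channel-averaged features (top vs bottom performers)
    n_top = min(config.n_top, config.n_subjects // 2)  # keep groups disjoint
    high, low = split_groups(auc, n_top=n_top, n_bottom=n_top)
    grows = []
    for name in FEATURE_NAMES[1:]:
        t, p = unpaired_ttest(features.loc[high, name], features.loc[low, name])
        grows.append((name, features.loc[high, name].mean(),
                      features.loc[low, name].mean(), t, p))
    group_stats = pd.DataFrame(
        grows, columns=["feature", "high_mean", "low_mean", "t", "p"])

    # channel-wise correlation topography per EEG feature
    topo_frames = []
    for name in FEATURE_NAMES[1:]:
        mat = pd.DataFrame({s: per_channel[s].set_index("channel")[name]
                            for s in auc.index}).T
        topo = correlation_topography(mat, auc, q=config.fdr_q)
        topo.insert(0, "feature", name)
        topo_frames.append(topo)
    topography = pd.concat(topo_frames, ignore_index=True)

    sweep = None
    if config.run_trial_sweep:
        n_range = range(5, config.paradigm.rsvp_trials + 1, config.sweep_step)
        sweep = trial_sweep(trial_tables, logs, auc, n_range=n_range)

    total = {k: sum(c[s][k] for c in counters for s in ("rsvp", "speller"))
             for k in ("extracted", "rejected", "dropped_adjacent", "retained")}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "config": config.to_dict(),
        "epoch_counts": total,
        "rejection_percent": 100.0 * total["rejected"] / total["extracted"],
        "outliers": outliers,
        "mean_auc": float(auc.mean()),
    }
    manifest["config"]["paradigm"]["channel_names"] = \
        list(manifest["config"]["paradigm"]["channel_names"])

    result = StudyResult(config=config, profiles=profiles, features=features,
                         auc=auc, fold_aucs=fold_aucs, outliers=outliers,
                         predictors=predictors, group_stats=group_stats,
                         topography=topography, sweep=sweep, manifest=manifest,
                         trial_tables=trial_tables, logs=logs)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: StudyResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "features.tsv": result.features.rename_axis("subject_id").reset_index(),
        "auc_summary.tsv": result.auc.rename_axis("subject_id").reset_index(),
        "auc.tsv": result.fold_aucs,
        "predictor_report.tsv": result.predictors,
        "group_stats.tsv": result.group_stats,
        "topography.tsv": result.topography,
    }
    if result.sweep is not None:
        files["trial_sweep.tsv"] = result.sweep
    hashes = {}
    for name, frame in files.items():
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = dict(result.manifest, file_sha256=hashes)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def make_fixture(name: str, seed: int, out_dir) -> Path:
    """Write a ready-made session bundle to disk.

    ``smoke``: 6 subjects, 10 RSVP trials, one test word — a fast format
    check. ``cohort48``: the full-size study emulation (48 subjects, 40 RSVP
    trials, four test words).
    """
    if name == "smoke":
        n_subjects = 6
        paradigm = ParadigmConfig(rsvp_trials=10, response_window=1.0,
                                  test_words=("BRAIN",), repetitions=3)
    elif name == "cohort48":
        n_subjects = 48
        paradigm = ParadigmConfig()
    else:
        raise ValueError(f"unknown fixture {name!r}")
    out = Path(out_dir)
    profiles = sample_cohort(n_subjects, seed=seed,
                             channel_names=paradigm.channel_names)
    seeds = _spawn_seeds(seed + 1, n_subjects)
    for profile, sseed in zip(profiles, seeds):
        s1, s2 = _spawn_seeds(sseed, 2)
        rsvp, behavior = generate_rsvp_session(profile, paradigm, seed=s1)
        save_session(rsvp, out / profile.subject_id / "rsvp", behavior=behavior)
        speller = generate_speller_session(profile, paradigm,
                                           paradigm.test_words, seed=s2)
        save_session(speller, out / profile.subject_id / "speller_test")
    return out
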