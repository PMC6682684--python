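"""Cohort-level statistics: group contrasts, correlation topographies,
FDR correction, outlier screening and the RSVP trial-count sweep."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as spst
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES, features_from_trials
from .predictor import loso_evaluate

__all__ = [
    "pearson",
    "split_groups",
    "unpaired_ttest",
    "fdr_bh",
    "correlation_topography",
    "detect_outliers",
    "trial_sweep",
]


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value.

    p comes from the t-transform t = r * sqrt((n-2) / (1-r^2)) with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = spst.pearsonr(x, y)
    return float(r), float(p)


def split_groups(auc: pd.Series, n_top: int = 10, n_bottom: int = 10,
                 ) -> tuple[list, list]:
    """Top/bottom performer groups by speller AUC.

    Sorts ascending with ties broken by subject id (deterministic) and
    returns (high ids, low ids).
    """
    if len(auc) < n_top + n_bottom:
        raise ValueError("cohort smaller than n_top + n_bottom")
    order = auc.reset_index()
    order.columns = ["subject", "auc"]
    order = order.sort_values(["auc", "subject"], kind="mergesort")
    low = order["subject"].iloc[:n_bottom].tolist()
    high = order["subject"].iloc[-n_top:].tolist()
    return high, low


def unpaired_ttest(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance; Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = spst.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t):
        raise ValueError("zero pooled variance")
    return float(t), float(p)


def fdr_bh(pvalues, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at FDR level q.

    Flags every p <= p_(k) where k is the largest index with
    p_(k) <= k * q / m.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def correlation_topography(per_channel: pd.DataFrame, auc: pd.Series,
                           q: float = 0.1) -> pd.DataFrame:
    """Channel-wise Pearson correlation of a feature with speller AUC.

    ``per_channel`` is subjects x channels (one column per montage channel,
    aligned to the same subjects as ``auc``). Returns one row per channel
    with r, the uncorrected p and the BH-FDR flag at level ``q``.
    """
    if len(per_channel) != len(auc):
        raise ValueError("subject counts differ")
    y = np.asarray(auc, dtype=float)
    rs, ps = [], []
    for col in per_channel.columns:
        r, p = pearson(per_channel[col].to_numpy(), y)
        rs.append(r)
        ps.append(p)
    return pd.DataFrame({"channel": list(per_channel.columns), "r": rs,
                         "p_uncorrected": ps,
                         "fdr_significant": fdr_bh(ps, q=q)})


def detect_outliers(auc: pd.Series, k: float = 2.5,
                    two_sided: bool = False) -> list:
    """Subjects whose AUC falls below mean - k * SD (low performers).

    The study flags only under-performers; ``two_sided`` also flags the
    high side.
    """
    if len(auc) < 3:
        raise ValueError("need >= 3 subjects")
    vals = np.asarray(auc, dtype=float)
    sd = vals.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(vals).max())):
        raise ValueError("zero SD across subjects")
    mu = vals.mean()
    low = vals < mu - k * sd
    flag = low | (vals > mu + k * sd) if two_sided else low
    return list(pd.Series(auc).index[flag])


def trial_sweep(trial_tables: dict, logs: dict, auc: pd.Series,
                n_range=range(5, 41), include_multi: bool = True,
                ) -> pd.DataFrame:
    """Correlation with speller AUC as a function of RSVP task length.

    For each N in ``n_range`` the five features are recomputed from RSVP
    trials 1..N per subject (subjects with fewer retained trials use all
    remaining) and correlated with AUC; optionally the two multi-feature
    predictors' LOSO outputs are correlated as well. ``trial_tables`` and
    ``logs`` map subject id -> per-trial measurement table / behavior log.

    Returns a tidy table (N, predictor, r, p).
    """
    if min(n_range) < 5:
        raise ValueError("trial variations need N >= 5")
    subjects = list(auc.index)
    y = auc.to_numpy(dtype=float)
    rows = []
    for n in n_range:
        feats = pd.DataFrame(
            [features_from_trials(trial_tables[s], logs[s], first_n=n)
             .to_series() for s in subjects], index=subjects)
        X = feats[list(FEATURE_NAMES)]
        for name in FEATURE_NAMES:
            r, p = pearson(X[name].to_numpy(), y)
            rows.append((n, name, r, p))
        if include_multi:
            for kind, label in (("multiple", "multi_regular"),
                                ("stepwise", "multi_stepwise")):
                _, st = loso_evaluate(X.to_numpy(), y, kind)
                rows.append((n, label, st.r, st.p))
    return pd.DataFrame(rows, columns=["N", "predictor", "r", "p"])
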