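"""Forward/backward stepwise least-squares feature selection.

The classic stepwise-regression loop behind SWLDA and stepwise linear
regression: starting from the empty model, repeatedly (a) add the candidate
feature whose partial-F p-value for entering is smallest, if below
``p_enter``; (b) remove any included feature whose partial-F p-value for
staying rises above ``p_remove``; stop when neither step changes the model
or a feature cap is reached. Coefficients are ordinary least squares on the
final set, with an intercept.

Implementation works on centered Gram matrices so each candidate evaluation
is a rank-one update: for the current set S with G = Xc'Xc, g = Xc'yc and
beta = G_SS^{-1} g_S, adding feature j reduces the residual sum of squares by
(g_j - G_jS beta)^2 / (G_jj - G_jS G_SS^{-1} G_Sj), which is evaluated for
all candidates at once. This keeps a 544-feature SWLDA fit at a few
milliseconds per step instead of refitting hundreds of regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spst

__all__ = ["StepwiseResult", "stepwise_select"]

_RIDGE = 1e-10   # relative collinearity guard on the partial variance


@dataclass(frozen=True)
class StepwiseResult:
    """Selected feature indices (in order of entry) and the OLS fit on them."""

    selected: tuple[int, ...]
    coef: np.ndarray          # per selected feature
    intercept: float
    rss: float
    n_obs: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.selected:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, list(self.selected)] @ self.coef


def _fit_on(G, g, yy, S):
    """beta and RSS of the centered OLS on index set S."""
    if not S:
        return np.empty(0), float(yy)
    GS = G[np.ix_(S, S)]
    beta = np.linalg.solve(GS, g[S])
    return beta, float(yy - g[S] @ beta)


def stepwise_select(X: np.ndarray, y: np.ndarray, p_enter: float = 0.10,
                    p_remove: float = 0.15, max_features: int | None = None,
                    ) -> StepwiseResult:
    """Run the forward/backward loop on design X (rows x features).

    ``y`` may be a continuous outcome or a +-1 class coding (the SWLDA use).
    Returns an empty model (intercept = mean of y, constant predictions)
    when no feature meets ``p_enter``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if n != y.size:
        raise ValueError("X and y row counts differ")
    if n <= 2:
        raise ValueError("need more than 2 observations")
    if max_features is None:
        max_features = m

    xm = X.mean(axis=0)
    Xc = X - xm
    yc = y - y.mean()
    G = Xc.T @ Xc
    g = Xc.T @ yc
    yy = float(yc @ yc)
    diag = np.diag(G).copy()
    usable = diag > _RIDGE * max(diag.max(), 1.0)   # drop zero-variance columns

    S: list[int] = []
    beta, rss = _fit_on(G, g, yy, S)
    seen: set[frozenset] = set()

    for _ in range(4 * m + 8):
        changed = False
        k = len(S)
        # --- forward step -------------------------------------------------
        if k < max_features and n - k - 2 > 0:
            cand = np.array([j for j in range(m) if usable[j] and j not in S],
                            dtype=int)
            if cand.size:
                if S:
                    A = G[np.ix_(S, cand)]                  # k x m_c
                    B = np.linalg.solve(G[np.ix_(S, S)], A)
                    denom = diag[cand] - np.einsum("ij,ij->j", A, B)
                    numer = g[cand] - beta @ A
                else:
                    denom = diag[cand]
                    numer = g[cand]
                ok = denom > _RIDGE * max(diag.max(), 1.0)
                red = np.zeros(cand.size)
                red[ok] = numer[ok] ** 2 / denom[ok]
                df2 = n - k - 2
                with np.errstate(divide="ignore", invalid="ignore"):
                    rss_new = rss - red
                    F = red * df2 / np.maximum(rss_new, 1e-300)
                pvals = np.where(ok, spst.f.sf(F, 1, df2), np.inf)
                best = int(np.argmin(pvals))
                if pvals[best] < p_enter:
                    S.append(int(cand[best]))
                    beta, rss = _fit_on(G, g, yy, S)
                    changed = True
        # --- backward step ------------------------------------------------
        while len(S) > 0:
            k = len(S)
            df2 = n - k - 1
            if df2 <= 0:
                break
            Ginv = np.linalg.inv(G[np.ix_(S, S)])
            s2 = rss / df2
            F_stay = beta ** 2 / (np.diag(Ginv) * s2)
            p_stay = spst.f.sf(F_stay, 1, df2)
            worst = int(np.argmax(p_stay))
            if p_stay[worst] > p_remove:
                S.pop(worst)
                beta, rss = _fit_on(G, g, yy, S)
                changed = True
            else:
                break
        if not changed:
            break
        key = frozenset(S)
        if key in seen:          # cycle guard (add/remove ping-pong)
            break
        seen.add(key)

    intercept = float(y.mean() - (xm[S] @ beta if S else 0.0))
    return StepwiseResult(selected=tuple(S), coef=np.asarray(beta, dtype=float),
                          intercept=intercept, rss=float(rss), n_obs=n)
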