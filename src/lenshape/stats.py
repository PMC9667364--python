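"""Non-phylogenetic statistics: Welch t-tests, PCA and a collinearity screen."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(x, y) -> WelchResult:
    """Unequal-variance (Welch) two-sample t-test, two-sided.

    The Welch–Satterthwaite degrees of freedom are generally non-integer,
    which is how a Welch test can be recognized in reported results.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance; t undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    # Welch–Satterthwaite d.f. recomputed explicitly for the report.
    a, b = vx / len(x), vy / len(y)
    df = (a + b) ** 2 / (a ** 2 / (len(x) - 1) + b ** 2 / (len(y) - 1))
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


@dataclass(frozen=True)
class PCAResult:
    """Loadings (variables x components), variance proportions and scores."""

    loadings: pd.DataFrame
    proportion_variance: pd.Series
    scores: pd.DataFrame
    scaled: bool


def pca(data: pd.DataFrame, scale: bool = True,
        sign_anchor: str | None = "anisotropy") -> PCAResult:
    """PCA by eigendecomposition of the covariance or correlation matrix.

    With ``scale=True`` (default) variables are standardized first, i.e. the
    correlation matrix is decomposed — appropriate when traits have very
    different variances.  The overall sign of each component is arbitrary;
    for display comparability it is fixed so that the component's largest
    loading is positive, and then, if ``sign_anchor`` names a column, so
    that that column's PC1 loading is negative.
    """
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs >= 2 rows and >= 2 columns")
    if data.isna().any().any():
        raise ValueError("PCA input contains missing values")
    X = data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [c for c, s in zip(data.columns, sd) if s == 0]
            raise ValueError(f"constant columns cannot be scaled: {bad}")
        X = X / sd
    S = X.T @ X / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    if sign_anchor is not None and sign_anchor in data.columns:
        i = list(data.columns).index(sign_anchor)
        if evecs[i, 0] > 0:
            evecs[:, 0] = -evecs[:, 0]

    comps = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=data.columns, columns=comps)
    proportions = pd.Series(evals / evals.sum(), index=comps)
    scores = pd.DataFrame(X @ evecs, index=data.index, columns=comps)
    return PCAResult(loadings=loadings, proportion_variance=proportions,
                     scores=scores, scaled=scale)


#: Default keep-priority: earlier names survive a collinear pair.
DEFAULT_METRIC_PRIORITY = ("anisotropy", "sphericity", "elongation", "flatness")


def collinearity_screen(data: pd.DataFrame, threshold: float = 0.9,
                        priority=DEFAULT_METRIC_PRIORITY):
    """Drop the lower-priority member of every highly correlated metric pair.

    Returns ``(retained, dropped, corr)`` where ``dropped`` maps each removed
    column to the (partner, r) pair that triggered the removal.  Columns not
    named in ``priority`` rank below all named ones, ties broken by column
    order.
    """
    if data.shape[0] < 3:
        raise ValueError("need >= 3 rows to estimate correlations")
    corr = data.corr(method="pearson")
    rank = {name: i for i, name in enumerate(priority)}

    def prio(col):
        return (rank.get(col, len(priority)), list(data.columns).index(col))

    retained = list(data.columns)
    dropped: dict[str, tuple[str, float]] = {}
    pairs = sorted(
        ((a, b) for i, a in enumerate(data.columns) for b in data.columns[i + 1:]),
        key=lambda ab: -abs(corr.loc[ab[0], ab[1]]))
    for a, b in pairs:
        r = corr.loc[a, b]
        if abs(r) <= threshold:
            continue
        if a not in retained or b not in retained:
            continue
        loser = max(a, b, key=prio)
        retained.remove(loser)
        dropped[loser] = (a if loser == b else b, float(r))
    return retained, dropped, corr
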