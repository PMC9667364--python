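"""Phylogenetic generalized least squares with maximum-likelihood Pagel's λ.

The model is ``y = X beta + e`` with ``e ~ N(0, sigma^2 * V(lambda))`` where
``V(lambda)`` is the phylogenetic covariance ``C`` with off-diagonal entries
scaled by λ.  λ is profiled out by maximizing the (restricted) log-likelihood
on a grid over [0, 1] followed by bounded local refinement; β, the overall
F-test against the intercept-only model and adjusted R² are evaluated at λ̂.

For ultrametric trees (constant diagonal of C) the profile is evaluated via
a single eigendecomposition of C — ``V(λ) = λC + (1−λ)hI`` shares C's
eigenvectors — which makes the grid search O(n p²) per λ instead of O(n³).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import Phylogeny, PhyloCovariance, lambda_transform, normalize_tip, phylo_covariance

_GRID_SIZE = 101
_FLAT_PROFILE_TOL = 1e-6


class RankDeficiencyError(ValueError):
    """Raised when the design matrix is singular; names aliased columns."""


@dataclass
class PGLSFit:
    """Result of one PGLS model fit."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fstat: float
    df_num: int
    df_den: int
    f_pvalue: float
    r2_adj: float
    lam: float
    lambda_mode: str
    method: str
    loglik: float
    flat_profile: bool
    profile: pd.DataFrame
    residuals: pd.Series
    n: int
    gls_rss: float
    gls_rss_null: float
    species: tuple[str, ...] = field(default_factory=tuple)
    param_cov: np.ndarray | None = None

    def summary(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "n": self.n,
            "lambda": self.lam,
            "lambda_mode": self.lambda_mode,
            "method": self.method,
            "loglik": self.loglik,
            "flat_profile": self.flat_profile,
            "F": self.fstat,
            "df": [self.df_num, self.df_den],
            "p": self.f_pvalue,
            "r2_adj": self.r2_adj,
            "coefficients": {
                name: {"estimate": float(self.params[name]),
                       "se": float(self.se[name]),
                       "t": float(self.tvalues[name]),
                       "p": float(self.pvalues[name])}
                for name in self.params.index
            },
        }


def build_design_matrix(design: pd.DataFrame,
                        reference: dict[str, str] | None = None) -> pd.DataFrame:
    """Expand a predictor table into an intercept + treatment-contrast matrix.

    Categorical (object / categorical dtype) columns become dummy columns
    against a reference level — the alphabetically first level unless
    overridden via ``reference``.
    """
    reference = reference or {}
    n = len(design)
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(n)}
    for name in design.columns:
        col = design[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            ref = str(reference.get(name, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {name}")
            for level in levels:
                if level == ref:
                    continue
                cols[f"{name}[{level}]"] = (col.astype(str) == level).to_numpy(float)
    return pd.DataFrame(cols, index=design.index)


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    q, r = np.linalg.qr(M)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(M.shape) * np.finfo(float).eps
    bad = [X.columns[i] for i in range(len(diag)) if diag[i] < tol]
    if bad or np.linalg.matrix_rank(M) < M.shape[1]:
        raise RankDeficiencyError(
            f"design matrix is rank deficient; aliased columns: {bad or 'unknown'}")


class _GLSEngine:
    """Evaluates GLS fits of (y, X) against V(λ) for many λ efficiently."""

    def __init__(self, C: np.ndarray, X: np.ndarray, y: np.ndarray):
        self.C, self.X, self.y = C, X, y
        self.n, self.p = X.shape
        diag = np.diag(C)
        self.h = float(diag.mean())
        self.ultrametric = bool(np.allclose(diag, self.h, rtol=1e-10, atol=1e-12))
        if self.ultrametric:
            evals, U = np.linalg.eigh(C)
            self.evals = evals
            self.yt = U.T @ y
            self.Xt = U.T @ X

    def solve(self, lam: float):
        """Return (beta, rss, logdetV, XtVinvX) at one λ."""
        if self.ultrametric:
            d = lam * self.evals + (1.0 - lam) * self.h
            d = np.maximum(d, 1e-300)
            w = 1.0 / d
            Xw = self.Xt * w[:, None]
            XtVX = self.Xt.T @ Xw
            beta = np.linalg.solve(XtVX, Xw.T @ self.yt)
            resid = self.yt - self.Xt @ beta
            rss = float(resid @ (w * resid))
            logdet = float(np.log(d).sum())
            return beta, rss, logdet, XtVX
        V = lambda_transform(self.C, lam)
        L = np.linalg.cholesky(V)
        yw = np.linalg.solve(L, self.y)
        Xw = np.linalg.solve(L, self.X)
        XtVX = Xw.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ yw)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        logdet = float(2.0 * np.log(np.diag(L)).sum())
        return beta, rss, logdet, XtVX

    def loglik(self, lam: float, method: str) -> float:
        _, rss, logdet, XtVX = self.solve(lam)
        n, p = self.n, self.p
        if method == "REML":
            df = n - p
            sigma2 = rss / df
            sign, logdetX = np.linalg.slogdet(XtVX)
            return -0.5 * (df * np.log(2 * np.pi * sigma2) + logdet + logdetX + df)
        sigma2 = rss / n
        return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _profile_lambda(engine: _GLSEngine, method: str):
    grid = np.linspace(0.0, 1.0, _GRID_SIZE)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.array([engine.loglik(l, method) for l in grid])
    ll = np.where(np.isfinite(ll), ll, -1e300)  # guards rss == 0 degeneracy
    flat = bool(ll.max() - ll.min() < _FLAT_PROFILE_TOL)
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if flat or lo == hi:
        lam_hat = grid[best]
    else:
        res = optimize.minimize_scalar(lambda l: -engine.loglik(l, method),
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        lam_hat = float(res.x)
        if engine.loglik(grid[best], method) > engine.loglik(lam_hat, method):
            lam_hat = grid[best]
    # Snap boundary optima to exactly 0 or 1.
    if lam_hat < 1e-5:
        lam_hat = 0.0
    elif lam_hat > 1 - 1e-5:
        lam_hat = 1.0
    return lam_hat, pd.DataFrame({"lambda": grid, "loglik": ll}), flat


def fit_pgls(response: pd.Series, design: pd.DataFrame | None,
             tree: Phylogeny | PhyloCovariance, lam: float | str = "ML",
             method: str = "ML",
             reference: dict[str, str] | None = None) -> PGLSFit:
    """Fit a PGLS model of a species-indexed response on a predictor table.

    Parameters
    ----------
    response
        Species-indexed trait values.
    design
        Species-indexed predictors (numeric and/or categorical); ``None``
        or empty fits the intercept-only model.
    tree
        A :class:`~lenshape.phylo.Phylogeny` or a precomputed covariance.
    lam
        ``"ML"`` to estimate Pagel's λ by profile (restricted) maximum
        likelihood, or a fixed value in [0, 1].  λ = 0 reduces exactly to
        ordinary least squares.
    method
        ``"ML"`` (default) or ``"REML"`` for the λ profile criterion.
    """
    response = response.rename(index=normalize_tip).astype(float)
    if design is None:
        design = pd.DataFrame(index=response.index)
    else:
        design = design.rename(index=normalize_tip)

    species = [s for s in response.index
               if s in design.index and np.isfinite(response[s])]
    if not design.empty:
        complete = design.loc[species].notna().all(axis=1)
        species = [s for s, ok in zip(species, complete) if ok]
    if isinstance(tree, PhyloCovariance):
        tree_tips = set(tree.tips)
    else:
        tree_tips = set(tree.tip_labels)
    missing = [s for s in species if s not in tree_tips]
    if missing:
        raise KeyError(f"species absent from tree: {', '.join(sorted(missing))}")
    if len(species) < 3:
        raise ValueError(f"need >= 3 complete species, have {len(species)}")

    if isinstance(tree, PhyloCovariance):
        C = tree.reordered(species)
    else:
        C = phylo_covariance(tree, species)
    y = response.loc[species].to_numpy(dtype=float)
    X_df = build_design_matrix(design.loc[species], reference=reference)
    _check_rank(X_df)
    X = X_df.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} coefficients")

    engine = _GLSEngine(C.matrix, X, y)
    lambda_mode = "ML" if isinstance(lam, str) else "fixed"
    if isinstance(lam, str):
        if lam.upper() not in ("ML", "REML"):
            raise ValueError(f"lam must be 'ML' or a value in [0,1], got {lam!r}")
        lam_hat, profile, flat = _profile_lambda(engine, method.upper())
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        lam_hat, flat = float(lam), False
        profile = pd.DataFrame({"lambda": [lam_hat],
                                "loglik": [engine.loglik(lam_hat, method.upper())]})

    beta, rss, logdet, XtVX = engine.solve(lam_hat)
    df_den = n - p
    sigma2 = rss / df_den
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_den)

    null_engine = _GLSEngine(C.matrix, np.ones((n, 1)), y)
    _, rss0, _, _ = null_engine.solve(lam_hat)
    if p > 1 and rss > 0:
        df_num = p - 1
        fstat = ((rss0 - rss) / df_num) / (rss / df_den)
        f_p = float(stats.f.sf(fstat, df_num, df_den))
    else:
        # Intercept-only model, or a perfect fit (rss = 0): F undefined.
        df_num, fstat, f_p = max(p - 1, 0), float("nan"), float("nan")
    r2_adj = (1.0 - (rss / df_den) / (rss0 / (n - 1))) if rss0 > 0 else float("nan")

    names = list(X_df.columns)
    return PGLSFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        fstat=float(fstat), df_num=df_num, df_den=df_den, f_pvalue=f_p,
        r2_adj=float(r2_adj), lam=lam_hat, lambda_mode=lambda_mode,
        method=method.upper(),
        loglik=float(engine.loglik(lam_hat, method.upper())),
        flat_profile=flat, profile=profile,
        residuals=pd.Series(y - X @ beta, index=species),
        n=n, gls_rss=rss, gls_rss_null=rss0,
        species=tuple(species), param_cov=cov_beta,
    )


def factor_term_f(full: PGLSFit, reduced: PGLSFit) -> tuple[float, int, int, float]:
    """Partial F-test for the terms dropped between two nested PGLS fits.

    Both fits must be evaluated on the same species under the same V̂ (fit
    the reduced model with ``lam=full.lam``).  Returns ``(F, df1, df2, p)``.
    """
    if full.species != reduced.species:
        raise ValueError("fits compare different species sets")
    df1 = len(reduced.params) and (len(full.params) - len(reduced.params))
    if df1 <= 0:
        raise ValueError("models are not nested (no dropped terms)")
    df2 = full.df_den
    scale = max(reduced.gls_rss_null, full.gls_rss_null)
    if full.gls_rss <= 1e-12 * scale:
        # Both models fit essentially perfectly; the extra terms explain
        # nothing beyond rounding noise.
        return 0.0, int(df1), int(df2), 1.0
    F = ((reduced.gls_rss - full.gls_rss) / df1) / (full.gls_rss / df2)
    return float(F), int(df1), int(df2), float(stats.f.sf(F, df1, df2))


def pairwise_contrasts(fit: PGLSFit, factor: str,
                       reference: str | None = None) -> pd.DataFrame:
    """Wald t-tests for all pairwise differences among a factor's levels.

    Levels are read from the fit's treatment-contrast columns
    ``factor[level]``; the reference level is the one without a column.
    Returns one row per unordered pair with the estimate, SE, t and raw p.
    """
    if fit.param_cov is None:
        raise ValueError("fit carries no coefficient covariance")
    names = list(fit.params.index)
    prefix = f"{factor}["
    level_cols = {name[len(prefix):-1]: i for i, name in enumerate(names)
                  if name.startswith(prefix) and name.endswith("]")}
    if not level_cols:
        raise ValueError(f"no treatment-contrast columns found for {factor!r}")
    # Reference level = contrast vector of zeros.
    ref_name = reference if reference is not None else "(reference)"
    levels = sorted(level_cols)
    rows = []
    k = len(names)

    def contrast_vector(level):
        v = np.zeros(k)
        if level is not None:
            v[level_cols[level]] = 1.0
        return v

    all_levels = [None] + levels
    for i in range(len(all_levels)):
        for j in range(i + 1, len(all_levels)):
            a, b = all_levels[i], all_levels[j]
            c = contrast_vector(a) - contrast_vector(b)
            est = float(c @ fit.params.to_numpy())
            se = float(np.sqrt(c @ fit.param_cov @ c))
            t = est / se
            p = 2.0 * stats.t.sf(abs(t), fit.df_den)
            rows.append({"level_a": a if a is not None else ref_name,
                         "level_b": b if b is not None else ref_name,
                         "estimate": est, "se": se, "t": t, "p": float(p)})
    return pd.DataFrame(rows)
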