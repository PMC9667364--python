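"""PGLS: OLS equivalence, λ profiling, contrasts and nested F-tests."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import lenshape as ls
from lenshape.pgls import RankDeficiencyError, build_design_matrix
from lenshape.phylo import phylo_covariance


@pytest.fixture(scope="module")
def xy64(tree64):
    rng = np.random.default_rng(10)
    y = ls.simulate_bm(tree64, 1, 1.0, 0.6, seed=11)["trait1"]
    x = pd.DataFrame({"x": rng.normal(size=len(y))}, index=y.index)
    return y, x


def test_lambda_zero_equals_ols(tree64, xy64):
    y, x = xy64
    fit = ls.fit_pgls(y, x, tree64, lam=0.0)
    ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-10)
    assert np.allclose(fit.se.to_numpy(), ols.bse, atol=1e-10)
    assert fit.fstat == pytest.approx(ols.fvalue, abs=1e-10)
    assert fit.f_pvalue == pytest.approx(ols.f_pvalue, abs=1e-12)
    assert fit.r2_adj == pytest.approx(ols.rsquared_adj, abs=1e-10)


def test_star_tree_lambda_unidentifiable(xy64):
    """On a star phylogeny C = I, so every λ gives the same fit."""
    y, x = xy64
    star = ls.Phylogeny.from_newick(
        "(" + ",".join(f"{t}:1" for t in y.index) + ");")
    fit = ls.fit_pgls(y, x, star, lam="ML")
    assert fit.flat_profile
    ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-8)


def test_species_order_invariance(tree64, xy64):
    y, x = xy64
    fit1 = ls.fit_pgls(y, x, tree64, lam="ML")
    perm = np.random.default_rng(5).permutation(len(y))
    fit2 = ls.fit_pgls(y.iloc[perm], x.iloc[perm], tree64, lam="ML")
    assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-9)
    assert fit1.lam == pytest.approx(fit2.lam, abs=1e-6)


def test_fast_path_matches_direct_gls(tree64, xy64):
    """The eigendecomposition shortcut equals the explicit V^-1 formula."""
    y, x = xy64
    lam = 0.37
    fit = ls.fit_pgls(y, x, tree64, lam=lam)
    C = phylo_covariance(tree64, list(fit.species)).matrix
    V = ls.lambda_transform(C, lam)
    X = np.column_stack([np.ones(len(y)), x.loc[list(fit.species), "x"]])
    yv = y.loc[list(fit.species)].to_numpy()
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ yv)
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-9)


def test_nonultrametric_tree_fits():
    tree = ls.Phylogeny.from_newick(
        "((A:0.2,B:0.9):0.4,(C:0.6,D:1.1):0.3,E:1.6);")
    rng = np.random.default_rng(2)
    y = pd.Series(rng.normal(size=5), index=list("ABCDE"))
    x = pd.DataFrame({"x": rng.normal(size=5)}, index=list("ABCDE"))
    fit = ls.fit_pgls(y, x, tree, lam=1.0)
    # oracle: explicit GLS with V = C
    C = phylo_covariance(tree, list(fit.species)).matrix
    X = np.column_stack([np.ones(5), x.loc[list(fit.species), "x"]])
    Vinv = np.linalg.inv(C)
    beta = np.linalg.solve(X.T @ Vinv @ X,
                           X.T @ Vinv @ y.loc[list(fit.species)].to_numpy())
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-9)


def test_treatment_contrasts_and_releveling(tree64):
    rng = np.random.default_rng(8)
    y = ls.simulate_bm(tree64, 1, 1.0, 0.0, seed=21)["trait1"]
    group = pd.Series(rng.choice(["low", "high"], size=len(y)),
                      index=y.index, name="group")
    y = y + (group == "high") * 0.8
    fit_ref_high = ls.fit_pgls(y, group.to_frame(), tree64, lam=0.0,
                               reference={"group": "high"})
    fit_ref_low = ls.fit_pgls(y, group.to_frame(), tree64, lam=0.0,
                              reference={"group": "low"})
    # Intercept under each releveling = that group's mean (λ=0 → OLS).
    assert fit_ref_high.params["(Intercept)"] == pytest.approx(
        y[group == "high"].mean(), abs=1e-10)
    assert fit_ref_low.params["(Intercept)"] == pytest.approx(
        y[group == "low"].mean(), abs=1e-10)
    assert fit_ref_low.params["group[high]"] == pytest.approx(
        -fit_ref_high.params["group[low]"], abs=1e-10)


def test_rank_deficiency_names_column(tree64, xy64):
    y, x = xy64
    x2 = x.copy()
    x2["x_dup"] = x2["x"] * 2.0
    with pytest.raises(RankDeficiencyError, match="x_dup|x"):
        ls.fit_pgls(y, x2, tree64, lam=0.0)


def test_species_tree_mismatch(tree64, xy64):
    y, x = xy64
    y2 = y.copy()
    y2.index = ["ghost" + str(i) for i in range(len(y2))]
    x2 = x.copy()
    x2.index = y2.index
    with pytest.raises(KeyError, match="ghost"):
        ls.fit_pgls(y2, x2, tree64)


def test_listwise_deletion(tree64, xy64):
    y, x = xy64
    x2 = x.copy()
    x2.iloc[:5, 0] = np.nan
    fit = ls.fit_pgls(y, x2, tree64, lam=0.0)
    assert fit.n == len(y) - 5


def test_effect_recovery_simulation():
    """A known +0.15 group effect is recovered without bias (2 MC SEs)."""
    tree = ls.make_tree(128, seed=77)
    C = phylo_covariance(tree)
    rng = np.random.default_rng(99)
    estimates = []
    for s in range(50):
        y = ls.simulate_bm(tree, 1, 0.01, 0.5, seed=500 + s)["trait1"]
        habit = pd.Series(rng.choice(["aquatic", "terrestrial"], size=128),
                          index=y.index, name="habit")
        y = y + (habit == "terrestrial") * 0.15
        fit = ls.fit_pgls(y, habit.to_frame(), C, lam="ML")
        estimates.append(fit.params["habit[terrestrial]"])
    mean = np.mean(estimates)
    sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(mean - 0.15) < 2 * sem + 1e-3


def test_factor_term_f_matches_ols_partial_f(tree64):
    """At λ=0 the nested-model F equals the classical OLS partial F."""
    rng = np.random.default_rng(31)
    y = ls.simulate_bm(tree64, 1, 1.0, 0.0, seed=41)["trait1"]
    cov = pd.Series(rng.normal(size=len(y)), index=y.index, name="cov")
    grp = pd.Series(rng.choice(list("pqr"), size=len(y)), index=y.index,
                    name="grp")
    design = pd.concat([cov, grp], axis=1)
    full = ls.fit_pgls(y, design, tree64, lam=0.0)
    reduced = ls.fit_pgls(y, cov.to_frame(), tree64, lam=0.0)
    F, df1, df2, p = ls.factor_term_f(full, reduced)

    Xf = build_design_matrix(design.loc[list(full.species)]).to_numpy()
    Xr = sm.add_constant(cov.loc[list(full.species)].to_numpy())
    yv = y.loc[list(full.species)].to_numpy()
    rss_f = sm.OLS(yv, Xf).fit().ssr
    rss_r = sm.OLS(yv, Xr).fit().ssr
    expected = ((rss_r - rss_f) / df1) / (rss_f / df2)
    assert F == pytest.approx(expected, rel=1e-9)
    assert df1 == 2


def test_pairwise_contrasts_cover_all_pairs(tree64):
    rng = np.random.default_rng(13)
    y = ls.simulate_bm(tree64, 1, 1.0, 0.0, seed=17)["trait1"]
    grp = pd.Series(rng.choice(list("abcd"), size=len(y)), index=y.index,
                    name="grp")
    fit = ls.fit_pgls(y, grp.to_frame(), tree64, lam=0.0)
    pairs = ls.pairwise_contrasts(fit, "grp", reference="a")
    assert len(pairs) == 6  # C(4, 2)
    # contrast of b vs c equals coefficient difference
    row = pairs[(pairs.level_a == "b") & (pairs.level_b == "c")].iloc[0]
    assert row.estimate == pytest.approx(
        fit.params["grp[b]"] - fit.params["grp[c]"], abs=1e-12)


def test_too_few_species(tree64):
    y = pd.Series([1.0, 2.0], index=tree64.tip_labels[:2])
    with pytest.raises(ValueError, match=">= 3"):
        ls.fit_pgls(y, None, tree64)
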