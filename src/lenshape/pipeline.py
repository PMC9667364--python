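"""The four-stage comparative analysis over a species trait table and a tree.

Stages, in the order :func:`run_all` executes them:

1. **lifestage** — pooled PCA of species-mean shape metrics, Welch t-tests
   of adults vs tadpoles per metric, and multivariate phylogenetic signal
   (K_mult) within each stage.
2. **metamorphosis** — per-species adult-minus-tadpole deltas, K_mult on the
   delta matrix, and PGLS of each delta on the post-metamorphic environment
   (aquatic vs terrestrial) with per-level slopes obtained by releveling.
3. **ecology** — PGLS of each adult metric on habit (6 levels) and on
   activity pattern (2 levels), with Holm-corrected pairwise contrasts and
   compact letter groupings for habit.
4. **relative size** — PGLS of adult lens diameter on eye diameter plus
   habit (or activity), with a partial F-test for the ecological term and
   residuals of the diameter-only model for display.

All stages are pure: the input table is never mutated, and a fixed seed
makes every report byte-identical across runs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .pgls import factor_term_f, fit_pgls, pairwise_contrasts
from .phylo import Phylogeny, normalize_tip
from .signal import ConstantDataError, kmult
from .stats import collinearity_screen, pca, welch_t

logger = logging.getLogger(__name__)

METRICS = ("anisotropy", "sphericity", "elongation")
ALL_METRICS = ("anisotropy", "flatness", "elongation", "sphericity")
STAGES = ("tadpole", "adult")
REQUIRED_COLUMNS = ("species", "life_stage", "anisotropy", "flatness",
                    "elongation", "sphericity")
ECOLOGY_COLUMNS = ("habit", "activity", "adult_environment",
                   "lens_diameter_mm", "eye_diameter_mm")


class TraitTableError(ValueError):
    """Raised when a trait table violates the documented header contract."""


@dataclass
class PipelineConfig:
    """All tunable switches of the analysis, serializable to/from YAML."""

    seed: int = 0
    n_perm: int = 999
    lambda_mode: str = "ML"          # "ML" or a fixed value in [0, 1]
    likelihood_method: str = "ML"    # "ML" or "REML" for the lambda profile
    pca_scale: bool = True
    posthoc: str = "holm"            # "holm" or "bonferroni"
    alpha: float = 0.05
    collinearity_threshold: float = 0.9
    mesh_smoothing: int = 20
    log_diameters: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def lam(self):
        if isinstance(self.lambda_mode, str):
            return "ML"
        return float(self.lambda_mode)


@dataclass
class StageReport:
    """One stage's statistics with full provenance."""

    stage: str
    statistics: dict
    tables: dict[str, pd.DataFrame]
    sample_sizes: dict
    seed: int
    config: dict

    def summary(self) -> dict:
        return {
            "stage": self.stage,
            "n": self.sample_sizes,
            "seed": self.seed,
            "statistics": self.statistics,
            "config": self.config,
        }


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the header contract and value ranges; returns a clean copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TraitTableError(f"trait table missing columns: {missing}")
    table = table.copy()
    table["species"] = table["species"].map(normalize_tip)
    bad_stage = set(table["life_stage"].dropna()) - set(STAGES)
    if bad_stage:
        raise TraitTableError(
            f"unknown life stages {sorted(bad_stage)}; expected {STAGES}")
    if table["life_stage"].isna().any():
        raise TraitTableError("specimens of unknown life stage are rejected")
    for m in ALL_METRICS:
        vals = table[m].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise TraitTableError(f"{m} outside [0, 1]")
    for col in ("lens_diameter_mm", "eye_diameter_mm"):
        if col in table.columns and (table[col].dropna() <= 0).any():
            raise TraitTableError(f"{col} must be positive where present")
    return table


def species_means(specimens: pd.DataFrame) -> pd.DataFrame:
    """Average per-specimen rows to one row per species x life stage.

    Metric and diameter columns are averaged with equal specimen weight;
    ecological scores must be consistent within a species (conflicts raise,
    listing every offending species/column).  A ``n_specimens`` column
    records how many rows were averaged.
    """
    specimens = validate_trait_table(specimens)
    eco = [c for c in ("habit", "activity", "adult_environment", "family")
           if c in specimens.columns]
    conflicts = []
    for col in eco:
        per_species = specimens.groupby("species")[col].nunique(dropna=True)
        for sp in per_species[per_species > 1].index:
            conflicts.append((sp, col))
    if conflicts:
        raise TraitTableError(
            "conflicting ecological scores within species: "
            + "; ".join(f"{sp}:{col}" for sp, col in conflicts))

    numeric = [c for c in specimens.columns
               if c in ALL_METRICS + ("lens_diameter_mm", "eye_diameter_mm")]
    grouped = specimens.groupby(["species", "life_stage"], sort=True)
    means = grouped[numeric].mean()
    means["n_specimens"] = grouped.size()
    means = means.reset_index()
    if eco:
        first = specimens.groupby("species")[eco].first()
        means = means.merge(first, on="species", how="left")
    return means


def _stage_matrix(table: pd.DataFrame, stage: str,
                  metrics=METRICS) -> pd.DataFrame:
    sub = table[table["life_stage"] == stage]
    return sub.set_index("species")[list(metrics)].dropna()


def compact_letter_display(levels, pairs: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Assign letters so that levels sharing a letter are not significantly
    different.  ``pairs`` needs columns level_a, level_b and p_adjusted.

    Letters label the maximal cliques of the graph whose edges connect
    non-significantly-different levels, ordered for stable output.
    """
    G = nx.Graph()
    G.add_nodes_from(levels)
    for _, row in pairs.iterrows():
        if row["p_adjusted"] > alpha:
            G.add_edge(row["level_a"], row["level_b"])
    cliques = sorted((sorted(c) for c in nx.find_cliques(G)),
                     key=lambda c: (-len(c), c))
    letters: dict[str, str] = {lv: "" for lv in levels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for lv in clique:
            letters[lv] += alphabet[i % len(alphabet)]
    return letters


def run_lifestage_stage(table: pd.DataFrame, tree: Phylogeny | None,
                        config: PipelineConfig) -> StageReport:
    """Do tadpoles have more spherical lenses than adults?"""
    table = validate_trait_table(table)
    adults = _stage_matrix(table, "adult")
    tadpoles = _stage_matrix(table, "tadpole")
    if len(adults) < 2 or len(tadpoles) < 2:
        raise ValueError("need >= 2 species per life stage")

    pooled = pd.concat([
        tadpoles.rename(index=lambda s: f"{s}|tadpole"),
        adults.rename(index=lambda s: f"{s}|adult"),
    ])
    pca_res = pca(pooled, scale=config.pca_scale)

    stats = {"pca": {
        "proportion_variance": pca_res.proportion_variance.round(12).to_dict(),
        "loadings": {c: pca_res.loadings[c].round(12).to_dict()
                     for c in pca_res.loadings.columns},
    }, "t_tests": {}, "kmult": {}}
    for m in METRICS:
        res = welch_t(adults[m], tadpoles[m])
        stats["t_tests"][m] = {"t": res.t, "df": res.df, "p": res.p}

    tables = {"pca_scores": pca_res.scores,
              "adult_means": adults, "tadpole_means": tadpoles}
    if tree is not None:
        for name, mat in (("adults", adults), ("tadpoles", tadpoles)):
            res = kmult(mat, tree, n_perm=config.n_perm, seed=config.seed)
            stats["kmult"][name] = res.summary()
    else:
        warnings.warn("no tree supplied: phylogenetic signal (K_mult) skipped "
                      "in the lifestage stage")
    return StageReport(
        stage="lifestage", statistics=stats, tables=tables,
        sample_sizes={"adults": len(adults), "tadpoles": len(tadpoles)},
        seed=config.seed, config=config.to_dict())


def run_metamorphosis_stage(table: pd.DataFrame, tree: Phylogeny,
                            config: PipelineConfig) -> StageReport:
    """Does lens shape change across metamorphosis with the adult environment?"""
    table = validate_trait_table(table)
    if tree is None:
        raise ValueError("the metamorphosis stage requires a tree")
    adults = _stage_matrix(table, "adult")
    tadpoles = _stage_matrix(table, "tadpole")
    paired = sorted(set(adults.index) & set(tadpoles.index))
    excluded = sorted(set(adults.index) ^ set(tadpoles.index))
    if excluded:
        logger.info("%d species lack one life stage and are excluded: %s",
                    len(excluded), ", ".join(excluded))
    if len(paired) < 4:
        raise ValueError(f"need >= 4 paired species, have {len(paired)}")
    deltas = adults.loc[paired, list(METRICS)] - tadpoles.loc[paired, list(METRICS)]
    env = (table[table["life_stage"] == "adult"]
           .set_index("species")["adult_environment"].loc[paired])
    if env.isna().any():
        raise TraitTableError(
            "adult_environment missing for paired species: "
            + ", ".join(env.index[env.isna()]))

    try:
        km = kmult(deltas, tree, n_perm=config.n_perm, seed=config.seed).summary()
    except ConstantDataError as exc:
        km = {"error": str(exc)}
    stats = {"kmult": km, "pgls": {}}
    design = env.to_frame("adult_environment")
    for m in METRICS:
        fit = fit_pgls(deltas[m], design, tree, lam=config.lam,
                       method=config.likelihood_method)
        entry = fit.summary()
        # Per-level slopes: the intercept of the refit with that level as
        # the reference is the mean delta for the level.
        entry["per_level"] = {}
        for level in sorted(env.unique()):
            refit = fit_pgls(deltas[m], design, tree, lam=fit.lam,
                             method=config.likelihood_method,
                             reference={"adult_environment": level})
            entry["per_level"][level] = {
                "estimate": float(refit.params["(Intercept)"]),
                "se": float(refit.se["(Intercept)"]),
            }
        stats["pgls"][m] = entry
    return StageReport(
        stage="metamorphosis", statistics=stats,
        tables={"deltas": deltas, "environment": env.to_frame()},
        sample_sizes={"paired_species": len(paired),
                      "excluded_single_stage": len(excluded)},
        seed=config.seed, config=config.to_dict())


def run_ecology_stage(table: pd.DataFrame, tree: Phylogeny,
                      config: PipelineConfig) -> StageReport:
    """Does adult lens shape correlate with habit or activity pattern?"""
    table = validate_trait_table(table)
    if tree is None:
        raise ValueError("the ecology stage requires a tree")
    adults = table[table["life_stage"] == "adult"].set_index("species")
    stats: dict = {}
    tables: dict = {}
    sizes: dict = {}
    for factor in ("habit", "activity"):
        if factor not in adults.columns:
            continue
        sub = adults.dropna(subset=[factor])
        counts = sub[factor].value_counts()
        keep_levels = counts[counts >= 2].index
        dropped = sorted(set(counts.index) - set(keep_levels))
        if dropped:
            warnings.warn(f"{factor} levels with < 2 species dropped: {dropped}")
        sub = sub[sub[factor].isin(keep_levels)]
        sizes[factor] = len(sub)
        if sub[factor].nunique() < 2:
            warnings.warn(f"{factor} has a single level; effect not testable")
            stats[factor] = {"note": "single level, not testable"}
            continue
        stats[factor] = {}
        for m in METRICS:
            y = sub[m].dropna()
            design = sub.loc[y.index, [factor]]
            fit = fit_pgls(y, design, tree, lam=config.lam,
                           method=config.likelihood_method)
            entry = fit.summary()
            if factor == "habit" and len(keep_levels) > 2:
                ref = sorted(map(str, keep_levels))[0]
                pairs = pairwise_contrasts(fit, factor, reference=ref)
                method = "holm" if config.posthoc == "holm" else "bonferroni"
                pairs["p_adjusted"] = multipletests(pairs["p"], method=method)[1]
                letters = compact_letter_display(
                    sorted(map(str, keep_levels)), pairs, config.alpha)
                entry["pairwise"] = pairs.round(12).to_dict(orient="records")
                entry["letters"] = letters
                tables[f"pairwise_{factor}_{m}"] = pairs
            stats[factor][m] = entry
    return StageReport(stage="ecology", statistics=stats, tables=tables,
                       sample_sizes=sizes, seed=config.seed,
                       config=config.to_dict())


def run_relative_size_stage(table: pd.DataFrame, tree: Phylogeny,
                            config: PipelineConfig) -> StageReport:
    """Is lens size relative to eye size associated with adult ecology?"""
    table = validate_trait_table(table)
    if tree is None:
        raise ValueError("the relative-size stage requires a tree")
    adults = table[table["life_stage"] == "adult"].set_index("species")
    adults = adults.dropna(subset=["lens_diameter_mm", "eye_diameter_mm"])
    if config.log_diameters:
        lens = np.log(adults["lens_diameter_mm"]).rename("lens")
        eye = np.log(adults["eye_diameter_mm"]).rename("eye")
    else:
        lens = adults["lens_diameter_mm"].rename("lens")
        eye = adults["eye_diameter_mm"].rename("eye")

    stats: dict = {}
    tables: dict = {}
    sizes: dict = {"with_diameters": len(adults)}
    baseline = fit_pgls(lens, eye.to_frame(), tree, lam=config.lam,
                        method=config.likelihood_method)
    stats["diameter_only"] = baseline.summary()
    tables["size_residuals"] = baseline.residuals.rename("residual").to_frame()

    for factor in ("habit", "activity"):
        if factor not in adults.columns:
            continue
        sub = adults.dropna(subset=[factor])
        counts = sub[factor].value_counts()
        sub = sub[sub[factor].isin(counts[counts >= 2].index)]
        sizes[factor] = len(sub)
        if sub[factor].nunique() < 2:
            warnings.warn(f"{factor} has a single level; effect not testable")
            stats[factor] = {"note": "single level, not testable"}
            continue
        design = pd.concat([eye.loc[sub.index], sub[factor]], axis=1)
        full = fit_pgls(lens.loc[sub.index], design, tree, lam=config.lam,
                        method=config.likelihood_method)
        reduced = fit_pgls(lens.loc[sub.index], eye.loc[sub.index].to_frame(),
                           tree, lam=full.lam, method=config.likelihood_method)
        F, df1, df2, p = factor_term_f(full, reduced)
        entry = full.summary()
        entry["factor_term"] = {"F": F, "df": [df1, df2], "p": p}
        stats[factor] = entry
    return StageReport(stage="relative_size", statistics=stats, tables=tables,
                       sample_sizes=sizes, seed=config.seed,
                       config=config.to_dict())


# --------------------------------------------------------------------------
# Driver
# --------------------------------------------------------------------------

def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not serializable: {type(obj)}")


def run_all(traits: str | Path | pd.DataFrame,
            tree: str | Path | Phylogeny | None,
            config: PipelineConfig | str | Path | None = None,
            out_dir: str | Path | None = None,
            collapse_specimens: bool = False) -> dict:
    """Run every stage; optionally write reports and a run manifest.

    ``traits`` may be a CSV path or DataFrame of species x stage rows (set
    ``collapse_specimens=True`` if it holds per-specimen rows instead).
    Without a tree, the non-phylogenetic parts of the lifestage stage still
    run with a prominent warning; the phylogenetic stages refuse.
    """
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if not isinstance(traits, pd.DataFrame):
        traits = pd.read_csv(traits)
    table = validate_trait_table(traits)
    if collapse_specimens:
        table = species_means(table)
    if tree is not None and not isinstance(tree, Phylogeny):
        tree = Phylogeny.from_newick(Path(tree))
    if tree is not None:
        tip_set = set(tree.tip_labels)
        absent = sorted(set(table["species"]) - tip_set)
        if absent:
            logger.info("%d species not in tree are excluded from "
                        "phylogenetic stages: %s", len(absent), ", ".join(absent))
            phylo_table = table[table["species"].isin(tip_set)]
        else:
            phylo_table = table
    else:
        warnings.warn("NO TREE SUPPLIED: only non-phylogenetic statistics "
                      "will be computed")
        phylo_table = None

    reports: dict[str, StageReport] = {}
    reports["lifestage"] = run_lifestage_stage(
        phylo_table if tree is not None else table, tree, config)
    if tree is not None:
        reports["metamorphosis"] = run_metamorphosis_stage(phylo_table, tree, config)
        reports["ecology"] = run_ecology_stage(phylo_table, tree, config)
        reports["relative_size"] = run_relative_size_stage(phylo_table, tree, config)

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_rows": int(len(table)),
        "n_species": int(table["species"].nunique()),
        "stages": {name: rep.sample_sizes for name, rep in reports.items()},
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, rep in reports.items():
            payload = json.dumps(rep.summary(), indent=2, sort_keys=True,
                                 default=_json_default)
            (out_dir / f"{name}.json").write_text(payload)
            for tname, tdf in rep.tables.items():
                tdf.to_csv(out_dir / f"{name}_{tname}.csv")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    return {"reports": reports, "manifest": manifest}
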