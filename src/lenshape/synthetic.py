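"""Synthetic inputs with known ground truth.

Three generators cover everything the analysis consumes:

* :func:`make_phantom` — voxelized sphere/ellipsoid/superellipsoid lens
  phantoms with analytic volume and surface area;
* :func:`make_tree` — pure-birth ultrametric phylogenies rescaled to
  height 1;
* :func:`make_study` — species trait tables evolved on a tree with known
  stage, environment, habit and allometry effects, so every pipeline
  estimate can be scored against the generating parameters.

Every generator is a pure function of its spec and seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .phylo import Phylogeny, simulate_bm
from .volume import VoxelVolume

HABITS = ("aquatic", "semiaquatic", "scansorial", "ground-dwelling",
          "subfossorial", "fossorial")
ACTIVITIES = ("nocturnal", "non-nocturnal")
METRICS = ("anisotropy", "sphericity", "elongation")


# --------------------------------------------------------------------------
# Voxel phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one voxel phantom.

    ``semi_axes`` are in voxels along grid axes 0/1/2 before rotation;
    ``orientation`` is an (angle0, angle1, angle2) triple of rotations (rad)
    about the grid axes applied in that order; ``noise`` is the standard
    deviation (voxels) of a smooth radial perturbation of the surface;
    ``exponent`` > 2 turns the ellipsoid into a boxier superellipsoid.
    """

    shape: str = "sphere"
    semi_axes: tuple[float, float, float] = (40.0, 40.0, 40.0)
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise: float = 0.0
    grid_size: int = 96
    spacing: tuple[float, float, float] = (0.01, 0.01, 0.01)
    exponent: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("sphere", "ellipsoid", "superellipsoid"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        axes = self.semi_axes
        if self.shape == "sphere" and len(set(axes)) != 1:
            raise ValueError("sphere phantom requires equal semi-axes")
        if min(axes) <= 2:
            raise ValueError("semi-axes must exceed 2 voxels")
        if max(axes) + self.noise > self.grid_size / 2 - 2:
            raise ValueError(
                f"phantom (max extent {max(axes) + self.noise:.1f}) does not fit a "
                f"{self.grid_size}^3 grid with a 2-voxel margin")


def _rotation_matrix(angles) -> np.ndarray:
    a0, a1, a2 = angles
    c, s = np.cos(a0), np.sin(a0)
    R0 = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    c, s = np.cos(a1), np.sin(a1)
    R1 = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    c, s = np.cos(a2), np.sin(a2)
    R2 = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    return R2 @ R1 @ R0


def ellipsoid_surface_area(a: float, b: float, c: float, n_grid: int = 2000) -> float:
    """Surface area of an ellipsoid; closed form for spheres/spheroids,
    numerical quadrature over the spherical parametrization otherwise."""
    axes = sorted((a, b, c), reverse=True)
    a, b, c = axes
    if np.isclose(a, b) and np.isclose(b, c):
        return 4.0 * np.pi * a ** 2
    if np.isclose(a, b):  # oblate spheroid (a = b > c)
        e = np.sqrt(1 - c ** 2 / a ** 2)
        return 2 * np.pi * a ** 2 * (1 + (1 - e ** 2) / e * np.arctanh(e))
    if np.isclose(b, c):  # prolate spheroid (a > b = c)
        e = np.sqrt(1 - b ** 2 / a ** 2)
        return 2 * np.pi * b ** 2 * (1 + a / (b * e) * np.arcsin(e))
    theta = (np.arange(n_grid) + 0.5) * np.pi / n_grid
    phi = (np.arange(2 * n_grid) + 0.5) * np.pi / n_grid
    T, P = np.meshgrid(theta, phi, indexing="ij")
    st, ct, sp, cp = np.sin(T), np.cos(T), np.sin(P), np.cos(P)
    # |r_theta x r_phi| for r = (a st cp, b st sp, c ct)
    integrand = st * np.sqrt((b * c * st * cp) ** 2 + (a * c * st * sp) ** 2
                             + (a * b * ct) ** 2)
    return float(integrand.sum() * (np.pi / n_grid) ** 2)


def make_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, dict]:
    """Voxelize a phantom; return the volume plus a ground-truth record.

    A voxel is foreground when its center lies inside the (optionally
    noise-perturbed) implicit surface.  The ground truth holds the analytic
    volume and surface area of the noise-free shape in both voxel and
    physical units.
    """
    g = spec.grid_size
    center = g / 2.0
    coords = np.arange(g) + 0.5 - center
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([X, Y, Z])
    R = _rotation_matrix(spec.orientation)
    local = np.tensordot(R.T, pts, axes=(1, 0))
    a, b, c = spec.semi_axes
    p = spec.exponent
    rho = (np.abs(local[0] / a) ** p + np.abs(local[1] / b) ** p
           + np.abs(local[2] / c) ** p) ** (1.0 / p)

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        field_ = ndimage.gaussian_filter(rng.standard_normal((g, g, g)), sigma=2.0)
        field_ /= field_.std()
        mean_axis = (a * b * c) ** (1.0 / 3.0)
        rho = rho - spec.noise * field_ / mean_axis
    grid = (rho <= 1.0).astype(np.uint8)

    spacing = spec.spacing
    vol_vox = 4.0 / 3.0 * np.pi * a * b * c if p == 2 else float("nan")
    area_vox = ellipsoid_surface_area(a, b, c) if p == 2 else float("nan")
    sx, sy, sz = spacing
    truth = {
        "semi_axes_voxels": (a, b, c),
        "semi_axes_mm": (a * sx, b * sy, c * sz),
        "volume_voxels": vol_vox,
        "volume_mm3": vol_vox * sx * sy * sz,
        "surface_area_voxels": area_vox,
        "surface_area_mm2": area_vox * float(np.mean([sx * sy, sy * sz, sx * sz]))
        if np.allclose([sx, sy], sz) else float("nan"),
        # Uniform solid ellipsoid: covariance = diag(a^2, b^2, c^2) / 5.
        "covariance_eigenvalues_mm2": tuple(
            sorted(((a * sx) ** 2 / 5, (b * sy) ** 2 / 5, (c * sz) ** 2 / 5),
                   reverse=True)),
        "spec": asdict(spec),
    }
    if not grid.any() or grid[0].any() or grid[-1].any():
        raise ValueError("phantom clipped by grid boundary")
    return VoxelVolume(grid=grid, spacing=spacing), truth


# --------------------------------------------------------------------------
# Trees
# --------------------------------------------------------------------------

def make_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree rescaled to ultrametric height 1.

    Tips are named ``sp0001 ... spNNNN``; the same seed always yields the
    same Newick string.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.split_time = t
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_tips)
    for node in tree.preorder_node_iter():
        end = getattr(node, "split_time", t_end)
        node.edge.length = end - node.birth_time
    tree.seed_node.edge.length = 0.0  # crown tree, no stem edge
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda nd: nd.birth_time)):
        leaf.taxon = taxa.new_taxon(f"sp{i + 1:04d}")
    # Rescale to height 1.
    phylo = Phylogeny(tree=tree)
    height = phylo.height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return phylo


# --------------------------------------------------------------------------
# Study tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpec:
    """Parameters of a simulated comparative study.

    Defaults mirror the sampling of a CT survey of biphasic frogs: 126
    species, 45 with paired tadpole and adult data, a pronounced increase
    in lens anisotropy across metamorphosis for species with terrestrial
    adults (+0.15) but not aquatic ones (+0.01), aquatic and fossorial
    habit offsets toward more spherical adult lenses, and a log-linear
    lens/eye diameter allometry with smaller relative lenses in aquatic
    and semiaquatic species.
    """

    n_species: int = 126
    n_paired: int = 45
    n_tadpole_only: int = 5
    habit_freqs: tuple[float, ...] = (0.10, 0.15, 0.25, 0.30, 0.10, 0.10)
    activity_freqs: tuple[float, ...] = (0.70, 0.30)
    missing_habit: float = 0.02
    missing_activity: float = 0.12

    # Baseline tadpole metric means and within-species noise sd.
    baseline_means: dict = field(default_factory=lambda: {
        "anisotropy": 0.10, "sphericity": 0.96, "elongation": 0.92})
    noise_sd: dict = field(default_factory=lambda: {
        "anisotropy": 0.04, "sphericity": 0.015, "elongation": 0.04})
    # Stage-by-environment deltas (adult - tadpole).
    delta_terrestrial: dict = field(default_factory=lambda: {
        "anisotropy": 0.15, "sphericity": -0.03, "elongation": 0.0})
    delta_aquatic: dict = field(default_factory=lambda: {
        "anisotropy": 0.01, "sphericity": -0.01, "elongation": 0.0})
    # Adult habit offsets (applied on top of the environment delta).  The
    # default gives fossorial adults — terrestrial, but with spherical
    # lenses — an offset that cancels most of the terrestrial delta;
    # aquatic-habit species are already spherical via the aquatic delta.
    habit_offsets: dict = field(default_factory=lambda: {
        "fossorial": {"anisotropy": -0.14, "sphericity": 0.02}})

    # Phylogenetic structure of the metric deviations.
    lambda_tadpole: float = 0.40
    lambda_adult: float = 0.45
    bm_sd: dict = field(default_factory=lambda: {
        "anisotropy": 0.05, "sphericity": 0.012, "elongation": 0.03})

    # log(lens_mm) = intercept + slope * log(eye_mm) + habit offset + noise
    diameter_fraction: float = 0.66
    allometric_slope: float = 0.90
    allometric_intercept: float = -0.75
    diameter_noise_sd: float = 0.05
    diameter_habit_offsets: dict = field(default_factory=lambda: {
        "aquatic": -0.05, "semiaquatic": -0.05})
    log_eye_mean: float = 1.8
    log_eye_sd: float = 0.35

    seed: int = 0

    def __post_init__(self):
        if not np.isclose(sum(self.habit_freqs), 1.0):
            raise ValueError("habit frequencies must sum to 1")
        if not np.isclose(sum(self.activity_freqs), 1.0):
            raise ValueError("activity frequencies must sum to 1")
        if self.n_paired + self.n_tadpole_only > self.n_species:
            raise ValueError("paired + tadpole-only species exceed n_species")
        if any(s <= 0 for s in self.noise_sd.values()):
            raise ValueError("noise sd must be positive")


def _clip_metric(values: np.ndarray, name: str) -> np.ndarray:
    if (values < 0).any() or (values > 1).any():
        warnings.warn(f"{name} values clipped to [0, 1]", stacklevel=2)
    return np.clip(values, 0.0, 1.0)


def make_study(spec: StudySpec, tree: Phylogeny) -> tuple[pd.DataFrame, dict]:
    """Simulate a species trait table on a tree; return (table, ground truth).

    The table has one row per species x life stage with the columns the
    pipeline reads (species, life_stage, habit, activity, adult_environment,
    the three shape metrics plus flatness, and adult diameters).  The ground
    truth records every generating parameter and per-species assignments.
    """
    tips = sorted(tree.tip_labels)
    if len(tips) < spec.n_species:
        raise ValueError(f"tree has {len(tips)} tips; need {spec.n_species}")
    rng = np.random.default_rng(spec.seed)
    species = list(rng.choice(tips, size=spec.n_species, replace=False))
    species.sort()

    habit = rng.choice(HABITS, size=spec.n_species, p=spec.habit_freqs)
    activity = rng.choice(ACTIVITIES, size=spec.n_species, p=spec.activity_freqs)
    env = np.where(habit == "aquatic", "aquatic", "terrestrial")

    # Stage availability.  Paired (tadpole + adult) sampling is stratified
    # by adult environment so both aquatic- and terrestrial-adult species
    # are represented among the paired records, as in a designed survey of
    # metamorphic change.
    stage_of = np.full(spec.n_species, "adult-only", dtype=object)
    aq_idx = rng.permutation(np.flatnonzero(env == "aquatic"))
    terr_idx = rng.permutation(np.flatnonzero(env == "terrestrial"))
    n_aq = int(round(spec.n_paired * len(aq_idx) / spec.n_species))
    n_aq = min(max(n_aq, min(2, len(aq_idx))), len(aq_idx), spec.n_paired)
    paired = list(aq_idx[:n_aq]) + list(terr_idx[:spec.n_paired - n_aq])
    stage_of[paired] = "paired"
    rest = rng.permutation([i for i in range(spec.n_species) if i not in set(paired)])
    stage_of[rest[:spec.n_tadpole_only]] = "tadpole-only"

    # Phylogenetic deviations shared within species, per metric and stage.
    dev = {}
    for stage, lam in (("tadpole", spec.lambda_tadpole), ("adult", spec.lambda_adult)):
        bm = simulate_bm(tree, n_traits=len(METRICS), rate=1.0, lam=lam,
                         seed=int(rng.integers(2 ** 31)), tips=species)
        bm.columns = METRICS
        dev[stage] = bm

    rows = []
    truth_species = []
    for i, sp in enumerate(species):
        has_tadpole = stage_of[i] in ("tadpole-only", "paired")
        has_adult = stage_of[i] in ("adult-only", "paired")
        hab = habit[i] if rng.random() > spec.missing_habit else None
        act = activity[i] if rng.random() > spec.missing_activity else None
        rec = {"species": sp, "habit": hab, "activity": act,
               "adult_environment": env[i], "stages": stage_of[i]}
        tad = {}
        for m in METRICS:
            tad[m] = (spec.baseline_means[m]
                      + spec.bm_sd[m] * dev["tadpole"].loc[sp, m]
                      + rng.normal(0.0, spec.noise_sd[m]))
        if has_tadpole:
            row = {"species": sp, "life_stage": "tadpole", "habit": hab,
                   "activity": act, "adult_environment": env[i],
                   "lens_diameter_mm": np.nan, "eye_diameter_mm": np.nan}
            for m in METRICS:
                row[m] = tad[m]
            rows.append(row)
        if has_adult:
            delta = (spec.delta_aquatic if env[i] == "aquatic"
                     else spec.delta_terrestrial)
            offsets = spec.habit_offsets.get(hab, {}) if hab else {}
            row = {"species": sp, "life_stage": "adult", "habit": hab,
                   "activity": act, "adult_environment": env[i]}
            for m in METRICS:
                row[m] = (tad[m] + delta[m] + offsets.get(m, 0.0)
                          + spec.bm_sd[m] * dev["adult"].loc[sp, m]
                          + rng.normal(0.0, spec.noise_sd[m]))
            if rng.random() < spec.diameter_fraction:
                log_eye = rng.normal(spec.log_eye_mean, spec.log_eye_sd)
                log_lens = (spec.allometric_intercept
                            + spec.allometric_slope * log_eye
                            + (spec.diameter_habit_offsets.get(hab, 0.0) if hab else 0.0)
                            + rng.normal(0.0, spec.diameter_noise_sd))
                row["eye_diameter_mm"] = float(np.exp(log_eye))
                row["lens_diameter_mm"] = float(np.exp(log_lens))
            else:
                row["eye_diameter_mm"] = np.nan
                row["lens_diameter_mm"] = np.nan
            rows.append(row)
        truth_species.append(rec)

    table = pd.DataFrame(rows)
    for m in METRICS:
        table[m] = _clip_metric(table[m].to_numpy(), m)
    # Flatness is reconstructed from the identity 1 - a = f * e so the
    # collinearity screen sees the expected near-perfect correlation.
    table["flatness"] = np.clip(
        (1.0 - table["anisotropy"]) / table["elongation"].clip(lower=1e-6),
        0.0, 1.0)
    cols = ["species", "life_stage", "habit", "activity", "adult_environment",
            "anisotropy", "flatness", "elongation", "sphericity",
            "lens_diameter_mm", "eye_diameter_mm"]
    table = table[cols]

    truth = {
        "spec": asdict(spec),
        "species": truth_species,
        "effects": {
            "delta_terrestrial": dict(spec.delta_terrestrial),
            "delta_aquatic": dict(spec.delta_aquatic),
            "habit_offsets": {k: dict(v) for k, v in spec.habit_offsets.items()},
            "allometric_slope": spec.allometric_slope,
            "diameter_habit_offsets": dict(spec.diameter_habit_offsets),
        },
    }
    return table, truth
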