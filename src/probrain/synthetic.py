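"""Synthetic data with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without external data:

* trait simulation on a tree — one multivariate-normal draw from the model
  covariance (so fitting and simulation exercise the same covariance code),
  plus an independent branch-by-branch Brownian recursion used as a
  cross-check oracle that also records internal-node states;
* allometric datasets — log body mass evolves by Brownian motion, log brain
  mass is intercept + slope * log body + phylogenetically correlated noise,
  emitted in the standard specimen schema.  Defaults mirror the study's
  final regression regime: 19 tips, slope 0.20, lambda 0.9, with rates
  matched to the spread of the packaged data;
* synthetic endocasts — perturbed-ellipsoid meshes of known volume together
  with their orthogonal silhouette profiles, standing in for digitized
  endocasts.

The module also packages the in-study fixtures: the printed trait table, the
consensus calibrated tree (built from an editable calibration file), and the
seven-specimen exclusion list.
"""

from __future__ import annotations

import importlib.resources as resources
import logging
import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import pcm
from .treedata import (
    CalibratedTree,
    SpecimenTable,
    attach_specimens,
    load_specimen_table,
    parse_newick,
    read_calibrations,
)
from .volumetrics import SilhouetteProfile, TriangleMesh

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "random_tree",
    "simulate_traits",
    "simulate_bm_recursive",
    "simulate_allometric_dataset",
    "synthetic_endocast",
    "build_species_tree",
    "fixtures",
    "FixtureBundle",
    "SPECIES_TOPOLOGY",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 0.01  # Ma; depth of conspecific specimen tips

# Defaults of the allometric simulator: the study's final-fit regime
# (19 tips, slope 0.20, lambda 0.9).  Rates are per-Ma on the ~40 Ma fixture
# tree and are matched to the packaged data: body_sigma2 reproduces the
# observed log10 body-mass spread, noise_sigma2 the ML residual scale of the
# final lambda-model fit.
DEFAULT_TRUTH = {
    "intercept": 1.76,      # log10 g at log10 body = 0, as in the final fit
    "slope": 0.20,
    "lam": 0.9,
    "body_sigma2": 0.003,   # log10^2 per Ma
    "noise_sigma2": 4e-4,   # log10^2 per Ma
}

# Consensus topology: (clade-name, [children]); leaves are species tip labels.
SPECIES_TOPOLOGY = (
    "Proboscidea",
    [
        "Moeritherium_lyonsi",
        (
            "Elephantiformes",
            [
                "Palaeomastodon_beadnelli",
                (
                    "Elephantimorpha",
                    [
                        ("Mammutida", ["Mammut_americanum", "Zygolophodon_borsoni"]),
                        (
                            "Elephantoidea",
                            [
                                "Stegodon_insignis",
                                (
                                    "Elephantidae",
                                    [
                                        ("Palaeoloxodon", ["Palaeoloxodon_antiquus", "Palaeoloxodon_falconeri"]),
                                        (
                                            "Mammuthus",
                                            [
                                                "Mammuthus_meridionalis",
                                                ("MammuthusCP", ["Mammuthus_columbi", "Mammuthus_primigenius"]),
                                            ],
                                        ),
                                        ("ElephasLoxodonta", ["Elephas_maximus", "Loxodonta_africana"]),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible trait-simulation setup (tree, model, truth, seed)."""

    n_tips: int = 19
    kind: str = "LAMBDA"
    sigma2: float = DEFAULT_TRUTH["noise_sigma2"]
    lam: float | None = DEFAULT_TRUTH["lam"]
    alpha: float | None = None
    r: float | None = None
    intercept: float = DEFAULT_TRUTH["intercept"]
    slope: float = DEFAULT_TRUTH["slope"]
    seed: int = 0

    def model(self) -> pcm.EvoModel:
        extra = {"LAMBDA": {"lam": self.lam}, "OU": {"alpha": self.alpha}, "EB": {"r": self.r}}
        return pcm.EvoModel(self.kind, sigma2=self.sigma2, **extra.get(self.kind, {}))


def random_tree(n_tips: int, seed: int, birth_rate: float = 1.0, death_rate: float = 0.0) -> CalibratedTree:
    """Random birth-death tree with ``n_tips`` extant tips (labels t1..tn).

    Zero-length branches occasionally produced by the sampler are floored to
    1e-3 time units so induced trait covariances stay nonsingular.
    """
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(dtree.leaf_node_iter(), 1):
        leaf.taxon.label = f"t{i}"
    tree = CalibratedTree.from_dendropy(dtree)
    tree.blen[0] = 0.0
    tree.blen[1:] = np.maximum(tree.blen[1:], 1e-3)
    return tree


def simulate_traits(tree: CalibratedTree, model: pcm.EvoModel, root_state: float, seed: int,
                    tip_order=None) -> pd.Series:
    """One multivariate-normal draw of tip states under ``model``."""
    cov = pcm.phylo_covariance(tree, model, tip_order)
    rng = np.random.default_rng(seed)
    if model.sigma2 == 0.0:  # degenerate: every tip equals the root state
        return pd.Series(np.full(len(cov.tip_order), root_state), index=list(cov.tip_order))
    try:
        values = rng.multivariate_normal(
            np.full(len(cov.tip_order), root_state), cov.matrix, method="cholesky"
        )
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"model covariance is not positive definite: {exc}") from None
    return pd.Series(values, index=list(cov.tip_order))


def simulate_bm_recursive(tree: CalibratedTree, sigma2: float, root_state: float, seed: int):
    """Branch-by-branch Brownian simulation (independent of the covariance code).

    Returns (tip values as a Series, internal-node states as a dict keyed by
    node id) — the recorded history used by interval-coverage checks.
    """
    rng = np.random.default_rng(seed)
    states = np.empty(tree.n_nodes)
    states[0] = root_state
    for v in range(1, tree.n_nodes):
        states[v] = states[tree.parent[v]] + rng.normal(0.0, np.sqrt(sigma2 * tree.blen[v]))
    tips = tree.tips
    tip_values = pd.Series([states[v] for v in tips], index=[tree.labels[v] for v in tips])
    internal = {v: float(states[v]) for v in tree.internal_nodes}
    return tip_values, internal


def simulate_allometric_dataset(
    tree: CalibratedTree,
    intercept: float = DEFAULT_TRUTH["intercept"],
    slope: float = DEFAULT_TRUTH["slope"],
    model: pcm.EvoModel | None = None,
    seed: int = 0,
    body_sigma2: float = DEFAULT_TRUTH["body_sigma2"],
    body_root: float = 6.5,
) -> SpecimenTable:
    """Simulated specimen table: log10 body by BM, log10 brain = allometry + noise."""
    if model is None:
        model = pcm.EvoModel("LAMBDA", sigma2=DEFAULT_TRUTH["noise_sigma2"], lam=DEFAULT_TRUTH["lam"])
    rng = np.random.default_rng(seed)
    log_body = simulate_traits(tree, pcm.EvoModel("BM", sigma2=body_sigma2), body_root,
                               seed=int(rng.integers(2**31)))
    noise = simulate_traits(tree, model, 0.0, seed=int(rng.integers(2**31)))
    log_brain = intercept + slope * log_body + noise.loc[log_body.index]
    df = pd.DataFrame({
        "specimen_id": log_body.index,
        "taxon": log_body.index,
        "endocast_cm3": np.nan,
        "brain_g": 10.0 ** log_brain.to_numpy(),
        "body_g": 10.0 ** log_body.to_numpy(),
        "eq": np.nan,
        "group": "proboscidean",
    })
    return SpecimenTable(df)


# ---------------------------------------------------------------------------
# Synthetic endocasts
# ---------------------------------------------------------------------------

def _icosphere(subdivisions: int = 4):
    import trimesh

    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)


def synthetic_endocast(
    a: float,
    b: float,
    c: float,
    perturbation: float = 0.0,
    seed: int = 0,
    subdivisions: int = 4,
    n_slices: int = 200,
):
    """Perturbed-ellipsoid endocast with silhouettes and reference volume.

    Returns ``(profile_xy, profile_xz, mesh, true_volume)``.  The mesh scales
    a unit icosphere to semi-axes (a, b, c) and, when ``perturbation`` > 0,
    modulates the radius by a smooth low-order angular polynomial with
    seed-reproducible coefficients.  Silhouettes are the per-slice extents of
    the mesh along y (top view) and z (side view); for the unperturbed
    ellipsoid they are exact and ``true_volume`` is (4/3)*pi*a*b*c, otherwise
    the reference volume is the divergence-theorem mesh volume.
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    base = _icosphere(subdivisions)
    verts = np.asarray(base.vertices).copy()
    if perturbation:
        rng = np.random.default_rng(seed)
        coef = rng.normal(size=6)
        u = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        f = (coef[0] * u[:, 0] * u[:, 1] + coef[1] * u[:, 1] * u[:, 2] + coef[2] * u[:, 0] * u[:, 2]
             + coef[3] * (u[:, 0] ** 2 - u[:, 1] ** 2) + coef[4] * (u[:, 1] ** 2 - u[:, 2] ** 2)
             + coef[5] * u[:, 0] * u[:, 1] * u[:, 2])
        f = f / max(np.max(np.abs(f)), 1e-12)
        verts = verts * (1.0 + perturbation * f)[:, None]
    verts = verts * np.array([a, b, c])
    mesh = TriangleMesh(verts, np.asarray(base.faces))

    if perturbation:
        from .volumetrics import mesh_volume

        true_volume = mesh_volume(mesh)
        xs = np.linspace(verts[:, 0].min(), verts[:, 0].max(), n_slices + 2)[1:-1]
        wy, wz = _mesh_silhouette_widths(mesh, xs)
        p_xy = SilhouetteProfile(xs, wy, view="dorsal")
        p_xz = SilhouetteProfile(xs, wz, view="lateral")
    else:
        true_volume = 4.0 / 3.0 * np.pi * a * b * c
        xs = np.linspace(-a, a, n_slices + 2)[1:-1]
        s = np.sqrt(np.clip(1.0 - (xs / a) ** 2, 0.0, None))
        p_xy = SilhouetteProfile(xs, 2.0 * b * s, view="dorsal")
        p_xz = SilhouetteProfile(xs, 2.0 * c * s, view="lateral")
    return p_xy, p_xz, mesh, float(true_volume)


def _mesh_silhouette_widths(mesh: TriangleMesh, xs: np.ndarray):
    """Widths of the cross-sections at planes x = xs (extent in y and z)."""
    v = mesh.vertices[mesh.faces]  # (m, 3, 3)
    wy = np.zeros(len(xs))
    wz = np.zeros(len(xs))
    x0, x1, x2 = v[:, 0, 0], v[:, 1, 0], v[:, 2, 0]
    for k, x in enumerate(xs):
        lo, hi = [], []
        for (i, j) in ((0, 1), (1, 2), (2, 0)):
            xi, xj = v[:, i, 0], v[:, j, 0]
            mask = ((xi <= x) & (xj > x)) | ((xj <= x) & (xi > x))
            if not np.any(mask):
                continue
            t = (x - xi[mask]) / (xj[mask] - xi[mask])
            pts = v[mask, i, :] + t[:, None] * (v[mask, j, :] - v[mask, i, :])
            lo.append(pts)
        if lo:
            pts = np.vstack(lo)
            wy[k] = pts[:, 1].max() - pts[:, 1].min()
            wz[k] = pts[:, 2].max() - pts[:, 2].min()
    return wy, wz


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("probrain").joinpath("data", name).read_text()


def build_species_tree(calibrations: dict[str, float], topology=SPECIES_TOPOLOGY) -> CalibratedTree:
    """Consensus species tree from node/tip ages (Ma).

    Every clade name and tip label in ``topology`` must appear in
    ``calibrations``; branch lengths are age(parent) - age(child) and must be
    non-negative.
    """

    def newick(node, parent_age: float | None) -> str:
        if isinstance(node, str):
            name, children = node, None
        else:
            name, children = node
        if name not in calibrations:
            raise ValueError(f"no calibration for {name!r}")
        age = calibrations[name]
        if parent_age is not None and age > parent_age + 1e-12:
            raise ValueError(f"{name} ({age} Ma) is older than its parent ({parent_age} Ma)")
        blen = 0.0 if parent_age is None else parent_age - age
        if children is None:
            return f"{name}:{blen:.10g}"
        inner = ",".join(newick(ch, age) for ch in children)
        return f"({inner}){name}:{blen:.10g}"

    return parse_newick(newick(topology, None) + ";")


@dataclass
class FixtureBundle:
    """The packaged study inputs."""

    table: SpecimenTable
    species_tree: CalibratedTree
    specimen_tree: CalibratedTree
    exclusions: list[str]
    calibrations: dict[str, float]
    epsilon: float = DEFAULT_EPSILON


def fixtures(epsilon: float = DEFAULT_EPSILON) -> FixtureBundle:
    """Load the packaged trait table, calibrated trees and exclusion list."""
    import io

    table = load_specimen_table(io.StringIO(_data_text("table1.csv")))
    calib = read_calibrations(io.StringIO(_data_text("calibrations.txt")))
    species = build_species_tree(calib)
    specimen = attach_specimens(species, table, epsilon=epsilon)
    exclusions = [
        line.strip()
        for line in _data_text("exclusions.txt").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return FixtureBundle(
        table=table,
        species_tree=species,
        specimen_tree=specimen,
        exclusions=exclusions,
        calibrations=calib,
    )
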