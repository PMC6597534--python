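"""Endocast volume estimation from silhouettes and triangle meshes.

Two routes mirror how fossil endocast volumes are measured in practice:

* double graphic integration — two orthogonal silhouette width profiles are
  combined slice by slice under an elliptical cross-section model,
  V = sum (pi/4) * w1(x) * w2(x) * dx (trapezoidal accumulation);
* mesh volume — the divergence-theorem sum of signed tetrahedra over a
  closed, consistently oriented triangle mesh (photogrammetry surrogate).

A hemi-endocast measured from a half cast is doubled to a whole-endocast
volume with :func:`mirror_double`.  Units are cm / cm3 throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "SilhouetteProfile",
    "TriangleMesh",
    "double_graphic_integration",
    "mesh_volume",
    "signed_mesh_volume",
    "mirror_double",
    "load_mesh",
    "load_profile_csv",
]

DEFAULT_SLICES = 200


@dataclass(frozen=True)
class SilhouetteProfile:
    """Width profile of one endocast view along its sampling axis (cm)."""

    x: np.ndarray
    width: np.ndarray
    view: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, float))
        object.__setattr__(self, "width", np.asarray(self.width, float))
        if self.x.ndim != 1 or self.x.shape != self.width.shape or len(self.x) < 2:
            raise ValueError("profile needs >= 2 (x, width) samples")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("axis positions must be strictly increasing")
        if np.any(self.width < 0):
            raise ValueError(f"negative width in view {self.view!r}")

    @property
    def length(self) -> float:
        return float(self.x[-1] - self.x[0])


def _resample(profile: SilhouetteProfile, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, profile.x, profile.width)


def double_graphic_integration(
    p1: SilhouetteProfile,
    p2: SilhouetteProfile,
    n_slices: int = DEFAULT_SLICES,
    align: str = "endpoints",
) -> float:
    """Volume (cm3) from two orthogonal silhouettes, elliptical sections.

    ``align="endpoints"`` (default) maps the second profile's axis linearly
    onto the first one's range before resampling, accommodating drawings in
    different axis frames; ``align="none"`` integrates over the overlap of
    the two supports and raises when they are disjoint.
    """
    if align not in ("endpoints", "none"):
        raise ValueError("align must be 'endpoints' or 'none'")
    if align == "endpoints":
        lo, hi = p1.x[0], p1.x[-1]
        grid = np.linspace(lo, hi, n_slices)
        w1 = _resample(p1, grid)
        scale = p2.length / p1.length
        w2 = np.interp(p2.x[0] + (grid - lo) * scale, p2.x, p2.width)
    else:
        lo, hi = max(p1.x[0], p2.x[0]), min(p1.x[-1], p2.x[-1])
        if hi <= lo:
            raise ValueError("profile supports are disjoint")
        grid = np.linspace(lo, hi, n_slices)
        w1 = _resample(p1, grid)
        w2 = _resample(p2, grid)
    return float(np.trapezoid(np.pi / 4.0 * w1 * w2, grid))


@dataclass(frozen=True)
class TriangleMesh:
    """Vertex/face triangle mesh in cm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, float))
        object.__setattr__(self, "faces", np.asarray(self.faces, int))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) index triples")
        if np.any(self.faces < 0) or np.any(self.faces >= len(self.vertices)):
            raise ValueError("face index out of range")

    def boundary_edge_count(self) -> int:
        """Number of edges not shared by exactly two triangles."""
        e = np.sort(np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0


def signed_mesh_volume(mesh: TriangleMesh) -> float:
    """Signed volume by summed tetrahedra against the origin."""
    v = mesh.vertices[mesh.faces]  # (m, 3, 3)
    return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (cm3) of a closed triangle mesh, orientation-safe.

    Raises for open meshes (naming the boundary-edge count) and warns about
    degenerate (zero-area) triangles.
    """
    nb = mesh.boundary_edge_count()
    if nb:
        raise ValueError(f"mesh is not closed: {nb} boundary/non-manifold edges")
    v = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
    if np.any(areas < 1e-14):
        warnings.warn(f"{int(np.sum(areas < 1e-14))} degenerate triangles in mesh")
    signed = signed_mesh_volume(mesh)
    if signed < 0:
        log.info("mesh orientation is inward-facing; reporting |volume|")
    return abs(signed)


def mirror_double(hemi_volume: float) -> float:
    """Whole-endocast volume from a half-endocast measurement."""
    if hemi_volume <= 0:
        raise ValueError("hemi-endocast volume must be > 0")
    return 2.0 * hemi_volume


def load_mesh(path: str | Path) -> TriangleMesh:
    """Read an OBJ or PLY mesh (via trimesh)."""
    import trimesh

    tm = trimesh.load(str(path), force="mesh")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def load_profile_csv(path: str | Path, view: str = "") -> SilhouetteProfile:
    """Read an ``x_cm,width_cm`` profile CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("x_cm", "width_cm"):
        if col not in df.columns:
            raise ValueError(f"profile CSV missing column {col!r}")
    return SilhouetteProfile(df["x_cm"].to_numpy(float), df["width_cm"].to_numpy(float), view=view)
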