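"""Flat cortical patch geometry.

The analyses in this package operate on a flattened representation of V2,
modelled as a regular triangulated grid in the plane. Euclidean distance on
the flat patch stands in for geodesic distance, and the per-vertex
"curvature" map is a synthetic confound field (the patch itself is flat; the
map emulates the local mean curvature of the folded sheet the data were
sampled from).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import squareform, pdist


def gaussian_random_field(
    grid_shape: tuple[int, int],
    spacing_mm: float,
    corr_length_mm: float,
    rng: np.random.Generator,
    sd: float = 1.0,
) -> np.ndarray:
    """Stationary Gaussian random field on a regular grid, flattened to 1D.

    White noise is convolved with a Gaussian kernel of standard deviation
    ``corr_length_mm / 2`` so that the autocorrelation falls to 1/e at lag
    ``corr_length_mm``. The field is normalised analytically (via the kernel
    l2 norm) to unit variance, then scaled by ``sd``. Periodic boundary
    conditions keep the field stationary across the patch.
    """
    if corr_length_mm < 0:
        raise ValueError("corr_length_mm must be >= 0")
    white = rng.standard_normal(grid_shape)
    if corr_length_mm == 0 or sd == 0:
        return (sd * white).ravel()
    sigma_px = corr_length_mm / (2.0 * spacing_mm)
    f = gaussian_filter(white, sigma_px, mode="wrap")
    # kernel l2 norm from an impulse on the same grid
    imp = np.zeros(grid_shape)
    imp[grid_shape[0] // 2, grid_shape[1] // 2] = 1.0
    k = gaussian_filter(imp, sigma_px, mode="wrap")
    norm = np.sqrt((k**2).sum())
    return (sd / norm) * f.ravel()


@dataclass
class CorticalPatch:
    """Triangulated flat patch with per-vertex geometry.

    vertex_coords : (N, 2) positions in mm
    faces         : (F, 3) triangle vertex indices
    vertex_area   : (N,) barycentric area share in mm^2
    curvature     : (N,) synthetic mean-curvature map in 1/mm
    v2_mask       : (N,) bool, vertices belonging to V2
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    vertex_area: np.ndarray
    curvature: np.ndarray
    v2_mask: np.ndarray
    grid_shape: tuple[int, int]
    spacing_mm: float
    _pairwise: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not np.all(self.vertex_area > 0):
            raise ValueError("all vertex areas must be positive")
        if not np.all(np.isfinite(self.curvature)):
            raise ValueError("curvature must be finite")
        if not self.v2_mask.any():
            raise ValueError("v2_mask must be non-empty")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def pairwise_dist(self) -> np.ndarray:
        """Full symmetric Euclidean distance matrix (mm); cached."""
        if self._pairwise is None:
            self._pairwise = squareform(pdist(self.vertex_coords))
        return self._pairwise


def _grid_faces(ny: int, nx: int) -> np.ndarray:
    idx = np.arange(ny * nx).reshape(ny, nx)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    # two triangles per cell
    return np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([b, d, c], axis=1)], axis=0
    )


def barycentric_vertex_areas(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """One third of each incident triangle's area, accumulated per vertex."""
    p = coords[faces]
    if p.shape[2] == 2:
        cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 1, 1] - p[:, 0, 1]
        ) * (p[:, 2, 0] - p[:, 0, 0])
        tri_area = 0.5 * np.abs(cross)
    else:
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        tri_area = 0.5 * np.linalg.norm(cr, axis=1)
    area = np.zeros(coords.shape[0])
    for j in range(3):
        np.add.at(area, faces[:, j], tri_area / 3.0)
    return area


def generate_patch(
    width_mm: float,
    height_mm: float,
    spacing_mm: float,
    curvature_field_spec: dict | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> CorticalPatch:
    """Build a regular triangulated flat patch.

    ``curvature_field_spec`` is ``None`` (flat: curvature identically zero) or
    ``{"kind": "grf", "sd": ..., "corr_length_mm": ...}`` for a smooth random
    confound field. The whole patch is V2.
    """
    if width_mm <= 0 or height_mm <= 0 or spacing_mm <= 0:
        raise ValueError("patch dimensions and spacing must be positive")
    if spacing_mm > min(width_mm, height_mm):
        raise ValueError("spacing larger than patch")
    nx = int(round(width_mm / spacing_mm)) + 1
    ny = int(round(height_mm / spacing_mm)) + 1
    x = np.arange(nx) * spacing_mm
    y = np.arange(ny) * spacing_mm
    xx, yy = np.meshgrid(x, y)
    coords = np.stack([xx.ravel(), yy.ravel()], axis=1)
    faces = _grid_faces(ny, nx)
    area = barycentric_vertex_areas(coords, faces)

    if curvature_field_spec is None or curvature_field_spec.get("kind") == "zero":
        curv = np.zeros(ny * nx)
    elif curvature_field_spec.get("kind") == "grf":
        rng = np.random.default_rng(seed)
        curv = gaussian_random_field(
            (ny, nx),
            spacing_mm,
            curvature_field_spec.get("corr_length_mm", 3.0),
            rng,
            sd=curvature_field_spec.get("sd", 0.15),
        )
    else:
        raise ValueError(f"unknown curvature field spec: {curvature_field_spec!r}")

    return CorticalPatch(
        vertex_coords=coords,
        faces=faces,
        vertex_area=area,
        curvature=curv,
        v2_mask=np.ones(ny * nx, dtype=bool),
        grid_shape=(ny, nx),
        spacing_mm=spacing_mm,
    )
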