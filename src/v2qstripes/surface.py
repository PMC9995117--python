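"""Mesh curvature, equi-volume cortical depth, and volume-to-surface sampling.

The equi-volume model places a depth surface so that the volume fraction of
cortex below it is preserved locally even where the sheet is curved: with
local one-ring areas A_w on the white and A_p on the pial boundary and a
cross-sectional area varying linearly between them, the depth fraction x
(0 = white boundary) enclosing volume fraction nu solves

    A_w x + x^2 (A_p - A_w) / 2 = nu (A_w + A_p) / 2

whose positive root is x = (-A_w + sqrt((1-nu) A_w^2 + nu A_p^2)) / (A_p - A_w),
reducing to the equi-distant x = nu when the areas are equal.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .patch import barycentric_vertex_areas

_EQUAL_AREA_EPS = 1e-9


def _as_mesh(obj):
    """Accept a CorticalPatch or a (coords, faces) pair; return 3D coords."""
    if hasattr(obj, "vertex_coords"):
        coords, faces = obj.vertex_coords, obj.faces
    else:
        coords, faces = obj
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    return coords, np.asarray(faces)


def vertex_normals(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(
        coords[faces[:, 1]] - coords[faces[:, 0]],
        coords[faces[:, 2]] - coords[faces[:, 0]],
    )
    vn = np.zeros_like(coords)
    for j in range(3):
        np.add.at(vn, faces[:, j], fn)
    norm = np.linalg.norm(vn, axis=1)
    norm[norm == 0] = 1.0
    return vn / norm[:, None]


def mesh_curvature(mesh) -> np.ndarray:
    """Discrete mean curvature per vertex (1/mm), cotangent-Laplacian estimate.

    The mean-curvature normal is accumulated over one-ring edges with
    cotangent weights and normalised by twice the barycentric vertex area;
    the signed magnitude uses the outward vertex normal, so a sphere of
    radius R with outward orientation measures approximately +1/R and a flat
    mesh measures exactly zero. Degenerate (zero-area) faces raise.
    """
    coords, faces = _as_mesh(mesh)
    p0, p1, p2 = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    area2 = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)  # 2x face area
    if np.any(area2 <= 0):
        raise ValueError("mesh contains degenerate faces")

    lap = np.zeros_like(coords)
    for (i, j, k) in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent at corner k weights edge (i, j)
        u = coords[faces[:, i]] - coords[faces[:, k]]
        v = coords[faces[:, j]] - coords[faces[:, k]]
        cot = (u * v).sum(axis=1) / area2
        d = coords[faces[:, i]] - coords[faces[:, j]]
        np.add.at(lap, faces[:, i], cot[:, None] * d)
        np.add.at(lap, faces[:, j], -cot[:, None] * d)

    area = barycentric_vertex_areas(coords, faces)
    hn = lap / (4.0 * area[:, None])
    normals = vertex_normals(coords, faces)
    # hn approximates H times the outward vertex normal
    return (hn * normals).sum(axis=1)


def equivolume_fraction(a_inner, a_outer, nu):
    """Equi-volume depth fraction x in [0, 1] for volume fraction ``nu``.

    ``a_inner`` is the white-side local area, ``a_outer`` the pial-side one.
    Falls back to the equi-distant x = nu where the areas agree to within
    a relative epsilon of 1e-9.
    """
    a_w = np.asarray(a_inner, dtype=float)
    a_p = np.asarray(a_outer, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(a_w <= 0) or np.any(a_p <= 0):
        raise ValueError("local areas must be positive")
    if np.any((nu < 0) | (nu > 1)):
        raise ValueError("nu must lie in [0, 1]")
    diff = a_p - a_w
    equal = np.abs(diff) < _EQUAL_AREA_EPS * a_w
    safe_diff = np.where(equal, 1.0, diff)
    x = (-a_w + np.sqrt((1.0 - nu) * a_w**2 + nu * a_p**2)) / safe_diff
    return np.where(equal, nu, x)


def build_depth_surface(
    inner_coords: np.ndarray,
    outer_coords: np.ndarray,
    nu: float | np.ndarray,
    faces: np.ndarray | None = None,
    a_inner: np.ndarray | None = None,
    a_outer: np.ndarray | None = None,
) -> np.ndarray:
    """Interpolate vertex-corresponding surfaces at the equi-volume depth.

    Local areas default to one-ring barycentric areas computed from ``faces``
    on each boundary surface.
    """
    inner_coords = np.asarray(inner_coords, dtype=float)
    outer_coords = np.asarray(outer_coords, dtype=float)
    if inner_coords.shape != outer_coords.shape:
        raise ValueError("inner and outer surfaces must have matching vertex counts")
    if a_inner is None or a_outer is None:
        if faces is None:
            raise ValueError("faces required to compute local areas")
        a_inner = barycentric_vertex_areas(inner_coords, faces)
        a_outer = barycentric_vertex_areas(outer_coords, faces)
    x = equivolume_fraction(a_inner, a_outer, nu)
    return inner_coords + np.asarray(x)[..., None] * (outer_coords - inner_coords)


def sample_to_surface(volume, vertices: np.ndarray, mode: str = "nearest"):
    """Sample a volume at surface vertex coordinates (world/RAS mm).

    ``volume`` is a nibabel spatial image or a ``(data, affine)`` pair.
    ``mode="nearest"`` (default) picks the owning voxel with half-open
    ownership (ties round toward the lower index); ``mode="linear"`` does
    trilinear interpolation. Vertices outside the volume are flagged invalid
    and returned as NaN. Returns ``(values, valid)``.
    """
    if hasattr(volume, "get_fdata"):
        data = volume.get_fdata()
        affine = volume.affine
    else:
        data, affine = volume
        data = np.asarray(data, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    inv = np.linalg.inv(affine)
    vox = vertices @ inv[:3, :3].T + inv[:3, 3]

    shape = np.array(data.shape[:3])
    if mode == "nearest":
        idx = np.ceil(vox - 0.5).astype(int)  # round-half-down toward lower index
        valid = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.full(len(vertices), np.nan)
        out[valid] = data[idx[valid, 0], idx[valid, 1], idx[valid, 2]]
    elif mode == "linear":
        valid = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
        out = map_coordinates(data, vox.T, order=1, mode="constant", cval=np.nan)
        out[~valid] = np.nan
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return out, valid
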