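"""Sphere meshing, texture back-projection and surface coverage.

The reconstructed ring is delivered as a textured spherical mesh fragment:
a UV sphere at the recovered radius, with each composite back-projected
onto the visible surface and blended with a cosine feather that favors the
image center.  Faces never hit by any projection stay uncovered; the
covered-area fraction is the analogue of the per-ring surface coverage
reported for the physical pearl.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh
from PIL import Image
from scipy import ndimage as ndi

from .geometry import CameraPose

__all__ = [
    "RingModel",
    "build_sphere_mesh",
    "texture_mesh",
    "surface_coverage",
    "export_obj",
    "export_ply",
    "import_ply",
]


@dataclass
class RingModel:
    """Textured spherical mesh fragment with physical scale.

    ``texture`` is an equirectangular canvas; ``uv`` maps vertices into it;
    ``covered`` flags the faces that received at least one projection.
    Physical scale is mm per mesh unit (the mesh is built in mm, so 1.0).
    """

    mesh: trimesh.Trimesh
    uv: np.ndarray
    texture: np.ndarray
    covered: np.ndarray
    scale_mm_per_unit: float = 1.0

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float)
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.scale_mm_per_unit <= 0:
            raise ValueError("scale must be positive")
        if len(self.covered) != len(self.mesh.faces):
            raise ValueError("covered flags must be per-face")


def build_sphere_mesh(radius_mm: float, n_subdivisions: int = 4) -> trimesh.Trimesh:
    """UV sphere of the given radius; area within 1% of 4*pi*R^2 at default
    resolution."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if n_subdivisions < 2:
        raise ValueError("n_subdivisions must be >= 2")
    n_lat = 16 * 2 ** (n_subdivisions - 2)
    return trimesh.creation.uv_sphere(radius=radius_mm, count=(n_lat, 2 * n_lat))


def _vertex_lonlat(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.linalg.norm(vertices, axis=1)
    lon = np.mod(np.arctan2(vertices[:, 1], vertices[:, 0]), 2 * np.pi)
    lat = np.arcsin(np.clip(vertices[:, 2] / np.where(r == 0, 1, r), -1, 1))
    return lon, lat


def _visible(points: np.ndarray, pose: CameraPose, radius: float, shape_px) -> np.ndarray:
    """Sphere points visible from the camera and projecting inside the frame."""
    w, h = shape_px
    above_horizon = points @ pose.center > radius**2  # dot(P_hat, c) > R
    uv = pose.project(points)
    in_frame = (
        (uv[:, 0] >= 0) & (uv[:, 0] <= w - 1) & (uv[:, 1] >= 0) & (uv[:, 1] <= h - 1)
    )
    return above_horizon & in_frame


def texture_mesh(
    mesh: trimesh.Trimesh,
    composites: Sequence[np.ndarray],
    poses: Sequence[CameraPose],
    canvas_width: int = 1024,
) -> RingModel:
    """Back-project composites onto the sphere mesh and blend overlaps.

    Each image contributes to the equirectangular texture canvas with a
    cosine feather weight that decreases from the image center, which
    suppresses seams where consecutive frames overlap.  Faces whose
    centroid is not visible in any image are marked uncovered.
    """
    if len(composites) != len(poses):
        raise ValueError("composites and poses must align 1:1")
    radius = float(np.linalg.norm(mesh.vertices, axis=1).mean())
    w_canvas = int(canvas_width)
    h_canvas = w_canvas // 2
    lon = (np.arange(w_canvas) + 0.5) / w_canvas * 2 * np.pi
    lat = (np.arange(h_canvas) + 0.5) / h_canvas * np.pi - np.pi / 2
    lon_g, lat_g = np.meshgrid(lon, lat)
    pts = radius * np.column_stack(
        [
            (np.cos(lat_g) * np.cos(lon_g)).ravel(),
            (np.cos(lat_g) * np.sin(lon_g)).ravel(),
            np.sin(lat_g).ravel(),
        ]
    )

    num = np.zeros(w_canvas * h_canvas)
    den = np.zeros(w_canvas * h_canvas)
    for img, pose in zip(composites, poses):
        img = np.asarray(img, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        h_img, w_img = img.shape
        vis = _visible(pts, pose, radius, (w_img, h_img))
        if not vis.any():
            continue
        uv = pose.project(pts[vis])
        samples = ndi.map_coordinates(img, [uv[:, 1], uv[:, 0]], order=1, mode="nearest")
        cx, cy = (w_img - 1) / 2.0, (h_img - 1) / 2.0
        dnorm = np.maximum(
            np.abs(uv[:, 0] - cx) / max(cx, 1e-9),
            np.abs(uv[:, 1] - cy) / max(cy, 1e-9),
        )
        weight = np.cos(0.5 * np.pi * np.clip(dnorm, 0, 1)) + 1e-6
        num[np.flatnonzero(vis)] += weight * samples
        den[np.flatnonzero(vis)] += weight

    if not (den > 0).any():
        raise ValueError("no texel received any projection")
    texture = np.zeros(w_canvas * h_canvas)
    texture[den > 0] = num[den > 0] / den[den > 0]
    texture = np.clip(texture, 0, 255).astype(np.uint8).reshape(h_canvas, w_canvas)

    centroids = mesh.triangles_center
    centroids_on_sphere = (
        centroids / np.linalg.norm(centroids, axis=1, keepdims=True) * radius
    )
    covered = np.zeros(len(mesh.faces), dtype=bool)
    for img, pose in zip(composites, poses):
        h_img, w_img = np.asarray(img).shape[:2]
        covered |= _visible(centroids_on_sphere, pose, radius, (w_img, h_img))
    if not covered.any():
        raise ValueError("no face covered by any image")

    v_lon, v_lat = _vertex_lonlat(mesh.vertices)
    uv_coords = np.column_stack([v_lon / (2 * np.pi), (v_lat + np.pi / 2) / np.pi])
    return RingModel(
        mesh=mesh, uv=uv_coords, texture=texture, covered=covered,
        scale_mm_per_unit=1.0,
    )


def surface_coverage(ring_model: RingModel) -> float:
    """Fraction of total mesh area carried by covered faces."""
    areas = ring_model.mesh.area_faces
    total = areas.sum()
    return float(areas[ring_model.covered].sum() / total) if total > 0 else 0.0


def export_obj(ring_model: RingModel, path) -> Path:
    """Write OBJ + MTL + PNG texture."""
    path = Path(path)
    mesh = ring_model.mesh.copy()
    image = Image.fromarray(ring_model.texture[::-1])  # OBJ v runs bottom-up
    mesh.visual = trimesh.visual.TextureVisuals(uv=ring_model.uv, image=image)
    mesh.export(path)
    return path


def export_ply(ring_model: RingModel, path) -> Path:
    """Write a binary little-endian PLY with per-vertex gray colors."""
    path = Path(path)
    mesh = ring_model.mesh.copy()
    h, w = ring_model.texture.shape
    cols = np.clip((ring_model.uv[:, 0] * w).astype(int), 0, w - 1)
    rows = np.clip((ring_model.uv[:, 1] * h).astype(int), 0, h - 1)
    gray = ring_model.texture[rows, cols]
    rgba = np.column_stack([gray, gray, gray, np.full_like(gray, 255)])
    mesh.visual = trimesh.visual.ColorVisuals(mesh, vertex_colors=rgba)
    mesh.export(path, encoding="binary")
    return path


def import_ply(path) -> trimesh.Trimesh:
    """Load an external PLY model for QC."""
    return trimesh.load(Path(path), force="mesh")
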