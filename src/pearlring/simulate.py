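"""Synthetic ring acquisitions around a textured near-spherical pearl.

Emulates the acquisition device: a fixed microscope above a pearl that is
rolled under it by translation stages, converting commanded translations
into rotations with a friction-dependent efficiency and lateral sliding
noise.  Every downstream stage of the package is validated against the
ground truth this module records (true angles, slips, sphere geometry).

The virtual camera is a pinhole whose working distance is tied to the
focal length and magnification by ``wd = f / m``, so the on-object pixel
footprint equals ``pixel_pitch / magnification`` exactly at the tangent
point and pixel-shift-to-arc conversions downstream are consistent with
the renderer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

import tifffile

from . import geometry as _geometry

__all__ = [
    "Optics",
    "SphereGroundTruth",
    "MotionModel",
    "ZStack",
    "DEFAULT_FEATURE_PARAMS",
    "generate_texture",
    "render_view",
    "simulate_ring",
    "overlap_stats",
    "save_dataset",
    "load_dataset",
    "study_optics",
    "study_motion",
]


@dataclass(frozen=True)
class Optics:
    """Microscope + camera optics.

    Defaults follow the physical device: 50x objective, 3.45 µm pixel
    pitch, 8.9 MP sensor (14.131 mm x 7.452 mm), calibrated focal length
    5.75 mm.  ``working_distance`` of None resolves to the pinhole relation
    ``focal_length / magnification``.
    """

    magnification: float = 50.0
    pixel_pitch: float = 3.45  # µm
    sensor_px: tuple[int, int] = (4096, 2160)  # width, height
    focal_length: float = 5.75  # mm
    working_distance: float | None = None  # mm
    dof_half_width: float = 0.01  # mm rendered sharp around the focus depth
    blur_scale: float = 150.0  # px of blur radius per mm of defocus
    illumination_gradient: float = 0.0  # relative intensity drop across x

    def __post_init__(self) -> None:
        if (
            self.magnification <= 0
            or self.pixel_pitch <= 0
            or self.focal_length <= 0
            or min(self.sensor_px) <= 0
        ):
            raise ValueError("optics parameters must be strictly positive")
        if self.working_distance is not None and self.working_distance <= 0:
            raise ValueError("working_distance must be positive")
        if self.dof_half_width < 0 or self.blur_scale < 0:
            raise ValueError("dof_half_width and blur_scale must be >= 0")
        if not (0.0 <= self.illumination_gradient < 1.0):
            raise ValueError("illumination_gradient must be in [0, 1)")

    @property
    def resolved_working_distance(self) -> float:
        """Camera-to-surface distance (mm); pinhole relation f/m by default."""
        if self.working_distance is not None:
            return self.working_distance
        return self.focal_length / self.magnification

    @property
    def mm_per_px(self) -> float:
        """On-object pixel footprint at the tangent point, mm."""
        return self.pixel_pitch * 1e-3 / self.magnification

    @property
    def fov_mm(self) -> tuple[float, float]:
        """Field of view on the object: sensor_px * pixel_pitch / magnification."""
        return (
            self.sensor_px[0] * self.mm_per_px,
            self.sensor_px[1] * self.mm_per_px,
        )

    @property
    def f_px(self) -> float:
        return self.focal_length / (self.pixel_pitch * 1e-3)


@dataclass
class SphereGroundTruth:
    """Near-spherical pearl: equatorial semi-axes and surface texture.

    The texture is an equirectangular 8-bit image (width = longitudes,
    height = latitudes) that is seamless at the longitude wrap; the 3D body
    is the ellipsoid with semi-axes (a, b, b), a >= b.
    """

    semi_axes: tuple[float, float]
    texture: np.ndarray
    feature_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("require semi-axes a >= b > 0")
        self.texture = np.asarray(self.texture)
        if self.texture.ndim != 2:
            raise ValueError("texture must be a 2D grayscale image")

    @property
    def ellipticity(self) -> float:
        a, b = self.semi_axes
        return (a - b) / a

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.semi_axes[0] + self.semi_axes[1])

    @property
    def circumference(self) -> float:
        """Equatorial circumference (mean-radius approximation)."""
        return 2.0 * np.pi * self.mean_radius

    def local_radius(self, theta_rad: float | np.ndarray) -> np.ndarray:
        """Equatorial ellipse radius at longitude theta."""
        a, b = self.semi_axes
        return a * b / np.sqrt(
            (b * np.cos(theta_rad)) ** 2 + (a * np.sin(theta_rad)) ** 2
        )


@dataclass(frozen=True)
class MotionModel:
    """Translation-to-rotation motion with friction loss and sliding noise.

    ``efficiency`` is arc rolled per mm commanded (~25 mm of arc per 32 mm
    commanded on the physical device).  ``arc_noise_sd`` perturbs each
    step's realized arc; ``lateral_sd`` is the per-step sd of the lateral
    (perpendicular-to-travel) random-walk slip.
    """

    efficiency: float = 25.13 / 32.0
    step_mm: float = 0.36
    arc_noise_sd: float = 0.05
    lateral_sd: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("efficiency must be in (0, 1]")
        if self.arc_noise_sd < 0 or self.lateral_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


@dataclass
class ZStack:
    """Ordered images of one field at successive focus depths."""

    frames: list[np.ndarray]
    z_positions: np.ndarray
    stage_position: float
    frame_index: int

    def __post_init__(self) -> None:
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if len(self.frames) != len(self.z_positions) or len(self.frames) < 1:
            raise ValueError("frames and z_positions must have equal length >= 1")
        if len(self.z_positions) > 1 and not np.all(np.diff(self.z_positions) > 0):
            raise ValueError("z_positions must be strictly increasing")


# Feature classes observed on the pearl surface at 50x, with physical sizes:
# stains/strains 0.02-0.2 mm, aragonite overlying fronts 0.005-0.01 mm,
# stripes from 0.05 mm up to the entire circumference.
DEFAULT_FEATURE_PARAMS: dict = {
    "stain": {"density_per_mm2": 2.0, "size_mm": (0.02, 0.2), "contrast": 45.0},
    "front": {"density_per_mm2": 150.0, "size_mm": (0.005, 0.01), "contrast": 25.0},
    "stripe": {
        "density_per_mm2": 0.25,
        "size_mm": (0.05, None),  # None -> up to full circumference
        "width_mm": 0.02,
        "contrast": 30.0,
    },
}


def generate_texture(
    feature_params: dict | None = None,
    texture_resolution: int = 4096,
    seed: int = 0,
    semi_axes: tuple[float, float] = (4.15, 4.15),
    background_level: float = 128.0,
    background_noise: float = 14.0,
    background_noise_sigma: float = 1.5,
) -> SphereGroundTruth:
    """Generate a seamless equirectangular pearl-surface texture.

    Three feature classes are drawn at their physical sizes on top of a
    smooth speckle background: stains (gaussian blobs), aragonite overlying
    fronts (short fine segments) and stripes (thin bands along the
    longitude direction, up to the full circumference).  Deterministic for
    a fixed seed.
    """
    params = DEFAULT_FEATURE_PARAMS if feature_params is None else feature_params
    if texture_resolution < 256:
        raise ValueError("texture_resolution must be >= 256 px")
    a, b = semi_axes
    circ = 2.0 * np.pi * 0.5 * (a + b)
    for name, p in params.items():
        lo, hi = p["size_mm"]
        hi = circ if hi is None else hi
        if not (0 < lo <= hi <= circ + 1e-9):
            raise ValueError(f"{name}: size range must lie within (0, circumference]")

    rng = np.random.default_rng(seed)
    w = int(texture_resolution)
    h = w // 2
    mm_per_texel = circ / w
    canvas = np.full((h, w), float(background_level))
    if background_noise > 0:
        noise = rng.normal(0.0, 1.0, (h, w))
        noise = ndi.gaussian_filter(noise, background_noise_sigma, mode=("nearest", "wrap"))
        sd = noise.std()
        if sd > 0:
            canvas += background_noise * noise / sd
    area_mm2 = circ * (circ / 2.0)  # equirect canvas extent in physical units

    yy = np.arange(h)
    xx = np.arange(w)

    def draw_blob(cx, cy, radius_px, amp):
        r = max(radius_px, 0.5)
        span = int(np.ceil(3 * r))
        ys = np.arange(int(round(cy)) - span, int(round(cy)) + span + 1)
        xs = np.arange(int(round(cx)) - span, int(round(cx)) + span + 1)
        ys_c = np.clip(ys, 0, h - 1)
        xs_w = np.mod(xs, w)
        dy = (ys - cy)[:, None]
        dx = (xs - cx)[None, :]
        g = amp * np.exp(-(dx**2 + dy**2) / (2 * (r / 1.5) ** 2))
        canvas[np.ix_(ys_c, xs_w)] += g

    if "stain" in params:
        p = params["stain"]
        n = rng.poisson(p["density_per_mm2"] * area_mm2)
        for _ in range(n):
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            size = rng.uniform(*p["size_mm"])
            amp = rng.uniform(-p["contrast"], p["contrast"])
            draw_blob(cx, cy, 0.5 * size / mm_per_texel, amp)

    if "front" in params:
        p = params["front"]
        n = rng.poisson(p["density_per_mm2"] * area_mm2)
        if n:
            cx = rng.uniform(0, w, n)
            cy = rng.uniform(0, h, n)
            length = rng.uniform(p["size_mm"][0], p["size_mm"][1], n) / mm_per_texel
            ang = rng.uniform(0, np.pi, n)
            amp = rng.uniform(-p["contrast"], p["contrast"], n)
            # short fine segments: sample points along each segment
            steps = max(2, int(np.ceil(length.max())) + 1)
            t = np.linspace(-0.5, 0.5, steps)
            px = cx[:, None] + np.cos(ang)[:, None] * length[:, None] * t
            py = cy[:, None] + np.sin(ang)[:, None] * length[:, None] * t
            ix = np.mod(np.round(px).astype(int), w)
            iy = np.clip(np.round(py).astype(int), 0, h - 1)
            np.add.at(canvas, (iy, ix), np.broadcast_to(amp[:, None], ix.shape))

    if "stripe" in params:
        p = params["stripe"]
        lo, hi = p["size_mm"]
        hi = circ if hi is None else hi
        n = rng.poisson(p["density_per_mm2"] * area_mm2)
        width_px = max(1, int(round(p["width_mm"] / mm_per_texel)))
        for _ in range(n):
            length_px = int(round(rng.uniform(lo, hi) / mm_per_texel))
            x0 = int(rng.uniform(0, w))
            y0 = int(rng.uniform(0.15 * h, 0.85 * h))
            amp = rng.uniform(-p["contrast"], p["contrast"])
            xs = np.mod(np.arange(x0, x0 + max(length_px, 1)), w)
            ys = slice(max(0, y0 - width_px // 2), min(h, y0 + (width_px + 1) // 2))
            canvas[ys, xs] += amp

    texture = np.clip(canvas, 0, 255).astype(np.uint8)
    return SphereGroundTruth(
        semi_axes=semi_axes, texture=texture, feature_params=dict(params)
    )


def _disk_kernel(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    k = (x**2 + y**2 <= radius**2).astype(float)
    return k / k.sum()


def _sample_texture(texture: np.ndarray, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Bilinear equirectangular lookup, wrapping in longitude."""
    h, w = texture.shape
    u = np.mod(lon, 2 * np.pi) / (2 * np.pi) * w - 0.5
    v = (lat + np.pi / 2) / np.pi * h - 0.5
    padded = np.concatenate([texture, texture[:, :1]], axis=1).astype(float)
    u = np.mod(u, w)
    v = np.clip(v, 0, h - 1)
    return ndi.map_coordinates(padded, [v, u], order=1, mode="nearest")


def render_view(
    ground_truth: SphereGroundTruth,
    pose: "_geometry.CameraPose",
    optics: Optics,
    focus_depth: float | None = None,
) -> np.ndarray:
    """Pinhole render of the textured sphere with depth-dependent defocus.

    Surface points whose depth differs from ``focus_depth`` (mm from the
    camera center; defaults to the depth of the nearest surface point along
    the boresight) by more than ``dof_half_width`` are blurred with a
    uniform disk of radius ``blur_scale * defocus``.  Background is black.
    """
    a, b = ground_truth.semi_axes
    axes = np.array([a, b, b])
    w, h = optics.sensor_px
    uu, vv = np.meshgrid(np.arange(w), np.arange(h))
    origins, dirs = pose.pixel_rays(np.column_stack([uu.ravel(), vv.ravel()]))

    # ray-ellipsoid intersection in axis-scaled space
    o = origins / axes
    d = dirs / axes
    aa = np.einsum("ij,ij->i", d, d)
    bb = np.einsum("ij,ij->i", o, d)
    cc = np.einsum("ij,ij->i", o, o) - 1.0
    disc = bb * bb - aa * cc
    front = disc >= 0
    t = np.full(len(dirs), np.nan)
    t[front] = (-bb[front] - np.sqrt(disc[front])) / aa[front]
    hit = front & (t > 0)
    if not hit.any():
        raise ValueError("camera pose does not look at the sphere")

    pts = origins[hit] + t[hit, None] * dirs[hit]
    unit = pts / axes
    lon = np.arctan2(unit[:, 1], unit[:, 0])
    lat = np.arcsin(np.clip(unit[:, 2], -1, 1))
    values = _sample_texture(ground_truth.texture, lon, lat)

    img = np.zeros(w * h, dtype=float)
    img[hit] = values
    img = img.reshape(h, w)
    footprint = hit.reshape(h, w)

    if optics.blur_scale > 0:
        if focus_depth is None:
            center = pose.center
            bs = pose.boresight
            t0 = -np.dot(center, bs)  # depth of closest approach to origin
            # nearest surface depth along boresight
            p0, _ = _geometry.intersect_sphere(
                center[None, :], bs[None, :], ground_truth.mean_radius
            )
            focus_depth = float(np.linalg.norm(p0[0] - center)) if t0 > 0 else t0
        depth = np.full(w * h, np.nan)
        depth[hit] = t[hit]
        depth = depth.reshape(h, w)
        defocus = np.abs(depth - focus_depth) - optics.dof_half_width
        defocus = np.where(np.isnan(defocus), 0.0, np.clip(defocus, 0.0, None))
        radius = optics.blur_scale * defocus
        max_r = int(min(np.ceil(radius.max()), 12))
        if max_r >= 1:
            level = np.clip(np.round(radius), 0, max_r).astype(int)
            out = img.copy()
            mask_f = footprint.astype(float)
            for r in range(1, max_r + 1):
                sel = level == r
                if not sel.any():
                    continue
                k = _disk_kernel(r)
                blurred = ndi.convolve(img, k, mode="constant")
                weight = ndi.convolve(mask_f, k, mode="constant")
                with np.errstate(invalid="ignore", divide="ignore"):
                    blurred = np.where(weight > 0, blurred / weight, 0.0)
                out[sel] = blurred[sel]
            img = out * footprint

    if optics.illumination_gradient > 0:
        # uneven lighting along the travel axis (off by default)
        ramp = 1.0 - optics.illumination_gradient * (np.arange(w) / max(w - 1, 1))
        img = img * ramp[None, :]

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def center_crop(image: np.ndarray, fraction: float) -> np.ndarray:
    """Center crop to a fraction of each dimension.

    Real acquisitions are cropped to the well-lit region before processing;
    this helper exposes the same preprocessing for externally captured
    frames.  ``fraction = 1`` returns the image unchanged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    img = np.asarray(image)
    if fraction == 1.0:
        return img
    h, w = img.shape[:2]
    ch, cw = max(1, int(round(h * fraction))), max(1, int(round(w * fraction)))
    top, left = (h - ch) // 2, (w - cw) // 2
    return img[top : top + ch, left : left + cw]


def simulate_ring(
    ground_truth: SphereGroundTruth,
    optics: Optics,
    motion: MotionModel,
    n_frames: int,
    z_plan: tuple[float, ...] = (0.0,),
    seed: int | None = None,
) -> tuple[list[ZStack], list["_geometry.CameraPose"], dict]:
    """Simulate one ring acquisition.

    Frame ``i`` is placed at the cumulative rotation obtained by dividing
    each realized arc (commanded step x efficiency + noise) by the local
    equatorial radius.  Each z-stack is rendered at focus depths
    ``working_distance + z_plan`` (offsets in mm).  Returns the stacks, the
    true camera poses and a manifest with the full ground truth.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    seed = motion.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    wd = optics.resolved_working_distance

    arcs = motion.step_mm * motion.efficiency + rng.normal(
        0.0, motion.arc_noise_sd, n_frames - 1
    )
    arcs = np.clip(arcs, 1e-6, None)
    angles = np.zeros(n_frames)
    for i in range(1, n_frames):
        angles[i] = angles[i - 1] + arcs[i - 1] / float(
            ground_truth.local_radius(angles[i - 1])
        )
    warnings_list = []
    tol = 0.5 * arcs.mean() / ground_truth.mean_radius
    if angles[-1] > 2 * np.pi + tol:
        msg = (
            f"cumulative arc {np.rad2deg(angles[-1]):.1f} deg exceeds a full ring"
        )
        warnings.warn(msg, stacklevel=2)
        warnings_list.append(msg)

    slips = np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, motion.lateral_sd, n_frames - 1))]
    )
    angles_deg = np.rad2deg(angles)

    poses = []
    z_plan = tuple(float(z) for z in z_plan)
    zstacks = []
    for i in range(n_frames):
        local_r = float(ground_truth.local_radius(angles[i]))
        pose_list = _geometry.build_ring_poses(
            [angles_deg[i]], local_r, wd, optics, slips_mm=[slips[i]]
        )
        pose = pose_list[0]
        poses.append(pose)
        frames = [
            render_view(ground_truth, pose, optics, focus_depth=wd + dz)
            for dz in z_plan
        ]
        zstacks.append(
            ZStack(
                frames=frames,
                z_positions=np.array([wd + dz for dz in z_plan]),
                stage_position=float(i * motion.step_mm),
                frame_index=i,
            )
        )

    manifest = {
        "n_frames": n_frames,
        "seed": int(seed),
        "optics": asdict(optics),
        "motion": asdict(motion),
        "semi_axes_mm": list(ground_truth.semi_axes),
        "z_plan_mm": list(z_plan),
        "commanded_positions_mm": [float(i * motion.step_mm) for i in range(n_frames)],
        "true_angles_deg": angles_deg.tolist(),
        "true_slips_mm": slips.tolist(),
        "true_arcs_mm": arcs.tolist(),
        "warnings": warnings_list,
        "fov_mm": list(optics.fov_mm),
    }
    return zstacks, poses, manifest


def overlap_stats(
    true_angles_deg, optics: Optics, radius: float
) -> tuple[float, float]:
    """Mean and sample SD (%) of consecutive-frame overlap.

    Per-pair overlap is ``max(0, 1 - arc_between / FOV_along_travel) * 100``.
    """
    angles = np.asarray(true_angles_deg, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least 2 frames")
    arcs = np.diff(np.deg2rad(angles)) * radius
    fov_w = optics.fov_mm[0]
    overlaps = np.clip(1.0 - arcs / fov_w, 0.0, None) * 100.0
    sd = float(np.std(overlaps, ddof=1)) if overlaps.size > 1 else 0.0
    return float(np.mean(overlaps)), sd


# Study conditions: effective on-object field of view sized so that ~93
# frames at ~68% overlap cover one full ring of an 8.3 mm pearl with
# 256 px frames (the on-object FOV after cropping is a free configuration
# value of the device).
def study_optics(sensor_px: tuple[int, int] = (256, 256)) -> Optics:
    return Optics(
        magnification=1.0,
        pixel_pitch=3.45,
        sensor_px=sensor_px,
        focal_length=5.75,
        working_distance=None,
        dof_half_width=0.01,
        blur_scale=150.0,
    )


def study_motion(seed: int = 0) -> MotionModel:
    return MotionModel(seed=seed)


def _frame_name(ring: int, frame: int, z: int, ext: str) -> str:
    return f"ring{ring}_frame{frame:04d}_z{z:02d}.{ext}"


def save_dataset(
    path,
    zstacks: list[ZStack],
    manifest: dict,
    fmt: str = "png",
    ring_index: int = 0,
) -> Path:
    """Write frames and manifest.json under ``path/frames``."""
    path = Path(path)
    frames_dir = path / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for stack in zstacks:
        for j, frame in enumerate(stack.frames):
            name = _frame_name(ring_index, stack.frame_index, j, fmt)
            if fmt == "tiff":
                tifffile.imwrite(frames_dir / name, frame)
            else:
                Image.fromarray(frame).save(frames_dir / name)
    manifest = dict(manifest)
    manifest["ring_index"] = ring_index
    manifest["format"] = fmt
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def load_dataset(path) -> tuple[list[ZStack], dict]:
    """Load a ring dataset (frames + manifest) saved by :func:`save_dataset`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    fmt = manifest.get("format", "png")
    ring = manifest.get("ring_index", 0)
    n_frames = manifest["n_frames"]
    z_plan = manifest["z_plan_mm"]
    wd_opt = manifest["optics"].get("working_distance")
    if wd_opt is None:
        wd_opt = manifest["optics"]["focal_length"] / manifest["optics"]["magnification"]
    zstacks = []
    for i in range(n_frames):
        frames = []
        for j in range(len(z_plan)):
            fp = path / "frames" / _frame_name(ring, i, j, fmt)
            if fmt == "tiff":
                frames.append(tifffile.imread(fp))
            else:
                frames.append(np.asarray(Image.open(fp)))
        zstacks.append(
            ZStack(
                frames=frames,
                z_positions=np.array([wd_opt + dz for dz in z_plan]),
                stage_position=float(manifest["commanded_positions_mm"][i]),
                frame_index=i,
            )
        )
    return zstacks, manifest
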