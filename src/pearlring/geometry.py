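"""Camera poses on the acquisition ring and sphere-constrained pose refinement.

The acquisition device rolls a near-spherical pearl under a fixed microscope,
which is equivalent to a virtual camera orbiting the sphere on an equatorial
ring.  This module builds that ring of pinhole cameras from cumulative
rotation angles, bootstraps the angles from measured inter-frame pixel shifts
(the reference-sphere routine), refines poses under the constraint that every
matched feature lies on a common sphere, and provides the ring-closure and
ellipse-fit estimators used for validation.

Conventions (fixed throughout the package): the sphere sits at the origin,
the acquisition ring lies in the equatorial plane ``z = 0``, longitude is
measured counterclockwise from ``+x``, each camera's boresight points at the
origin and its up-vector is ``+z`` (image ``y`` runs toward ``-z``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as ScipyRotation
from skimage.measure import EllipseModel

from . import match as _match

__all__ = [
    "CameraPose",
    "RingFit",
    "RefinementResult",
    "RefinementError",
    "build_ring_poses",
    "ring_rotation_matrix",
    "cumulative_angles_from_shifts",
    "bootstrap_reference_poses",
    "render_reference_dataset",
    "refine_poses",
    "ring_closure_radius",
    "fit_ring_ellipse",
    "intersect_sphere",
    "poses_to_frame",
    "poses_to_json",
    "poses_from_json",
]


@dataclass
class CameraPose:
    """Pinhole camera on the acquisition ring.

    Parameters
    ----------
    center : (3,) array
        Camera center in world coordinates, mm.
    rotation : (3, 3) array
        World-to-camera rotation; rows are the camera x, y, z axes
        expressed in world coordinates.
    focal_length : float
        Focal length in mm.
    pixel_pitch : float
        Sensor pixel pitch in µm.
    principal_point : (2,) array
        Principal point (cx, cy) in pixels.
    """

    center: np.ndarray
    rotation: np.ndarray
    focal_length: float
    pixel_pitch: float
    principal_point: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.principal_point = np.asarray(self.principal_point, dtype=float).reshape(2)
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        rrt = self.rotation @ self.rotation.T
        if not np.allclose(rrt, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")

    @property
    def f_px(self) -> float:
        """Focal length expressed in pixels."""
        return self.focal_length / (self.pixel_pitch * 1e-3)

    @property
    def boresight(self) -> np.ndarray:
        """Unit viewing direction (camera z axis) in world coordinates."""
        return self.rotation[2]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project world points (N, 3) to pixel coordinates (N, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = (pts - self.center) @ self.rotation.T
        uv = self.f_px * q[:, :2] / q[:, 2:3] + self.principal_point
        return uv

    def pixel_rays(self, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World-space rays through pixels ``uv`` (N, 2).

        Returns (origins, unit directions), each (N, 3); all origins equal
        the camera center.
        """
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        d_cam = np.column_stack(
            [
                (uv[:, 0] - self.principal_point[0]) / self.f_px,
                (uv[:, 1] - self.principal_point[1]) / self.f_px,
                np.ones(len(uv)),
            ]
        )
        d_world = d_cam @ self.rotation
        d_world /= np.linalg.norm(d_world, axis=1, keepdims=True)
        origins = np.broadcast_to(self.center, d_world.shape)
        return origins, d_world

    def to_dict(self) -> dict:
        quat = ScipyRotation.from_matrix(self.rotation).as_quat()
        return {
            "center_mm": self.center.tolist(),
            "quaternion_xyzw": quat.tolist(),
            "focal_length_mm": self.focal_length,
            "pixel_pitch_um": self.pixel_pitch,
            "principal_point_px": self.principal_point.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraPose":
        rot = ScipyRotation.from_quat(d["quaternion_xyzw"]).as_matrix()
        return cls(
            center=np.array(d["center_mm"]),
            rotation=rot,
            focal_length=d["focal_length_mm"],
            pixel_pitch=d["pixel_pitch_um"],
            principal_point=np.array(d["principal_point_px"]),
        )


@dataclass
class RingFit:
    """Ellipse fitted to the reconstructed ring (vertical view)."""

    d_min: float
    d_max: float
    ellipticity: float
    center: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if not (self.d_max >= self.d_min > 0):
            raise ValueError("require d_max >= d_min > 0")
        if not (0.0 <= self.ellipticity < 1.0):
            raise ValueError("ellipticity must lie in [0, 1)")


def ring_rotation_matrix(theta_rad: float) -> np.ndarray:
    """World-to-camera rotation for a ring camera at longitude ``theta``.

    Camera x axis is the direction of travel (tangential), camera y axis is
    ``-z`` (image rows grow downward while up is ``+z``), camera z axis is
    the boresight pointing radially inward.
    """
    ct, st = np.cos(theta_rad), np.sin(theta_rad)
    x_cam = np.array([-st, ct, 0.0])
    y_cam = np.array([0.0, 0.0, -1.0])
    z_cam = np.array([-ct, -st, 0.0])
    return np.vstack([x_cam, y_cam, z_cam])


def build_ring_poses(
    cumulative_angles_deg: Sequence[float],
    radius_mm: float,
    working_distance_mm: float,
    optics,
    slips_mm: Sequence[float] | None = None,
) -> list[CameraPose]:
    """Place one camera per cumulative angle on the equatorial ring.

    Camera ``i`` sits at distance ``radius + working_distance`` from the
    origin at longitude ``cumulative_angles_deg[i]``, boresight toward the
    origin, up-vector ``+z``.  Optional per-frame lateral offsets
    ``slips_mm`` displace the camera along ``+z`` (the sliding phenomenon of
    the physical device).
    """
    if radius_mm <= 0 or working_distance_mm <= 0:
        raise ValueError("radius and working distance must be positive")
    angles = np.asarray(cumulative_angles_deg, dtype=float)
    slips = np.zeros(len(angles)) if slips_mm is None else np.asarray(slips_mm, float)
    ring_r = radius_mm + working_distance_mm
    cx, cy = (np.asarray(optics.sensor_px, float) - 1.0) / 2.0
    poses = []
    for theta_deg, slip in zip(angles, slips):
        theta = np.deg2rad(theta_deg)
        center = np.array([ring_r * np.cos(theta), ring_r * np.sin(theta), slip])
        poses.append(
            CameraPose(
                center=center,
                rotation=ring_rotation_matrix(theta),
                focal_length=optics.focal_length,
                pixel_pitch=optics.pixel_pitch,
                principal_point=np.array([cx, cy]),
            )
        )
    return poses


def intersect_sphere(
    origins: np.ndarray, dirs: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect rays with the origin-centered sphere of given radius.

    Returns (points, hit_mask).  Rays that miss the sphere are assigned the
    point of closest approach radially projected onto the sphere, so the
    result is always usable as a sphere-constrained estimate; ``hit_mask``
    records which rays genuinely intersected.
    """
    o = np.atleast_2d(origins).astype(float)
    d = np.atleast_2d(dirs).astype(float)
    b = np.einsum("ij,ij->i", o, d)
    c = np.einsum("ij,ij->i", o, o) - radius**2
    disc = b * b - c
    hit = disc >= 0.0
    t = np.where(hit, -b - np.sqrt(np.clip(disc, 0.0, None)), -b)
    pts = o + t[:, None] * d
    miss = ~hit
    if np.any(miss):
        norm = np.linalg.norm(pts[miss], axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        pts[miss] = pts[miss] / norm * radius
    return pts, hit


def cumulative_angles_from_shifts(
    shift_estimates: Sequence,
    optics,
    radius_mm: float | None = None,
    closure_shift=None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Convert consecutive-pair shift estimates into cumulative ring angles.

    Each shift's ``dx`` (pixels along the travel direction) is converted to
    an on-object arc with :func:`pearlring.match.pixel_shift_to_arc`; the
    feature flow is opposite to the travel direction, hence the sign flip.
    If ``radius_mm`` is None the radius is estimated by ring closure from
    the sum of all arcs (including the closing pair when supplied).

    Returns ``(angles_deg, radius_mm, slips_mm)`` where ``slips_mm`` is the
    cumulative lateral offset implied by the vertical shift components.
    """
    missing = [i for i, s in enumerate(shift_estimates) if s is None]
    if missing:
        raise ValueError(
            "missing shift estimate for consecutive pair(s) "
            + ", ".join(f"({i}, {i + 1})" for i in missing)
            + "; supply pinned correspondences for these pairs"
        )
    arcs = np.array(
        [-_match.pixel_shift_to_arc(s.dx, optics) for s in shift_estimates]
    )
    slips_step = np.array(
        [_match.pixel_shift_to_arc(s.dy, optics) for s in shift_estimates]
    )
    if radius_mm is None:
        total = arcs.sum()
        if closure_shift is not None:
            total += -_match.pixel_shift_to_arc(closure_shift.dx, optics)
        radius_mm = ring_closure_radius([total])
    angles = np.concatenate([[0.0], np.cumsum(arcs)]) / radius_mm
    slips = np.concatenate([[0.0], np.cumsum(slips_step)])
    return np.rad2deg(angles), float(radius_mm), slips


def bootstrap_reference_poses(
    shift_estimates: Sequence,
    optics,
    radius_guess: float | None = None,
    closure_shift=None,
    use_slips: bool = True,
) -> list[CameraPose]:
    """Bootstrap ring camera poses from consecutive-frame shift estimates.

    This is the closed-form equivalent of the reference-sphere routine:
    every measured pixel shift is converted to an on-object arc and then to
    a rotation angle on a sphere of ``radius_guess`` (estimated by ring
    closure when omitted), and a full ring of pinhole cameras is built at
    the accumulated longitudes.  The rendered reference-sphere round trip is
    available separately via :func:`render_reference_dataset`.
    """
    angles, radius, slips = cumulative_angles_from_shifts(
        shift_estimates, optics, radius_mm=radius_guess, closure_shift=closure_shift
    )
    return build_ring_poses(
        angles,
        radius,
        optics.resolved_working_distance,
        optics,
        slips_mm=slips if use_slips else None,
    )


def render_reference_dataset(poses: Sequence[CameraPose], ground_truth, optics):
    """Render a reference-sphere image at each bootstrapped pose.

    Cross-validation path: the rendered dataset can be re-matched and
    re-bootstrapped to confirm that the closed-form pose construction agrees
    with the render-then-align loop.
    """
    from . import simulate as _simulate  # local import; simulate depends on geometry

    return [_simulate.render_view(ground_truth, p, optics) for p in poses]


class RefinementError(RuntimeError):
    """Raised when sphere-constrained refinement diverges.

    Carries a ``diagnostics`` dict with the residual history.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class RefinementResult:
    poses: list[CameraPose]
    angles_deg: np.ndarray
    slips_mm: np.ndarray
    radius_mm: float
    focal_length_mm: float
    rms_residual_px: float
    rms_history: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


@dataclass
class SpherePrior:
    """Prior geometry for refinement: sphere radius and camera standoff."""

    radius_mm: float
    working_distance_mm: float


def _ring_residuals(
    angles_rad: np.ndarray,
    slips: np.ndarray,
    radius: float,
    focal: float,
    pairs: Sequence[tuple[int, int, np.ndarray, np.ndarray]],
    optics,
) -> np.ndarray:
    """Stacked reprojection residuals (px) for all matched pairs.

    A feature observed at ``pts_i`` in frame ``i`` is back-projected onto
    the sphere and reprojected into frame ``j``; the residual is the
    difference from its observed position ``pts_j``.
    """
    wd = optics.resolved_working_distance
    f_px = focal / (optics.pixel_pitch * 1e-3)
    cx, cy = (np.asarray(optics.sensor_px, float) - 1.0) / 2.0
    ring_r = radius + wd
    res = []
    for a, b, pa, pb in pairs:
        ca, sa = np.cos(angles_rad[a]), np.sin(angles_rad[a])
        center_a = np.array([ring_r * ca, ring_r * sa, slips[a]])
        cb, sb = np.cos(angles_rad[b]), np.sin(angles_rad[b])
        center_b = np.array([ring_r * cb, ring_r * sb, slips[b]])
        rot_a = ring_rotation_matrix(angles_rad[a])
        rot_b = ring_rotation_matrix(angles_rad[b])
        d_cam = np.column_stack(
            [
                (pa[:, 0] - cx) / f_px,
                (pa[:, 1] - cy) / f_px,
                np.ones(len(pa)),
            ]
        )
        d_world = d_cam @ rot_a
        d_world /= np.linalg.norm(d_world, axis=1, keepdims=True)
        pts3d, _ = intersect_sphere(
            np.broadcast_to(center_a, d_world.shape), d_world, radius
        )
        q = (pts3d - center_b) @ rot_b.T
        uv = f_px * q[:, :2] / q[:, 2:3] + np.array([cx, cy])
        res.append((uv - pb).ravel())
    return np.concatenate(res) if res else np.zeros(0)


def refine_poses(
    match_pairs: Sequence[tuple[int, int, np.ndarray, np.ndarray]],
    init_poses: Sequence[CameraPose],
    sphere_prior: SpherePrior,
    optics,
    *,
    optimize_radius: bool = True,
    optimize_focal: bool = False,
    max_iterations: int = 100,
    tol_px: float = 1e-3,
    max_points_per_pair: int = 40,
) -> RefinementResult:
    """Sphere-constrained refinement of ring camera poses.

    Free parameters are the per-frame longitudes (frame 0 fixed as gauge),
    per-frame lateral offsets (slip; frame 0 fixed), and optionally the
    global sphere radius and global focal length.  Matched feature points
    are constrained to lie on the sphere; the objective is the RMS
    reprojection error in pixels, minimized by damped Gauss-Newton
    (Levenberg-Marquardt) with forward-difference Jacobians.  The recorded
    RMS sequence is monotone non-increasing because steps that do not reduce
    the objective are rejected.

    ``match_pairs`` is a sequence of ``(i, j, pts_i, pts_j)`` tuples of
    inlier correspondences in pixel coordinates.
    """
    if len(init_poses) < 2:
        raise ValueError("refinement needs at least two frames")
    n = len(init_poses)
    angles = np.array(
        [np.arctan2(p.center[1], p.center[0]) for p in init_poses], dtype=float
    )
    angles = np.unwrap(angles)
    slips = np.array([p.center[2] for p in init_poses], dtype=float)
    radius = float(sphere_prior.radius_mm)
    focal = float(init_poses[0].focal_length)

    pairs = []
    for i, j, pa, pb in match_pairs:
        pa = np.atleast_2d(np.asarray(pa, float))
        pb = np.atleast_2d(np.asarray(pb, float))
        if len(pa) > max_points_per_pair:
            idx = np.linspace(0, len(pa) - 1, max_points_per_pair).astype(int)
            pa, pb = pa[idx], pb[idx]
        pairs.append((int(i), int(j), pa, pb))

    def pack():
        p = [angles[1:], slips[1:]]
        if optimize_radius:
            p.append([radius])
        if optimize_focal:
            p.append([focal])
        return np.concatenate(p)

    def unpack(p):
        ang = np.concatenate([[angles[0]], p[: n - 1]])
        slp = np.concatenate([[slips[0]], p[n - 1 : 2 * (n - 1) + 1]])
        k = 2 * (n - 1)
        r = p[k] if optimize_radius else radius
        k += int(optimize_radius)
        f = p[k] if optimize_focal else focal
        return ang, slp, float(r), float(f)

    def residuals(p):
        ang, slp, r, f = unpack(p)
        return _ring_residuals(ang, slp, r, f, pairs, optics)

    p = pack()
    r0 = residuals(p)
    rms = float(np.sqrt(np.mean(r0**2))) if r0.size else 0.0
    history = [rms]

    if max_iterations == 0 or r0.size == 0:
        return RefinementResult(
            poses=list(init_poses),
            angles_deg=np.rad2deg(angles),
            slips_mm=slips,
            radius_mm=radius,
            focal_length_mm=focal,
            rms_residual_px=rms,
            rms_history=history,
            n_iterations=0,
            converged=False,
        )

    lam = 1e-3
    steps = np.full(p.shape, 1e-6)
    if optimize_radius:
        steps[2 * (n - 1)] = 1e-5
    if optimize_focal:
        steps[-1] = 1e-5
    r = r0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iterations + 1):
        # forward-difference Jacobian
        jac = np.empty((r.size, p.size))
        for k in range(p.size):
            pk = p.copy()
            pk[k] += steps[k]
            jac[:, k] = (residuals(pk) - r) / steps[k]
        jtj = jac.T @ jac
        jtr = jac.T @ r
        accepted = False
        for _ in range(8):
            try:
                delta = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj) + 1e-12), -jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            p_new = p + delta
            r_new = residuals(p_new)
            rms_new = float(np.sqrt(np.mean(r_new**2)))
            if rms_new < history[-1]:
                p, r = p_new, r_new
                history.append(rms_new)
                lam = max(lam / 10.0, 1e-9)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True
            break
        if len(history) >= 2 and history[-2] - history[-1] < tol_px:
            converged = True
            break

    if history[-1] > history[0] + 1e-12:
        raise RefinementError(
            "refinement diverged: final residual exceeds initial",
            diagnostics={"rms_history": history, "n_iterations": n_iter},
        )

    ang, slp, radius, focal = unpack(p)
    refined_optics = replace(optics, focal_length=focal)
    poses = build_ring_poses(
        np.rad2deg(ang),
        radius,
        optics.resolved_working_distance,
        refined_optics,
        slips_mm=slp,
    )
    return RefinementResult(
        poses=poses,
        angles_deg=np.rad2deg(ang),
        slips_mm=slp,
        radius_mm=radius,
        focal_length_mm=focal,
        rms_residual_px=history[-1],
        rms_history=history,
        n_iterations=n_iter,
        converged=converged,
    )


def ring_closure_radius(arcs_mm: Sequence[float]) -> float:
    """Sphere radius from the ring-closure constraint.

    The arcs of one full acquisition ring sum to the circumference, so the
    radius is ``sum(arcs) / (2 pi)``.
    """
    arcs = np.asarray(arcs_mm, dtype=float)
    if arcs.size == 0:
        raise ValueError("need at least one arc")
    return float(arcs.sum() / (2.0 * np.pi))


def fit_ring_ellipse(points_2d: np.ndarray) -> RingFit:
    """Least-squares ellipse fit to 2D ring points (vertical view).

    Returns minor/major axis *diameters* and the ellipticity
    ``(d_max - d_min) / d_max``.
    """
    pts = np.atleast_2d(np.asarray(points_2d, dtype=float))
    if len(pts) < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            model = EllipseModel.from_estimate(pts)
            ok = bool(model)
        except AttributeError:  # older scikit-image
            model = EllipseModel()
            ok = model.estimate(pts)
    if not ok:
        raise ValueError("ellipse fit failed on degenerate configuration")
    xc, yc = model.center
    a, b = model.axis_lengths if hasattr(model, "axis_lengths") else model.params[2:4]
    if not np.all(np.isfinite([xc, yc, a, b])):
        raise ValueError("ellipse fit failed on degenerate configuration")
    semi = sorted([abs(a), abs(b)])
    d_min, d_max = 2.0 * semi[0], 2.0 * semi[1]
    residual = float(np.sqrt(np.mean(model.residuals(pts) ** 2)))
    return RingFit(
        d_min=d_min,
        d_max=d_max,
        ellipticity=(d_max - d_min) / d_max,
        center=np.array([xc, yc]),
        residual=residual,
    )


def poses_to_frame(poses: Sequence[CameraPose]) -> pd.DataFrame:
    """Tabulate poses (the analogue of a camera-import CSV)."""
    rows = []
    for i, p in enumerate(poses):
        quat = ScipyRotation.from_matrix(p.rotation).as_quat()
        rows.append(
            {
                "frame_index": i,
                "x_mm": p.center[0],
                "y_mm": p.center[1],
                "z_mm": p.center[2],
                "qx": quat[0],
                "qy": quat[1],
                "qz": quat[2],
                "qw": quat[3],
                "focal_mm": p.focal_length,
            }
        )
    return pd.DataFrame(rows)


def poses_to_json(poses: Sequence[CameraPose], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in poses], fh, indent=1)


def poses_from_json(path) -> list[CameraPose]:
    with open(path) as fh:
        return [CameraPose.from_dict(d) for d in json.load(fh)]
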