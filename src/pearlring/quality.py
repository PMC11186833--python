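"""Ring-alignment quality metric and focal-length calibration.

Focus stacking alters the effective perspective of the composites, so the
focal length used in reconstruction must be re-calibrated.  Alignment
quality is scored with an empirical error combining three equally weighted
criteria measured on orthographic views of the reconstructed ring:

    E_tot = eps/lambda1 + E_vertical/lambda2 + E_horizontal/lambda3

where ``eps`` is the ellipticity of the ring in the vertical (top-down)
view, and ``E_vertical`` / ``E_horizontal`` are the start-to-end gap of the
ring in the vertical and horizontal views (px).  The lambdas normalize each
criterion to [0, 1] over a calibration grid, so absolute E_tot values are
comparable only within one calibration run.  The calibrated focal length is
the grid argmin of E_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.morphology import skeletonize

from . import geometry as _geometry

__all__ = [
    "QualityReport",
    "orthographic_view",
    "ring_gap",
    "e_tot",
    "ring_terms_from_poses",
    "calibrate_focal_length",
]


@dataclass(frozen=True)
class QualityReport:
    """The alignment-error terms for one trial."""

    epsilon: float
    e_vertical: float
    e_horizontal: float
    lambda1: float
    lambda2: float
    lambda3: float
    e_tot: float
    focal_mm: float | None = None

    def __post_init__(self) -> None:
        if min(self.epsilon, self.e_vertical, self.e_horizontal) < 0:
            raise ValueError("raw terms must be >= 0")


def orthographic_view(
    points_3d: np.ndarray,
    axis: str = "z",
    resolution_px: int = 256,
    splat_radius: float = 1.5,
    extent: float | None = None,
    return_transform: bool = False,
):
    """Rasterize a point set viewed orthographically along one world axis.

    ``axis='z'`` is the vertical (top-down) view, keeping (x, y);
    ``axis='y'`` is the horizontal view, keeping (x, z).  Points are
    splatted as ~3 px disks so a sparse ring forms a connected mask for
    contour analysis.  Returns the binary mask, plus ``(scale_px_per_mm,
    origin_mm)`` when ``return_transform`` is set.
    """
    pts = np.atleast_2d(np.asarray(points_3d, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    if axis == "z":
        p2 = pts[:, :2]
    elif axis == "y":
        p2 = pts[:, [0, 2]]
    elif axis == "x":
        p2 = pts[:, 1:]
    else:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    lo = p2.min(axis=0)
    hi = p2.max(axis=0)
    span = float(max(np.max(hi - lo), 1e-9)) if extent is None else float(extent)
    margin = 0.08 * span
    scale = (resolution_px - 1) / (span + 2 * margin)
    origin = (lo + hi) / 2 - (span / 2 + margin)
    ij = np.round((p2 - origin) * scale).astype(int)
    ij = np.clip(ij, 0, resolution_px - 1)
    mask = np.zeros((resolution_px, resolution_px), dtype=bool)
    r = int(np.floor(splat_radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = np.argwhere(xx**2 + yy**2 <= splat_radius**2) - r
    for du, dv in disk:
        u = np.clip(ij[:, 0] + du, 0, resolution_px - 1)
        v = np.clip(ij[:, 1] + dv, 0, resolution_px - 1)
        mask[v, u] = True
    if return_transform:
        return mask, (scale, origin)
    return mask


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def ring_gap(view_mask: np.ndarray) -> float:
    """Start-to-end gap (px) of the ring traced by a binary mask.

    The mask is skeletonized and contour endpoints (skeleton pixels with a
    single neighbor) are extracted; the gap is the Euclidean distance
    between the two endpoints of the largest open contour, and 0 when the
    largest contour is closed (no endpoints).  Skeleton endpoints sit at
    the tip of the stroke's rounded cap, about one stroke-halfwidth past
    the true curve endpoint, so each endpoint is refined by walking to the
    mask tip along the local skeleton direction and pulling back by the
    stroke halfwidth (median distance-transform value on the skeleton).
    """
    from scipy import ndimage as ndi

    mask = np.asarray(view_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(mask)
    labels, n = ndi.label(skel, structure=np.ones((3, 3)))
    if n == 0:
        return 0.0
    sizes = ndi.sum(skel, labels, index=np.arange(1, n + 1))
    main = labels == (1 + int(np.argmax(sizes)))
    neighbors = ndi.convolve(main.astype(int), _NEIGHBOR_KERNEL, mode="constant")
    endpoints = np.argwhere(main & (neighbors == 1))
    if len(endpoints) < 2:
        return 0.0
    if len(endpoints) > 2:
        # spurs can add endpoints; take the pair furthest apart
        d = np.linalg.norm(endpoints[:, None] - endpoints[None, :], axis=2)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        endpoints = endpoints[[i, j]]
    dt = ndi.distance_transform_edt(mask)
    halfwidth = float(np.median(dt[main])) if main.sum() > 4 else 1.0
    h, w = mask.shape
    refined = []
    for e in endpoints:
        y0, y1 = max(0, e[0] - 6), min(h, e[0] + 7)
        x0, x1 = max(0, e[1] - 6), min(w, e[1] + 7)
        near = np.argwhere(main[y0:y1, x0:x1]) + [y0, x0]
        near = near[np.linalg.norm(near - e, axis=1) > 0.5]
        if len(near) == 0:
            refined.append(e.astype(float))
            continue
        inward = near.mean(axis=0) - e
        inward /= np.linalg.norm(inward)
        tip = e.astype(float)
        for s in np.arange(0.25, 4 * halfwidth, 0.25):
            p = np.rint(e - inward * s).astype(int)
            if 0 <= p[0] < h and 0 <= p[1] < w and mask[tuple(p)]:
                tip = e - inward * s
            else:
                break
        refined.append(tip + inward * halfwidth)
    return float(np.linalg.norm(refined[0] - refined[1]))


def e_tot(
    epsilon: float,
    e_vertical: float,
    e_horizontal: float,
    lambdas: tuple[float, float, float],
    focal_mm: float | None = None,
) -> QualityReport:
    """Total alignment error with equal weighting via the normalizers."""
    l1, l2, l3 = lambdas
    if min(l1, l2, l3) <= 0:
        raise ValueError("normalization factors must be positive")
    total = epsilon / l1 + e_vertical / l2 + e_horizontal / l3
    return QualityReport(
        epsilon=epsilon,
        e_vertical=e_vertical,
        e_horizontal=e_horizontal,
        lambda1=l1,
        lambda2=l2,
        lambda3=l3,
        e_tot=float(total),
        focal_mm=focal_mm,
    )


def ring_terms_from_poses(
    poses, resolution_px: int = 512
) -> tuple[float, float, float]:
    """Raw (epsilon, e_vertical, e_horizontal) for a ring of camera poses.

    Epsilon is the ellipticity of the ellipse fitted to the camera centers
    in the vertical view.  The gaps are the start-to-end distance of the
    ordered camera ring in each rasterized orthographic view, in px; for an
    open ring this coincides with the open-contour endpoint distance of
    :func:`ring_gap`, and it remains informative when a wrong focal guess
    makes the cumulative rotation overshoot a full turn and the rasterized
    contour closes on itself.
    """
    centers = np.array([p.center for p in poses], dtype=float)
    if len(centers) < 5:
        raise ValueError("need at least 5 poses")
    try:
        fit = _geometry.fit_ring_ellipse(centers[:, :2])
        epsilon = fit.ellipticity
    except ValueError:
        epsilon = 1.0  # degenerate, worst-case ellipticity
    gaps = []
    for axis in ("z", "y"):
        _, (scale, _origin) = orthographic_view(
            centers, axis=axis, resolution_px=resolution_px, return_transform=True
        )
        p2 = centers[:, :2] if axis == "z" else centers[:, [0, 2]]
        gaps.append(float(np.linalg.norm(p2[-1] - p2[0]) * scale))
    return float(epsilon), gaps[0], gaps[1]


# Normalization floors: terms at or below the measurement resolution of the
# rasterized views (one pixel for the gaps, 0.01 ellipticity) carry no
# signal and must not be amplified by the per-term-max normalization.
LAMBDA_FLOORS = (0.01, 1.0, 1.0)


def calibrate_focal_length(
    shift_estimates,
    optics,
    focal_grid,
    radius_mm: float,
    closure_shift=None,
    match_pairs=None,
    refine_iterations: int = 0,
    resolution_px: int = 512,
) -> tuple[float, pd.DataFrame]:
    """Grid search of the focal length minimizing the alignment error.

    For each grid focal length the ring is re-bootstrapped from the same
    measured shifts with that focal held fixed (the assumed on-object scale
    follows the pinhole relation through the fixed working distance), poses
    are optionally refined (radius and focal held fixed), and the raw error
    terms are measured on the resulting camera ring.  When the ring-closure
    shift (last frame back to first) is supplied, the ring is walked all the
    way around: a correct focal length brings the walk-around endpoint back
    onto the start regardless of motion noise, while a wrong one leaves a
    gap proportional to the scale error.  Lambdas are set to the per-term
    maximum across the grid (floored at the view's measurement resolution)
    so each criterion is equally weighted in [0, 1].  Returns the argmin
    focal and the full per-grid table.
    """
    focal_grid = [float(f) for f in focal_grid]
    if len(focal_grid) == 0:
        raise ValueError("focal grid must be nonempty")
    wd = optics.resolved_working_distance
    shifts_ext = list(shift_estimates)
    if closure_shift is not None:
        shifts_ext.append(closure_shift)
    rows = []
    for f in focal_grid:
        trial_optics = replace(
            optics, focal_length=f, magnification=f / wd, working_distance=wd
        )
        try:
            poses = _geometry.bootstrap_reference_poses(
                shifts_ext, trial_optics, radius_guess=radius_mm
            )
            if match_pairs is not None and refine_iterations > 0:
                result = _geometry.refine_poses(
                    match_pairs,
                    poses[: len(shift_estimates) + 1],
                    _geometry.SpherePrior(radius_mm, wd),
                    trial_optics,
                    optimize_radius=False,
                    optimize_focal=False,
                    max_iterations=refine_iterations,
                )
                poses = result.poses
            eps, ev, eh = ring_terms_from_poses(poses, resolution_px=resolution_px)
            rows.append(
                {"focal_mm": f, "epsilon": eps, "e_vertical": ev, "e_horizontal": eh,
                 "failed": False}
            )
        except (ValueError, _geometry.RefinementError):
            rows.append(
                {"focal_mm": f, "epsilon": np.nan, "e_vertical": np.nan,
                 "e_horizontal": np.nan, "failed": True}
            )
    table = pd.DataFrame(rows)
    # failed grid points get worst-case terms
    for col in ("epsilon", "e_vertical", "e_horizontal"):
        finite = table[col].dropna()
        worst_val = float(finite.max()) if len(finite) else 1.0
        table[col] = table[col].fillna(max(worst_val, 1.0))
    lambdas = []
    for col, floor in zip(("epsilon", "e_vertical", "e_horizontal"), LAMBDA_FLOORS):
        lambdas.append(max(float(table[col].max()), floor))
    table["e_tot"] = (
        table["epsilon"] / lambdas[0]
        + table["e_vertical"] / lambdas[1]
        + table["e_horizontal"] / lambdas[2]
    )
    best = float(table.loc[table["e_tot"].idxmin(), "focal_mm"])
    return best, table
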