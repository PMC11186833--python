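"""End-to-end ring reconstruction: focus -> match -> bootstrap -> refine ->
texture -> validate.

This module ties the stage modules into the single automated workflow the
tool exposes; the CLI wraps these functions and the test-suite drives them
directly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import focus as _focus
from . import geometry as _geometry
from . import match as _match
from . import metrics as _metrics
from . import quality as _quality
from . import simulate as _simulate
from . import surface as _surface

__all__ = [
    "InsufficientMatchesError",
    "ReconstructionResult",
    "stack_all",
    "match_ring",
    "reconstruct_ring",
    "calibrate_ring",
]


class InsufficientMatchesError(RuntimeError):
    """A frame pair produced too few matches and no pins were supplied."""

    def __init__(self, pair: tuple[int, int]):
        super().__init__(
            f"insufficient matches for frame pair {pair}; supply pinned "
            "correspondences for this pair"
        )
        self.pair = pair


@dataclass
class ReconstructionResult:
    composites: list[np.ndarray]
    shift_records: list[dict]
    shift_estimates: list[_match.ShiftEstimate]
    closure_shift: _match.ShiftEstimate | None
    match_pairs: list[tuple]
    bootstrap_angles_deg: np.ndarray
    refinement: _geometry.RefinementResult
    ring_fit: _geometry.RingFit
    ring_model: _surface.RingModel | None
    coverage: float
    report: _metrics.ValidationReport | None
    overlap_mean: float | None = None
    overlap_sd: float | None = None
    timings_s: dict = field(default_factory=dict)

    @property
    def poses(self) -> list[_geometry.CameraPose]:
        return self.refinement.poses

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.refinement.radius_mm

    @property
    def angles_deg(self) -> np.ndarray:
        return self.refinement.angles_deg


def stack_all(zstacks, window: int = 9, smooth_sigma: float = 4.0):
    """Focus-stack every z-stack into its composite."""
    return [
        _focus.focus_stack(z, window=window, smooth_sigma=smooth_sigma)
        for z in zstacks
    ]


def match_ring(
    composites: Sequence[np.ndarray],
    ratio: float = 0.75,
    inlier_tol_px: float = 2.0,
    upsampling: int = 1,
    pins: dict | None = None,
    include_closure: bool = True,
):
    """Match consecutive composites (plus the ring-closure pair).

    Returns (shift_estimates, closure_shift, match_pairs, records) where
    ``match_pairs`` holds the inlier correspondences used by refinement.
    Pairs flagged insufficient fall back to pinned correspondences from
    ``pins`` (a mapping (i, j) -> (pts_i, pts_j)); with no pins available
    an :class:`InsufficientMatchesError` is raised naming the pair.
    """
    pins = pins or {}
    n = len(composites)
    feats = [
        _match.detect_keypoints(np.asarray(c), upsampling=upsampling)
        for c in composites
    ]
    pair_ids = [(i, i + 1) for i in range(n - 1)]
    if include_closure and n > 2:
        pair_ids.append((n - 1, 0))
    estimates: dict[tuple[int, int], _match.ShiftEstimate] = {}
    match_pairs = []
    records = []
    for i, j in pair_ids:
        mset = _match.match_from_keypoints(*feats[i], *feats[j], ratio=ratio)
        if mset.insufficient:
            if (i, j) in pins:
                pts_i, pts_j = pins[(i, j)]
                pts_i = np.atleast_2d(np.asarray(pts_i, float))
                pts_j = np.atleast_2d(np.asarray(pts_j, float))
                pairs = np.column_stack([np.arange(len(pts_i))] * 2)
                mset = _match.MatchSet(pts_i, pts_j, pairs, ratio=ratio)
            else:
                raise InsufficientMatchesError((i, j))
        est = _match.estimate_shift(mset, inlier_tol_px=inlier_tol_px)
        estimates[(i, j)] = est
        d = mset.displacements
        inlier = (
            np.sum((d - [est.dx, est.dy]) ** 2, axis=1) <= inlier_tol_px**2
        )
        pts_i = mset.keypoints_a[mset.pairs[inlier, 0]]
        pts_j = mset.keypoints_b[mset.pairs[inlier, 1]]
        match_pairs.append((i, j, pts_i, pts_j))
        records.append(
            {
                "frame_i": i,
                "frame_j": j,
                "dx": est.dx,
                "dy": est.dy,
                "n_valid": est.n_valid,
                "n_invalid": est.n_invalid,
            }
        )
    consecutive = [estimates[(i, i + 1)] for i in range(n - 1)]
    closure = estimates.get((n - 1, 0))
    return consecutive, closure, match_pairs, records


def reconstruct_ring(
    zstacks,
    optics: _simulate.Optics,
    measured_diameters: tuple[float, float] | None = None,
    true_angles_deg=None,
    *,
    ratio: float = 0.75,
    inlier_tol_px: float = 2.0,
    upsampling: int = 1,
    stack_window: int = 9,
    stack_sigma: float = 4.0,
    refine_max_iterations: int = 30,
    refine_tol_px: float = 1e-3,
    optimize_radius: bool = True,
    optimize_focal: bool = False,
    max_points_per_pair: int = 40,
    pins: dict | None = None,
    build_model: bool = True,
    mesh_subdivisions: int = 4,
    texture_canvas_width: int = 1024,
    ring_name: str = "ring1",
) -> ReconstructionResult:
    """Run the full reconstruction pipeline on one ring of z-stacks."""
    timings = {}
    t0 = time.perf_counter()
    composites = stack_all(zstacks, window=stack_window, smooth_sigma=stack_sigma)
    timings["focus_stack"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    shifts, closure, match_pairs, records = match_ring(
        composites,
        ratio=ratio,
        inlier_tol_px=inlier_tol_px,
        upsampling=upsampling,
        pins=pins,
    )
    timings["match"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    angles, radius, slips = _geometry.cumulative_angles_from_shifts(
        shifts, optics, radius_mm=None, closure_shift=closure
    )
    wd = optics.resolved_working_distance
    init_poses = _geometry.build_ring_poses(angles, radius, wd, optics, slips_mm=slips)
    refinement = _geometry.refine_poses(
        match_pairs,
        init_poses,
        _geometry.SpherePrior(radius, wd),
        optics,
        optimize_radius=optimize_radius,
        optimize_focal=optimize_focal,
        max_iterations=refine_max_iterations,
        tol_px=refine_tol_px,
        max_points_per_pair=max_points_per_pair,
    )
    timings["refine"] = time.perf_counter() - t0

    centers = np.array([p.center for p in refinement.poses])
    cam_fit = _geometry.fit_ring_ellipse(centers[:, :2])
    ring_fit = _geometry.RingFit(
        d_min=max(cam_fit.d_min - 2 * wd, 1e-9),
        d_max=max(cam_fit.d_max - 2 * wd, 1e-9),
        ellipticity=0.0,
        center=cam_fit.center,
        residual=cam_fit.residual,
    )
    ring_fit.ellipticity = (ring_fit.d_max - ring_fit.d_min) / ring_fit.d_max

    ring_model = None
    coverage = 0.0
    if build_model:
        t0 = time.perf_counter()
        mesh = _surface.build_sphere_mesh(
            refinement.radius_mm, n_subdivisions=mesh_subdivisions
        )
        ring_model = _surface.texture_mesh(
            mesh, composites, refinement.poses, canvas_width=texture_canvas_width
        )
        coverage = _surface.surface_coverage(ring_model)
        timings["texture"] = time.perf_counter() - t0

    report = None
    if measured_diameters is not None:
        report = _metrics.build_validation_report(
            {ring_name: measured_diameters}, {ring_name: ring_fit}, coverage
        )

    overlap_mean = overlap_sd = None
    if true_angles_deg is not None:
        overlap_mean, overlap_sd = _simulate.overlap_stats(
            true_angles_deg, optics, radius=refinement.radius_mm
        )

    return ReconstructionResult(
        composites=composites,
        shift_records=records,
        shift_estimates=shifts,
        closure_shift=closure,
        match_pairs=match_pairs,
        bootstrap_angles_deg=angles,
        refinement=refinement,
        ring_fit=ring_fit,
        ring_model=ring_model,
        coverage=coverage,
        report=report,
        overlap_mean=overlap_mean,
        overlap_sd=overlap_sd,
        timings_s=timings,
    )


def calibrate_ring(
    zstacks,
    optics: _simulate.Optics,
    focal_grid,
    radius_guess_mm: float,
    *,
    upsampling: int = 1,
    refine_iterations: int = 0,
    pins: dict | None = None,
):
    """Focal-length calibration on one ring dataset.

    Composites and shifts are computed once (the measured pixel shifts do
    not depend on the assumed focal length); the grid search re-runs the
    pose bootstrap per trial focal.
    """
    composites = stack_all(zstacks)
    shifts, closure, match_pairs, _records = match_ring(
        composites, upsampling=upsampling, pins=pins
    )
    return _quality.calibrate_focal_length(
        shifts,
        optics,
        focal_grid,
        radius_guess_mm,
        closure_shift=closure,
        match_pairs=match_pairs if refine_iterations > 0 else None,
        refine_iterations=refine_iterations,
    )
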