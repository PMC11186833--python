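"""Pairwise SIFT matching and robust translation estimation.

Consecutive composites on the acquisition ring differ, to first order, by a
pure image translation: the sphere rotates by a few degrees per step, which
at the tangent point is a lateral shift of the surface texture.  Scale
invariant keypoints are detected on both frames, matched with Lowe's ratio
test, and the displacement is estimated by a translation-only consensus
(the rotational/parallax residue is handled later by pose refinement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors

__all__ = [
    "MatchSet",
    "ShiftEstimate",
    "detect_keypoints",
    "detect_and_match",
    "match_from_keypoints",
    "estimate_shift",
    "pixel_shift_to_arc",
    "arc_to_angle",
    "matches_to_frame",
]

MIN_PAIRS = 4  # fewer surviving pairs flags the constraint-injection path


def _as_gray_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img)
    return img.astype(float)


@dataclass
class MatchSet:
    """Keypoints on two images plus ratio-test surviving index pairs.

    Keypoint coordinates are subpixel ``(x, y)`` image coordinates.
    """

    keypoints_a: np.ndarray
    keypoints_b: np.ndarray
    pairs: np.ndarray
    ratio: float = 0.75

    def __post_init__(self) -> None:
        self.keypoints_a = np.asarray(self.keypoints_a, float).reshape(-1, 2)
        self.keypoints_b = np.asarray(self.keypoints_b, float).reshape(-1, 2)
        self.pairs = np.asarray(self.pairs, int).reshape(-1, 2)
        if len(self.pairs):
            if self.pairs[:, 0].max() >= len(self.keypoints_a) or self.pairs[
                :, 1
            ].max() >= len(self.keypoints_b):
                raise ValueError("pair indices out of keypoint range")
            if len(np.unique(self.pairs, axis=0)) != len(self.pairs):
                raise ValueError("duplicate pairs")

    @property
    def insufficient(self) -> bool:
        """True when too few pairs survive to estimate a shift reliably.

        Signals the pinned-correspondence path (the open equivalent of
        adding manual markers when overlap drops too low).
        """
        return len(self.pairs) < MIN_PAIRS

    @property
    def displacements(self) -> np.ndarray:
        """Per-pair displacement vectors b - a, (M, 2) in px."""
        return (
            self.keypoints_b[self.pairs[:, 1]] - self.keypoints_a[self.pairs[:, 0]]
        )


@dataclass
class ShiftEstimate:
    """Robust translation between a frame pair.

    ``dx, dy`` are the median inlier displacement in px; ``n_valid`` and
    ``n_invalid`` partition the ratio-test pairs by consensus membership.
    """

    dx: float
    dy: float
    n_valid: int
    n_invalid: int
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.n_valid < 0 or self.n_invalid < 0:
            raise ValueError("counts must be non-negative")


def detect_keypoints(image: np.ndarray, upsampling: int = 1):
    """Detect SIFT keypoints and descriptors; returns (xy, descriptors).

    ``upsampling=1`` skips the initial 2x upscale octave, trading a denser
    keypoint set for speed; the ring pipeline has texture to spare.
    Featureless images yield empty arrays rather than an error.
    """
    img = _as_gray_float(image)
    if img.size == 0:
        raise ValueError("empty image")
    sift = SIFT(upsampling=upsampling)
    try:
        sift.detect_and_extract(img)
    except RuntimeError:
        return np.zeros((0, 2)), np.zeros((0, 128), dtype=np.uint8)
    xy = sift.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return xy, sift.descriptors


def match_from_keypoints(
    kp_a: np.ndarray,
    desc_a: np.ndarray,
    kp_b: np.ndarray,
    desc_b: np.ndarray,
    ratio: float = 0.75,
) -> MatchSet:
    """Ratio-test matching of precomputed descriptors."""
    if len(kp_a) == 0 or len(kp_b) == 0:
        return MatchSet(kp_a, kp_b, np.zeros((0, 2), int), ratio=ratio)
    pairs = match_descriptors(
        desc_a, desc_b, max_ratio=ratio, cross_check=True
    )
    return MatchSet(kp_a, kp_b, pairs, ratio=ratio)


def detect_and_match(
    image_a: np.ndarray,
    image_b: np.ndarray,
    ratio: float = 0.75,
    upsampling: int = 1,
) -> MatchSet:
    """SIFT keypoints on both images, matched with Lowe's ratio test.

    Nearest-neighbor pairs are kept iff best/second-best descriptor distance
    is below ``ratio`` (with cross-checking).  The returned set's
    ``insufficient`` flag is True when fewer than four pairs survive.
    """
    kp_a, desc_a = detect_keypoints(image_a, upsampling=upsampling)
    kp_b, desc_b = detect_keypoints(image_b, upsampling=upsampling)
    return match_from_keypoints(kp_a, desc_a, kp_b, desc_b, ratio=ratio)


def estimate_shift(match_set: MatchSet, inlier_tol_px: float = 2.0) -> ShiftEstimate:
    """Consensus translation between a frame pair.

    The consensus displacement is the pair displacement with the largest
    number of other displacements within ``inlier_tol_px`` (an exhaustive
    translation-only RANSAC); pairs within tolerance of the consensus are
    valid, the rest invalid, and the reported ``(dx, dy)`` is the median of
    the valid displacements.
    """
    d = match_set.displacements
    if len(d) == 0:
        raise ValueError("no pairs to estimate a shift from")
    # exhaustive consensus: each displacement votes as candidate
    diff = d[:, None, :] - d[None, :, :]
    within = np.einsum("ijk,ijk->ij", diff, diff) <= inlier_tol_px**2
    counts = within.sum(axis=1)
    best = int(np.argmax(counts))
    inliers = within[best]
    if not inliers.any():
        raise ValueError("zero inliers")
    dx, dy = np.median(d[inliers], axis=0)
    resid = d[inliers] - np.array([dx, dy])
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return ShiftEstimate(
        dx=float(dx),
        dy=float(dy),
        n_valid=int(inliers.sum()),
        n_invalid=int(len(d) - inliers.sum()),
        rms_residual=rms,
    )


def pixel_shift_to_arc(shift_px: float, optics) -> float:
    """Convert an image-plane shift (px) to an on-object arc (mm).

    arc = shift_px * pixel_pitch / magnification, with the µm pixel pitch
    converted to mm.
    """
    return float(shift_px) * optics.pixel_pitch * 1e-3 / optics.magnification


def arc_to_angle(arc_mm: float, radius_mm: float) -> float:
    """Rotation angle (degrees) subtended by an arc on a sphere.

    Uses the spherical assumption of the rolling pearl: angle = arc/radius.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    return float(np.rad2deg(arc_mm / radius_mm))


def matches_to_frame(records: list[dict]) -> pd.DataFrame:
    """Diagnostics table (frame_i, frame_j, dx, dy, n_valid, n_invalid)."""
    return pd.DataFrame(
        records,
        columns=["frame_i", "frame_j", "dx", "dy", "n_valid", "n_invalid"],
    )
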