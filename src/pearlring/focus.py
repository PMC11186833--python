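"""Focus measurement, autofocus selection and focus stacking.

The shallow depth of field of a 50x objective leaves most of a curved
pearl surface out of focus in any single frame; each stage position is
therefore acquired as a z-stack and fused into one extended-depth-of-field
composite before matching.  Sharpness is scored with the squared-gradient
(GRAS) focus measure, the metric selected for these images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray

__all__ = [
    "FocusScore",
    "focus_measure_gras",
    "autofocus_select",
    "focus_stack",
    "FOCUS_METRICS",
]


@dataclass(frozen=True)
class FocusScore:
    """Non-negative sharpness score from one focus metric."""

    value: float
    metric_name: str = "GRAS"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("focus score must be >= 0")


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img) * 255.0
    return img.astype(float)


def focus_measure_gras(image: np.ndarray, threshold: float = 0.0) -> FocusScore:
    """Squared-gradient (GRAS) focus measure.

    ``value = sum(d**2)`` over horizontal differences
    ``d = I(x+1, y) - I(x, y)``, keeping only terms with ``|d| > threshold``
    (gray levels).  Invariant to adding a constant to all pixels and to
    cyclic translation along y; strictly larger on sharp images than on
    their defocused copies.
    """
    img = _as_gray(image)
    if img.ndim != 2 or img.shape[1] < 2:
        raise ValueError("image must be 2D and at least 2 px wide")
    d = np.diff(img, axis=1)
    keep = np.abs(d) > threshold
    return FocusScore(
        value=float(np.sum(d[keep] ** 2)), metric_name="GRAS", threshold=threshold
    )


FOCUS_METRICS: dict[str, Callable[..., FocusScore]] = {"GRAS": focus_measure_gras}


def autofocus_select(zstack, metric: str | Callable = "GRAS") -> int:
    """Index of the sharpest frame in a z-stack (ties -> lowest index)."""
    frames = zstack.frames if hasattr(zstack, "frames") else list(zstack)
    if len(frames) == 0:
        raise ValueError("empty z-stack")
    fn = FOCUS_METRICS[metric] if isinstance(metric, str) else metric
    scores = np.array([fn(f).value for f in frames])
    return int(np.argmax(scores))


def _local_sharpness(image: np.ndarray, window: int) -> np.ndarray:
    """Windowed squared-gradient sharpness map (same shape as the image)."""
    img = _as_gray(image)
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    gx[:, :-1] = np.diff(img, axis=1)
    gy[:-1, :] = np.diff(img, axis=0)
    return ndi.uniform_filter(gx**2 + gy**2, size=window, mode="nearest")


def focus_stack(
    zstack,
    window: int = 9,
    smooth_sigma: float = 4.0,
    return_decision: bool = False,
):
    """Fuse a z-stack into one extended-depth-of-field composite.

    Per pixel, the source frame is the one with the largest local
    squared-gradient sharpness in a ``window`` px neighborhood; the
    per-frame sharpness maps are Gaussian-smoothed (``smooth_sigma``)
    before the argmax so seams fall along a smooth decision map.  A stack
    of identical frames (or a single frame) is returned unchanged.
    """
    frames = zstack.frames if hasattr(zstack, "frames") else list(zstack)
    if len(frames) == 0:
        raise ValueError("empty z-stack")
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("all frames must share one shape")
    frames = [np.asarray(f) for f in frames]
    if len(frames) == 1:
        decision = np.zeros(frames[0].shape[:2], dtype=int)
        return (frames[0].copy(), decision) if return_decision else frames[0].copy()

    sharp = np.stack(
        [
            ndi.gaussian_filter(_local_sharpness(f, window), smooth_sigma)
            for f in frames
        ]
    )
    decision = np.argmax(sharp, axis=0)
    stack_arr = np.stack(frames)
    if stack_arr.ndim == 4:  # RGB
        composite = np.take_along_axis(
            stack_arr, decision[None, :, :, None], axis=0
        )[0]
    else:
        composite = np.take_along_axis(stack_arr, decision[None, :, :], axis=0)[0]
    return (composite, decision) if return_decision else composite
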