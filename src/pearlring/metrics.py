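"""Validation arithmetic: diameter accuracies and ellipticity reporting.

Reconstructed ring diameters are compared against caliper measurements of
the physical sphere.  Accuracy is reported as a percentage truncated (not
rounded) at one decimal place, which is the reporting rule that reproduces
the published style of table; ellipticity is reported to three decimals.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "RingValidation",
    "ValidationReport",
    "accuracy_percent",
    "ellipticity_from_diameters",
    "build_validation_report",
]


def accuracy_percent(measured_mm: float, reconstructed_mm: float) -> float:
    """Reconstruction accuracy: ``100 * (1 - |rec - meas| / meas)``.

    Truncated toward zero at one decimal place and clamped to [0, 100].
    """
    if measured_mm <= 0:
        raise ValueError("measured value must be positive")
    acc = 100.0 * (1.0 - abs(reconstructed_mm - measured_mm) / measured_mm)
    acc = max(acc, 0.0)
    return math.floor(acc * 10.0 + 1e-9) / 10.0


def ellipticity_from_diameters(d_max_mm: float, d_min_mm: float) -> float:
    """Ellipticity ``(d_max - d_min) / d_max``, reported to 3 decimals."""
    if not (d_max_mm >= d_min_mm > 0):
        raise ValueError("require d_max >= d_min > 0")
    return round((d_max_mm - d_min_mm) / d_max_mm, 3)


@dataclass
class RingValidation:
    """Per-ring comparison of measured vs reconstructed diameters."""

    ring: str
    measured_d_min: float
    measured_d_max: float
    reconstructed_d_min: float
    reconstructed_d_max: float
    accuracy_min: float = field(init=False)
    accuracy_max: float = field(init=False)
    measured_ellipticity: float = field(init=False)
    reconstructed_ellipticity: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy_min = accuracy_percent(
            self.measured_d_min, self.reconstructed_d_min
        )
        self.accuracy_max = accuracy_percent(
            self.measured_d_max, self.reconstructed_d_max
        )
        self.measured_ellipticity = ellipticity_from_diameters(
            self.measured_d_max, self.measured_d_min
        )
        self.reconstructed_ellipticity = ellipticity_from_diameters(
            max(self.reconstructed_d_min, self.reconstructed_d_max),
            min(self.reconstructed_d_min, self.reconstructed_d_max),
        )


@dataclass
class ValidationReport:
    """Validation table for one or more rings plus surface coverage."""

    rings: list[RingValidation]
    coverage_fraction: float = 0.0
    ellipse_ellipticity: float | None = None  # direct fit on the model ring

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rings])

    def to_json(self, path=None) -> str:
        payload = {
            "rings": [asdict(r) for r in self.rings],
            "coverage_fraction": self.coverage_fraction,
            "ellipse_ellipticity": self.ellipse_ellipticity,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ValidationReport":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        rings = [
            RingValidation(
                ring=r["ring"],
                measured_d_min=r["measured_d_min"],
                measured_d_max=r["measured_d_max"],
                reconstructed_d_min=r["reconstructed_d_min"],
                reconstructed_d_max=r["reconstructed_d_max"],
            )
            for r in payload["rings"]
        ]
        return cls(
            rings=rings,
            coverage_fraction=payload["coverage_fraction"],
            ellipse_ellipticity=payload.get("ellipse_ellipticity"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_validation_report(
    measured: dict[str, tuple[float, float]],
    ring_fits: dict[str, "object"],
    coverage: float,
) -> ValidationReport:
    """Assemble the validation table from measured diameters and ring fits.

    ``measured`` maps ring name to (d_min, d_max) in mm; ``ring_fits`` maps
    ring name to a :class:`pearlring.geometry.RingFit` (or any object with
    ``d_min``/``d_max``/``ellipticity``).
    """
    rings = []
    ellipse_eps = None
    for name, (m_min, m_max) in measured.items():
        fit = ring_fits[name]
        rings.append(
            RingValidation(
                ring=name,
                measured_d_min=m_min,
                measured_d_max=m_max,
                reconstructed_d_min=fit.d_min,
                reconstructed_d_max=fit.d_max,
            )
        )
        ellipse_eps = float(fit.ellipticity)
    return ValidationReport(
        rings=rings, coverage_fraction=float(coverage), ellipse_ellipticity=ellipse_eps
    )
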