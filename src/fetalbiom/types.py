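"""Core domain types for whole-scan fetal biometry.

Fetal biometrics at the 20-week anomaly scan are measured in standard
anatomical planes: head circumference (HC) and biparietal diameter (BPD)
in the transventricular brain view, transcerebellar diameter (TCD) in the
transcerebellar view, abdominal circumference (AC) in the abdominal view,
and femur length (FL) in the femur view.  This module defines those
biometrics, the per-frame record consumed by the pipeline, the
gestational-age centile reference that powers priors and plausibility
windows, and the final per-scan report.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "GeometryKind",
    "BiometricSpec",
    "BIOMETRICS",
    "FrameRecord",
    "CentileReference",
    "CentileError",
    "load_centile_reference",
    "default_centile_reference",
    "ScanReport",
    "BiometricEstimate",
]


class GeometryKind(str, Enum):
    """How a biometric is extracted from a landmark heatmap."""

    LINEAR = "linear"                      # distance between two caliper points
    ELLIPTICAL = "elliptical"              # perimeter of a fitted ellipse
    DERIVED_MINOR_AXIS = "derived_minor_axis"  # minor axis of the head ellipse


@dataclass(frozen=True)
class BiometricSpec:
    """One fetal biometric: its code, extraction geometry and source plane."""

    code: str
    geometry_kind: GeometryKind
    source_plane: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("biometric code must be non-empty")


#: The five mandated 20-week biometrics.  HC and AC are elliptical; FL and
#: TCD are linear two-point distances; BPD is the minor axis of the head
#: ellipse and therefore shares the Brain-TV plane with HC.
BIOMETRICS: Mapping[str, BiometricSpec] = {
    "HC": BiometricSpec("HC", GeometryKind.ELLIPTICAL, "Brain-TV"),
    "BPD": BiometricSpec("BPD", GeometryKind.DERIVED_MINOR_AXIS, "Brain-TV"),
    "TCD": BiometricSpec("TCD", GeometryKind.LINEAR, "Brain-CB"),
    "AC": BiometricSpec("AC", GeometryKind.ELLIPTICAL, "Abdominal"),
    "FL": BiometricSpec("FL", GeometryKind.LINEAR, "Femur"),
}

#: Plane label → biometrics measured in that plane.
PLANE_BIOMETRICS: Mapping[str, tuple[str, ...]] = {
    "Brain-TV": ("HC", "BPD"),
    "Brain-CB": ("TCD",),
    "Abdominal": ("AC",),
    "Femur": ("FL",),
}


@dataclass
class FrameRecord:
    """One frame's classification and (optional) raw measurement.

    ``measurement_px`` is absent when extraction failed; ``pixel_size_mm``
    (mm per pixel, L_x) is absent when scale-bar calibration failed.
    """

    frame_index: int
    plane_label: str
    confidence: float
    ga_weeks: float
    measurement_px: Optional[float] = None
    pixel_size_mm: Optional[float] = None
    biometric: Optional[str] = None
    heatmap_path: Optional[str] = None
    image_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} not in [0, 1]")
        if self.pixel_size_mm is not None and self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive when present")
        if self.measurement_px is not None and self.measurement_px < 0:
            raise ValueError("measurement_px must be non-negative")

    @property
    def measurement_mm(self) -> Optional[float]:
        """Calibrated measurement, or None when either factor is missing."""
        if self.measurement_px is None or self.pixel_size_mm is None:
            return None
        return self.measurement_px * self.pixel_size_mm


class CentileError(ValueError):
    """Raised when a centile table violates its invariants."""


class CentileReference:
    """Per-biometric gestational-age centile lookup (p3/p50/p97, mm).

    Queries linearly interpolate between tabulated gestational ages and
    clamp to the nearest endpoint outside the tabulated range.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"biometric", "ga_weeks", "p3", "p50", "p97"}
        missing = required - set(table.columns)
        if missing:
            raise CentileError(f"centile table missing columns: {sorted(missing)}")
        table = table.sort_values(["biometric", "ga_weeks"]).reset_index(drop=True)
        for _, row in table.iterrows():
            if not (row.p3 < row.p50 < row.p97):
                raise CentileError(
                    f"non-monotone centiles for {row.biometric} at "
                    f"GA {row.ga_weeks}w: p3={row.p3}, p50={row.p50}, p97={row.p97}"
                )
        counts = table.groupby("biometric").size()
        thin = counts[counts < 2]
        if len(thin):
            raise CentileError(
                f"need at least 2 GA rows per biometric; short: {list(thin.index)}"
            )
        self._table = table
        self._by_biometric = {
            code: grp.sort_values("ga_weeks") for code, grp in table.groupby("biometric")
        }

    @property
    def biometrics(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_biometric))

    def _interp(self, biometric: str, ga_weeks: float, column: str) -> float:
        try:
            grp = self._by_biometric[biometric]
        except KeyError:
            raise CentileError(f"unknown biometric {biometric!r}") from None
        # np.interp clamps outside the tabulated GA range by construction
        return float(np.interp(ga_weeks, grp["ga_weeks"].values, grp[column].values))

    def p3(self, biometric: str, ga_weeks: float) -> float:
        return self._interp(biometric, ga_weeks, "p3")

    def p50(self, biometric: str, ga_weeks: float) -> float:
        return self._interp(biometric, ga_weeks, "p50")

    def p97(self, biometric: str, ga_weeks: float) -> float:
        return self._interp(biometric, ga_weeks, "p97")

    def centiles(self, biometric: str, ga_weeks: float) -> tuple[float, float, float]:
        return (
            self.p3(biometric, ga_weeks),
            self.p50(biometric, ga_weeks),
            self.p97(biometric, ga_weeks),
        )

    def to_csv(self, path: Union[str, Path, io.IOBase]) -> None:
        self._table.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()


def load_centile_reference(path: Union[str, Path, io.IOBase]) -> CentileReference:
    """Load a centile reference from a CSV table.

    Expected columns: ``biometric, ga_weeks, p3, p50, p97`` with one row
    per (biometric, gestational age).
    """
    return CentileReference(pd.read_csv(path))


# Plausible 20-week medians (mm) and weekly growth rates for the synthetic
# default chart.  SYNTHETIC, NON-CLINICAL: smooth quadratic-in-GA curves
# anchored at values in the range textbooks quote for 20 weeks; they exist
# so the pipeline and tests run without a licensed growth chart.
_SYNTHETIC_ANCHORS = {
    # code: (p50 at 20w, linear growth mm/week, quadratic term, half-width frac)
    "HC": (175.0, 11.0, 0.10, 0.065),
    "BPD": (48.0, 3.0, 0.03, 0.070),
    "AC": (150.0, 11.5, 0.12, 0.080),
    "FL": (33.0, 2.6, 0.02, 0.090),
    "TCD": (20.0, 1.3, 0.02, 0.090),
}


def default_centile_reference(
    ga_min: float = 14.0, ga_max: float = 28.0, step: float = 1.0
) -> CentileReference:
    """Synthetic default centile chart (non-clinical).

    Median curves are quadratic in gestational age; the 3rd/97th centiles
    sit at a fixed fraction below/above the median, so p3 < p50 < p97 holds
    everywhere and every curve is increasing in GA.
    """
    rows = []
    gas = np.arange(ga_min, ga_max + 1e-9, step)
    for code, (m20, slope, quad, halfwidth) in _SYNTHETIC_ANCHORS.items():
        d = gas - 20.0
        p50 = m20 + slope * d + quad * d**2
        p3 = p50 * (1.0 - 2.0 * halfwidth)
        p97 = p50 * (1.0 + 2.0 * halfwidth)
        for ga, lo, mid, hi in zip(gas, p3, p50, p97):
            rows.append(
                {"biometric": code, "ga_weeks": float(ga), "p3": float(lo),
                 "p50": float(mid), "p97": float(hi)}
            )
    return CentileReference(pd.DataFrame(rows))


@dataclass
class BiometricEstimate:
    """Final state of one biometric's estimator, plus bookkeeping counts."""

    biometric: str
    final_estimate_mm: float
    standard_error_mm: float
    ci95_low_mm: float
    ci95_high_mm: float
    final_P_t: float
    n_frames_seen: int = 0
    n_frames_measured: int = 0
    n_rejected_confidence: int = 0
    n_rejected_frozen: int = 0
    n_rejected_plausibility: int = 0
    n_rejected_degenerate: int = 0


@dataclass
class ScanReport:
    """Aggregate result of processing one whole scan."""

    estimates: dict[str, BiometricEstimate] = field(default_factory=dict)
    ga_weeks: float = float("nan")
    n_frames_total: int = 0
    config_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "ga_weeks": self.ga_weeks,
            "n_frames_total": self.n_frames_total,
            "config": self.config_summary,
            "biometrics": {
                code: vars(est).copy() for code, est in self.estimates.items()
            },
        }
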