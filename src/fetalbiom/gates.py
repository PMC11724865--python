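"""Pre-estimator frame and measurement filters.

Four gates run before a measurement reaches the Bayesian estimator, in a
fixed order so that the attributed rejection reason is deterministic when
several would fire:

1. confidence gate — the frame must be classified as a biometric-bearing
   standard plane with confidence strictly above the threshold (>95%);
2. frozen-frame gate — paused frames (sonographer annotating) are detected
   by near-total pixel identity with the previous frame and dropped;
3. degenerate-geometry gate — heatmaps from which no two endpoints or no
   ellipse could be extracted contribute nothing;
4. plausibility gate — a measurement below the 3rd centile at GA−3 weeks
   or above the 97th centile at GA+3 weeks is anatomically implausible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np

from .types import BiometricSpec, CentileReference, FrameRecord, PLANE_BIOMETRICS

__all__ = [
    "GateReason",
    "GateDecision",
    "confidence_gate",
    "frozen_frame",
    "plausibility_gate",
    "degenerate_geometry_gate",
]


class GateReason(str, Enum):
    OK = "ok"
    LOW_CONFIDENCE = "low_confidence"
    FROZEN_FRAME = "frozen_frame"
    IMPLAUSIBLE_LOW = "implausible_low"
    IMPLAUSIBLE_HIGH = "implausible_high"
    DEGENERATE_GEOMETRY = "degenerate_geometry"


@dataclass(frozen=True)
class GateDecision:
    accepted: bool
    reason: GateReason

    def __post_init__(self) -> None:
        if self.accepted != (self.reason is GateReason.OK):
            raise ValueError("accepted iff reason == ok")


_ACCEPT = GateDecision(True, GateReason.OK)


def confidence_gate(record: FrameRecord, threshold: float = 0.95) -> GateDecision:
    """Accept only biometric-bearing planes classified strictly above threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if record.plane_label not in PLANE_BIOMETRICS:
        return GateDecision(False, GateReason.LOW_CONFIDENCE)
    if record.confidence > threshold:
        return _ACCEPT
    return GateDecision(False, GateReason.LOW_CONFIDENCE)


def frozen_frame(
    prev: np.ndarray,
    curr: np.ndarray,
    frac_threshold: float = 0.95,
    pixel_tolerance: float = 0.0,
) -> bool:
    """True when over ``frac_threshold`` of pixels did not change.

    ``pixel_tolerance`` is the absolute intensity difference still counted
    as "unchanged"; 0 (exact equality) suits clean 8-bit synthetic frames,
    a small positive value absorbs compression noise in real captures.
    """
    prev = np.asarray(prev)
    curr = np.asarray(curr)
    if prev.shape != curr.shape:
        raise ValueError(f"shape mismatch: {prev.shape} vs {curr.shape}")
    diff = np.abs(curr.astype(np.float64) - prev.astype(np.float64))
    frac_unchanged = np.count_nonzero(diff <= pixel_tolerance) / diff.size
    return bool(frac_unchanged > frac_threshold)


def plausibility_gate(
    x_mm: float,
    biometric: Union[BiometricSpec, str],
    ga_weeks: float,
    ref: CentileReference,
    window_weeks: float = 3.0,
) -> GateDecision:
    """Reject anatomically implausible measurements.

    The window is [p3 at GA−3w, p97 at GA+3w]; boundary values are
    accepted ("lower than" / "higher than" read as strict).
    """
    code = biometric.code if isinstance(biometric, BiometricSpec) else biometric
    lo = ref.p3(code, ga_weeks - window_weeks)
    hi = ref.p97(code, ga_weeks + window_weeks)
    if x_mm < lo:
        return GateDecision(False, GateReason.IMPLAUSIBLE_LOW)
    if x_mm > hi:
        return GateDecision(False, GateReason.IMPLAUSIBLE_HIGH)
    return _ACCEPT


def degenerate_geometry_gate(extraction_result: Optional[object]) -> GateDecision:
    """Reject frames whose heatmap yielded no usable geometry.

    ``extraction_result`` is whatever the geometry stage returned: None (or
    anything flagged ``failed``) means fewer than two distinct peaks were
    found or the ellipse fit failed, and the frame is discarded.
    """
    if extraction_result is None or getattr(extraction_result, "failed", False):
        return GateDecision(False, GateReason.DEGENERATE_GEOMETRY)
    return _ACCEPT
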