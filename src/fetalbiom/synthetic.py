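"""Synthetic generators for every input the pipeline consumes.

Real 20-week scan recordings are confidential, so each stage is exercised
against generated inputs with known ground truth instead:

- measurement streams drawn from the Gaussian + uniform contamination
  mixture (valid frames scatter around the true biometric, contaminated
  frames land anywhere in the plausibility window), interleaved with
  background frames and sub-threshold classifier confidences;
- scale-bar strips with major ticks at a known pixel pitch (and shorter
  minor ticks at one-fifth and one-tenth of it, as on real machines),
  optional sensor noise and bright anatomical clutter;
- landmark heatmaps rendered from known endpoints or ellipse parameters by
  Gaussian convolution, as the measurement networks are trained to emit.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .types import BIOMETRICS, FrameRecord

__all__ = [
    "StreamScenario",
    "simulate_measurement_stream",
    "stream_to_jsonl",
    "render_scalebar_frame",
    "render_linear_heatmap",
    "render_ellipse_heatmap",
]


@dataclass(frozen=True)
class StreamScenario:
    """One simulated scan segment for a single biometric.

    Defaults mirror a realistic 20-week femur acquisition: ~30 frames per
    second, true FL near the mid-trimester median, measurement noise of a
    couple of millimetres, and ~80% of frames yielding valid measurements.
    """

    biometric: str = "FL"
    true_value_mm: float = 34.0
    sigma_mm: float = 1.8
    P_t: float = 0.8
    n_frames: int = 600
    ga_weeks: float = 20.0
    seed: int = 0
    frame_rate_hz: float = 30.0
    a_mm: Optional[float] = None          # uniform nuisance bounds; default
    b_mm: Optional[float] = None          # +/- 40% around the true value
    background_fraction: float = 0.0      # extra non-biometric frames
    low_confidence_fraction: float = 0.0  # biometric frames failing the gate
    confidence_threshold: float = 0.95
    pixel_size_mm: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.P_t <= 1.0:
            raise ValueError("P_t must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.biometric not in BIOMETRICS:
            raise ValueError(f"unknown biometric {self.biometric!r}")

    @property
    def bounds(self) -> tuple[float, float]:
        a = self.a_mm if self.a_mm is not None else 0.6 * self.true_value_mm
        b = self.b_mm if self.b_mm is not None else 1.4 * self.true_value_mm
        return a, b


def simulate_measurement_stream(
    scenario: StreamScenario,
) -> tuple[list[FrameRecord], dict]:
    """Draw a per-frame measurement stream from the contamination mixture.

    Each biometric frame's measurement is N(true_value, sigma^2) with
    probability P_t, else U(a, b).  Confidences are drawn above the gate
    threshold except for a configurable fraction forced below it;
    background frames are interleaved uniformly at random.  Returns the
    frame records plus a ground-truth dict (per-frame component labels and
    realized counts) for exact bookkeeping checks downstream.
    """
    rng = np.random.default_rng(scenario.seed)
    a, b = scenario.bounds
    plane = BIOMETRICS[scenario.biometric].source_plane

    n_bio = scenario.n_frames
    n_bg = int(round(scenario.background_fraction * n_bio))
    n_total = n_bio + n_bg
    is_background = np.zeros(n_total, dtype=bool)
    if n_bg:
        is_background[rng.choice(n_total, size=n_bg, replace=False)] = True

    records: list[FrameRecord] = []
    labels: list[str] = []
    for idx in range(n_total):
        if is_background[idx]:
            records.append(
                FrameRecord(
                    frame_index=idx,
                    plane_label="Background",
                    confidence=float(rng.uniform(0.5, 1.0)),
                    ga_weeks=scenario.ga_weeks,
                )
            )
            labels.append("background")
            continue
        inlier = rng.random() < scenario.P_t
        if inlier:
            x = rng.normal(scenario.true_value_mm, scenario.sigma_mm)
        else:
            x = rng.uniform(a, b)
        low_conf = rng.random() < scenario.low_confidence_fraction
        if low_conf:
            conf = float(rng.uniform(0.5, scenario.confidence_threshold))
        else:
            conf = float(rng.uniform(scenario.confidence_threshold + 1e-6, 1.0))
        records.append(
            FrameRecord(
                frame_index=idx,
                plane_label=plane,
                confidence=conf,
                ga_weeks=scenario.ga_weeks,
                measurement_px=float(x) / scenario.pixel_size_mm,
                pixel_size_mm=scenario.pixel_size_mm,
                biometric=scenario.biometric,
            )
        )
        labels.append(
            ("inlier" if inlier else "outlier") + ("_lowconf" if low_conf else "")
        )
    truth = {
        "scenario": asdict(scenario),
        "bounds": [a, b],
        "labels": labels,
        "n_background": int(n_bg),
        "n_inlier": labels.count("inlier"),
        "n_outlier": labels.count("outlier"),
        "n_low_confidence": sum(1 for l in labels if l.endswith("_lowconf")),
    }
    return records, truth


def stream_to_jsonl(records: Sequence[FrameRecord], path: Union[str, Path]) -> None:
    """Write frame records as JSON-Lines, one object per frame."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "frame": r.frame_index,
                        "plane": r.plane_label,
                        "confidence": r.confidence,
                        "ga_weeks": r.ga_weeks,
                        "measurement_px": r.measurement_px,
                        "pixel_size_mm": r.pixel_size_mm,
                        "biometric": r.biometric,
                        "heatmap": r.heatmap_path,
                        "image": r.image_path,
                    }
                )
                + "\n"
            )


def render_scalebar_frame(
    pitch_px: int,
    d_bar_mm: float = 50.0,
    shape: tuple[int, int] = (576, 120),
    bar_col: int = 20,
    noise_sd: float = 0.0,
    n_clutter: int = 0,
    minor_ticks: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a vertical scale-bar strip with known tick pitch.

    Major ticks (physical spacing ``d_bar_mm``) are bright and long;
    optional minor ticks at one-fifth and one-tenth of the pitch are dimmer
    and shorter, as on real machine overlays — so a scan line offset from
    the bar axis crosses only the major ticks.  Optional additive Gaussian
    noise and bright clutter blobs emulate anatomy bleeding into the bar.

    Returns (uint8 image, ground truth) where the ground truth carries the
    pitch, the mm-per-pixel value, and the scan-line column that crosses
    only major ticks.
    """
    if pitch_px < 5:
        raise ValueError("pitch_px must be >= 5")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    img = np.zeros(shape, dtype=float)
    img += 12.0  # dim background

    major_len, minor10_len, minor5_len = 9, 5, 3
    for r in range(0, n_rows, pitch_px):
        img[r, bar_col : bar_col + major_len] = 255.0
    if minor_ticks and pitch_px >= 10:
        step10 = max(pitch_px // 5, 1)   # 10 mm ticks
        step5 = max(pitch_px // 10, 1)   # 5 mm ticks
        for r in range(0, n_rows, step5):
            if r % pitch_px == 0:
                continue
            length = minor10_len if r % step10 == 0 else minor5_len
            img[r, bar_col : bar_col + length] = 140.0

    for _ in range(n_clutter):
        cr = int(rng.integers(0, n_rows))
        cc = int(rng.integers(bar_col + major_len + 5, n_cols))
        rr, cc_grid = np.mgrid[0:n_rows, 0:n_cols]
        blob = 200.0 * np.exp(-(((rr - cr) ** 2 + (cc_grid - cc) ** 2) / (2 * 8.0**2)))
        img += blob

    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)

    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = {
        "pitch_px": pitch_px,
        "d_bar_mm": d_bar_mm,
        "L_x": d_bar_mm / pitch_px,
        "scanline_col": bar_col + major_len - 2,  # crosses major ticks only
        "orientation": "vertical",
    }
    return img, truth


def render_linear_heatmap(
    endpoint_a: tuple[float, float],
    endpoint_b: tuple[float, float],
    shape: tuple[int, int] = (288, 384),
    blob_sigma_px: float = 4.0,
) -> tuple[np.ndarray, dict]:
    """Heatmap with Gaussian blobs at two caliper endpoints."""
    for pt in (endpoint_a, endpoint_b):
        if not (0 <= pt[0] < shape[0] and 0 <= pt[1] < shape[1]):
            raise ValueError(f"endpoint {pt} outside image of shape {shape}")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    h = np.zeros(shape, dtype=float)
    for r0, c0 in (endpoint_a, endpoint_b):
        if blob_sigma_px > 0:
            h += np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * blob_sigma_px**2)))
        else:
            h[int(round(r0)), int(round(c0))] += 1.0
    truth = {
        "endpoints": [list(endpoint_a), list(endpoint_b)],
        "length_px": math.hypot(
            endpoint_a[0] - endpoint_b[0], endpoint_a[1] - endpoint_b[1]
        ),
        "blob_sigma_px": blob_sigma_px,
    }
    return h, truth


def render_ellipse_heatmap(
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    angle: float = 0.0,
    shape: tuple[int, int] = (288, 384),
    ridge_sigma_px: float = 3.0,
) -> tuple[np.ndarray, dict]:
    """Heatmap with a Gaussian-profile ridge along a known ellipse.

    Intensity falls off with the distance from the ellipse outline,
    approximated via the normalized implicit function scaled by the local
    gradient — accurate near the outline, which is all the ridge occupies.
    """
    if not semi_major >= semi_minor > 0:
        raise ValueError("require semi_major >= semi_minor > 0")
    cy, cx = center
    if not (0 <= cy < shape[0] and 0 <= cx < shape[1]):
        raise ValueError("ellipse centre outside image")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    ca, sa = math.cos(angle), math.sin(angle)
    # rotate into the ellipse frame: u along major axis (col direction at
    # angle=0), v along minor
    dx = cc - cx
    dy = rr - cy
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    q = (u / semi_major) ** 2 + (v / semi_minor) ** 2
    grad = 2.0 * np.sqrt((u / semi_major**2) ** 2 + (v / semi_minor**2) ** 2)
    dist = np.abs(q - 1.0) / np.maximum(grad, 1e-9)
    h = np.exp(-(dist**2) / (2 * ridge_sigma_px**2))
    truth = {
        "ellipse": {
            "center": [cy, cx],
            "semi_major": semi_major,
            "semi_minor": semi_minor,
            "angle": angle,
        },
        "ridge_sigma_px": ridge_sigma_px,
    }
    return h, truth
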