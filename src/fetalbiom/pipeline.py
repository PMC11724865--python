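"""Whole-scan orchestration: gates -> extraction -> calibration -> update.

Each frame of a scan stream is routed through the gate cascade; surviving
measurements are calibrated to millimetres and folded into one streaming
Bayesian estimator per biometric.  The final report carries each
biometric's central estimate, its 95% credible interval, and an exact
accounting of why frames were rejected.

Frame records arrive as JSON-Lines (one object per frame) with either a
precomputed pixel measurement or a reference to a heatmap file; the
measurement source is pluggable so a live CNN backend can substitute for
either without touching the estimator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .estimator import (
    EstimatorState,
    PriorConfig,
    credible_interval,
    init_state,
    posterior_true_prob,
    update,
)
from .gates import GateReason, confidence_gate, degenerate_geometry_gate, plausibility_gate
from .types import (
    BIOMETRICS,
    PLANE_BIOMETRICS,
    BiometricEstimate,
    CentileReference,
    FrameRecord,
    GeometryKind,
    ScanReport,
    default_centile_reference,
    load_centile_reference,
)

logger = logging.getLogger("fetalbiom")

__all__ = ["PipelineConfig", "process_scan", "read_jsonl_stream"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds and priors, with the published defaults.

    ``readiness_ci_width_mm``, when set, suppresses reporting of a
    biometric whose credible interval has not yet shrunk below the given
    width (off by default: any number of measurements yields an estimate).
    """

    confidence_threshold: float = 0.95
    frozen_frame_threshold: float = 0.95
    frozen_pixel_tolerance: float = 0.0
    heatmap_mass_threshold: float = 0.5
    min_peak_separation_px: int = 10
    plausibility_window_weeks: float = 3.0
    P_t0: float = 0.75
    W_0: float = 10.0
    W_mu0: float = 1.0
    W_sigma2_0: float = 1.0
    perimeter_formula: str = "ramanujan2"
    scalebar_dialect: str = "default"
    centile_table: Optional[str] = None   # path; None -> synthetic default
    readiness_ci_width_mm: Optional[float] = None
    log_every: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_threshold < 1.0:
            raise ValueError("confidence_threshold must lie in (0, 1)")
        if not 0.0 < self.frozen_frame_threshold < 1.0:
            raise ValueError("frozen_frame_threshold must lie in (0, 1)")
        if not 0.0 < self.heatmap_mass_threshold < 1.0:
            raise ValueError("heatmap_mass_threshold must lie in (0, 1)")
        if not 0.0 < self.P_t0 < 1.0:
            raise ValueError("P_t0 must lie strictly in (0, 1)")
        if self.perimeter_formula not in geometry.PERIMETER_FORMULAS:
            raise ValueError(f"unknown perimeter formula {self.perimeter_formula!r}")

    def prior_config(self) -> PriorConfig:
        return PriorConfig(
            P_t0=self.P_t0,
            W_0=self.W_0,
            W_mu0=self.W_mu0,
            W_sigma2_0=self.W_sigma2_0,
            plausibility_window_weeks=self.plausibility_window_weeks,
        )

    def centile_reference(self) -> CentileReference:
        if self.centile_table is None:
            return default_centile_reference()
        return load_centile_reference(self.centile_table)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


def read_jsonl_stream(path: Union[str, Path]) -> tuple[list[FrameRecord], int]:
    """Parse a JSON-Lines stream file into frame records.

    Unreadable lines are skipped with a warning and counted; the caller
    receives (records, n_skipped).
    """
    records: list[FrameRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                records.append(
                    FrameRecord(
                        frame_index=int(obj["frame"]),
                        plane_label=str(obj["plane"]),
                        confidence=float(obj["confidence"]),
                        ga_weeks=float(obj.get("ga_weeks", float("nan"))),
                        measurement_px=obj.get("measurement_px"),
                        pixel_size_mm=obj.get("pixel_size_mm"),
                        biometric=obj.get("biometric"),
                        heatmap_path=obj.get("heatmap"),
                        image_path=obj.get("image"),
                    )
                )
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                n_skipped += 1
                logger.warning("skipping unreadable record at line %d: %s", lineno, exc)
    return records, n_skipped


def _measure_from_heatmap(
    record: FrameRecord, biometric: str, config: PipelineConfig
) -> Optional[float]:
    """Extract a pixel measurement from the frame's heatmap file."""
    import imageio.v3 as iio

    h = np.asarray(iio.imread(record.heatmap_path), dtype=float)
    spec = BIOMETRICS[biometric]
    if spec.geometry_kind is GeometryKind.LINEAR:
        m = geometry.find_two_peaks(h, min_separation_px=config.min_peak_separation_px)
        return None if m is None else m.length_px
    fit = geometry.fit_ellipse(h, mass_threshold=config.heatmap_mass_threshold)
    if fit is None:
        return None
    if spec.geometry_kind is GeometryKind.DERIVED_MINOR_AXIS:
        return geometry.bpd_from_head_fit(fit)
    return geometry.ellipse_perimeter(fit, formula=config.perimeter_formula)


def process_scan(
    records: Iterable[FrameRecord],
    ga_weeks: float,
    config: Optional[PipelineConfig] = None,
    ref: Optional[CentileReference] = None,
    biometrics: Optional[Sequence[str]] = None,
) -> tuple[ScanReport, dict[str, pd.DataFrame]]:
    """Run the whole-scan estimation pipeline over an ordered frame stream.

    Maintains one estimator state per biometric (initialised from the
    centile chart at the scan's gestational age) and routes every frame
    through confidence, geometry and plausibility gates before updating.
    Returns the final report and a per-biometric trajectory table
    (columns ``i, x, p_true, P_t, mu, sigma2, sigma_hat``).

    Deterministic: the same record sequence and config always produce the
    same report.
    """
    config = config or PipelineConfig()
    ref = ref or config.centile_reference()
    codes = tuple(biometrics) if biometrics else tuple(sorted(BIOMETRICS))
    prior = config.prior_config()

    states: dict[str, EstimatorState] = {
        code: init_state(ref, code, ga_weeks, prior) for code in codes
    }
    counts = {
        code: {
            "n_frames_seen": 0,
            "n_frames_measured": 0,
            "n_rejected_confidence": 0,
            "n_rejected_frozen": 0,
            "n_rejected_plausibility": 0,
            "n_rejected_degenerate": 0,
        }
        for code in codes
    }
    traj_rows: dict[str, list[tuple]] = {code: [] for code in codes}

    n_total = 0
    for record in records:
        n_total += 1
        plane_codes = [
            c for c in PLANE_BIOMETRICS.get(record.plane_label, ()) if c in states
        ]
        if record.biometric is not None:
            plane_codes = [c for c in plane_codes if c == record.biometric]
        for code in plane_codes:
            counts[code]["n_frames_seen"] += 1
            decision = confidence_gate(record, config.confidence_threshold)
            if not decision.accepted:
                counts[code]["n_rejected_confidence"] += 1
                continue
            # obtain a pixel measurement: precomputed, or from a heatmap
            measurement_px = record.measurement_px
            if measurement_px is None and record.heatmap_path is not None:
                measurement_px = _measure_from_heatmap(record, code, config)
            geom = degenerate_geometry_gate(measurement_px)
            if not geom.accepted:
                counts[code]["n_rejected_degenerate"] += 1
                continue
            if record.pixel_size_mm is None:
                counts[code]["n_rejected_degenerate"] += 1
                continue
            x_mm = geometry.to_mm(measurement_px, record.pixel_size_mm)
            plaus = plausibility_gate(
                x_mm, code, record.ga_weeks, ref, config.plausibility_window_weeks
            )
            if not plaus.accepted:
                counts[code]["n_rejected_plausibility"] += 1
                continue
            state = states[code]
            p = posterior_true_prob(state, x_mm)
            state = update(state, x_mm)
            states[code] = state
            counts[code]["n_frames_measured"] += 1
            ci = credible_interval(state)
            traj_rows[code].append(
                (counts[code]["n_frames_measured"] - 1, x_mm, p, state.P_t,
                 state.mu, state.sigma2, ci.sigma_hat)
            )
        if config.log_every and n_total % config.log_every == 0:
            logger.info("processed %d frames", n_total)

    report = ScanReport(ga_weeks=ga_weeks, n_frames_total=n_total,
                        config_summary={"perimeter_formula": config.perimeter_formula,
                                        "P_t0": config.P_t0, "W_0": config.W_0})
    trajectories: dict[str, pd.DataFrame] = {}
    for code in codes:
        state = states[code]
        ci = credible_interval(state)
        ready = (
            config.readiness_ci_width_mm is None
            or (ci.high - ci.low) < config.readiness_ci_width_mm
        )
        est = BiometricEstimate(
            biometric=code,
            final_estimate_mm=ci.mu if ready else float("nan"),
            standard_error_mm=ci.sigma_hat,
            ci95_low_mm=ci.low,
            ci95_high_mm=ci.high,
            final_P_t=state.P_t,
            **counts[code],
        )
        report.estimates[code] = est
        trajectories[code] = pd.DataFrame(
            traj_rows[code],
            columns=["i", "x", "p_true", "P_t", "mu", "sigma2", "sigma_hat"],
        )
    return report, trajectories
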