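"""Error quantification of reconstructed maps against ground truth.

ROI-integrated totals (mJ), signed percent errors, peak-TKE timing
relative to peak flow rate, and voxel-wise peak statistics.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import Grid3D, GroundTruthField

__all__ = [
    "ROISpec",
    "ErrorReport",
    "turbulent_envelope",
    "total_in_roi",
    "percent_error",
    "inlet_flow_rate",
    "peak_delay",
    "voxelwise_peak_stats",
]


@dataclass(frozen=True)
class ROISpec:
    """Integration region: turbulent envelope, whole geometry, or custom.

    The turbulent envelope is derived from the *ground-truth* TKE:
    voxels (in any frame) whose TKE reaches ``threshold`` times the
    spatiotemporal peak, morphologically closed.
    """

    kind: str = "whole_geometry"  # turbulent_envelope | whole_geometry | custom_mask
    threshold: float = 0.05
    custom: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("turbulent_envelope", "whole_geometry", "custom_mask"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "custom_mask" and self.custom is None:
            raise ValueError("custom_mask ROI requires a mask")

    def build(self, truth: GroundTruthField) -> np.ndarray:
        if self.kind == "whole_geometry":
            return truth.mask.copy()
        if self.kind == "custom_mask":
            roi = np.asarray(self.custom, dtype=bool)
        else:
            roi = turbulent_envelope(truth.tke(), self.threshold)
        return roi & truth.mask


def turbulent_envelope(tke_series: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Voxels reaching ``threshold`` of peak TKE in any frame, closed."""
    peak = tke_series.max()
    if peak <= 0:
        return np.zeros(tke_series.shape[-3:], dtype=bool)
    env = (tke_series >= threshold * peak).any(axis=0)
    return ndimage.binary_closing(env, structure=np.ones((3, 3, 3), dtype=bool))


def total_in_roi(
    energy_density: np.ndarray, roi: np.ndarray, grid: Grid3D
) -> float:
    """Volumetric integral of an energy density (J/m^3) over the ROI, in mJ."""
    roi = np.asarray(roi, dtype=bool)
    if energy_density.shape[-3:] != roi.shape:
        raise ValueError("field and ROI must share a grid")
    if not np.any(roi):
        raise ValueError("empty ROI")
    # mm^3 -> m^3 is 1e-9; J -> mJ is 1e3
    return float(energy_density[..., roi].sum() * grid.voxel_volume_mm3 * 1e-6)


def percent_error(measured_total: float, truth_total: float) -> float:
    """Signed percent error; overestimation is positive."""
    if truth_total <= 0:
        raise ValueError("percent error undefined for non-positive truth total")
    return 100.0 * (measured_total - truth_total) / truth_total


def inlet_flow_rate(field: GroundTruthField, slice_index: int = 0) -> np.ndarray:
    """Slice-integrated axial flux at the inlet plane per frame, in ml/s."""
    dx, dy = field.grid.spacing[0], field.grid.spacing[1]
    uz = field.u_mean[:, 2, :, :, slice_index]
    # m/s * mm^2 = 1e-6 m^3/s = ml/s
    return uz.sum(axis=(1, 2)) * dx * dy


def _subframe_argmax(times: np.ndarray, values: np.ndarray) -> float:
    """Time of the maximum with 3-point quadratic interpolation."""
    i = int(np.argmax(values))
    if i == 0 or i == len(values) - 1:
        return float(times[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(times[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = 0.5 * (times[i + 1] - times[i - 1])
    return float(times[i] + np.clip(delta, -1.0, 1.0) * dt)


def peak_delay(
    times_ms: np.ndarray, flow_rate: np.ndarray, total_tke: np.ndarray
) -> float:
    """Lag (ms) between peak total TKE and peak flow rate.

    Both peaks are located with quadratic sub-frame interpolation.
    Requires at least 5 frames; flat series are rejected.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    flow_rate = np.asarray(flow_rate, dtype=float)
    total_tke = np.asarray(total_tke, dtype=float)
    if times_ms.size < 5:
        raise ValueError("peak_delay needs at least 5 frames")
    if np.ptp(flow_rate) == 0 or np.ptp(total_tke) == 0:
        raise ValueError("peak_delay undefined for a flat series")
    return _subframe_argmax(times_ms, total_tke) - _subframe_argmax(
        times_ms, flow_rate
    )


def voxelwise_peak_stats(
    tke_series: np.ndarray, roi: np.ndarray
) -> tuple[float, float]:
    """Mean and std over the ROI of the per-voxel temporal TKE maximum."""
    roi = np.asarray(roi, dtype=bool)
    if not np.any(roi):
        raise ValueError("empty ROI")
    peaks = np.asarray(tke_series).max(axis=0)[roi]
    return float(peaks.mean()), float(peaks.std())


@dataclass
class ErrorReport:
    """Per-frame, per-ROI totals and errors for one pipeline condition.

    ``rows`` holds dicts with keys: frame_time_ms, roi, measured_tke_mJ,
    truth_tke_mJ, measured_ke_mJ, truth_ke_mJ, pct_error_tke,
    pct_error_ke (percent errors are None where the truth total is 0).
    """

    condition: dict = field(default_factory=dict)
    rows: list[dict] = field(default_factory=list)
    peak_delay_ms: float | None = None
    voxelwise_peak_mean: float | None = None
    voxelwise_peak_std: float | None = None
    n_clamped: int = 0

    def add_frame(
        self,
        frame_time_ms: float,
        roi_name: str,
        measured_tke_mJ: float,
        truth_tke_mJ: float,
        measured_ke_mJ: float,
        truth_ke_mJ: float,
    ) -> None:
        self.rows.append(
            {
                "frame_time_ms": frame_time_ms,
                "roi": roi_name,
                "measured_tke_mJ": measured_tke_mJ,
                "truth_tke_mJ": truth_tke_mJ,
                "measured_ke_mJ": measured_ke_mJ,
                "truth_ke_mJ": truth_ke_mJ,
                "pct_error_tke": (
                    percent_error(measured_tke_mJ, truth_tke_mJ)
                    if truth_tke_mJ > 0
                    else None
                ),
                "pct_error_ke": (
                    percent_error(measured_ke_mJ, truth_ke_mJ)
                    if truth_ke_mJ > 0
                    else None
                ),
            }
        )

    def totals(self, roi_name: str, which: str = "measured_tke_mJ") -> np.ndarray:
        return np.array([r[which] for r in self.rows if r["roi"] == roi_name])

    def frame_times(self, roi_name: str) -> np.ndarray:
        return np.array(
            [r["frame_time_ms"] for r in self.rows if r["roi"] == roi_name]
        )

    def cycle_integrated_error(self, roi_name: str) -> float:
        """Percent error of the cycle-integrated total TKE for one ROI."""
        meas = self.totals(roi_name, "measured_tke_mJ").sum()
        truth = self.totals(roi_name, "truth_tke_mJ").sum()
        return percent_error(float(meas), float(truth))

    def to_json(self, path) -> None:
        payload = {
            "condition": self.condition,
            "peak_delay_ms": self.peak_delay_ms,
            "voxelwise_peak_mean": self.voxelwise_peak_mean,
            "voxelwise_peak_std": self.voxelwise_peak_std,
            "n_clamped": self.n_clamped,
            "rows": self.rows,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        cols = [
            "frame_time_ms",
            "roi",
            "measured_tke_mJ",
            "truth_tke_mJ",
            "measured_ke_mJ",
            "truth_ke_mJ",
            "pct_error_tke",
            "pct_error_ke",
        ]
        with open(path, "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.rows)
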