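"""Serial fiber-diffraction monitor.

Workers divide each frame by the beam's polarization factor, subtract the
mean signal in each resolution ring (so the azimuthally symmetric water
background cancels and the fibers' diffraction streaks stand out), record
the integrated signal on each detector panel, and count residual-frame
peaks for hit classification.  The master keeps a rolling integration of
the corrected frames over ~1000 shots, per-panel signal histories, the hit
rate, and the latest residual frame.

Polarization factor (Thomson dipole, fraction ``p`` polarized along the
horizontal x axis):

    P = p * (1 - sin^2(2theta) cos^2 phi) + (1 - p) * (1 - sin^2(2theta) sin^2 phi)

with phi the pixel azimuth from +x and 2theta its scattering angle.  Pixels
where P falls below a floor (default 1e-3) are flagged invalid rather than
amplified.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from ..engine import PipelineDefinition
from ..geometry import DetectorFrame, GeometrySpec, PixelMaps, build_pixel_maps
from ..peaks import PeakSearchParams, compute_radial_statistics, find_peaks
from ..sources import Event, ExtractedData, extract_data
from .sfx import RunningAverageSeries, classify_hit

__all__ = [
    "PanelSignalRecord",
    "IntegratedImage",
    "polarization_factor",
    "polarization_correct",
    "radial_background_subtract",
    "panel_sums",
    "integrate_frame",
    "FiberState",
    "build_fiber_pipeline",
]

P_FLOOR = 1e-3


@dataclass(frozen=True)
class PanelSignalRecord:
    """Per-shot integrated signal on each panel (valid pixels only)."""

    sums: dict[int, float]
    timestamp: float


def polarization_factor(maps: PixelMaps, pixel_size_mm: float,
                        distance_mm: float,
                        polarization_fraction: float) -> np.ndarray:
    """Per-pixel Thomson polarization factor for the detector geometry."""
    p = polarization_fraction
    if not (0.0 <= p <= 1.0):
        raise ValueError("polarization fraction must lie in [0, 1]")
    two_theta = np.arctan(maps.radius_px * pixel_size_mm / distance_mm)
    s2 = np.sin(two_theta) ** 2
    cphi2 = np.cos(maps.azimuth_rad) ** 2
    sphi2 = np.sin(maps.azimuth_rad) ** 2
    return p * (1.0 - s2 * cphi2) + (1.0 - p) * (1.0 - s2 * sphi2)


def polarization_correct(frame: DetectorFrame, maps: PixelMaps,
                         polarization_fraction: float,
                         pixel_size_mm: float, distance_mm: float,
                         floor: float = P_FLOOR) -> DetectorFrame:
    """Divide out the polarization modulation; near-zero factors invalidate
    the pixel instead of amplifying it."""
    pol = polarization_factor(maps, pixel_size_mm, distance_mm,
                              polarization_fraction)
    ok = pol >= floor
    data = np.where(ok, frame.data / np.where(ok, pol, 1.0), frame.data)
    return DetectorFrame(
        data=data,
        timestamp=frame.timestamp,
        event_id=frame.event_id,
        photon_energy_ev=frame.photon_energy_ev,
        detector_distance_mm=frame.detector_distance_mm,
        valid=frame.valid & ok,
    )


def radial_background_subtract(
    frame: DetectorFrame,
    radius_map: np.ndarray,
    bin_px: float = 1.0,
    clip_sigma: float | None = None,
    clip_iterations: int = 0,
) -> DetectorFrame:
    """Subtract each pixel's resolution-ring mean.

    By default the plain ring mean is used (no sigma clipping); clipping is
    available for streak-heavy data.  Pixels in rings with no valid pixels
    become invalid.
    """
    params = PeakSearchParams(
        radial_bin_px=bin_px,
        clip_sigma=clip_sigma if clip_sigma is not None else 3.0,
        clip_iterations=clip_iterations if clip_sigma is not None else 0,
    )
    profile = compute_radial_statistics(frame, radius_map, params)
    bin_idx = np.floor(radius_map / bin_px).astype(np.intp)
    mean_map = profile.mean[bin_idx]
    ok = frame.valid & profile.valid[bin_idx]
    residual = np.where(ok, frame.data - np.where(ok, mean_map, 0.0), 0.0)
    return DetectorFrame(
        data=residual,
        timestamp=frame.timestamp,
        event_id=frame.event_id,
        photon_energy_ev=frame.photon_energy_ev,
        detector_distance_mm=frame.detector_distance_mm,
        valid=ok,
    )


def panel_sums(frame: DetectorFrame, panel_map: np.ndarray,
               n_panels: int | None = None) -> dict[int, float]:
    """Per-panel sum of valid pixel values (all panels, always)."""
    if n_panels is None:
        n_panels = int(panel_map.max()) + 1
    flat_pid = panel_map.ravel()
    flat_val = np.where(frame.valid, frame.data, 0.0).ravel()
    sums = np.bincount(flat_pid, weights=flat_val, minlength=n_panels)
    return {i: float(sums[i]) for i in range(n_panels)}


@dataclass
class IntegratedImage:
    """Running sum of frames over a bounded window (default: rolling)."""

    grid: np.ndarray
    capacity: int = 1000
    mode: str = "roll"  # "roll": drop oldest; "hold": stop adding when full
    n_frames: int = 0
    _buffer: deque = field(default_factory=deque, repr=False)

    @classmethod
    def zeros(cls, shape: tuple[int, int], capacity: int = 1000,
              mode: str = "roll") -> "IntegratedImage":
        if mode not in ("roll", "hold"):
            raise ValueError("integration mode must be 'roll' or 'hold'")
        return cls(grid=np.zeros(shape, dtype=np.float64),
                   capacity=capacity, mode=mode)

    def reset(self) -> None:
        self.grid[:] = 0.0
        self.n_frames = 0
        self._buffer.clear()


def integrate_frame(acc: IntegratedImage, frame: DetectorFrame
                    ) -> IntegratedImage:
    """Element-wise running sum; invalid pixels contribute zero.

    In "roll" mode the window slides (the oldest frame is subtracted once
    the capacity is reached); in "hold" mode integration stops at capacity.
    """
    if frame.data.shape != acc.grid.shape:
        raise ValueError(
            f"frame shape {frame.data.shape} != accumulator shape "
            f"{acc.grid.shape}"
        )
    contribution = np.where(frame.valid, frame.data, 0.0)
    if acc.n_frames >= acc.capacity:
        if acc.mode == "hold":
            return acc
        oldest = acc._buffer.popleft()
        acc.grid -= oldest
        acc.n_frames -= 1
    if acc.mode == "roll":
        acc._buffer.append(contribution.astype(np.float32).astype(np.float64))
        acc.grid += acc._buffer[-1]
    else:
        acc.grid += contribution
    acc.n_frames += 1
    return acc


@dataclass
class FiberState:
    """Master-side cross-event state of the fiber monitor."""

    integrated: IntegratedImage
    hit_rate: RunningAverageSeries
    panel_history: deque = field(default_factory=lambda: deque(maxlen=2000))
    latest_residual: np.ndarray | None = None
    n_events: int = 0


def build_fiber_pipeline(
    geom: GeometrySpec,
    polarization_fraction: float = 0.99,
    bin_px: float = 1.0,
    integration_frames: int = 1000,
    integration_mode: str = "roll",
    selected_panels: tuple[int, ...] | None = None,
    min_peaks_for_hit: int = 2,
    peak_params: PeakSearchParams | None = None,
    window: int = 100,
    mask: np.ndarray | None = None,
    state: FiberState | None = None,
    broadcast_every: int = 1,
) -> tuple[PipelineDefinition, FiberState]:
    """Wire the fiber worker and master stages into a pipeline."""
    maps = build_pixel_maps(geom)
    n_panels = len(geom.panels)
    if selected_panels:
        unknown = [p for p in selected_panels if not (0 <= p < n_panels)]
        if unknown:
            from ..sources import ConfigurationError
            raise ConfigurationError(
                f"selected panels {unknown} do not exist "
                f"(geometry has {n_panels} panels)"
            )
    peak_params = peak_params or PeakSearchParams(snr_min=6.0,
                                                  pixel_count_min=2)
    if state is None:
        state = FiberState(
            integrated=IntegratedImage.zeros(geom.shape, integration_frames,
                                             integration_mode),
            hit_rate=RunningAverageSeries(window),
        )

    def extract(event: Event) -> ExtractedData:
        return extract_data(event, ("raw_data", "event_timestamp"))

    def process(extracted: ExtractedData) -> dict:
        frame = DetectorFrame(data=extracted.raw_data,
                              timestamp=extracted.event_timestamp,
                              event_id=extracted.event_id,
                              valid=None if mask is None else mask != 0)
        corrected = polarization_correct(frame, maps, polarization_fraction,
                                         geom.pixel_size_mm,
                                         geom.detector_distance_mm)
        residual = radial_background_subtract(corrected, maps.radius_px,
                                              bin_px)
        profile = compute_radial_statistics(residual, maps.radius_px,
                                            peak_params)
        peaks = find_peaks(residual, maps, profile, peak_params)
        sums = panel_sums(corrected, maps.panel_id, n_panels)
        return {
            "event_id": extracted.event_id,
            "event_timestamp": extracted.event_timestamp,
            "corrected": corrected.data.astype(np.float32),
            "corrected_valid": corrected.valid,
            "residual": residual.data.astype(np.float32),
            "panel_sums": np.array([sums[i] for i in range(n_panels)]),
            "n_peaks": len(peaks),
            "hit": classify_hit(len(peaks), min_peaks_for_hit),
        }

    def collect(result: dict) -> dict | None:
        state.n_events += 1
        ts = result["event_timestamp"]
        corrected = DetectorFrame(
            data=np.asarray(result["corrected"], dtype=np.float64),
            timestamp=ts, valid=result["corrected_valid"])
        integrate_frame(state.integrated, corrected)
        state.hit_rate.update(1.0 if result["hit"] else 0.0)
        state.panel_history.append(
            PanelSignalRecord(
                sums=dict(enumerate(result["panel_sums"].tolist())),
                timestamp=ts))
        state.latest_residual = result["residual"]
        if state.n_events % broadcast_every != 0:
            return None
        selected = (tuple(selected_panels) if selected_panels
                    else tuple(range(n_panels)))
        return {
            "monitor": "fiber",
            "integrated_image": state.integrated.grid,
            "integrated_frames": state.integrated.n_frames,
            "residual_frame": state.latest_residual,
            "panel_sums_history": np.array(
                [[rec.sums[i] for i in selected]
                 for rec in state.panel_history]),
            "selected_panels": list(selected),
            "hit_rate": state.hit_rate.current,
            "hit_rate_history": np.asarray(state.hit_rate.history),
            "delay_s": max(time.time() - ts, 0.0),
            "timestamp": ts,
        }

    return PipelineDefinition(extract, process, collect), state
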