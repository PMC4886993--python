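"""Serial-crystallography monitor.

Workers correct each detector frame, find Bragg-peak candidates against a
radial background model, and classify the frame as a hit (enough peaks) and
as saturated (more than three peaks at the detector's dynamic-range limit).
The master keeps running averages of the hit and saturation rates over a
user-chosen window, accumulates a virtual powder pattern from the detected
peaks, and reports a display-delay estimate (broadcast wall time minus the
event timestamp).
"""

from __future__ import annotations

import math
import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from ..engine import PipelineDefinition
from ..geometry import (DetectorFrame, GeometrySpec, PixelMaps,
                        apply_corrections, build_pixel_maps)
from ..peaks import (Peak, PeakSearchParams, compute_radial_statistics,
                     count_saturated_peaks, find_peaks)
from ..sources import Event, ExtractedData, extract_data

__all__ = [
    "classify_hit",
    "is_frame_saturated",
    "RunningAverageSeries",
    "VirtualPowder",
    "accumulate_powder",
    "SfxState",
    "assemble_sfx_aggregate",
    "build_sfx_pipeline",
]

#: A frame is saturated when *more than* this many peaks hit the limit.
MAX_UNSATURATED_PEAKS = 3


def classify_hit(n_peaks: int, min_peaks_for_hit: int) -> bool:
    """Hit iff the peak count reaches the threshold (inclusive boundary)."""
    if min_peaks_for_hit < 1:
        raise ValueError("min_peaks_for_hit must be >= 1")
    return n_peaks >= min_peaks_for_hit


def is_frame_saturated(n_saturated_peaks: int,
                       max_unsaturated: int = MAX_UNSATURATED_PEAKS) -> bool:
    """Strictly more than ``max_unsaturated`` saturated peaks flags the frame."""
    return n_saturated_peaks > max_unsaturated


@dataclass
class RunningAverageSeries:
    """Unweighted moving average of a 0/1 indicator over the last ``window``
    events, with a bounded history of past average values for plotting."""

    window: int
    history_length: int = 2000
    _indicators: deque = field(default_factory=deque, repr=False)
    history: deque = field(default_factory=deque, repr=False)
    current: float = float("nan")

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        self._indicators = deque(maxlen=self.window)
        self.history = deque(maxlen=self.history_length)

    def update(self, indicator: float) -> float:
        """Record one indicator; the average warms up over the first window."""
        self._indicators.append(float(indicator))
        self.current = sum(self._indicators) / len(self._indicators)
        self.history.append(self.current)
        return self.current

    def reset(self) -> None:
        self._indicators.clear()
        self.history.clear()
        self.current = float("nan")


@dataclass
class VirtualPowder:
    """Accumulation grid of detected-peak intensities over many frames."""

    grid: np.ndarray
    n_contributing_frames: int = 0

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "VirtualPowder":
        return cls(grid=np.zeros(shape, dtype=np.float64))

    def reset(self) -> None:
        self.grid[:] = 0.0
        self.n_contributing_frames = 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def accumulate_powder(powder: VirtualPowder, peaks: list[Peak]) -> VirtualPowder:
    """Add each peak's integrated intensity at the pixel nearest its centroid.

    Out-of-bounds centroids are skipped.  Frames contributing at least one
    peak increment the frame counter.
    """
    n_slow, n_fast = powder.grid.shape
    for p in peaks:
        s = _round_half_up(p.centroid_slow)
        f = _round_half_up(p.centroid_fast)
        if 0 <= s < n_slow and 0 <= f < n_fast:
            powder.grid[s, f] += p.integrated_intensity
    if peaks:
        powder.n_contributing_frames += 1
    return powder


@dataclass
class SfxState:
    """Master-side cross-event state of the SFX monitor."""

    hit_rate: RunningAverageSeries
    sat_rate: RunningAverageSeries
    powder: VirtualPowder
    n_events: int = 0

    @classmethod
    def create(cls, frame_shape: tuple[int, int], window: int = 100,
               history_length: int = 2000) -> "SfxState":
        return cls(
            hit_rate=RunningAverageSeries(window, history_length),
            sat_rate=RunningAverageSeries(window, history_length),
            powder=VirtualPowder.zeros(frame_shape),
        )

    def reset(self) -> None:
        self.hit_rate.reset()
        self.sat_rate.reset()
        self.powder.reset()
        self.n_events = 0


def assemble_sfx_aggregate(state: SfxState, latest: dict,
                           now: float | None = None) -> dict:
    """The complete broadcast snapshot: a viewer attaching mid-run can render
    everything from one message."""
    now = time.time() if now is None else now
    ts = latest.get("event_timestamp")
    delay = None if ts is None else max(now - ts, 0.0)
    return {
        "monitor": "sfx",
        "hit_rate": state.hit_rate.current,
        "sat_rate": state.sat_rate.current,
        "hit_rate_history": np.asarray(state.hit_rate.history),
        "sat_rate_history": np.asarray(state.sat_rate.history),
        "powder": state.powder.grid,
        "powder_frames": state.powder.n_contributing_frames,
        "n_events": state.n_events,
        "delay_s": delay,
        "timestamp": ts,
    }


def build_sfx_pipeline(
    geom: GeometrySpec,
    peak_params: PeakSearchParams | None = None,
    min_peaks_for_hit: int = 10,
    saturation_threshold: float = 10000.0,
    window: int = 100,
    mask: np.ndarray | None = None,
    gain_map: np.ndarray | None = None,
    state: SfxState | None = None,
    broadcast_every: int = 1,
) -> tuple[PipelineDefinition, SfxState]:
    """Wire the SFX worker and master stages into a pipeline.

    Returns the pipeline plus the live master state so callers (tests, the
    CLI's final summary) can inspect the aggregates after the run.
    """
    peak_params = peak_params or PeakSearchParams()
    maps = build_pixel_maps(geom)
    if state is None:
        state = SfxState.create(geom.shape, window=window)

    def extract(event: Event) -> ExtractedData:
        return extract_data(event, ("raw_data", "event_timestamp"))

    def process(extracted: ExtractedData) -> dict:
        frame = DetectorFrame(data=extracted.raw_data,
                              timestamp=extracted.event_timestamp,
                              event_id=extracted.event_id)
        frame = apply_corrections(frame, mask=mask, gain_map=gain_map)
        profile = compute_radial_statistics(frame, maps.radius_px, peak_params)
        peaks = find_peaks(frame, maps, profile, peak_params)
        n_sat = count_saturated_peaks(peaks, saturation_threshold)
        return {
            "event_id": extracted.event_id,
            "event_timestamp": extracted.event_timestamp,
            "n_peaks": len(peaks),
            "hit": classify_hit(len(peaks), min_peaks_for_hit),
            "n_saturated_peaks": n_sat,
            "saturated_frame": is_frame_saturated(n_sat),
            "peak_fs": np.array([p.centroid_fast for p in peaks]),
            "peak_ss": np.array([p.centroid_slow for p in peaks]),
            "peak_intensity": np.array([p.integrated_intensity for p in peaks]),
            "peak_max_pixel": np.array([p.max_pixel for p in peaks]),
        }

    def collect(result: dict) -> dict | None:
        state.n_events += 1
        state.hit_rate.update(1.0 if result["hit"] else 0.0)
        state.sat_rate.update(1.0 if result["saturated_frame"] else 0.0)
        peaks = [
            Peak(seed_fast=_round_half_up(f), seed_slow=_round_half_up(s),
                 centroid_fast=f, centroid_slow=s, integrated_intensity=i,
                 max_pixel=m, n_pixels=1, radius_px=0.0, snr=0.0)
            for f, s, i, m in zip(result["peak_fs"], result["peak_ss"],
                                  result["peak_intensity"],
                                  result["peak_max_pixel"])
        ]
        accumulate_powder(state.powder, peaks)
        if state.n_events % broadcast_every == 0:
            return assemble_sfx_aggregate(state, result)
        return None

    return PipelineDefinition(extract, process, collect), state
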