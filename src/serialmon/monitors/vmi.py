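"""Velocity-map-imaging monitor.

Workers detect ion spots on each camera image (simple threshold + connected
components) and localize them with sub-pixel center-of-mass centroiding.
The master registers the spot positions (translation then rotation),
filters them through a user-defined wedge about the vertical alignment
axis, accumulates spots over a sliding block of events, and reports the
degree-of-alignment statistics: the mean |theta| from the vertical axis and
<cos^2 theta>, where cos theta = |y| / r (1 = perfectly aligned with the
alignment laser, 0.5 = isotropic in the screen plane, 0 = anti-aligned).

Screen coordinates: x along image columns, y along image rows; the two-fold
symmetry of the statistics (|y|) makes the row direction's sign irrelevant.
"""

from __future__ import annotations

import math
import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..engine import PipelineDefinition
from ..sources import Event, ExtractedData, extract_data

__all__ = [
    "IonSpot",
    "WedgeRegion",
    "AlignmentStats",
    "detect_spots",
    "centroid",
    "register_positions",
    "in_wedge",
    "alignment_stats",
    "VmiState",
    "build_vmi_pipeline",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class IonSpot:
    """One detected ion impact, localized to sub-pixel precision."""

    x: float
    y: float
    total_intensity: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("ion spot must have positive total intensity")


@dataclass(frozen=True)
class WedgeRegion:
    """Wedge-shaped inclusion region about the vertical axis.

    Positions are first shifted by the apex offset and rotated by
    ``rotation_deg`` (counter-clockwise), then kept when their radius lies
    in [r_min, r_max] and their angle from the vertical axis is at most
    ``half_width_deg``.  With ``two_fold`` set, the mirror wedge through the
    apex is included too (the angle is measured from the nearer vertical
    half-axis).
    """

    apex_x: float = 0.0
    apex_y: float = 0.0
    rotation_deg: float = 0.0
    half_width_deg: float = 30.0
    r_min: float = 0.0
    r_max: float = float("inf")
    two_fold: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.half_width_deg <= 90.0):
            raise ValueError("wedge half-width must be in (0, 90] degrees")
        if not (self.r_min < self.r_max):
            raise ValueError("wedge needs r_min < r_max")


@dataclass(frozen=True)
class AlignmentStats:
    theta_mean_deg: float
    cos2_mean: float
    n_ions: int


def detect_spots(image: np.ndarray, intensity_threshold: float
                 ) -> list[np.ndarray]:
    """8-connected components of above-threshold pixels.

    Each region is returned as an (n, 2) array of (row, col) indices.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("VMI camera image must be 2-D")
    labels, n = ndimage.label(image > intensity_threshold,
                              structure=_EIGHT_CONN)
    if n == 0:
        return []
    order = np.argsort(labels.ravel(), kind="stable")
    flat = labels.ravel()[order]
    coords = np.column_stack(np.unravel_index(order, image.shape))
    bounds = np.searchsorted(flat, np.arange(1, n + 2))
    return [coords[bounds[i]:bounds[i + 1]] for i in range(n)]


def centroid(image: np.ndarray, region: np.ndarray) -> IonSpot:
    """Intensity-weighted center of mass over the region's pixels."""
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("cannot centroid an empty region")
    vals = image[region[:, 0], region[:, 1]].astype(np.float64)
    total = vals.sum()
    if total <= 0:
        raise ValueError("cannot centroid a region with non-positive intensity")
    y = float((vals * region[:, 0]).sum() / total)
    x = float((vals * region[:, 1]).sum() / total)
    return IonSpot(x=x, y=y, total_intensity=float(total),
                   n_pixels=int(len(vals)))


def register_positions(positions: np.ndarray,
                       translation: tuple[float, float] = (0.0, 0.0),
                       rotation_deg: float = 0.0) -> np.ndarray:
    """p' = R(rotation) @ (p - translation); rotation counter-clockwise."""
    p = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    p = p - np.asarray(translation, dtype=np.float64)
    a = math.radians(rotation_deg)
    rot = np.array([[math.cos(a), -math.sin(a)],
                    [math.sin(a), math.cos(a)]])
    return p @ rot.T


def _vertical_angle_deg(x: np.ndarray, y: np.ndarray,
                        two_fold: bool) -> np.ndarray:
    """Angle from the vertical axis: the +y half-axis, or the nearer
    half-axis (via |y|) when two_fold."""
    yy = np.abs(y) if two_fold else y
    return np.degrees(np.arctan2(np.abs(x), yy))


def in_wedge(positions: np.ndarray, wedge: WedgeRegion) -> np.ndarray:
    """Boolean inclusion flags for registered positions."""
    p = register_positions(positions, (wedge.apex_x, wedge.apex_y),
                           wedge.rotation_deg)
    x, y = p[:, 0], p[:, 1]
    r = np.hypot(x, y)
    ang = _vertical_angle_deg(x, y, wedge.two_fold)
    return ((r >= wedge.r_min) & (r <= wedge.r_max)
            & (ang <= wedge.half_width_deg))


def alignment_stats(positions: np.ndarray) -> AlignmentStats:
    """Mean |theta| and <cos^2 theta> over included spot positions.

    theta is each spot's angle from the vertical axis, cos theta = |y|/r;
    spots are weighted equally.  Zero-radius spots carry no direction and
    are excluded; with no usable spots the statistics are undefined (NaN).
    """
    p = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    if p.size == 0:
        return AlignmentStats(float("nan"), float("nan"), 0)
    x, y = p[:, 0], p[:, 1]
    r = np.hypot(x, y)
    ok = r > 0
    if not ok.any():
        return AlignmentStats(float("nan"), float("nan"), 0)
    cos_t = np.abs(y[ok]) / r[ok]
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    return AlignmentStats(
        theta_mean_deg=float(theta.mean()),
        cos2_mean=float((cos_t ** 2).mean()),
        n_ions=int(ok.sum()),
    )


@dataclass
class VmiState:
    """Sliding accumulation of spots over the configured number of events."""

    accumulation_events: int
    density_shape: tuple[int, int]
    spots_per_event: deque = field(default_factory=deque)
    cos2_history: deque = field(default_factory=lambda: deque(maxlen=2000))
    n_events: int = 0

    def __post_init__(self) -> None:
        self.spots_per_event = deque(maxlen=self.accumulation_events)


def build_vmi_pipeline(
    image_shape: tuple[int, int],
    intensity_threshold: float,
    wedge: WedgeRegion,
    translation: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    accumulation_events: int = 100,
    state: VmiState | None = None,
    broadcast_every: int = 1,
) -> tuple[PipelineDefinition, VmiState]:
    """Wire the VMI worker and master stages into a pipeline.

    ``translation`` should carry the screen center (and any interaction-
    point offset): statistics are computed about the registered origin.
    """
    if state is None:
        state = VmiState(accumulation_events, image_shape)

    def extract(event: Event) -> ExtractedData:
        return extract_data(event, ("raw_data", "event_timestamp"))

    def process(extracted: ExtractedData) -> dict:
        image = np.asarray(extracted.raw_data, dtype=np.float64)
        spots = [centroid(image, reg)
                 for reg in detect_spots(image, intensity_threshold)]
        return {
            "event_id": extracted.event_id,
            "event_timestamp": extracted.event_timestamp,
            "spot_x": np.array([s.x for s in spots]),
            "spot_y": np.array([s.y for s in spots]),
            "spot_intensity": np.array([s.total_intensity for s in spots]),
        }

    def collect(result: dict) -> dict | None:
        state.n_events += 1
        state.spots_per_event.append(
            np.column_stack([result["spot_x"], result["spot_y"]])
            if len(result["spot_x"]) else np.empty((0, 2)))
        if state.n_events % broadcast_every != 0:
            return None
        # statistics are recomputed over the sliding block only when a
        # snapshot goes out; between broadcasts the buffer just accumulates
        raw = (np.vstack(state.spots_per_event)
               if state.spots_per_event else np.empty((0, 2)))
        registered = (register_positions(raw, translation, rotation_deg)
                      if len(raw) else raw)
        included = registered[in_wedge(registered, wedge)] if len(raw) else raw
        stats = alignment_stats(included)
        state.cos2_history.append(stats.cos2_mean)

        density, _, _ = np.histogram2d(
            raw[:, 1] if len(raw) else np.empty(0),
            raw[:, 0] if len(raw) else np.empty(0),
            bins=state.density_shape,
            range=[[0, state.density_shape[0]], [0, state.density_shape[1]]],
        )
        ts = result.get("event_timestamp")
        return {
            "monitor": "vmi",
            "spots": registered,
            "density_grid": density,
            "theta_mean_deg": stats.theta_mean_deg,
            "cos2_mean": stats.cos2_mean,
            "n_ions": stats.n_ions,
            "cos2_history": np.asarray(state.cos2_history),
            "delay_s": None if ts is None else max(time.time() - ts, 0.0),
            "timestamp": ts,
        }

    return PipelineDefinition(extract, process, collect), state
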