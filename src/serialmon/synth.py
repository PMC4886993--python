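"""Seeded synthetic data with known ground truth for every monitor.

Every generator is a pure function of (parameters, seed): regenerating with
the same arguments is bit-identical.  Frames carry Gaussian noise by default
(closed-form SNR for planted features); Poisson noise is available where a
counting model matters.  Truth labels (planted peak positions and
intensities, true ion emission angles, streak pixels, per-event hit and
corrupt flags) are returned alongside the data and, for file streams,
written into a ``/truth`` sidecar group of the CXI file.

These generators emulate the *statistical* structure the monitors reduce —
blob-shaped Bragg candidates on smooth background, angularly structured ion
impacts, an azimuthally symmetric ring plus streaks — not the physics of
diffraction (no structure factors, no Ewald geometry).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from .geometry import DetectorFrame, GeometrySpec, single_panel_geometry
from .sources import (DEFAULT_DATA_PATH, DETECTOR_DISTANCE_PATH,
                      PHOTON_ENERGY_PATH, TIMESTAMP_PATH)

__all__ = [
    "SyntheticTruth",
    "generate_sfx_frame",
    "generate_vmi_image",
    "generate_fiber_frame",
    "generate_event_stream",
    "write_cxi",
    "default_geometry",
    "four_panel_geometry",
]

BLOB_SIGMA_PX = 1.2
MIN_PEAK_SEPARATION_PX = 6.0


@dataclass
class SyntheticTruth:
    """Ground-truth labels for one generated object (frame/image/stream)."""

    seed: int
    params: dict = field(default_factory=dict)
    peak_positions: np.ndarray | None = None   # (n, 2) (fast, slow)
    peak_intensities: np.ndarray | None = None
    n_saturated: int = 0
    ion_angles_rad: np.ndarray | None = None   # from the vertical axis
    ion_positions: np.ndarray | None = None    # (n, 2) (x, y) screen coords
    streak_pixels: np.ndarray | None = None    # (n, 2) (slow, fast)
    hit_flags: np.ndarray | None = None        # per-event, streams only
    corrupt_flags: np.ndarray | None = None
    timestamps: np.ndarray | None = None
    peaks_per_event: list | None = None


def default_geometry(n: int = 512) -> GeometrySpec:
    """The standard single-panel toy detector, beam-centered."""
    return single_panel_geometry(n)


def four_panel_geometry(n: int = 128, gap_px: float = 4.0) -> GeometrySpec:
    """A 2x2 quad of panels around the beam axis, exercising panel logic."""
    from .geometry import PanelSpec
    panels = (
        PanelSpec("q0", n, n, -n - gap_px / 2, -n - gap_px / 2),
        PanelSpec("q1", n, n, gap_px / 2, -n - gap_px / 2),
        PanelSpec("q2", n, n, -n - gap_px / 2, gap_px / 2),
        PanelSpec("q3", n, n, gap_px / 2, gap_px / 2),
    )
    return GeometrySpec(panels, pixel_size_mm=0.1, detector_distance_mm=100.0,
                        photon_energy_ev=9000.0)


def _render_blobs(shape: tuple[int, int], centers: np.ndarray,
                  amplitudes: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of Gaussian blobs; centers given as (fast, slow)."""
    img = np.zeros(shape, dtype=np.float64)
    half = max(3, int(np.ceil(4 * sigma)))
    n_slow, n_fast = shape
    for (cf, cs), amp in zip(centers, amplitudes):
        s0, s1 = int(np.floor(cs)) - half, int(np.floor(cs)) + half + 1
        f0, f1 = int(np.floor(cf)) - half, int(np.floor(cf)) + half + 1
        s0, s1 = max(s0, 0), min(s1, n_slow)
        f0, f1 = max(f0, 0), min(f1, n_fast)
        if s0 >= s1 or f0 >= f1:
            continue
        ss = np.arange(s0, s1)[:, None]
        ff = np.arange(f0, f1)[None, :]
        img[s0:s1, f0:f1] += amp * np.exp(
            -((ss - cs) ** 2 + (ff - cf) ** 2) / (2 * sigma ** 2))
    return img


def _place_on_rings(rng: np.random.Generator, shape: tuple[int, int],
                    n_peaks: int, ring_radii_px: tuple[float, ...],
                    min_sep: float = MIN_PEAK_SEPARATION_PX,
                    margin: float = 6.0, max_tries: int = 20000
                    ) -> np.ndarray:
    """Peak centers at the given radii, uniform random azimuth, min separation."""
    n_slow, n_fast = shape
    c_s, c_f = (n_slow - 1) / 2.0, (n_fast - 1) / 2.0
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_peaks:
        if tries >= max_tries:
            raise ValueError(
                f"cannot place {n_peaks} peaks with separation {min_sep} px "
                f"on radii {ring_radii_px} within a {shape} frame"
            )
        tries += 1
        radius = ring_radii_px[len(centers) % len(ring_radii_px)]
        phi = rng.uniform(-np.pi, np.pi)
        cf = c_f + radius * np.cos(phi)
        cs = c_s + radius * np.sin(phi)
        if not (margin <= cf < n_fast - margin
                and margin <= cs < n_slow - margin):
            continue
        if any((cf - f) ** 2 + (cs - s) ** 2 < min_sep ** 2
               for f, s in centers):
            continue
        centers.append((cf, cs))
    return np.asarray(centers)


def generate_sfx_frame(
    n_peaks: int = 30,
    ring_radii_px: tuple[float, ...] = (100.0, 200.0),
    peak_amplitude: float = 100.0,
    noise_sigma: float = 1.0,
    noise_mean: float = 10.0,
    saturation_level: float = 10000.0,
    n_saturated: int = 0,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    poisson: bool = False,
    water_ring: tuple[float, float, float] | None = None,
) -> tuple[DetectorFrame, SyntheticTruth]:
    """A crystallography-like frame: Gaussian blobs on noisy background.

    Peaks sit on the given rings at uniform random azimuths with a minimum
    separation of 6 px; the first ``n_saturated`` blobs are boosted and
    clipped at ``saturation_level``.  ``water_ring`` optionally adds a
    smooth azimuthally symmetric ring (radius, width, amplitude).
    """
    if n_saturated > n_peaks:
        raise ValueError("n_saturated cannot exceed n_peaks")
    rng = np.random.default_rng(seed)
    centers = (_place_on_rings(rng, shape, n_peaks, ring_radii_px)
               if n_peaks else np.empty((0, 2)))
    amplitudes = np.full(n_peaks, float(peak_amplitude))
    # saturated blobs: amplitude well beyond the clip level
    amplitudes[:n_saturated] = saturation_level * 2.0

    signal = _render_blobs(shape, centers, amplitudes, BLOB_SIGMA_PX)
    if water_ring is not None:
        r0, w, amp = water_ring
        n_slow, n_fast = shape
        ss = np.arange(n_slow)[:, None] - (n_slow - 1) / 2.0
        ff = np.arange(n_fast)[None, :] - (n_fast - 1) / 2.0
        rr = np.hypot(ss, ff)
        signal += amp * np.exp(-((rr - r0) ** 2) / (2 * w ** 2))
    if poisson:
        data = rng.poisson(np.maximum(signal + noise_mean, 0.0)).astype(float)
    else:
        data = signal + noise_mean + rng.normal(0.0, noise_sigma, shape)
    np.clip(data, None, saturation_level, out=data)

    # planted integrated intensity of an un-clipped blob (continuous sum)
    blob_integral = 2 * np.pi * BLOB_SIGMA_PX ** 2
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_peaks=n_peaks, ring_radii_px=list(ring_radii_px),
                    peak_amplitude=peak_amplitude, noise_sigma=noise_sigma,
                    noise_mean=noise_mean, saturation_level=saturation_level,
                    n_saturated=n_saturated, shape=list(shape)),
        peak_positions=centers,
        peak_intensities=amplitudes * blob_integral,
        n_saturated=n_saturated,
    )
    frame = DetectorFrame(data=data, timestamp=1.0, event_id=f"sfx-{seed}")
    return frame, truth


def generate_vmi_image(
    n_ions: int = 50,
    aligned_fraction: float = 0.5,
    spot_sigma: float = 1.5,
    spot_amplitude: float = 100.0,
    noise_sigma: float = 1.0,
    r_range: tuple[float, float] = (20.0, 90.0),
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """A VMI camera image of Gaussian ion spots with known emission angles.

    With probability ``aligned_fraction`` an ion lies exactly on the
    vertical axis (theta = 0); otherwise its angle is uniform, so the true
    expectation is E[cos^2 theta] = a + 0.5 (1 - a).
    """
    if not (0.0 <= aligned_fraction <= 1.0):
        raise ValueError("aligned_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aligned = rng.random(n_ions) < aligned_fraction
    # angle measured from the vertical (+y) axis, in (-pi, pi]
    theta = np.where(aligned, 0.0, rng.uniform(-np.pi, np.pi, n_ions))
    radii = rng.uniform(*r_range, n_ions)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    x = cx + radii * np.sin(theta)
    y = cy + radii * np.cos(theta)
    centers = np.column_stack([x, y])  # (fast=x, slow=y)
    img = _render_blobs(shape, centers, np.full(n_ions, spot_amplitude),
                        spot_sigma)
    img += rng.normal(0.0, noise_sigma, shape)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_ions=n_ions, aligned_fraction=aligned_fraction,
                    spot_sigma=spot_sigma, r_range=list(r_range),
                    shape=list(shape)),
        ion_angles_rad=theta,
        ion_positions=centers,
    )
    return img, truth


def generate_fiber_frame(
    ring_radius: float = 80.0,
    ring_width: float = 10.0,
    ring_amplitude: float = 50.0,
    streaks: tuple[tuple[float, float, float, float], ...] = (),
    noise_sigma: float = 1.0,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[DetectorFrame, SyntheticTruth]:
    """A fiber frame: azimuthally symmetric water ring plus radial streaks.

    Each streak is (azimuth_rad, r_min, r_max, amplitude): a one-pixel-wide
    radial segment of excess intensity.  Truth records the streak pixels
    and the planted excess per pixel.
    """
    rng = np.random.default_rng(seed)
    n_slow, n_fast = shape
    ss = np.arange(n_slow)[:, None] - (n_slow - 1) / 2.0
    ff = np.arange(n_fast)[None, :] - (n_fast - 1) / 2.0
    rr = np.hypot(ss, ff)
    data = ring_amplitude * np.exp(-((rr - ring_radius) ** 2)
                                   / (2 * ring_width ** 2))
    streak_pix: list[tuple[int, int]] = []
    streak_excess: list[float] = []
    for az, r0, r1, amp in streaks:
        for r in np.arange(r0, r1, 0.5):
            f = int(round((n_fast - 1) / 2.0 + r * np.cos(az)))
            s = int(round((n_slow - 1) / 2.0 + r * np.sin(az)))
            if 0 <= s < n_slow and 0 <= f < n_fast:
                if (s, f) not in streak_pix:
                    streak_pix.append((s, f))
    for s, f in streak_pix:
        amp = next(a for az, r0, r1, a in streaks
                   if r0 - 1 <= rr[s, f] <= r1 + 1)
        data[s, f] += amp
        streak_excess.append(amp)
    data += rng.normal(0.0, noise_sigma, shape)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(ring_radius=ring_radius, ring_width=ring_width,
                    ring_amplitude=ring_amplitude,
                    streaks=[list(s) for s in streaks], shape=list(shape)),
        streak_pixels=(np.asarray(streak_pix, dtype=np.intp)
                       if streak_pix else np.empty((0, 2), dtype=np.intp)),
        peak_intensities=np.asarray(streak_excess),
    )
    frame = DetectorFrame(data=data, timestamp=1.0, event_id=f"fiber-{seed}")
    return frame, truth


def write_cxi(
    path: str | os.PathLike,
    frames: np.ndarray,
    timestamps: np.ndarray,
    photon_energies: np.ndarray | None = None,
    detector_distance_mm: float | None = None,
    truth: SyntheticTruth | None = None,
    dataset_path: str = DEFAULT_DATA_PATH,
) -> None:
    """Write a (event, slow, fast) frame stack in the CXI/HDF5 layout the
    file backend reads, with optional ground-truth sidecar group."""
    frames = np.asarray(frames, dtype=np.float32)
    with h5py.File(path, "w") as fh:
        fh.create_dataset(dataset_path, data=frames)
        fh.create_dataset(TIMESTAMP_PATH, data=np.asarray(timestamps,
                                                          dtype=np.float64))
        if photon_energies is not None:
            fh.create_dataset(PHOTON_ENERGY_PATH,
                              data=np.asarray(photon_energies))
        if detector_distance_mm is not None:
            fh.create_dataset(DETECTOR_DISTANCE_PATH,
                              data=np.full(len(frames), detector_distance_mm))
        if truth is not None:
            grp = fh.create_group("truth")
            grp.attrs["seed"] = truth.seed
            if truth.hit_flags is not None:
                grp.create_dataset("hit_flags", data=truth.hit_flags)
            if truth.corrupt_flags is not None:
                grp.create_dataset("corrupt_flags", data=truth.corrupt_flags)
            if truth.timestamps is not None:
                grp.create_dataset("timestamps", data=truth.timestamps)


def generate_event_stream(
    path: str | os.PathLike,
    n_events: int = 1000,
    hit_fraction: float = 0.3,
    corrupt_fraction: float = 0.0,
    rate_hz: float = 120.0,
    min_peaks: int = 10,
    shape: tuple[int, int] = (128, 128),
    ring_radii_px: tuple[float, ...] = (25.0, 35.0, 45.0, 55.0),
    peak_amplitude: float = 100.0,
    noise_sigma: float = 1.0,
    t0: float = 1.0e9,
    seed: int = 0,
) -> SyntheticTruth:
    """Write a CXI event stream with known hit and corrupt fractions.

    Hit events carry frames with at least ``min_peaks`` planted peaks,
    misses carry pure noise.  Corrupt events stand in for truncated records:
    their frame slice is unreadable as data (all-NaN), and the reader flags
    them.  Timestamps increase strictly at 1/rate_hz from ``t0``.
    """
    rng = np.random.default_rng(seed)
    hit_flags = rng.random(n_events) < hit_fraction
    corrupt_flags = rng.random(n_events) < corrupt_fraction
    timestamps = t0 + np.arange(n_events) / rate_hz
    frames = np.empty((n_events, *shape), dtype=np.float32)
    peaks_per_event: list[np.ndarray | None] = []
    for i in range(n_events):
        if corrupt_flags[i]:
            frames[i] = np.nan
            peaks_per_event.append(None)
            continue
        # hits carry a cushion above the classification threshold so a
        # single marginal blob merge cannot flip the label
        n_pk = (int(min_peaks + 2 + rng.integers(0, min_peaks))
                if hit_flags[i] else 0)
        frame, ftruth = generate_sfx_frame(
            n_peaks=n_pk, ring_radii_px=ring_radii_px,
            peak_amplitude=peak_amplitude, noise_sigma=noise_sigma,
            shape=shape, seed=int(rng.integers(0, 2 ** 31 - 1)))
        frames[i] = frame.data.astype(np.float32)
        peaks_per_event.append(ftruth.peak_positions)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_events=n_events, hit_fraction=hit_fraction,
                    corrupt_fraction=corrupt_fraction, rate_hz=rate_hz,
                    min_peaks=min_peaks, shape=list(shape)),
        hit_flags=hit_flags,
        corrupt_flags=corrupt_flags,
        timestamps=timestamps,
        peaks_per_event=peaks_per_event,
    )
    write_cxi(path, frames, timestamps, truth=truth)
    return truth
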