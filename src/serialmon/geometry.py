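"""Detector geometry, per-pixel coordinate maps and frame corrections.

A detector is described by one or more flat rectangular panels lying in a
plane perpendicular to the beam.  Each panel occupies a block of rows of the
assembled 2-D data array (the "slab" layout used by CSPAD-style detectors)
and carries its own position and orientation in the laboratory frame.

Conventions (fixed so that centroid, azimuth and polarization arithmetic are
exact and testable):

* pixel centers sit at integer coordinates, index origin 0;
* the panel corner position refers to the *center* of the panel's first
  pixel (fast index 0, slow index 0), in pixel units relative to the point
  where the beam axis pierces the detector plane;
* azimuth is measured counter-clockwise from the +x (horizontal) axis and
  lies in (-pi, pi];
* scattering angle uses the exact form two_theta = atan(r / D).

Geometry files are a strict subset of the CrystFEL ``.geom`` dialect: global
``clen`` (m), ``res`` (pixels per metre) and optional ``photon_energy`` (eV),
then per-panel ``min_fs/max_fs/min_ss/max_ss``, ``corner_x/corner_y`` (pixel
units) and ``fs``/``ss`` direction vectors such as ``+1.0x +0.0y``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PanelSpec",
    "GeometrySpec",
    "PixelMaps",
    "DetectorFrame",
    "GeometryError",
    "build_pixel_maps",
    "apply_corrections",
    "resolution_at_radius",
    "parse_geom",
    "load_geom",
    "format_geom",
    "single_panel_geometry",
]


class GeometryError(ValueError):
    """Raised for invalid or inconsistent geometry descriptions."""


@dataclass(frozen=True)
class PanelSpec:
    """One flat rectangular panel.

    ``corner_x`` / ``corner_y`` locate the center of pixel (fs=0, ss=0) in
    pixel units relative to the beam axis.  ``fs_vec`` and ``ss_vec`` are
    unit direction vectors of the fast- and slow-scan axes in the detector
    plane (lab x, y components).
    """

    panel_id: str
    n_fast: int
    n_slow: int
    corner_x: float
    corner_y: float
    fs_vec: tuple[float, float] = (1.0, 0.0)
    ss_vec: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1:
            raise GeometryError(
                f"panel {self.panel_id!r}: n_fast and n_slow must be >= 1"
            )
        for name, v in (("fs", self.fs_vec), ("ss", self.ss_vec)):
            norm = math.hypot(*v)
            if not math.isclose(norm, 1.0, rel_tol=1e-6):
                raise GeometryError(
                    f"panel {self.panel_id!r}: {name} vector {v} is not unit length"
                )
        cross = (self.fs_vec[0] * self.ss_vec[1]
                 - self.fs_vec[1] * self.ss_vec[0])
        if abs(cross) < 1e-9:
            raise GeometryError(
                f"panel {self.panel_id!r}: fs and ss vectors are collinear"
            )


@dataclass(frozen=True)
class GeometrySpec:
    """A multi-panel detector: panels stacked row-wise in the data array."""

    panels: tuple[PanelSpec, ...]
    pixel_size_mm: float
    detector_distance_mm: float
    photon_energy_ev: float | None = None

    def __post_init__(self) -> None:
        if not self.panels:
            raise GeometryError("geometry needs at least one panel")
        if self.pixel_size_mm <= 0:
            raise GeometryError("pixel_size_mm must be > 0")
        if self.detector_distance_mm <= 0:
            raise GeometryError("detector_distance_mm must be > 0")
        widths = {p.n_fast for p in self.panels}
        if len(widths) != 1:
            raise GeometryError(
                "all panels must share n_fast in the slab layout "
                f"(got widths {sorted(widths)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Assembled (slow, fast) shape of the data array."""
        return (sum(p.n_slow for p in self.panels), self.panels[0].n_fast)

    def rotated_180(self) -> "GeometrySpec":
        """The same detector rotated half a turn about the beam axis."""
        flipped = tuple(
            replace(
                p,
                corner_x=-p.corner_x,
                corner_y=-p.corner_y,
                fs_vec=(-p.fs_vec[0], -p.fs_vec[1]),
                ss_vec=(-p.ss_vec[0], -p.ss_vec[1]),
            )
            for p in self.panels
        )
        return replace(self, panels=flipped)


@dataclass(frozen=True)
class PixelMaps:
    """Per-pixel coordinate maps over the assembled frame shape."""

    radius_px: np.ndarray
    azimuth_rad: np.ndarray
    panel_id: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.radius_px.shape


@dataclass
class DetectorFrame:
    """One event's intensity grid plus beam metadata.

    ``valid`` marks pixels usable by downstream statistics; masked pixels
    are excluded, never zeroed.
    """

    data: np.ndarray
    timestamp: float
    event_id: str = ""
    photon_energy_ev: float | None = None
    detector_distance_mm: float | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2-D")
        if self.timestamp <= 0:
            raise ValueError("timestamp must be > 0")
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError(
                    f"valid mask shape {self.valid.shape} != data shape "
                    f"{self.data.shape}"
                )


def _panel_corners_px(panel: PanelSpec) -> np.ndarray:
    """Lab xy (pixel units) of the four extreme pixel centers of a panel."""
    fx, fy = panel.fs_vec
    sx, sy = panel.ss_vec
    pts = []
    for jf in (0, panel.n_fast - 1):
        for js in (0, panel.n_slow - 1):
            pts.append((panel.corner_x + jf * fx + js * sx,
                        panel.corner_y + jf * fy + js * sy))
    return np.asarray(pts)


def _check_overlap(panels: Sequence[PanelSpec]) -> None:
    boxes = []
    for p in panels:
        c = _panel_corners_px(p)
        boxes.append((c[:, 0].min() - 0.5, c[:, 0].max() + 0.5,
                      c[:, 1].min() - 0.5, c[:, 1].max() + 0.5, p.panel_id))
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            a, b = boxes[i], boxes[j]
            if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                raise GeometryError(
                    f"panels {a[4]!r} and {b[4]!r} overlap in the detector plane"
                )


def build_pixel_maps(geom: GeometrySpec) -> PixelMaps:
    """Per-pixel radius, azimuth, panel index and lab coordinates.

    Raises :class:`GeometryError` when panels overlap in the lab plane.
    """
    _check_overlap(geom.panels)
    n_slow, n_fast = geom.shape
    x_px = np.empty((n_slow, n_fast))
    y_px = np.empty((n_slow, n_fast))
    pid = np.empty((n_slow, n_fast), dtype=np.int32)
    row = 0
    for idx, p in enumerate(geom.panels):
        jf = np.arange(p.n_fast)
        js = np.arange(p.n_slow)[:, None]
        x_px[row:row + p.n_slow] = (p.corner_x
                                    + jf * p.fs_vec[0] + js * p.ss_vec[0])
        y_px[row:row + p.n_slow] = (p.corner_y
                                    + jf * p.fs_vec[1] + js * p.ss_vec[1])
        pid[row:row + p.n_slow] = idx
        row += p.n_slow
    radius = np.hypot(x_px, y_px)
    azimuth = np.arctan2(y_px, x_px)
    # arctan2 returns [-pi, pi]; fold -pi onto +pi for the half-open interval
    azimuth[azimuth == -np.pi] = np.pi
    ps = geom.pixel_size_mm
    return PixelMaps(radius_px=radius, azimuth_rad=azimuth, panel_id=pid,
                     x_mm=x_px * ps, y_mm=y_px * ps)


def apply_corrections(
    frame: DetectorFrame,
    mask: np.ndarray | None = None,
    gain_map: np.ndarray | None = None,
) -> DetectorFrame:
    """Apply a bad-pixel mask and/or per-pixel gain to a frame.

    ``mask`` follows the usual convention: nonzero = keep, 0 = reject.
    Masked pixels become invalid for all downstream statistics; unmasked
    pixel values are multiplied by the gain.  Mask-only application is
    idempotent.
    """
    data = frame.data
    valid = frame.valid.copy()
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != data.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match frame shape {data.shape}"
            )
        valid &= mask != 0
    if gain_map is not None:
        gain_map = np.asarray(gain_map, dtype=np.float64)
        if gain_map.shape != data.shape:
            raise ValueError(
                f"gain map shape {gain_map.shape} does not match frame shape "
                f"{data.shape}"
            )
        data = np.where(valid, data * gain_map, data)
    else:
        data = data.copy()
    return DetectorFrame(
        data=data,
        timestamp=frame.timestamp,
        event_id=frame.event_id,
        photon_energy_ev=frame.photon_energy_ev,
        detector_distance_mm=frame.detector_distance_mm,
        valid=valid,
    )


def resolution_at_radius(
    radius_px: float | np.ndarray,
    pixel_size_mm: float,
    distance_mm: float,
    wavelength_a: float,
) -> float | np.ndarray:
    """Bragg d-spacing (angstrom) of pixels at a given radius.

    Uses the exact scattering angle 2*theta = atan(r * pixel / D) and
    d = lambda / (2 sin theta).  Radius 0 (forward scattering) maps to the
    +infinity sentinel.
    """
    if distance_mm <= 0:
        raise ValueError("detector distance must be > 0")
    if wavelength_a <= 0:
        raise ValueError("wavelength must be > 0")
    r = np.asarray(radius_px, dtype=np.float64)
    two_theta = np.arctan(r * pixel_size_mm / distance_mm)
    with np.errstate(divide="ignore"):
        d = wavelength_a / (2.0 * np.sin(two_theta / 2.0))
    d = np.where(r == 0, np.inf, d)
    if np.isscalar(radius_px) or np.ndim(radius_px) == 0:
        return float(d)
    return d


# --- .geom subset reading / writing -------------------------------------

_VEC_RE = re.compile(r"([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\s*([xy])")


def _parse_vector(text: str, where: str) -> tuple[float, float]:
    comps = {"x": 0.0, "y": 0.0}
    found = _VEC_RE.findall(text)
    if not found:
        raise GeometryError(f"cannot parse direction vector {text!r} in {where}")
    for value, axis in found:
        comps[axis] = float(value)
    return (comps["x"], comps["y"])


def parse_geom(text: str) -> GeometrySpec:
    """Parse a geometry description in the supported ``.geom`` subset."""
    globals_: dict[str, float] = {}
    panels: dict[str, dict[str, object]] = {}
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise GeometryError(f"malformed geometry line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if "/" in key:
            pname, prop = key.split("/", 1)
            panels.setdefault(pname, {})[prop] = value
        else:
            globals_[key] = float(value)
    if "clen" not in globals_:
        raise GeometryError("geometry is missing the global 'clen' (metres)")
    if "res" not in globals_:
        raise GeometryError("geometry is missing the global 'res' (pixels/metre)")
    pixel_size_mm = 1000.0 / globals_["res"]
    distance_mm = globals_["clen"] * 1000.0
    energy = globals_.get("photon_energy")

    specs = []
    for pname in panels:  # dict preserves stanza order
        p = panels[pname]
        try:
            n_fast = int(p["max_fs"]) - int(p["min_fs"]) + 1  # type: ignore[arg-type]
            n_slow = int(p["max_ss"]) - int(p["min_ss"]) + 1  # type: ignore[arg-type]
            corner_x = float(p["corner_x"])  # type: ignore[arg-type]
            corner_y = float(p["corner_y"])  # type: ignore[arg-type]
        except KeyError as exc:
            raise GeometryError(f"panel {pname!r} is missing {exc.args[0]!r}")
        fs_vec = _parse_vector(str(p.get("fs", "+1.0x +0.0y")), pname)
        ss_vec = _parse_vector(str(p.get("ss", "+0.0x +1.0y")), pname)
        specs.append(PanelSpec(pname, n_fast, n_slow, corner_x, corner_y,
                               fs_vec, ss_vec))
    return GeometrySpec(tuple(specs), pixel_size_mm, distance_mm, energy)


def load_geom(path) -> GeometrySpec:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_geom(fh.read())


def format_geom(geom: GeometrySpec) -> str:
    lines = [
        f"clen = {geom.detector_distance_mm / 1000.0:.9g}",
        f"res = {1000.0 / geom.pixel_size_mm:.9g}",
    ]
    if geom.photon_energy_ev is not None:
        lines.append(f"photon_energy = {geom.photon_energy_ev:.9g}")
    lines.append("")
    row = 0
    for p in geom.panels:
        lines += [
            f"{p.panel_id}/min_fs = 0",
            f"{p.panel_id}/max_fs = {p.n_fast - 1}",
            f"{p.panel_id}/min_ss = {row}",
            f"{p.panel_id}/max_ss = {row + p.n_slow - 1}",
            f"{p.panel_id}/corner_x = {p.corner_x:.9g}",
            f"{p.panel_id}/corner_y = {p.corner_y:.9g}",
            f"{p.panel_id}/fs = {p.fs_vec[0]:+.6f}x {p.fs_vec[1]:+.6f}y",
            f"{p.panel_id}/ss = {p.ss_vec[0]:+.6f}x {p.ss_vec[1]:+.6f}y",
            "",
        ]
        row += p.n_slow
    return "\n".join(lines)


def single_panel_geometry(
    n: int = 512,
    pixel_size_mm: float = 0.1,
    distance_mm: float = 100.0,
    photon_energy_ev: float | None = 9000.0,
) -> GeometrySpec:
    """A beam-centered square single-panel detector (the default toy geometry)."""
    half = (n - 1) / 2.0
    panel = PanelSpec("panel0", n, n, -half, -half)
    return GeometrySpec((panel,), pixel_size_mm, distance_mm, photon_energy_ev)
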