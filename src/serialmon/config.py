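"""Plain-text monitor configuration.

All monitor options live in one INI-style file with the sections the
monitors document: ``[peakfinder]``, ``[hit]``, ``[saturation]``,
``[averages]`` for the SFX monitor; ``[vmi]``; ``[fiber]``; plus
``[engine]`` and ``[source]`` for the run itself.  Values are coerced to
int/float/bool where they look like one; comma-separated values become
lists.  Unknown sections and keys are preserved (monitors validate what
they actually consume).
"""

from __future__ import annotations

import configparser
from typing import Any

from .peaks import PeakSearchParams

__all__ = ["load_config", "parse_config", "peak_params_from_config"]


def _coerce(value: str) -> Any:
    text = value.strip()
    low = text.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    if "," in text:
        return [_coerce(part) for part in text.split(",") if part.strip()]
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def parse_config(text: str) -> dict[str, dict[str, Any]]:
    parser = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    parser.read_string(text)
    return {section: {key: _coerce(value)
                      for key, value in parser.items(section)}
            for section in parser.sections()}


def load_config(path) -> dict[str, dict[str, Any]]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config(fh.read())


def peak_params_from_config(cfg: dict[str, dict[str, Any]]
                            ) -> PeakSearchParams:
    """Build peak-search parameters from the ``[peakfinder]`` section."""
    pf = cfg.get("peakfinder", {})
    defaults = PeakSearchParams()
    return PeakSearchParams(
        snr_min=float(pf.get("snr_min", defaults.snr_min)),
        intensity_min=float(pf.get("intensity_min", defaults.intensity_min)),
        pixel_count_min=int(pf.get("pixel_count_min",
                                   defaults.pixel_count_min)),
        pixel_count_max=int(pf.get("pixel_count_max",
                                   defaults.pixel_count_max)),
        max_peaks=int(pf.get("max_peaks", defaults.max_peaks)),
        radial_bin_px=float(pf.get("radial_bin_px", defaults.radial_bin_px)),
        clip_sigma=float(pf.get("clip_sigma", defaults.clip_sigma)),
        clip_iterations=int(pf.get("clip_iterations",
                                   defaults.clip_iterations)),
    )
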