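"""Reveal fiber-diffraction streaks under a dominant water-ring background.

Builds a synthetic fiber frame — an azimuthally symmetric ring from the
liquid jet plus two faint diffraction streaks — applies the polarization
correction and subtracts the mean of each resolution ring.  The ring
cancels almost exactly while the planted streaks survive.
"""

import numpy as np

from serialmon.geometry import build_pixel_maps, single_panel_geometry
from serialmon.monitors.fiber import (panel_sums, polarization_correct,
                                      radial_background_subtract)
from serialmon.synth import generate_fiber_frame

geom = single_panel_geometry(256)
maps = build_pixel_maps(geom)

streaks = ((0.7, 60.0, 110.0, 30.0), (2.3, 60.0, 110.0, 30.0))
frame, truth = generate_fiber_frame(ring_radius=80.0, ring_width=10.0,
                                    ring_amplitude=50.0, streaks=streaks,
                                    noise_sigma=1.0, shape=(256, 256),
                                    seed=5)

corrected = polarization_correct(frame, maps, polarization_fraction=0.99,
                                 pixel_size_mm=geom.pixel_size_mm,
                                 distance_mm=geom.detector_distance_mm)
residual = radial_background_subtract(corrected, maps.radius_px, bin_px=1.0)

ring = np.abs(maps.radius_px - 80.0) < 5.0
s, f = truth.streak_pixels[:, 0], truth.streak_pixels[:, 1]
off_streak = ring.copy()
off_streak[s, f] = False

print(f"ring mean before subtraction   {frame.data[ring].mean():8.2f} counts")
print(f"ring mean after subtraction    "
      f"{residual.data[off_streak].mean():8.3f} counts")
print(f"planted streak excess          "
      f"{truth.peak_intensities.sum():8.0f} counts")
print(f"retained streak excess         {residual.data[s, f].sum():8.0f} counts"
      f"  ({residual.data[s, f].sum() / truth.peak_intensities.sum():.1%})")
print(f"panel sums (counts)            "
      f"{ {k: round(v) for k, v in panel_sums(corrected, maps.panel_id).items()} }")
# The off-streak residual hovers near zero (the radial model removed the
# water ring) while the streaks keep well over 90% of their excess counts.
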