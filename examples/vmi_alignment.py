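"""Measure molecular alignment from velocity-map-imaging camera frames.

Renders ion-impact images from a known angular mixture (60% of ions exactly
along the vertical alignment-laser axis, the rest uniform) and recovers
<cos^2 theta> through the full pipeline: spot detection, center-of-mass
centroiding, registration, wedge filtering and angular statistics.  The
expected value is a + 0.5 (1 - a) = 0.8 for a = 0.6.
"""

import numpy as np

from serialmon.monitors.vmi import WedgeRegion, build_vmi_pipeline
from serialmon.sources import ExtractedData
from serialmon.synth import generate_vmi_image

a = 0.6
shape = (128, 128)
center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
wedge = WedgeRegion(half_width_deg=90.0, r_min=1.0, r_max=100.0)
pipeline, state = build_vmi_pipeline(shape, intensity_threshold=20.0,
                                     wedge=wedge, translation=center,
                                     accumulation_events=2000,
                                     broadcast_every=100)

agg = None
for i in range(2000):
    image, _ = generate_vmi_image(n_ions=1, aligned_fraction=a,
                                  r_range=(10.0, 50.0), shape=shape,
                                  seed=40_000 + i)
    result = pipeline.process_fn(ExtractedData(raw_data=image,
                                               event_timestamp=float(i + 1)))
    latest = pipeline.collect_fn(result)
    agg = latest if latest is not None else agg

expected = a + 0.5 * (1 - a)
print(f"ions included        {agg['n_ions']}")
print(f"<cos^2 theta>        {agg['cos2_mean']:.4f}")
print(f"expected             {expected:.4f}")
print(f"mean |theta|         {agg['theta_mean_deg']:.2f} deg")
# cos2_mean near 0.8 confirms the pipeline recovers the planted degree of
# alignment; 1.0 would be perfect alignment, 0.5 an isotropic distribution.
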