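import numpy as np
import pytest

from serialmon.geometry import (GeometrySpec, PanelSpec, build_pixel_maps,
                                single_panel_geometry)
from serialmon.peaks import PeakSearchParams


@pytest.fixture(scope="session")
def geom128():
    return single_panel_geometry(128)


@pytest.fixture(scope="session")
def maps128(geom128):
    return build_pixel_maps(geom128)


@pytest.fixture(scope="session")
def geom3x3():
    """A 3x3 single panel whose central pixel sits on the beam axis."""
    panel = PanelSpec("p0", 3, 3, -1.0, -1.0)
    return GeometrySpec((panel,), pixel_size_mm=1.0, detector_distance_mm=100.0)


@pytest.fixture(scope="session")
def stream_peak_params():
    """Peak-search settings used throughout for the 128 px synthetic frames."""
    return PeakSearchParams(snr_min=8.0, intensity_min=15.0,
                            pixel_count_min=2, pixel_count_max=60)
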