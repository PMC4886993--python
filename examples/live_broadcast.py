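"""Broadcast aggregates to a detached viewer over TCP.

Runs a small SFX monitor with a publisher attached and a headless
subscriber connected from "outside".  The subscriber can attach or vanish
at any time without affecting the monitor; each received snapshot is
complete, so a viewer joining mid-run renders full state immediately.
"""

import tempfile
import threading
import time

from serialmon.broadcast import Publisher, Subscriber
from serialmon.engine import run_monitor
from serialmon.geometry import single_panel_geometry
from serialmon.monitors.sfx import build_sfx_pipeline
from serialmon.peaks import PeakSearchParams
from serialmon.sources import file_list_source
from serialmon.synth import generate_event_stream

publisher = Publisher()  # binds an ephemeral localhost port
host, port = publisher.address
print(f"publishing on {host}:{port}")

received = []


def viewer():
    sub = Subscriber(host, port)
    try:
        while len(received) < 5:
            received.append(sub.recv())
    finally:
        sub.close()


thread = threading.Thread(target=viewer, daemon=True)
thread.start()

with tempfile.NamedTemporaryFile(suffix=".cxi") as tmp:
    # stamp events with the current wall time so the delay estimate reads
    # like a live run rather than a replay of an old file
    generate_event_stream(tmp.name, n_events=60, hit_fraction=0.4,
                          t0=time.time(), seed=2)
    geom = single_panel_geometry(128)
    params = PeakSearchParams(snr_min=8.0, intensity_min=15.0,
                              pixel_count_min=2, pixel_count_max=60)
    pipeline, state = build_sfx_pipeline(geom, peak_params=params,
                                         min_peaks_for_hit=10)
    report = run_monitor(file_list_source([tmp.name]), pipeline,
                         n_workers=2, publisher=publisher)

thread.join(timeout=5.0)
publisher.close()

print(f"monitor processed {report.processed} events, "
      f"broadcast {report.broadcasts} snapshots")
print(f"viewer received {len(received)} snapshots before detaching")
last = received[-1]
print(f"last snapshot: hit rate {last['hit_rate']:.2f}, "
      f"powder grid {last['powder'].shape}, delay {last['delay_s']:.3f} s")
# The delay is wall time minus the event timestamp; with live timestamps
# it is the end-to-end latency from "data taken" to "result displayed".
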