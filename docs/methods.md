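# Methods

This note records the models, conventions and numerical choices behind
`serialmon`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real detector data.

## Streaming model

A monitor is three functions. `extract_fn` (workers) pulls named properties
out of an event — at minimum the raw frame and its timestamp — and raises a
skip signal on corrupted or incomplete payloads. `process_fn` (workers)
reduces one event to a flat, self-contained key-value record. `collect_fn`
(master) is the only holder of cross-event state; it is called once per
received record and returns the aggregate snapshot to broadcast, or None.
Records are discarded after collection unless the collector retains derived
state, so master memory is bounded by the aggregates, not the stream.

The engine runs the roles as threads under a message-passing contract
(worker results travel over a queue to the master, exactly as records would
travel over an interconnect in a multi-node deployment). This keeps every
observable property — per-event dispatch, skip/drop accounting, crash
survival, serial equivalence — testable in a plain process. Worker death is
detected by liveness polling of the worker threads; a crashed worker simply
stops contributing and the master finishes with the survivors' results. The
poll interval (`poll_s`, default 50 ms) plays the role a heartbeat timeout
plays across machines.

**Stale-event skipping.** Each worker owns a drop-oldest backlog of
configurable depth (default 4 events/worker; the policy is what matters,
the depth is a tuning knob). When events arrive faster than processing, the
oldest pending events are dropped and counted, and the worker always takes
the oldest *retained* event, so processing order is preserved within the
capacity window. The engine logs, for every processed event, the newest
arrival index known at selection time; the freshness guarantee
`newest − selected ≤ capacity` is asserted directly in tests. With
unbounded capacity the engine processes every fetched event, and the
multiset of its frame results equals a single-threaded reference run —
checked on 1000-event streams.

**Conservation.** For every run,
`fetched = processed + skipped(corrupt) + dropped(stale) (+ lost when a
worker dies with events still queued)`. The lost term is reported, never
silently absorbed.

**Broadcast.** Aggregates go out over TCP as length-prefixed JSON;
dense grids are tagged objects carrying dtype, shape and base64 raw bytes,
so one-platform round trips are bit-exact (cross-platform bit-exactness is
not promised). Each subscriber has a bounded outgoing queue drained by its
own sender thread; a slow or dead subscriber loses its oldest snapshots,
never the master's time. Every snapshot is complete: a viewer attaching
mid-run renders full state from its first message.

## Detector geometry

Flat rectangular panels, all perpendicular to the beam, stacked row-wise in
the assembled array (the slab layout of CSPAD-style detectors; all panels
share the fast-axis width). Conventions, declared rather than inherited
from any instrument: pixel centers at integer coordinates with index origin
0; the per-panel corner position names the *center* of pixel (0,0) in pixel
units relative to the beam axis; azimuth counter-clockwise from +x in
(−π, π]. Geometry files are a strict subset of the CrystFEL `.geom` dialect
(`clen`, `res`, per-panel `min_fs/max_fs/min_ss/max_ss`, `corner_x/y`,
`fs`/`ss` vectors), which keeps single-panel toy cases one stanza long.
Masked pixels are *excluded* from every statistic, never zeroed — zeroing
would bias radial means downward. Resolution uses the exact
`2θ = atan(r·pixel/D)` (no small-angle shortcut; it costs nothing), and
`d = λ / 2 sin θ`, with radius 0 reported as infinite d. Tilted or curved
panels and solid-angle corrections are out of scope.

## Peak detection

The background model is purely radial: per-1-px-annulus mean and standard
deviation over valid pixels, after 2 rounds of one-sided 3σ clipping
(bright outliers — the peaks — are rejected; the low side never is). A pixel
is an eligible seed when its value exceeds both `μ_r + snr_min·σ_r` and an
absolute floor `intensity_min`; in degenerate zero-spread bins the
threshold is `μ_r + intensity_min`. Candidates are 8-connected components
of eligible pixels, size-filtered, ranked by integrated intensity
(ties broken by (slow, fast) seed order) and truncated to `max_peaks`.

Per-peak quantities: `integrated_intensity` and `max_pixel` are raw sums
and maxima over the component (so `max_pixel ≤ integrated_intensity`
always, and adding a constant c to the frame shifts intensities by exactly
c·n_pixels while leaving the detected set unchanged — the radial model
absorbs c); the centroid is the background-subtracted intensity-weighted
mean position; SNR is `(max − μ_r)/σ_r` at the seed's bin. Saturation uses
`max_pixel ≥ threshold` — the max pixel is the dynamic-range quantity — and
a frame counts toward the saturation rate only when *strictly more than
three* peaks are saturated. Local annulus background refinement around each
peak is deliberately omitted; the radial model is the only background. The
clipping defaults fail gracefully but visibly when blobs occupy a large
fraction of a thin ring (heavily contaminated bins keep inflated σ and
suppress detection there); realistic peak densities per annulus avoid this.

## SFX aggregation

Hit iff `n_peaks ≥ min_peaks_for_hit` (inclusive boundary, configurable).
Running averages are plain unweighted moving means over the most recent
`window` indicators, warming up over the first window. The virtual powder
adds each peak's integrated intensity at the pixel nearest its centroid
(half-up rounding, (slow, fast) order); a per-peak count mode would be a
one-line switch but intensity accumulation is closest to what a powder
pattern means. The saturation rate's denominator is all processed frames
("fraction of shots"), not hits only. The delay estimate is
`max(now − latest event timestamp, 0)`; on monotone synthetic streams it is
non-negative by construction, and a missing timestamp reports as unknown
rather than negative.

## VMI statistics

Spots are 8-connected components above an intensity threshold, centroided
by center of mass over their above-threshold pixels. Registration is
translate-then-rotate: `p' = R(α)(p − t)`, rotation counter-clockwise, with
the screen center (plus any interaction-point offset) supplied as the
translation. The wedge filter keeps positions with radius in
`[r_min, r_max]` and angle from the vertical axis within the half-width;
the two-fold flag includes the mirror wedge (angle measured from the nearer
vertical half-axis via |y|). θ is defined from the vertical axis with
`cos θ = |y|/r`, and the monitor reports the *mean* |θ| and the mean cos²θ,
unweighted over spots (intensity weighting is a config switch). Zero-radius
spots carry no direction and are excluded; an empty accumulation reports
NaN and the stream continues. Statistics are recomputed over a sliding
block of the configured number of events each time a snapshot is broadcast.

Exactly coincident ions merge into one detected spot. Merging on the
alignment axis does not move ⟨cos²θ⟩, but at high per-frame densities it
thins the aligned component relative to the uniform one; the recovery tests
therefore plant one ion per event when they need the 10⁴-spot statistic to
be bias-free at the three-standard-error level.

## Fiber monitor

The polarization factor assumes Thomson dipole scattering with a fraction
`p` (default 0.99, typical of an FEL's horizontal polarization) along +x:
`P = p(1 − sin²2θ cos²φ) + (1−p)(1 − sin²2θ sin²φ)`. Pixels with `P` below
10⁻³ are invalidated rather than amplified. Correction precedes ring-mean
estimation; ring means for subtraction use *no* sigma clipping by default
(the background of interest is the mean signal itself; clipping is
available by config for streak-heavy data). Subtraction is exact (zero
residual) on bin-wise-constant radial images and retains planted streak
intensity to within the noise. Per-panel sums run over valid pixels only;
panel selection is validated against the geometry at startup. Frame
integration uses a rolling window of exactly 1000 frames by default (a
circular buffer storing float32 contributions, so the running sum is exact
with respect to what was added; "hold" mode stops at capacity instead).
Fiber hits reuse the SFX hit classifier on residual-frame peaks.

## Synthetic data

Every generator is a pure function of (parameters, seed). SFX frames plant
Gaussian blobs (σ = 1.2 px) at given ring radii with uniform random azimuth
and ≥ 6 px separation, on Gaussian noise (mean 10, σ 1 counts by default;
Poisson mode available — Gaussian is the default because it gives
closed-form SNR for the planted peaks). Saturated blobs are boosted and
clipped at the saturation level. VMI images draw each ion exactly vertical
with probability `a`, otherwise at a uniform angle, so
`E[cos²θ] = a + 0.5(1−a)`; radii are uniform in a configurable annulus.
Fiber frames are a Gaussian-profile ring plus one-pixel-wide radial streak
segments with recorded pixels and excesses. Event streams are written as
CXI/HDF5 stacks (`/entry_1/data_1/data`, with per-event timestamps and
optional photon energies in an `/LCLS`-style group and ground truth in a
`/truth` sidecar); hit events carry frames with at least the hit
threshold's worth of planted peaks plus a two-peak cushion so a single
marginal blob merge cannot flip a label, misses are pure noise, and
timestamps increase strictly at the configured repetition rate (120 Hz
default). "Corrupted" events stand in for truncated records: their slice
is written all-NaN and the extractor flags any non-finite frame as corrupt.

Problem sizes: streams default to 1000 events of single-panel 128×128
frames with peaks on rings at 25–55 px — statistically equivalent to larger
detectors for every property measured here, since all statistics are per
annulus or per event. Single-frame generators default to 512×512; a 2×2
quad geometry exercises multi-panel logic.

What the synthetic data does *not* emulate: real crystal diffraction
(no structure factors or Ewald geometry), detector artifacts (common-mode
noise, hot pixels, panel gain drift), jet-background structure beyond a
smooth ring, or facility data sources (the psana and beamline stream
backends are replaced by file replay and synthesis; CBF reading is stubbed
unimplemented). Passing tests therefore certify the *reduction machinery* —
background modelling, detection, statistics, streaming semantics — under
known truth, not end-to-end performance on any particular instrument.

## Numerical details and edge cases

- Sigma-clip iteration stops early when no pixel is rejected; final
  statistics always reflect the surviving pixel set exactly.
- Empty streams, blank frames, fully masked frames and empty accumulations
  all produce well-defined "nothing" results (empty lists, NaN statistics,
  invalid bins) rather than errors.
- Timestamps are epoch-scale doubles: spacings are exact only to ~10⁻⁷ s,
  which bounds how finely the delay estimate and rate checks can resolve.
- Powder rounding uses floor(x + 0.5) (half-up) for determinism across
  platforms rather than banker's rounding.
- Generic HDF5 files without timestamps fall back to file mtime plus the
  event index at a nominal rate (default 120 Hz) so delay estimation always
  has an input; the resulting delays measure file age, not pipeline latency.
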